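# Methods

## Problem setting

Validation studies of self-reported physical activity compare two
questionnaires — the 49-item long-form International Physical Activity
Questionnaire (IPAQ) and the 16-item Modified Active Australia Survey
(MAAS), both asking about the preceding 7 days — against a body-worn
monitor that records metabolic equivalents (MET) minute by minute over
a week of wear. The comparison needs three ingredients the raw data do
not directly provide: bouts (questionnaires only ask about activity
sustained ≥ 10 min), wear-time filtering (off-body minutes must not
count as inactivity), and a common weekly scale (MET-min/week). This
package implements that reduction and the agreement statistics on top
of it.

## Bout blocking

A minute is *active* at MET ≥ 3.3 and a *rest* below it. A candidate
window of contiguous, on-body minutes is a valid block iff

1. it spans at least 10 minute readings (the inclusive reading count;
   the duration convention is configurable),
2. its first and last minutes are active,
3. ≥ 80 % of minutes are active if the window is ≤ 15 min,
4. ≥ 75 % if longer,
5. interior rest runs are ≤ 2 min for windows ≤ 15 min,
6. ≤ 3 min for longer windows,
7. windows of 30–60 min (inclusive) may carry **one** rest run of
   exactly 4 min,
8. windows > 60 min may carry **two**,
9. rests of 5+ minutes always invalidate.

The 4-minute allowance *replaces* the cap for the allowed runs only;
all other runs still obey the base cap. Boundary readings: a 15-minute
window uses the short-block rules, 30 and 60 both fall in the one-rest
band, and "80 % must be ≥ 3.3" is satisfied at exactly 80 %.

**Block search.** Within each contiguous on-body segment the package
enumerates every valid window by an incremental forward scan (a rest
run reaching 5 minutes prunes all longer windows from that start) and
then selects the non-overlapping subset maximising covered minutes,
with supra-threshold MET as deterministic tie-break, by
weighted-interval dynamic programming. A simpler greedy
longest-window-first scan is available (`block_strategy="greedy"`) but
is *not* the default: on randomised dense days it under-covers relative
to the optimum whenever duration-dependent rest allowances interact
across window boundaries, so the exact selection is the contract the
test suite enforces. Correctness is anchored by a fully independent
brute-force oracle (`metbout.bruteforce`) that re-derives window
validity from prefix sums over the day's maximal rest runs and solves
the same selection problem; the two routes agree on 500+ seeded random
days, and this equivalence is part of the acceptance checks.

A block's MET-minutes sum the MET of its supra-threshold minutes only;
whether rest minutes' MET should count is not fixed by the rule set, so
a switch (`count_rest_met_in_blocks`) exposes the alternative. Blocks
never span midnight: days are calendar days in local time, consistent
with day-level scoring.

## Wear time, valid days, weekly scores

Monitor-log entries (`time_removed ≤ t < time_replaced`) flag minutes
back to on-body; a previously off-body minute receives the nominal MET
of the logged intensity (low 2.0, moderate 4.0, vigorous 8.0) when
imputation is enabled, otherwise MET 0 (wear-time credit only). Imputed
minutes count toward wear time and the minute-wise score but are
excluded from block formation by default — blocks should reflect
measured data; `include_imputed_in_blocks` opts in.

A day is valid at ≥ 1296 on-body minutes (90 % of 24 h). Two daily
scores are kept: *blocked* (MET-minutes inside blocks) and
*minute-wise* (MET over all on-body supra-threshold minutes; the
all-minutes variant sits behind `minutewise_all_minutes`). The weekly
score averages valid weekdays and valid weekend days separately
(arithmetic means) and combines them as `5·avg_weekday +
2·avg_weekend`; a participant is included with ≥ 4 valid days of which
≥ 2 are weekend days (Saturday/Sunday), which structurally guarantees
both averages exist. Excluded participants carry a missing weekly
total, never a silent zero.

## Questionnaire scoring

Continuous totals are `Σ_items weight(domain, intensity) ×
min(minutes/day, cap) × days/week` in MET-min/week. Defaults: IPAQ
weights walking 3.3, moderate 4.0, vigorous 8.0, cycling-for-transport
6.0, vigorous yard work 5.5, moderate yard work 4.0, inside chores 3.0,
with the standard 180-min/day per-item truncation; MAAS weights walking
3.33, moderate 3.33, vigorous 6.66, no cap. Categories: IPAQ *high* =
vigorous on ≥ 3 days with total ≥ 1500 MET-min/week, or any activity on
7 days with ≥ 3000; *moderate* = vigorous ≥ 20 min on ≥ 3 days, or
moderate/walking ≥ 30 min on ≥ 5 days, or ≥ 5 days of any combination
with ≥ 600 MET-min/week; *low* otherwise. MAAS uses weighted minutes
(walking + moderate + 2 × vigorous): *high* ≥ 300 min/week over ≥ 5
sessions, *moderate* ≥ 150 over ≥ 5 sessions, *low* otherwise. A zero
total ("none") is always grouped into *low*. These cut-offs follow the
conventional published protocols but the original study's exact MAAS
cut-offs are not restated anywhere accessible, so every weight and
threshold lives in `ScoringRules` configuration and alternative
published rule sets can be swapped in without code changes.

Weekly totals are strongly right-skewed, so scores carry
`ln(total + 1)`; the +1 offset makes zero totals finite and is recorded
on each score (`ln_offset`) so the transform is invertible.

## Agreement statistics

Unweighted Cohen's kappa `κ = (p_o − p_e)/(1 − p_e)` on K×K tables
(weighting is deliberately absent from the default battery); percent
agreement `100·p_o`; a degenerate single-category margin yields NaN
rather than an exception. The accompanying p-value uses the Fleiss
large-sample SE under H₀. Pearson r is computed on identically
transformed pairs with pairwise deletion; canonical correlation of two
univariate sets equals |r| and is reported as such. Bland-Altman limits
use the n−1 SD and a fixed 1.96 multiplier (the conventional 95 %
band), not a t-quantile. Test-retest analyses first drop participants
who reported exercising more because they wore the monitor; missing
feedback retains the participant with a logged warning.

## Synthetic cohort generator

Each participant receives `n_days` (default 7, starting on a Monday so
a full week contains both weekend days) × 1440 minutes: sedentary
baseline MET ~ N(1.3, 0.15) clipped below the 3.3 threshold; Poisson
bouts (mean 2/day, scaled per participant by a lognormal(0, 0.6)
multiplier so the cohort spans low-to-high activity) placed uniformly
and non-overlapping in waking hours 07:00–23:00 (midnight-spanning
bouts available via `allow_midnight_bouts`); lognormal bout durations
(median 30 min, log-SD 0.4); per-bout MET level ~ N(5.0, 0.8) floored
above threshold with small per-minute jitter; each bout minute replaced
by a sub-threshold rest with probability 0.05. One early-morning
off-body gap per day (exponential, mean 30 min, confined to 05:00–07:00
so removal never eats bout minutes) is written to the monitor log with
a sampled intensity.

Questionnaire answers assign all simulated activity to the leisure
moderate/vigorous items (vigorous when the bout's MET level ≥ 6);
reported weekly duration per intensity is `true minutes ×
overreport_factor × lognormal(0, noise_sd)`, rounded to whole minutes.
Days/week is the count of days with ≥ 10 true minutes of that
intensity, and minutes/day is stored as weekly/days (possibly
fractional) so the weekly total is preserved exactly — the instruments'
whole-minute granularity is applied at the weekly level, where the
bias-free limit (factor 1, zero noise) must reproduce the true totals
identically. Defaults `overreport_factor = 1.5`,
`reporting_noise_sd = 0.1` encode the over-reporting regime the
pipeline is designed to detect. Ground truth (per-day supra-threshold
bout minutes and weekly MET-minutes) is bookkept during generation and
is exactly recomputable from the emitted stream (`truth_from_series`),
which the tests assert.

What the generator does **not** emulate: raw accelerometer/heat-flux
channels, demographic structure, weekday/weekend or seasonal activity
asymmetries, domain mixing across questionnaire sections, and
non-compliance severe enough to invalidate days (exclusion paths are
exercised with constructed fixtures instead). Passing tests therefore
demonstrate the pipeline's internal correctness and its sensitivity to
a known reporting bias — not that real cohorts behave like the
simulation.

## Reference fixtures

The packaged tables (`metbout.fixtures`) are printed summary tables
from a published validation study in young Australian women: two 3×3
category cross-classifications (n = 52) and a 12-statement
device-acceptability rating summary. Recomputing kappa from the
concurrent-validity table gives 0.4803 (printed .48, 65 % agreement);
the test-retest table gives 0.19246, which the source printed as .193 —
one unit in the third decimal, presumably display rounding — so fixture
verification accepts agreement within one unit of the printed last
digit rather than exact round-tripping. The printed IQR of the first
acceptability statement is not reproducible from its own printed counts
under standard percentile definitions, so only medians are verified.

## Problem sizes and numerical choices

The reference simulated study uses 200 participants × 7 days (≈ 2M
minutes, a few seconds end to end); blocking-oracle equivalence runs on
500 random days of ≤ 200 minutes spanning sparse to dense activity;
null checks use 1000 label permutations and 10 000 Gaussian
differences. The block search is exact, so ties are resolved
deterministically (earliest-start among equal-objective selections);
all generator and test randomness flows from explicit seeds;
floating-point equality is asserted exactly where the arithmetic is
exact (the 5/2 weekly identity) and to tight absolute tolerances
elsewhere.
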