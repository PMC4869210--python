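"""Exhaustive reference implementation of bout blocking.

The production scanner in :mod:`metbout.armband` is a greedy linear
pass.  This module re-derives the blocked minute set a completely
different way — enumerate *every* window that satisfies the blocking
conditions, then pick the non-overlapping subset that maximises covered
minutes (ties broken toward higher supra-threshold MET, then earliest
start) by weighted-interval dynamic programming.  It exists purely as a
validation oracle for small inputs: quadratic in day length, so keep
days to a few hundred minutes.
"""

from __future__ import annotations

from bisect import bisect_left, bisect_right
from dataclasses import dataclass

import numpy as np

from .armband import BlockingConfig

__all__ = ["enumerate_valid_windows", "optimal_blocks", "BruteForceResult"]


@dataclass(frozen=True)
class BruteForceResult:
    """Optimal non-overlapping blocking of one contiguous minute array."""

    intervals: tuple[tuple[int, int], ...]  # inclusive index pairs
    covered_minutes: int
    met_minutes: float  # supra-threshold MET inside chosen intervals


def enumerate_valid_windows(
    met: np.ndarray, config: BlockingConfig | None = None
) -> list[tuple[int, int]]:
    """All inclusive index windows of ``met`` passing the blocking rules.

    Uses prefix sums over the active mask and over the day's maximal rest
    runs; because valid windows start and end on active minutes, every
    rest run inside a window is one of the day's own maximal runs.
    """
    if config is None:
        config = BlockingConfig()
    met = np.asarray(met, dtype=float)
    n = met.size
    thr = config.met_threshold
    active = met >= thr
    act_idx = np.flatnonzero(active)
    prefix_act = np.concatenate([[0], np.cumsum(active)])

    # maximal rest runs: starts, and per-run prefix counters by class
    run_starts: list[int] = []
    run_lens: list[int] = []
    k = 0
    while k < n:
        if not active[k]:
            s = k
            while k < n and not active[k]:
                k += 1
            run_starts.append(s)
            run_lens.append(k - s)
        else:
            k += 1
    lens = np.asarray(run_lens, dtype=int)
    pref_gt2 = np.concatenate([[0], np.cumsum(lens > 2)])
    pref_gt3 = np.concatenate([[0], np.cumsum(lens > 3)])
    pref_eq4 = np.concatenate([[0], np.cumsum(lens == config.four_rest_length)])
    pref_ge5 = np.concatenate([[0], np.cumsum(lens > config.four_rest_length)])

    windows: list[tuple[int, int]] = []
    for i in act_idx:
        for j in act_idx[act_idx >= i + config.min_block_minutes - 1]:
            d = int(j - i + 1)
            n_act = int(prefix_act[j + 1] - prefix_act[i])
            if n_act < config.frac_required(d) * d:
                continue
            lo = bisect_left(run_starts, int(i))
            hi = bisect_right(run_starts, int(j))
            if pref_ge5[hi] - pref_ge5[lo]:
                continue
            cap = config.rest_cap(d)
            pref_over = pref_gt2 if cap <= 2 else pref_gt3
            over_cap = int(pref_over[hi] - pref_over[lo])
            n_four = int(pref_eq4[hi] - pref_eq4[lo])
            # every run above the cap must be an exactly-4-minute run
            # inside the duration-dependent quota; 5+ runs never pass
            if over_cap != n_four or n_four > config.four_rest_allowance(d):
                continue
            windows.append((int(i), int(j)))
    return windows


def optimal_blocks(
    met: np.ndarray, config: BlockingConfig | None = None
) -> BruteForceResult:
    """Maximum-coverage non-overlapping selection of valid windows.

    Weighted interval scheduling on the enumerated windows, maximising
    the lexicographic objective (covered minutes, supra-threshold MET,
    earliest starts).
    """
    if config is None:
        config = BlockingConfig()
    met = np.asarray(met, dtype=float)
    windows = enumerate_valid_windows(met, config)
    if not windows:
        return BruteForceResult((), 0, 0.0)
    thr = config.met_threshold
    active_met = np.where(met >= thr, met, 0.0)
    pref_met = np.concatenate([[0.0], np.cumsum(active_met)])

    windows.sort(key=lambda w: (w[1], w[0]))
    ends = [w[1] for w in windows]
    m = len(windows)
    # best[k]: (coverage, met, -n_intervals?) up to the k-th window (1-based)
    best: list[tuple[int, float]] = [(0, 0.0)] * (m + 1)
    choice: list[tuple[int, bool]] = [(0, False)] * (m + 1)  # (prev index, taken)
    for k in range(1, m + 1):
        i, j = windows[k - 1]
        p = bisect_right(ends, i - 1, 0, k - 1)
        take = (
            best[p][0] + (j - i + 1),
            best[p][1] + float(pref_met[j + 1] - pref_met[i]),
        )
        skip = best[k - 1]
        if take > skip:
            best[k] = take
            choice[k] = (p, True)
        else:
            best[k] = skip
            choice[k] = (k - 1, False)
    chosen: list[tuple[int, int]] = []
    k = m
    while k > 0:
        p, taken = choice[k]
        if taken:
            chosen.append(windows[k - 1])
        k = p
    chosen.reverse()
    cov, metsum = best[m]
    return BruteForceResult(tuple(chosen), int(cov), float(metsum))
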