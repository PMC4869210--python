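"""End-to-end study pipeline: device reduction -> scoring -> agreement.

Mirrors the analysis flow of a questionnaire-validation study: reduce
each participant's minute stream to weekly device scores (blocked and
minute-wise), score the questionnaires, apply the exclusion rules
(insufficient valid days; activity increased because of the monitor),
and run the agreement battery on every instrument pair.  The whole run
is deterministic given the simulation seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Any

from .agreement import (
    bland_altman,
    canonical_corr,
    cohens_kappa,
    ln_plus_one,
    pearson_ln,
    tabulate,
    test_retest_filter,
)
from .armband import BlockingConfig, process_series, weekly_score
from .fixtures import (
    ACCEPTABILITY_PRINTED_MEDIANS,
    ACCEPTABILITY_RATING_COUNTS,
    MAAS_IPAQ_FOLLOWUP_TABLE,
    MAAS_TEST_RETEST_TABLE,
    PUBLISHED_MAAS_IPAQ_KAPPA,
    PUBLISHED_MAAS_IPAQ_PERCENT_AGREEMENT,
    PUBLISHED_TEST_RETEST_KAPPA,
    median_from_rating_counts,
)
from .questionnaires import ScoringRules, default_rules, score_batch
from .synthetic import CohortConfig, CohortData, generate_cohort

__all__ = ["StudyConfig", "run_study", "verify_fixtures"]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Inputs of one study run: a simulation config or pre-built data."""

    cohort: CohortConfig | None = None
    data: CohortData | None = None
    blocking: BlockingConfig = field(default_factory=BlockingConfig)
    rules: dict[str, ScoringRules] | None = None

    def __post_init__(self) -> None:
        if (self.cohort is None) == (self.data is None):
            raise ValueError("provide exactly one of a cohort config or prepared data")


def _corr_block(a, b) -> dict[str, Any]:
    """Correlation + Bland-Altman summary for two paired weekly totals.

    Both vectors are ln(x+1)-transformed before every statistic, as
    skewed weekly totals conventionally are.
    """
    pear = pearson_ln(a, b)
    canon = canonical_corr(a, b)
    ba = bland_altman(ln_plus_one(a), ln_plus_one(b))
    return {
        "pearson_r": pear.r,
        "pearson_p": pear.p_value,
        "canonical_r": canon.r,
        "n_pairs": pear.n_pairs,
        "bland_altman": {
            "mean_difference": ba.mean_difference,
            "sd_difference": ba.sd_difference,
            "loa_lower": ba.loa_lower,
            "loa_upper": ba.loa_upper,
            "n_pairs": ba.n_pairs,
        },
    }


def _kappa_block(cats_a, cats_b) -> dict[str, Any]:
    table = tabulate(cats_a, cats_b)
    res = cohens_kappa(table)
    return {
        "kappa": res.kappa,
        "percent_agreement": res.percent_agreement,
        "p_value": res.p_value,
        "n": res.n,
        "counts": table.counts.tolist(),
        "n_dropped": table.n_dropped,
    }


def run_study(config: StudyConfig) -> dict[str, Any]:
    """Run the full pipeline and return a JSON-serialisable report."""
    data = config.data if config.data is not None else generate_cohort(config.cohort)
    rules = config.rules or {"IPAQ": default_rules("IPAQ"), "MAAS": default_rules("MAAS")}

    # --- device reduction
    logs = {log.participant_id: log for log in data.logs}
    device: dict[str, dict[str, Any]] = {}
    for series in data.series:
        days = process_series(series, logs.get(series.participant_id), config.blocking)
        blocked = weekly_score(days, "blocked")
        minutewise = weekly_score(days, "minutewise")
        device[series.participant_id] = {
            "n_valid_days": blocked.n_valid_weekdays + blocked.n_valid_weekend_days,
            "n_valid_weekend_days": blocked.n_valid_weekend_days,
            "included": blocked.included,
            "weekly_blocked": blocked.weekly_total,
            "weekly_minutewise": minutewise.weekly_total,
            "n_blocks": sum(len(d.blocks) for d in days),
        }
    excluded_days = sorted(p for p, d in device.items() if not d["included"])
    logger.info(
        "device stage: %d participants, %d excluded for insufficient valid days",
        len(device), len(excluded_days),
    )

    # --- questionnaire scoring
    scores = score_batch(list(data.responses), rules)
    by_key = {(s.participant_id, s.instrument, s.timepoint): s for s in scores}

    def total(pid, inst, tp):
        s = by_key.get((pid, inst, tp))
        return None if s is None or s.missing else s.total_met_minutes_per_week

    def cat(pid, inst, tp):
        s = by_key.get((pid, inst, tp))
        return None if s is None or s.missing else s.category

    pids = sorted(device)
    incl = [p for p in pids if device[p]["included"]]

    # --- agreement battery
    comparisons: dict[str, Any] = {}
    for inst in ("IPAQ", "MAAS"):
        for dev_field in ("weekly_blocked", "weekly_minutewise"):
            key = f"{inst.lower()}_followup_vs_device_{dev_field.removeprefix('weekly_')}"
            a = [total(p, inst, "followup") for p in incl]
            b = [device[p][dev_field] for p in incl]
            comparisons[key] = _corr_block(a, b)

    comparisons["maas_vs_ipaq_followup"] = {
        **_corr_block(
            [total(p, "MAAS", "followup") for p in pids],
            [total(p, "IPAQ", "followup") for p in pids],
        ),
        "categorical": _kappa_block(
            [cat(p, "MAAS", "followup") for p in pids],
            [cat(p, "IPAQ", "followup") for p in pids],
        ),
    }

    retained, n_removed = test_retest_filter(pids, data.exercised_more)
    comparisons["maas_baseline_vs_followup"] = {
        **_corr_block(
            [total(p, "MAAS", "baseline") for p in retained],
            [total(p, "MAAS", "followup") for p in retained],
        ),
        "categorical": _kappa_block(
            [cat(p, "MAAS", "baseline") for p in retained],
            [cat(p, "MAAS", "followup") for p in retained],
        ),
        "n_excluded_exercised_more": n_removed,
    }

    report = {
        "n_participants": len(pids),
        "device": device,
        "questionnaire_scores": {
            f"{s.participant_id}:{s.instrument}:{s.timepoint}": {
                "total_met_minutes_per_week": s.total_met_minutes_per_week,
                "sessions": s.total_sessions_per_week,
                "category": s.category,
                "ln_score": s.ln_score,
                "missing": s.missing,
            }
            for s in scores
        },
        "exclusions": {
            "insufficient_days": excluded_days,
            "test_retest_exercised_more": sorted(
                p for p in pids if data.exercised_more.get(p)
            ),
        },
        "comparisons": comparisons,
    }
    return report


def verify_fixtures() -> dict[str, dict[str, Any]]:
    """Recompute the published summary statistics from the packaged tables.

    Each check recomputes a statistic from printed counts and compares
    it to the printed value within one unit of its printed last digit.
    """
    results: dict[str, dict[str, Any]] = {}

    def check(name: str, value: float, expected: float, tol: float) -> None:
        results[name] = {
            "value": value,
            "expected": expected,
            "tolerance": tol,
            "passed": abs(value - expected) <= tol,
        }

    concurrent = cohens_kappa(MAAS_IPAQ_FOLLOWUP_TABLE)
    check("maas_ipaq_kappa", concurrent.kappa, PUBLISHED_MAAS_IPAQ_KAPPA, 0.01)
    check(
        "maas_ipaq_percent_agreement",
        round(concurrent.percent_agreement),
        PUBLISHED_MAAS_IPAQ_PERCENT_AGREEMENT,
        0,
    )
    retest = cohens_kappa(MAAS_TEST_RETEST_TABLE)
    check("maas_test_retest_kappa", retest.kappa, PUBLISHED_TEST_RETEST_KAPPA, 0.001)
    for name, counts in ACCEPTABILITY_RATING_COUNTS.items():
        check(
            f"acceptability_median:{name}",
            median_from_rating_counts(counts),
            ACCEPTABILITY_PRINTED_MEDIANS[name],
            0.05,
        )
    return results
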