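"""Reference summary tables from a published validation study.

The pipeline cannot reproduce that study's participant-level results
(raw data were never deposited), but its printed summary tables are
exact inputs: two 3x3 cross-classifications of activity categories and
a 12-statement device-acceptability rating summary (n = 52 throughout).
They anchor the agreement statistics — recomputing kappa and percent
agreement from these counts must hit the published values.
"""

from __future__ import annotations

import numpy as np

from .agreement import ContingencyTable, DEFAULT_LABELS

__all__ = [
    "MAAS_IPAQ_FOLLOWUP_TABLE",
    "MAAS_TEST_RETEST_TABLE",
    "ACCEPTABILITY_RATING_COUNTS",
    "ACCEPTABILITY_PRINTED_MEDIANS",
    "PUBLISHED_MAAS_IPAQ_KAPPA",
    "PUBLISHED_MAAS_IPAQ_PERCENT_AGREEMENT",
    "PUBLISHED_TEST_RETEST_KAPPA",
    "median_from_rating_counts",
]

#: MAAS (rows) vs IPAQ (columns) follow-up categories, low/moderate/high.
MAAS_IPAQ_FOLLOWUP_TABLE = ContingencyTable(
    DEFAULT_LABELS, np.array([[13, 3, 1], [4, 8, 5], [0, 5, 13]])
)

#: Baseline (rows) vs follow-up (columns) MAAS categories.
MAAS_TEST_RETEST_TABLE = ContingencyTable(
    DEFAULT_LABELS, np.array([[11, 5, 2], [4, 5, 8], [2, 7, 8]])
)

#: Device-acceptability statements: counts of ratings 1..5
#: (1 = completely false ... 5 = completely true), one row per statement.
ACCEPTABILITY_RATING_COUNTS = {
    "felt_self_conscious": (15, 11, 13, 11, 2),
    "uncomfortable_to_wear": (10, 17, 14, 7, 4),
    "painful_to_wear": (29, 13, 7, 2, 1),
    "proud_to_wear": (7, 17, 18, 9, 1),
    "skipped_wear_self_conscious": (43, 7, 1, 1, 0),
    "skipped_wear_discomfort": (42, 7, 3, 0, 0),
    "skipped_wear_sleep": (40, 5, 4, 2, 1),
    "skipped_wear_wet": (37, 7, 2, 3, 3),
    "skipped_wear_prohibited": (46, 3, 0, 2, 1),
    "exercised_more_because_of_device": (34, 13, 3, 1, 1),
    "prefer_survey_over_device": (35, 7, 7, 2, 1),
    "would_wear_daily_with_feedback": (5, 4, 13, 15, 15),
}

#: Published medians of the rating distributions above.
ACCEPTABILITY_PRINTED_MEDIANS = {
    "felt_self_conscious": 2.5,
    "uncomfortable_to_wear": 2.0,
    "painful_to_wear": 1.0,
    "proud_to_wear": 3.0,
    "skipped_wear_self_conscious": 1.0,
    "skipped_wear_discomfort": 1.0,
    "skipped_wear_sleep": 1.0,
    "skipped_wear_wet": 1.0,
    "skipped_wear_prohibited": 1.0,
    "exercised_more_because_of_device": 1.0,
    "prefer_survey_over_device": 1.0,
    "would_wear_daily_with_feedback": 4.0,
}

PUBLISHED_MAAS_IPAQ_KAPPA = 0.48           # printed to 2 dp
PUBLISHED_MAAS_IPAQ_PERCENT_AGREEMENT = 65  # 34/52, printed as integer %
PUBLISHED_TEST_RETEST_KAPPA = 0.193         # printed to 3 dp


def median_from_rating_counts(counts) -> float:
    """Median of a 1..5 rating distribution given its counts."""
    ratings = np.repeat(np.arange(1, len(counts) + 1), counts)
    return float(np.median(ratings))
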