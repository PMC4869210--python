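"""Agreement statistics for method-comparison studies.

Implements the battery used to compare two activity instruments:

* cross-classification of categorical levels (:func:`tabulate`),
* unweighted Cohen's kappa with percent agreement
  (:func:`cohens_kappa`): ``kappa = (p_o - p_e) / (1 - p_e)`` where
  ``p_o`` is the observed diagonal proportion and ``p_e`` the chance
  agreement from the margins,
* Pearson correlation on natural-log-transformed continuous totals
  (:func:`pearson_ln`) and its canonical-correlation form, which for
  univariate sets is simply ``|r|`` (:func:`canonical_corr`),
* Bland-Altman mean difference with 95 % limits of agreement
  ``mean(d) +/- 1.96 * SD(d)`` (:func:`bland_altman`),
* the test-retest exclusion rule dropping participants whose activity
  changed *because* they wore the monitor (:func:`test_retest_filter`).

P-values accompany kappa (large-sample normal test) and r (t transform)
for reporting; the agreement quantities themselves are the substance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "ContingencyTable",
    "AgreementResult",
    "BlandAltmanResult",
    "CorrelationResult",
    "tabulate",
    "cohens_kappa",
    "pearson_ln",
    "canonical_corr",
    "bland_altman",
    "bland_altman_plot",
    "test_retest_filter",
    "ln_plus_one",
]

logger = logging.getLogger(__name__)

DEFAULT_LABELS = ("low", "moderate", "high")


def ln_plus_one(x):
    """ln(x + 1), the transform applied to skewed weekly totals."""
    return np.log(np.asarray(x, dtype=float) + 1.0)


@dataclass(frozen=True)
class ContingencyTable:
    labels: tuple[str, ...]
    counts: np.ndarray  # K x K, counts[i][j]: a = labels[i], b = labels[j]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        k = len(self.labels)
        if counts.shape != (k, k):
            raise ValueError("counts must be square and match the labels")
        if (counts < 0).any():
            raise ValueError("counts must be nonnegative")
        object.__setattr__(self, "counts", counts)

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class AgreementResult:
    observed_agreement: float
    expected_agreement: float
    kappa: float
    percent_agreement: float
    n: int
    se_kappa: float | None = None
    p_value: float | None = None


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_difference: float
    sd_difference: float
    loa_lower: float
    loa_upper: float
    n_pairs: int


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n_pairs: int
    method: str
    p_value: float | None = None


def _is_missing(v) -> bool:
    return v is None or (isinstance(v, float) and math.isnan(v))


def tabulate(
    cat_a: Sequence[str | None],
    cat_b: Sequence[str | None],
    labels: Sequence[str] = DEFAULT_LABELS,
) -> ContingencyTable:
    """Cross-classify two paired category vectors.

    Pairs with a missing value on either side are dropped and counted in
    ``n_dropped``; unknown category values raise ``ValueError``.
    """
    if len(cat_a) != len(cat_b):
        raise ValueError("category vectors must be paired (equal length)")
    index = {lab: i for i, lab in enumerate(labels)}
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    dropped = 0
    for a, b in zip(cat_a, cat_b):
        if _is_missing(a) or _is_missing(b):
            dropped += 1
            continue
        if a not in index or b not in index:
            raise ValueError(f"unknown category in pair ({a!r}, {b!r})")
        counts[index[a], index[b]] += 1
    return ContingencyTable(tuple(labels), counts, n_dropped=dropped)


def cohens_kappa(table: ContingencyTable) -> AgreementResult:
    """Unweighted Cohen's kappa and percent agreement for a K x K table.

    A degenerate table whose margins put all mass in one category has
    chance agreement 1; kappa is then undefined and reported as NaN.
    """
    n = table.n
    if n < 1:
        raise ValueError("kappa needs at least one pair")
    counts = table.counts.astype(float)
    p = counts / n
    p_o = float(np.trace(p))
    row, col = p.sum(axis=1), p.sum(axis=0)
    p_e = float(row @ col)
    if p_e >= 1.0 - 1e-12:
        kappa, se, pval = float("nan"), None, None
    else:
        kappa = (p_o - p_e) / (1.0 - p_e)
        # large-sample SE under H0 (Fleiss), for the reported normal test
        se0 = math.sqrt(
            max(p_e + p_e**2 - float(sum(row * col * (row + col))), 0.0)
        ) / ((1.0 - p_e) * math.sqrt(n))
        se = se0 if se0 > 0 else None
        pval = 2.0 * stats.norm.sf(abs(kappa) / se0) if se0 > 0 else None
    return AgreementResult(
        observed_agreement=p_o,
        expected_agreement=p_e,
        kappa=kappa,
        percent_agreement=100.0 * p_o,
        n=n,
        se_kappa=se,
        p_value=pval,
    )


def _paired_complete(a, b) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray([np.nan if _is_missing(x) else float(x) for x in a])
    b = np.asarray([np.nan if _is_missing(x) else float(x) for x in b])
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(a) | np.isnan(b))
    return a[keep], b[keep]


def pearson_ln(
    scores_a,
    scores_b,
    transform: Callable[[np.ndarray], np.ndarray] | None = ln_plus_one,
) -> CorrelationResult:
    """Pearson product-moment r on (transformed) paired totals.

    Missing pairs are deleted pairwise; zero variance on either side
    yields r = NaN.  Pass ``transform=None`` to correlate raw values.
    """
    a, b = _paired_complete(scores_a, scores_b)
    if a.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if transform is not None:
        a, b = transform(a), transform(b)
    if np.std(a) == 0 or np.std(b) == 0:
        return CorrelationResult(float("nan"), int(a.size), "pearson", None)
    r, p = stats.pearsonr(a, b)
    return CorrelationResult(float(r), int(a.size), "pearson", float(p))


def canonical_corr(
    set_a,
    set_b,
    transform: Callable[[np.ndarray], np.ndarray] | None = ln_plus_one,
) -> CorrelationResult:
    """Canonical correlation between two univariate sets.

    For one variable per set the first canonical correlation is the
    absolute Pearson correlation (canonical r is sign-invariant).
    """
    res = pearson_ln(set_a, set_b, transform)
    return CorrelationResult(abs(res.r), res.n_pairs, "canonical", res.p_value)


def bland_altman(scores_a, scores_b) -> BlandAltmanResult:
    """Mean difference (a - b) with 95 % limits of agreement.

    SD uses the n-1 denominator; the limits are mean +/- 1.96 SD.
    Inputs are typically ln-transformed weekly totals.
    """
    a, b = _paired_complete(scores_a, scores_b)
    if a.size < 2:
        raise ValueError("need at least 2 complete pairs")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        mean_difference=mean,
        sd_difference=sd,
        loa_lower=mean - 1.96 * sd,
        loa_upper=mean + 1.96 * sd,
        n_pairs=int(d.size),
    )


def bland_altman_plot(scores_a, scores_b, ax=None, label_a: str = "A", label_b: str = "B"):
    """Bland-Altman plot: difference vs mean with the 95 % limits drawn.

    Needs matplotlib (the ``plots`` extra).  Returns the axes.
    """
    import matplotlib.pyplot as plt

    a, b = _paired_complete(scores_a, scores_b)
    res = bland_altman(a, b)
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter((a + b) / 2.0, a - b, s=18, alpha=0.7)
    for y, style in ((res.mean_difference, "-"), (res.loa_lower, "--"), (res.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="grey")
    ax.set_xlabel(f"mean of {label_a} and {label_b}")
    ax.set_ylabel(f"{label_a} − {label_b}")
    return ax


def test_retest_filter(
    participant_ids: Sequence[str],
    exercised_more: dict[str, bool],
) -> tuple[list[str], int]:
    """Drop participants whose activity rose because of the monitor.

    Returns (retained ids, number removed).  Participants without
    feedback are retained with a logged warning.
    """
    retained: list[str] = []
    removed = 0
    for pid in participant_ids:
        flag = exercised_more.get(pid)
        if flag is None:
            logger.warning("no device feedback for %s; retained in test-retest", pid)
            retained.append(pid)
        elif flag:
            removed += 1
        else:
            retained.append(pid)
    return retained, removed
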