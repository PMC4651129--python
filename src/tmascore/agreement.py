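"""Inter-rater agreement statistics for masks and ordinal IHC scores.

Pixel-level mask agreement is summarised by the observed agreement (the
diagonal mass of the normalised 2x2 contingency table) and by Cohen's
chance-corrected kappa.  Ordinal score agreement (intensity 0–3, Allred and
Quickscore proportions and totals) uses the two-rater quadratic-weighted
kappa with disagreement weights ``((i-j)/(k-1))**2`` — for two categories it
reduces exactly to unweighted Cohen's kappa.  Percent-positive measurements
from two sources are compared by Bland–Altman bias and 95% limits of
agreement.

Note on conventions: in the study design this package reproduces, the
pixel-level "kappa" figures quoted for mask comparisons numerically equal
the observed agreement (diagonal sums), not the chance-corrected statistic;
both are therefore always reported side by side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .comparison import ContingencyTable2x2
from .scoring import SpotIHCScore

logger = logging.getLogger(__name__)

__all__ = [
    "OrdinalConfusion",
    "AgreementResult",
    "BlandAltmanResult",
    "observed_agreement",
    "cohen_kappa",
    "weighted_kappa",
    "agreement_result",
    "bland_altman",
    "score_histograms",
    "confusion_from_scores",
]


@dataclass
class OrdinalConfusion:
    """k x k confusion of two raters over an ordered category list.

    The category list fixes the full ordinal range (e.g. Allred totals 0–8)
    even when some categories are unobserved, so expected agreement and
    weights stay well-defined across cohorts.
    """

    categories: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, float)
        k = len(self.categories)
        if self.counts.shape != (k, k):
            raise ValueError("counts must be k x k for k categories")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> float:
        return float(self.counts.sum())


def confusion_from_scores(
    values_1, values_2, categories: list
) -> OrdinalConfusion:
    """Build an ordinal confusion matrix from two paired score sequences."""
    v1 = list(values_1)
    v2 = list(values_2)
    if len(v1) != len(v2):
        raise ValueError("score sequences must have equal length")
    index = {c: i for i, c in enumerate(categories)}
    counts = np.zeros((len(categories), len(categories)))
    for a, b in zip(v1, v2):
        counts[index[a], index[b]] += 1
    return OrdinalConfusion(categories, counts)


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, ContingencyTable2x2):
        return np.asarray(table.counts, float)
    if isinstance(table, OrdinalConfusion):
        return table.counts
    return np.asarray(table, float)


def observed_agreement(table) -> float:
    """Proportion of same-label mass: trace of the normalised table."""
    m = _as_matrix(table)
    total = m.sum()
    if total == 0:
        raise ValueError("empty table")
    return float(np.trace(m) / total)


def cohen_kappa(table) -> float:
    """Chance-corrected agreement ``(po - pe) / (1 - pe)``.

    ``pe`` is the product-of-marginals expected agreement.  When both raters
    are constant (``pe == 1``) kappa is undefined; NaN is returned and a
    warning logged rather than raising, so cohort tables stay rectangular.
    """
    m = _as_matrix(table)
    total = m.sum()
    if total == 0:
        raise ValueError("empty table")
    p = m / total
    po = float(np.trace(p))
    pe = float(p.sum(axis=1) @ p.sum(axis=0))
    if abs(1.0 - pe) < 1e-12:
        logger.warning("cohen_kappa undefined: both raters constant (pe = 1)")
        return float("nan")
    return (po - pe) / (1.0 - pe)


def weighted_kappa(conf, weights: str = "quadratic") -> float:
    """Two-rater weighted kappa for ordered categories.

    ``kappa_w = 1 - sum(w * o) / sum(w * e)`` with disagreement weights
    ``w_ij = (|i - j| / (k - 1)) ** p`` (p = 2 quadratic, 1 linear),
    observed proportions ``o`` and expected ``e`` from the marginal
    products.  Degenerate marginals (no expected disagreement) yield NaN
    with a logged warning.
    """
    m = _as_matrix(conf)
    k = m.shape[0]
    if k < 2 or m.shape != (k, k):
        raise ValueError("confusion must be square with k >= 2 categories")
    total = m.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    power = {"quadratic": 2, "linear": 1}.get(weights)
    if power is None:
        raise ValueError("weights must be 'quadratic' or 'linear'")
    idx = np.arange(k)
    w = (np.abs(idx[:, None] - idx[None, :]) / (k - 1)) ** power
    o = m / total
    e = np.outer(o.sum(axis=1), o.sum(axis=0))
    denom = float((w * e).sum())
    if denom < 1e-12:
        logger.warning("weighted_kappa undefined: degenerate marginals")
        return float("nan")
    return 1.0 - float((w * o).sum()) / denom


@dataclass
class AgreementResult:
    """Observed agreement with unweighted and quadratic-weighted kappa."""

    observed_agreement: float
    cohen_kappa: float
    weighted_kappa_quadratic: float


def agreement_result(table) -> AgreementResult:
    m = _as_matrix(table)
    wk = weighted_kappa(m) if m.shape[0] >= 2 else float("nan")
    return AgreementResult(observed_agreement(table), cohen_kappa(table), wk)


@dataclass
class BlandAltmanResult:
    """Bias and 95% limits of agreement for paired percent-positive values.

    Differences are ``source1 - source2``; limits are ``bias ± 1.96 sd``
    with the sample (ddof=1) standard deviation.
    """

    means: np.ndarray
    differences: np.ndarray
    bias: float
    sd: float
    loa_lower: float
    loa_upper: float


def bland_altman(pairs) -> BlandAltmanResult:
    arr = np.asarray(list(pairs), float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need >= 2 (value1, value2) pairs")
    diffs = arr[:, 0] - arr[:, 1]
    means = arr.mean(axis=1)
    bias = float(diffs.mean())
    sd = float(diffs.std(ddof=1))
    return BlandAltmanResult(
        means=means,
        differences=diffs,
        bias=bias,
        sd=sd,
        loa_lower=bias - 1.96 * sd,
        loa_upper=bias + 1.96 * sd,
    )


ALLRED_TOTAL_RANGE = list(range(0, 9))
QUICKSCORE_TOTAL_RANGE = list(range(1, 10))
INTENSITY_RANGE = list(range(0, 4))


def score_histograms(scores_by_source: dict[str, list[SpotIHCScore]]) -> pd.DataFrame:
    """Count tables of Allred totals (0–8) and Quickscore totals per source."""
    rows = []
    for source, scores in scores_by_source.items():
        for total_name, rng, getter in (
            ("allred_total", ALLRED_TOTAL_RANGE, lambda s: s.allred_total),
            ("quickscore_total", QUICKSCORE_TOTAL_RANGE, lambda s: s.quickscore_total),
        ):
            counts = {v: 0 for v in rng}
            for s in scores:
                counts[getter(s)] = counts.get(getter(s), 0) + 1
            for value, count in sorted(counts.items()):
                rows.append(
                    {"source": source, "score": total_name, "total": value, "count": count}
                )
    return pd.DataFrame(rows, columns=["source", "score", "total", "count"])
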