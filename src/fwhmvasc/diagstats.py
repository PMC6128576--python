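"""Diagnostic-agreement statistics for modality comparison studies.

Implements the evaluation machinery used to compare a screening modality
against a reference standard on a 2×2 classification table —
sensitivity, specificity, predictive values with exact Clopper–Pearson
confidence intervals, percent agreement and Cohen's kappa — plus the
paired-measurement statistics (Spearman's rank correlation, Wilcoxon
signed-rank test) used to compare size measurements between modalities.

A utility reconstructs the unique 2×2 table behind a published set of
interval bounds by exhaustive search, which lets printed summary tables
be checked end-to-end without the underlying patient-level data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
from scipy import stats

from fwhmvasc._errors import ReconstructionError, ValidationError

__all__ = [
    "ConfusionMatrix",
    "MetricWithCI",
    "DiagnosticMetrics",
    "clopper_pearson",
    "diagnostic_metrics",
    "percent_agreement",
    "cohens_kappa",
    "spearman_rho",
    "wilcoxon_signed_rank",
    "reconstruct_confusion_matrix",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    """2×2 counts against the reference standard.

    ``tp``: positive on both modalities; ``fp``: positive on the index
    test only; ``fn``: positive on the reference only; ``tn``: negative
    on both.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer")
        if self.total < 1:
            raise ValidationError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricWithCI:
    """A proportion with its exact confidence interval.

    ``defined`` is False when the denominator is zero, in which case the
    point and bounds are NaN rather than raising.
    """

    point: float
    lo: float
    hi: float
    defined: bool = True


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Se / Sp / PPV / NPV with exact binomial confidence intervals."""

    se: MetricWithCI
    sp: MetricWithCI
    ppv: MetricWithCI
    npv: MetricWithCI
    alpha: float = 0.05


def clopper_pearson(x: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact binomial confidence interval via Beta quantiles.

    ``lo = Beta(alpha/2; x, n-x+1)`` (0 when x = 0) and
    ``hi = Beta(1-alpha/2; x+1, n-x)`` (1 when x = n); guarantees at
    least ``1 - alpha`` coverage for every true proportion.
    """
    if not (isinstance(x, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValidationError("x and n must be integers")
    if n < 1 or not (0 <= x <= n):
        raise ValidationError(f"invalid counts: x={x}, n={n}")
    if not (0 < alpha < 1):
        raise ValidationError("alpha must be in (0, 1)")
    lo = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    hi = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return lo, hi


def _metric(x: int, n: int, alpha: float) -> MetricWithCI:
    if n == 0:
        return MetricWithCI(float("nan"), float("nan"), float("nan"), defined=False)
    lo, hi = clopper_pearson(x, n, alpha)
    return MetricWithCI(x / n, lo, hi)


def diagnostic_metrics(cm: ConfusionMatrix, alpha: float = 0.05) -> DiagnosticMetrics:
    """Sensitivity, specificity and predictive values with exact CIs.

    A zero denominator yields an undefined (NaN-valued) metric flagged by
    ``defined=False`` rather than an exception.
    """
    return DiagnosticMetrics(
        se=_metric(cm.tp, cm.tp + cm.fn, alpha),
        sp=_metric(cm.tn, cm.tn + cm.fp, alpha),
        ppv=_metric(cm.tp, cm.tp + cm.fp, alpha),
        npv=_metric(cm.tn, cm.tn + cm.fn, alpha),
        alpha=alpha,
    )


def percent_agreement(cm: ConfusionMatrix) -> float:
    """Observed agreement ``(tp + tn) / total`` as a proportion."""
    return (cm.tp + cm.tn) / cm.total


def cohens_kappa(cm: ConfusionMatrix) -> float:
    """Chance-corrected agreement between the two classifications.

    ``kappa = (po - pe) / (1 - pe)`` with ``po`` the observed agreement
    and ``pe`` the agreement expected from the marginals. Perfect
    observed agreement returns 1 regardless of ``pe`` (limit
    convention); ``pe = 1`` with ``po < 1`` is undefined and returns NaN.
    """
    n = cm.total
    po = (cm.tp + cm.tn) / n
    row_pos = (cm.tp + cm.fp) / n
    col_pos = (cm.tp + cm.fn) / n
    pe = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    if po == 1.0:
        return 1.0
    if pe == 1.0:
        return float("nan")
    return (po - pe) / (1 - pe)


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman's rank correlation: Pearson correlation of mid-ranks.

    Ties receive average (mid) ranks. A constant vector has no rank
    variation and returns NaN.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1D sequences of equal length")
    if len(xa) < 3:
        raise ValidationError("need at least 3 pairs")
    rx = stats.rankdata(xa, method="average")
    ry = stats.rankdata(ya, method="average")
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return float("nan")
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / math.sqrt((rx @ rx) * (ry @ ry)))


def _exact_wilcoxon_p(ranks: np.ndarray, w_obs: float) -> float:
    """Two-sided exact p over all 2^n sign assignments.

    With no ties the ranks are the integers 1..n, so the full
    sign-assignment distribution of W is tabulated by convolution
    (equivalent to, but far cheaper than, materializing the 2^n
    assignments).
    """
    int_ranks = np.rint(ranks).astype(int)
    total = int(int_ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in int_ranks:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    n_assign = 2.0 ** len(int_ranks)
    w = int(round(w_obs))
    p_le = counts[: w + 1].sum() / n_assign
    p_ge = counts[w:].sum() / n_assign
    return min(1.0, 2.0 * min(p_le, p_ge))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's original convention); ties
    in |d| receive mid-ranks. ``W`` is the sum of ranks of positive
    differences. The two-sided p is exact (full enumeration of sign
    assignments) when the effective n is at most 20 and |d| has no ties;
    otherwise a normal approximation with tie and continuity corrections
    is used. All differences zero → ``(NaN, NaN)``.
    """
    xa = np.asarray(x, dtype=np.float64)
    ya = np.asarray(y, dtype=np.float64)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1D sequences of equal length")
    d = xa - ya
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return float("nan"), float("nan")
    if n < 5:
        raise ValidationError("need at least 5 nonzero differences")
    ranks = stats.rankdata(np.abs(d), method="average")
    w = float(np.sum(ranks[d > 0]))

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= 20 and not has_ties:
        return w, _exact_wilcoxon_p(ranks, w)

    mean = n * (n + 1) / 4.0
    var = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var -= np.sum(counts**3 - counts) / 48.0
    if var <= 0:
        return w, float("nan")
    diff = w - mean
    # continuity correction toward the null centre
    cc = 0.5 * np.sign(diff) if diff != 0 else 0.0
    z = (diff - cc) / math.sqrt(var)
    return w, float(2 * stats.norm.sf(abs(z)))


def _round_half_up(value: float, decimals: int) -> float:
    return float(
        Decimal(repr(value)).quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    )


def reconstruct_confusion_matrix(
    n_total: int,
    se_ci_printed: tuple[float, float],
    sp_ci_printed: tuple[float, float],
    decimals: int = 2,
    alpha: float = 0.05,
) -> ConfusionMatrix:
    """Recover the unique 2×2 table behind printed Se/Sp interval bounds.

    Searches all tables ``(tp, fp, fn, tn)`` summing to ``n_total`` whose
    exact Clopper–Pearson intervals for sensitivity and specificity,
    rounded half-up to ``decimals``, equal the printed bounds. Raises
    :class:`ReconstructionError` when no table matches and when the match
    is ambiguous.
    """
    if n_total < 1:
        raise ValidationError("n_total must be >= 1")
    for name, ci in (("Se", se_ci_printed), ("Sp", sp_ci_printed)):
        if not (0 <= ci[0] <= 1 and 0 <= ci[1] <= 1):
            raise ValidationError(f"printed {name} bounds must lie in [0, 1]")

    def matches(x: int, n: int, printed: tuple[float, float]) -> bool:
        lo, hi = clopper_pearson(x, n, alpha)
        return (
            _round_half_up(lo, decimals) == _round_half_up(printed[0], decimals)
            and _round_half_up(hi, decimals) == _round_half_up(printed[1], decimals)
        )

    # (x, n) pairs consistent with each printed interval, per denominator
    se_pairs = {
        n_pos: [tp for tp in range(n_pos + 1) if matches(tp, n_pos, se_ci_printed)]
        for n_pos in range(1, n_total)
    }
    candidates = []
    for n_pos, tps in se_pairs.items():
        if not tps:
            continue
        n_neg = n_total - n_pos
        for tn in range(n_neg + 1):
            if matches(tn, n_neg, sp_ci_printed):
                for tp in tps:
                    candidates.append(
                        ConfusionMatrix(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
                    )
    if not candidates:
        raise ReconstructionError(
            "no 2x2 table is consistent with the printed interval bounds"
        )
    if len(candidates) > 1:
        raise ReconstructionError(
            f"ambiguous reconstruction: {len(candidates)} tables match "
            f"(e.g. {candidates[0]} and {candidates[1]})"
        )
    return candidates[0]
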