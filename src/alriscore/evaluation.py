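"""Discrimination analysis of score totals against in-hospital mortality.

The AUROC is the Mann-Whitney estimator with midrank tie handling: the
probability that a randomly chosen death scores above a randomly chosen
discharge, ties credited one half. Inference uses DeLong's nonparametric
method: per-subject placement values give the variance of one AUROC and the
covariance between two correlated AUROCs measured on the same subjects,
enabling Wald confidence intervals and two-sided paired z-tests.

Threshold sweeps classify ``score >= cutoff`` as high risk, report
sensitivity, specificity and the Youden J index at every distinct observed
score value, and pick the cutoff maximizing J (ties toward the smaller
cutoff). AUROC magnitudes are labeled with the conventional discrimination
bands (boundaries at 0.50, 0.70, 0.80 and 0.90).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import norm

from .errors import DegenerateInputError, DegenerateVarianceError

__all__ = [
    "RocAnalysis",
    "ThresholdRow",
    "PairedComparison",
    "empirical_auroc",
    "delong_ci",
    "delong_paired_test",
    "threshold_table",
    "optimal_cutoff",
    "stratified_auroc",
    "discrimination_band",
    "BANDS",
]

BANDS = ("none", "poor", "acceptable", "good", "excellent")

#: paired tests use the significance level the analysis plan fixes
SIGNIFICANCE_LEVEL = 0.01


@dataclass(frozen=True)
class RocAnalysis:
    score_id: str
    auroc: float
    delong_variance: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    band: str


@dataclass(frozen=True)
class ThresholdRow:
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    proportion_high_risk: float
    observed_cfr_high_risk: float | None


@dataclass(frozen=True)
class PairedComparison:
    score_a: str
    score_b: str
    auroc_a: float
    auroc_b: float
    z_statistic: float
    p_value: float
    significant_at_0_01: bool


def _split(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and outcomes must be aligned 1-d sequences")
    y = y.astype(bool)
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise DegenerateInputError(
            "outcomes must contain both classes "
            f"(got {len(pos)} positives, {len(neg)} negatives)"
        )
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values via sorted-array midrank counting, O(n log n).

    ``v10[i]`` is the fraction of negatives below the i-th positive (ties 1/2);
    ``v01[j]`` the fraction of positives above the j-th negative (ties 1/2).
    """
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / len(neg)
    pos_sorted = np.sort(pos)
    lo_p = np.searchsorted(pos_sorted, neg, side="left")
    hi_p = np.searchsorted(pos_sorted, neg, side="right")
    v01 = ((len(pos) - hi_p) + 0.5 * (hi_p - lo_p)) / len(pos)
    return v10, v01


def empirical_auroc(scores: Sequence[float], outcomes: Sequence[int]) -> float:
    """Mann-Whitney AUROC with ties credited 0.5."""
    pos, neg = _split(scores, outcomes)
    v10, _ = _placements(pos, neg)
    return float(v10.mean())


def discrimination_band(auroc: float) -> str:
    """Label an AUROC: none / poor / acceptable / good / excellent."""
    if not 0 <= auroc <= 1:
        raise ValueError(f"AUROC must lie in [0, 1], got {auroc}")
    if auroc < 0.50:
        return "none"
    if auroc < 0.70:
        return "poor"
    if auroc < 0.80:
        return "acceptable"
    if auroc < 0.90:
        return "good"
    return "excellent"


def delong_ci(
    scores: Sequence[float],
    outcomes: Sequence[int],
    level: float = 0.95,
    score_id: str = "",
) -> RocAnalysis:
    """AUROC with DeLong variance and a Wald CI truncated to [0, 1].

    The CI is computed on the AUROC scale (no logit transform) and clipped to
    the unit interval, so ``ci95 ⊆ [0, 1]`` always holds.
    """
    pos, neg = _split(scores, outcomes)
    if len(pos) < 2 or len(neg) < 2:
        raise DegenerateInputError(
            "DeLong variance needs at least 2 subjects in each outcome class"
        )
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = float(v10.var(ddof=1) / len(pos) + v01.var(ddof=1) / len(neg))
    half = norm.ppf(0.5 + level / 2) * np.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return RocAnalysis(
        score_id=score_id,
        auroc=auc,
        delong_variance=var,
        ci95=(float(lo), float(hi)),
        n_pos=len(pos),
        n_neg=len(neg),
        band=discrimination_band(auc),
    )


def delong_paired_test(
    scores_a: Sequence[float],
    scores_b: Sequence[float],
    outcomes: Sequence[int],
    score_a: str = "a",
    score_b: str = "b",
) -> PairedComparison:
    """Two-sided paired DeLong z-test between two scores on the same subjects.

    z = (AUC_a - AUC_b) / sqrt(var_a + var_b - 2 cov_ab), with variance and
    covariance from the per-subject placement values. A zero pooled variance
    with equal AUROCs yields z = 0, p = 1 by convention; with unequal AUROCs
    it raises :class:`DegenerateVarianceError`.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    if sa.shape != sb.shape:
        raise ValueError("paired scores must cover the same subjects")
    pos_a, neg_a = _split(sa, outcomes)
    pos_b, neg_b = _split(sb, outcomes)
    m, n = len(pos_a), len(neg_a)
    if m < 2 or n < 2:
        raise DegenerateInputError(
            "paired DeLong test needs at least 2 subjects in each outcome class"
        )
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    s10 = np.cov(v10a, v10b, ddof=1)
    s01 = np.cov(v01a, v01b, ddof=1)
    var = s10[0, 0] / m + s01[0, 0] / n + s10[1, 1] / m + s01[1, 1] / n
    cov = s10[0, 1] / m + s01[0, 1] / n
    pooled = var - 2 * cov
    if pooled <= 0 or not np.isfinite(pooled):
        if np.isclose(auc_a, auc_b):
            z, p = 0.0, 1.0
        else:
            raise DegenerateVarianceError(
                "paired DeLong variance is zero while the AUROCs differ "
                f"({auc_a:.4f} vs {auc_b:.4f})"
            )
    else:
        z = (auc_a - auc_b) / np.sqrt(pooled)
        p = 2 * norm.sf(abs(z))
    return PairedComparison(
        score_a=score_a,
        score_b=score_b,
        auroc_a=auc_a,
        auroc_b=auc_b,
        z_statistic=float(z),
        p_value=float(p),
        significant_at_0_01=bool(p < SIGNIFICANCE_LEVEL),
    )


def threshold_table(
    scores: Sequence[float], outcomes: Sequence[int]
) -> list[ThresholdRow]:
    """Operating characteristics at every distinct observed score value.

    Each row classifies ``score >= cutoff`` as high risk; sensitivity is the
    high-risk fraction among deaths, specificity the low-risk fraction among
    discharges, and the observed case fatality rate is deaths / admissions in
    the high-risk group (``None`` when nobody is classified high risk).
    """
    pos, neg = _split(scores, outcomes)
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    rows = []
    for c in np.unique(s):
        high = s >= c
        sens = float((pos >= c).mean())
        spec = float((neg < c).mean())
        n_high = int(high.sum())
        cfr = float(y[high].mean()) if n_high else None
        rows.append(
            ThresholdRow(
                cutoff=float(c),
                sensitivity=sens,
                specificity=spec,
                youden_j=sens + spec - 1.0,
                proportion_high_risk=n_high / len(s),
                observed_cfr_high_risk=cfr,
            )
        )
    return rows


def optimal_cutoff(table: Sequence[ThresholdRow]) -> ThresholdRow:
    """Row maximizing the Youden J index; ties broken toward the smaller cutoff."""
    if not table:
        raise ValueError("threshold table is empty")
    best = table[0]
    for row in table[1:]:
        if row.youden_j > best.youden_j or (
            row.youden_j == best.youden_j and row.cutoff < best.cutoff
        ):
            best = row
    return best


def stratified_auroc(
    scores: Sequence[float],
    outcomes: Sequence[int],
    strata: Sequence,
    score_id: str = "",
) -> list[tuple[object, RocAnalysis | str]]:
    """Independent ROC analysis per stratum.

    Strata lacking both outcome classes (or with a single subject in a class)
    are reported as skipped with the reason string instead of raising.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes).astype(bool)
    g = np.asarray(strata)
    out: list[tuple[object, RocAnalysis | str]] = []
    for label in np.unique(g):
        mask = g == label
        try:
            out.append((label, delong_ci(s[mask], y[mask], score_id=score_id)))
        except DegenerateInputError as exc:
            out.append((label, f"skipped: {exc}"))
    return out
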