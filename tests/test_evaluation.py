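"""Discrimination analysis against brute-force and external oracles."""

from __future__ import annotations

import statistics
import subprocess

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from alriscore.errors import DegenerateInputError
from alriscore.evaluation import (
    delong_ci,
    delong_paired_test,
    discrimination_band,
    empirical_auroc,
    optimal_cutoff,
    stratified_auroc,
    threshold_table,
)

# ---------------------------------------------------------------------------
# Independent oracles: naive O(n^2) enumerations of the defining formulas.


def brute_auroc(scores, outcomes):
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_placements(scores, outcomes):
    pos = [s for s, y in zip(scores, outcomes) if y]
    neg = [s for s, y in zip(scores, outcomes) if not y]
    v10 = [
        sum(1.0 if p > n else 0.5 if p == n else 0.0 for n in neg) / len(neg)
        for p in pos
    ]
    v01 = [
        sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos) / len(pos)
        for n in neg
    ]
    return v10, v01


def brute_delong_variance(scores, outcomes):
    v10, v01 = brute_placements(scores, outcomes)
    return statistics.variance(v10) / len(v10) + statistics.variance(v01) / len(v01)


def brute_paired_z(scores_a, scores_b, outcomes):
    v10a, v01a = brute_placements(scores_a, outcomes)
    v10b, v01b = brute_placements(scores_b, outcomes)
    m, n = len(v10a), len(v01a)
    var_a = statistics.variance(v10a) / m + statistics.variance(v01a) / n
    var_b = statistics.variance(v10b) / m + statistics.variance(v01b) / n
    cov = statistics.covariance(v10a, v10b) / m + statistics.covariance(v01a, v01b) / n
    num = statistics.fmean(v10a) - statistics.fmean(v10b)
    return num / (var_a + var_b - 2 * cov) ** 0.5


# ---------------------------------------------------------------------------
# AUROC point estimate

def test_perfect_separation_is_one():
    assert empirical_auroc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0


def test_complete_tie_is_half():
    assert empirical_auroc([5, 5], [0, 1]) == 0.5


def test_five_observation_enumeration():
    scores, outcomes = [1, 3, 2, 4, 4], [0, 0, 1, 1, 0]
    assert empirical_auroc(scores, outcomes) == pytest.approx(
        brute_auroc(scores, outcomes)
    )


def test_single_class_is_degenerate():
    with pytest.raises(DegenerateInputError):
        empirical_auroc([1, 2, 3], [1, 1, 1])


_score_lists = st.lists(st.integers(min_value=0, max_value=12), min_size=4, max_size=200)


@given(_score_lists, st.randoms(use_true_random=False))
def test_auroc_equals_exhaustive_oracle(scores, rnd):
    outcomes = [rnd.random() < 0.4 for _ in scores]
    if not (any(outcomes) and not all(outcomes)):
        outcomes[0], outcomes[-1] = True, False
    assert empirical_auroc(scores, outcomes) == pytest.approx(
        brute_auroc(scores, outcomes), abs=1e-12
    )


@given(_score_lists, st.randoms(use_true_random=False))
def test_monotone_transform_invariance(scores, rnd):
    outcomes = [rnd.random() < 0.5 for _ in scores]
    if not (any(outcomes) and not all(outcomes)):
        outcomes[0], outcomes[-1] = True, False
    transformed = [3.0 * s**3 + 7.5 for s in scores]  # strictly increasing
    assert empirical_auroc(scores, outcomes) == pytest.approx(
        empirical_auroc(transformed, outcomes)
    )


@given(_score_lists, st.randoms(use_true_random=False))
def test_label_flip_symmetry(scores, rnd):
    outcomes = [rnd.random() < 0.5 for _ in scores]
    if not (any(outcomes) and not all(outcomes)):
        outcomes[0], outcomes[-1] = True, False
    flipped = [not y for y in outcomes]
    assert empirical_auroc(scores, outcomes) + empirical_auroc(
        scores, flipped
    ) == pytest.approx(1.0)


def test_matches_sklearn_on_tied_integer_scores():
    from sklearn.metrics import roc_auc_score

    rng = np.random.default_rng(7)
    scores = rng.integers(0, 10, size=500)
    outcomes = rng.random(500) < 0.2
    assert empirical_auroc(scores, outcomes) == pytest.approx(
        roc_auc_score(outcomes, scores), abs=1e-12
    )


# ---------------------------------------------------------------------------
# DeLong variance and CI

def test_perfect_separation_has_zero_variance_ci():
    roc = delong_ci([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1])
    assert roc.auroc == 1.0
    assert roc.delong_variance == 0.0
    assert roc.ci95 == (1.0, 1.0)


def test_ci_estimator_consistency_and_variance_oracle():
    scores = [3, 1, 4, 1, 5, 9, 2, 6, 5, 3]
    outcomes = [0, 0, 1, 0, 1, 1, 0, 1, 0, 0]
    roc = delong_ci(scores, outcomes)
    assert roc.auroc == pytest.approx(empirical_auroc(scores, outcomes))
    assert roc.delong_variance == pytest.approx(
        brute_delong_variance(scores, outcomes), abs=1e-14
    )
    assert 0 <= roc.ci95[0] <= roc.auroc <= roc.ci95[1] <= 1
    assert roc.band == discrimination_band(roc.auroc)


@given(_score_lists, st.randoms(use_true_random=False))
def test_delong_variance_matches_brute_force(scores, rnd):
    outcomes = [rnd.random() < 0.4 for _ in scores]
    # guarantee two subjects per class without disturbing the middle
    outcomes[:2] = [True, True]
    outcomes[-2:] = [False, False]
    roc = delong_ci(scores, outcomes)
    assert roc.delong_variance == pytest.approx(
        brute_delong_variance(scores, outcomes), abs=1e-12
    )


def test_delong_ci_matches_r_proc():
    """Cross-check AUROC, variance and CI against pROC's DeLong implementation."""
    rng = np.random.default_rng(11)
    scores = rng.integers(0, 14, size=60).tolist()
    outcomes = (rng.random(60) < 0.3).astype(int).tolist()
    roc = delong_ci(scores, outcomes)
    r_code = f"""
    suppressMessages(library(pROC))
    y <- c({','.join(map(str, outcomes))})
    s <- c({','.join(map(str, scores))})
    r <- roc(y, s, levels = c(0, 1), direction = "<", quiet = TRUE)
    ci <- ci.auc(r, method = "delong")
    cat(sprintf("%.12f %.12f %.12f %.12g", ci[2], ci[1], ci[3], var(r)))
    """
    out = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
    )
    auc_r, lo_r, hi_r, var_r = map(float, out.stdout.split())
    assert roc.auroc == pytest.approx(auc_r, abs=1e-10)
    assert roc.delong_variance == pytest.approx(var_r, rel=1e-8)
    assert roc.ci95[0] == pytest.approx(lo_r, abs=1e-8)
    assert roc.ci95[1] == pytest.approx(hi_r, abs=1e-8)


def test_null_scores_large_sample():
    """Outcome-independent scores: AUROC near 0.5 and the CI covers 0.5."""
    rng = np.random.default_rng(42)
    scores = np.concatenate([rng.normal(size=2000), rng.normal(size=2000)])
    outcomes = np.array([1] * 2000 + [0] * 2000)
    roc = delong_ci(scores, outcomes)
    assert 0.45 <= roc.auroc <= 0.55
    assert roc.ci95[0] <= 0.5 <= roc.ci95[1]


# ---------------------------------------------------------------------------
# Paired test

def test_self_comparison_is_null():
    scores = [1, 5, 2, 8, 3, 9, 1, 7]
    outcomes = [0, 1, 0, 1, 0, 1, 0, 0]
    cmp = delong_paired_test(scores, scores, outcomes)
    assert cmp.z_statistic == 0.0
    assert cmp.p_value == 1.0
    assert not cmp.significant_at_0_01


def test_antisymmetry():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 10, 40)
    b = rng.integers(0, 10, 40)
    y = rng.random(40) < 0.4
    ab = delong_paired_test(a, b, y)
    ba = delong_paired_test(b, a, y)
    assert ab.z_statistic == pytest.approx(-ba.z_statistic)
    assert ab.p_value == pytest.approx(ba.p_value)


def test_paired_z_matches_brute_force_on_12_observations():
    a = [1, 4, 2, 7, 3, 9, 5, 6, 2, 8, 4, 7]
    b = [2, 3, 3, 5, 1, 8, 6, 4, 2, 9, 5, 5]
    y = [0, 0, 0, 1, 0, 1, 1, 0, 0, 1, 0, 1]
    cmp = delong_paired_test(a, b, y)
    assert cmp.z_statistic == pytest.approx(brute_paired_z(a, b, y), abs=1e-12)


def test_paired_test_matches_r_proc():
    rng = np.random.default_rng(19)
    a = rng.integers(0, 14, 80).tolist()
    b = rng.integers(0, 8, 80).tolist()
    y = (rng.random(80) < 0.3).astype(int).tolist()
    cmp = delong_paired_test(a, b, y)
    r_code = f"""
    suppressMessages(library(pROC))
    y <- c({','.join(map(str, y))})
    a <- c({','.join(map(str, a))})
    b <- c({','.join(map(str, b))})
    ra <- roc(y, a, levels = c(0, 1), direction = "<", quiet = TRUE)
    rb <- roc(y, b, levels = c(0, 1), direction = "<", quiet = TRUE)
    t <- roc.test(ra, rb, method = "delong", paired = TRUE)
    cat(sprintf("%.12f %.12g", t$statistic, t$p.value))
    """
    out = subprocess.run(
        ["Rscript", "-e", r_code], capture_output=True, text=True, check=True
    )
    z_r, p_r = map(float, out.stdout.split())
    assert cmp.z_statistic == pytest.approx(z_r, abs=1e-8)
    assert cmp.p_value == pytest.approx(p_r, rel=1e-6)


# ---------------------------------------------------------------------------
# Threshold sweep

def brute_threshold_rows(scores, outcomes):
    rows = {}
    for c in sorted(set(scores)):
        high = [(s, y) for s, y in zip(scores, outcomes) if s >= c]
        deaths = [y for _, y in zip(scores, outcomes) if y]
        sens = sum(1 for s, y in zip(scores, outcomes) if y and s >= c) / sum(outcomes)
        spec = sum(1 for s, y in zip(scores, outcomes) if not y and s < c) / (
            len(outcomes) - sum(outcomes)
        )
        rows[c] = (
            sens,
            spec,
            sens + spec - 1,
            len(high) / len(scores),
            (sum(y for _, y in high) / len(high)) if high else None,
        )
    return rows


def test_threshold_rows_match_brute_force_recount():
    rng = np.random.default_rng(5)
    scores = rng.integers(0, 8, 50).tolist()
    outcomes = (rng.random(50) < 0.3).astype(int).tolist()
    expected = brute_threshold_rows(scores, outcomes)
    for row in threshold_table(scores, outcomes):
        sens, spec, j, prop, cfr = expected[row.cutoff]
        assert row.sensitivity == pytest.approx(sens)
        assert row.specificity == pytest.approx(spec)
        assert row.youden_j == pytest.approx(j)
        assert row.proportion_high_risk == pytest.approx(prop)
        assert row.observed_cfr_high_risk == pytest.approx(cfr)


def test_minimum_cutoff_classifies_everyone_high_risk():
    scores = [2, 3, 5, 2, 4]
    outcomes = [0, 1, 1, 0, 0]
    first = threshold_table(scores, outcomes)[0]
    assert first.cutoff == 2
    assert first.sensitivity == 1.0
    assert first.proportion_high_risk == 1.0
    assert first.observed_cfr_high_risk == pytest.approx(2 / 5)


def test_perfectly_separating_cutoff():
    rows = {r.cutoff: r for r in threshold_table([1, 2, 3, 4], [0, 0, 1, 1])}
    assert rows[3].sensitivity == 1.0
    assert rows[3].specificity == 1.0
    assert rows[3].youden_j == pytest.approx(1.0)


@given(_score_lists, st.randoms(use_true_random=False))
def test_threshold_monotonicity(scores, rnd):
    outcomes = [rnd.random() < 0.4 for _ in scores]
    if not (any(outcomes) and not all(outcomes)):
        outcomes[0], outcomes[-1] = True, False
    rows = threshold_table(scores, outcomes)
    for lo, hi in zip(rows, rows[1:]):
        assert hi.sensitivity <= lo.sensitivity + 1e-12
        assert hi.specificity >= lo.specificity - 1e-12


def test_optimal_cutoff_argmax_and_tiebreak():
    rng = np.random.default_rng(9)
    scores = rng.integers(0, 10, 60).tolist()
    outcomes = (rng.random(60) < 0.35).astype(int).tolist()
    rows = threshold_table(scores, outcomes)
    best = optimal_cutoff(rows)
    max_j = max(r.youden_j for r in rows)
    assert best.youden_j == max_j
    assert best.cutoff == min(r.cutoff for r in rows if r.youden_j == max_j)
    # explicit tie: both cutoffs achieve J = 0 at the extremes
    tied = threshold_table([1, 2], [0, 1])
    assert optimal_cutoff(tied).cutoff == min(
        r.cutoff for r in tied if r.youden_j == max(t.youden_j for t in tied)
    )


# ---------------------------------------------------------------------------
# Stratified analysis and banding

def test_identical_strata_identical_auroc():
    scores = [1, 2, 3, 4, 5, 6] * 2
    outcomes = [0, 0, 1, 0, 1, 1] * 2
    strata = ["x"] * 6 + ["y"] * 6
    results = dict(stratified_auroc(scores, outcomes, strata))
    assert results["x"].auroc == results["y"].auroc


def test_stratum_without_deaths_is_skipped():
    scores = [1, 2, 3, 4, 9, 8, 7, 6]
    outcomes = [0, 0, 1, 1, 0, 0, 0, 0]
    results = dict(stratified_auroc(scores, outcomes, ["a"] * 4 + ["b"] * 4))
    assert results["a"].auroc == 1.0
    assert isinstance(results["b"], str) and "skipped" in results["b"]


def test_pooled_auroc_can_reverse_strata():
    """Perfect within-stratum discrimination, pooled AUROC below one half."""
    scores = [3] * 6 + [2] * 2 + [30] * 2 + [29] * 6
    outcomes = [1] * 6 + [0] * 2 + [1] * 2 + [0] * 6
    strata = ["a"] * 8 + ["b"] * 8
    per_stratum = dict(stratified_auroc(scores, outcomes, strata))
    assert per_stratum["a"].auroc == 1.0 and per_stratum["b"].auroc == 1.0
    assert empirical_auroc(scores, outcomes) == pytest.approx(28 / 64)


@pytest.mark.parametrize(
    "auroc, band",
    [
        (0.49, "none"),
        (0.50, "poor"),
        (0.69, "poor"),
        (0.70, "acceptable"),
        (0.79, "acceptable"),
        (0.80, "good"),
        (0.83, "good"),
        (0.89, "good"),
        (0.90, "excellent"),
        (1.0, "excellent"),
    ],
)
def test_discrimination_bands(auroc, band):
    assert discrimination_band(auroc) == band


def test_band_rejects_out_of_range():
    with pytest.raises(ValueError):
        discrimination_band(1.2)
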