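"""Tabular report builders for the score-validation workflow.

Given a score matrix (admissions x scores) and the matching binary outcome
vector, these helpers produce the publication-shaped tables: per-score AUROC
with DeLong confidence intervals, per-cutoff operating characteristics, the
Youden-optimal cutoff summary, and the pairwise DeLong p-value matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluation import (
    ThresholdRow,
    delong_ci,
    delong_paired_test,
    optimal_cutoff,
    threshold_table,
)

__all__ = [
    "auroc_report",
    "threshold_report",
    "optimal_cutoff_report",
    "pairwise_pvalue_matrix",
]


def auroc_report(matrix: pd.DataFrame, outcomes) -> pd.DataFrame:
    """One row per score: AUROC, DeLong variance, 95% CI, band."""
    y = np.asarray(outcomes)
    rows = []
    for score_id in matrix.columns:
        roc = delong_ci(matrix[score_id].to_numpy(), y, score_id=score_id)
        rows.append(
            {
                "score_id": score_id,
                "auroc": roc.auroc,
                "delong_variance": roc.delong_variance,
                "ci95_lo": roc.ci95[0],
                "ci95_hi": roc.ci95[1],
                "n_deaths": roc.n_pos,
                "n_discharges": roc.n_neg,
                "band": roc.band,
            }
        )
    return pd.DataFrame(rows)


def _row_to_dict(score_id: str, row: ThresholdRow) -> dict:
    return {
        "score_id": score_id,
        "cutoff": row.cutoff,
        "sensitivity": row.sensitivity,
        "specificity": row.specificity,
        "youden_j": row.youden_j,
        "proportion_high_risk": row.proportion_high_risk,
        "observed_cfr_high_risk": row.observed_cfr_high_risk,
    }


def threshold_report(matrix: pd.DataFrame, outcomes) -> dict[str, pd.DataFrame]:
    """Per-score table of operating characteristics at every observed cutoff."""
    y = np.asarray(outcomes)
    return {
        score_id: pd.DataFrame(
            [
                _row_to_dict(score_id, row)
                for row in threshold_table(matrix[score_id].to_numpy(), y)
            ]
        )
        for score_id in matrix.columns
    }


def optimal_cutoff_report(matrix: pd.DataFrame, outcomes) -> pd.DataFrame:
    """The Youden-optimal row per score (ties toward the smaller cutoff)."""
    y = np.asarray(outcomes)
    rows = []
    for score_id in matrix.columns:
        best = optimal_cutoff(threshold_table(matrix[score_id].to_numpy(), y))
        rows.append(_row_to_dict(score_id, best))
    return pd.DataFrame(rows)


def pairwise_pvalue_matrix(matrix: pd.DataFrame, outcomes) -> pd.DataFrame:
    """Symmetric matrix of two-sided paired DeLong p-values (diagonal 1)."""
    y = np.asarray(outcomes)
    ids = list(matrix.columns)
    out = pd.DataFrame(np.ones((len(ids), len(ids))), index=ids, columns=ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            cmp = delong_paired_test(
                matrix[a].to_numpy(), matrix[b].to_numpy(), y, score_a=a, score_b=b
            )
            out.loc[a, b] = out.loc[b, a] = cmp.p_value
    return out
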