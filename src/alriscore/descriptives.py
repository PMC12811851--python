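"""Table-1 style descriptive statistics: counts, crude and adjusted odds ratios.

Crude odds ratios come from 2x2 cross-products with Woolf (log-OR) confidence
intervals, exp(ln OR +/- 1.96 * sqrt(1/a + 1/b + 1/c + 1/d)). Adjusted odds
ratios exponentiate the exposure coefficient of a maximum-likelihood logistic
regression of death on the exposure dummies plus age band (2-5 months
reference) and sex (female reference) — one fit per exposure variable.

The logistic fitter is an iteratively reweighted least squares (Newton)
solver with convergence declared when the log-likelihood changes by less than
1e-8 (at most 25 iterations). Rank-deficient designs raise an error naming the
collinear columns; complete separation is detected and reported as a distinct
failure rather than returning a divergent estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import qr as _qr
from scipy.special import expit

from . import anthropometry as anthro
from .errors import (
    DegenerateInputError,
    RankDeficiencyError,
    SeparationError,
    ZeroCellError,
)
from .records import SIGN_FLAGS, AdmissionRecord, Outcome

__all__ = [
    "TwoByTwo",
    "OrEstimate",
    "LogisticFit",
    "TABLE1_VARIABLES",
    "crude_or",
    "categorical_or",
    "fit_logistic",
    "irls_logistic",
    "build_design",
    "adjusted_or",
    "build_table1",
    "round_half_away",
    "round_table1",
]

_Z95 = 1.959963984540054  # norm.ppf(0.975)


@dataclass(frozen=True)
class TwoByTwo:
    """Exposed/reference x died/discharged cell counts."""

    a: int  # exposed deaths
    b: int  # exposed discharges
    c: int  # reference deaths
    d: int  # reference discharges

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be nonnegative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("2x2 table is empty")


@dataclass(frozen=True)
class OrEstimate:
    odds_ratio: float
    ci95: tuple[float, float]
    kind: str  # "crude" | "adjusted"
    exposure_label: str
    reference_label: str
    log_se: float


def crude_or(
    table: TwoByTwo,
    haldane: bool = False,
    exposure_label: str = "exposed",
    reference_label: str = "reference",
) -> OrEstimate:
    """Cross-product odds ratio with a Woolf confidence interval.

    Zero cells raise :class:`ZeroCellError` unless ``haldane=True`` adds the
    Haldane-Anscombe +0.5 continuity correction to every cell.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ZeroCellError(
                f"2x2 table has a zero cell (a={a}, b={b}, c={c}, d={d}); "
                "pass haldane=True for the +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(or_) - _Z95 * se), math.exp(math.log(or_) + _Z95 * se)
    return OrEstimate(or_, (lo, hi), "crude", exposure_label, reference_label, se)


# ---------------------------------------------------------------------------
# Variable accessor layer shared by the OR machinery and the table builder.

def _sign_accessor(flag: str) -> Callable[[AdmissionRecord], str | None]:
    def fn(r: AdmissionRecord) -> str | None:
        v = r.signs[flag]
        return None if v is None else ("present" if v else "absent")

    return fn


def _opt(fn: Callable, attr: str) -> Callable[[AdmissionRecord], str | None]:
    def accessor(r: AdmissionRecord) -> str | None:
        v = getattr(r, attr)
        return None if v is None else fn(v).value

    return accessor


def _spo2_cat(r: AdmissionRecord) -> str | None:
    if r.spo2_percent is None:
        return None
    if r.spo2_percent < 90:
        return "lt90"
    return "90_92" if r.spo2_percent <= 92 else "gt92"


def _rr_cat(r: AdmissionRecord) -> str | None:
    if r.resp_rate is None or r.age_months < 2:
        return None
    return anthro.respiratory_rate_category(r.resp_rate, r.age_months).value


@dataclass(frozen=True)
class _Variable:
    name: str
    categories: tuple[str, ...]  # reference first
    accessor: Callable[[AdmissionRecord], str | None]

    @property
    def reference(self) -> str:
        return self.categories[0]


_NUT = ("normal", "moderate", "severe")

TABLE1_VARIABLES: dict[str, _Variable] = {
    v.name: v
    for v in [
        _Variable(
            "age_band",
            tuple(b.value for b in anthro.AgeBand),
            # ages below 2 months fall outside the banded range
            lambda r: anthro.age_band(r.age_months).value if r.age_months >= 2 else None,
        ),
        _Variable("sex", ("female", "male"), lambda r: r.sex.value),
        _Variable(
            "resp_rate",
            tuple(c.value for c in anthro.RespRateCategory),
            _rr_cat,
        ),
        _Variable("muac", _NUT, _opt(anthro.classify_muac, "muac_cm")),
        _Variable("waz", _NUT, _opt(anthro.classify_zscore, "waz")),
        _Variable("wlz", _NUT, _opt(anthro.classify_zscore, "wlz")),
        _Variable(
            "conscious_level",
            ("normal", "agitated", "lethargic", "prostrate", "unconscious"),
            lambda r: None if r.conscious_level is None else r.conscious_level.value,
        ),
        _Variable("spo2", ("gt92", "90_92", "lt90"), _spo2_cat),
    ]
    + [
        _Variable(flag, ("absent", "present"), _sign_accessor(flag))
        for flag in SIGN_FLAGS
    ]
}


def _counts(
    records: Sequence[AdmissionRecord], var: _Variable
) -> dict[str, tuple[int, int]]:
    """(deaths, discharges) per observed category; other outcomes are not counted."""
    counts = {c: [0, 0] for c in var.categories}
    for r in records:
        cat = var.accessor(r)
        if cat is None:
            continue
        if r.outcome is Outcome.DIED:
            counts[cat][0] += 1
        elif r.outcome is Outcome.DISCHARGED:
            counts[cat][1] += 1
    return {c: (d, s) for c, (d, s) in counts.items()}


def categorical_or(
    records: Sequence[AdmissionRecord],
    variable: str,
    reference_category: str | None = None,
    haldane: bool = False,
) -> list[OrEstimate]:
    """Crude OR of death for each non-reference category vs the reference.

    Each 2x2 uses only the records in the two categories being compared.
    """
    var = TABLE1_VARIABLES[variable]
    ref = reference_category or var.reference
    if ref not in var.categories:
        raise ValueError(f"{ref!r} is not a category of {variable!r}")
    counts = _counts(records, var)
    c_ref, d_ref = counts[ref]
    if c_ref + d_ref == 0:
        raise DegenerateInputError(
            f"reference category {ref!r} of {variable!r} is empty"
        )
    observed = [c for c in var.categories if sum(counts[c]) > 0]
    if len(observed) < 2:
        raise DegenerateInputError(
            f"variable {variable!r} is constant across records"
        )
    return [
        crude_or(
            TwoByTwo(counts[cat][0], counts[cat][1], c_ref, d_ref),
            haldane=haldane,
            exposure_label=f"{variable}={cat}",
            reference_label=f"{variable}={ref}",
        )
        for cat in observed
        if cat != ref
    ]


# ---------------------------------------------------------------------------
# Logistic regression (IRLS)

@dataclass(frozen=True)
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    cov_params: pd.DataFrame
    loglik: float
    converged: bool
    n_iter: int
    n_obs: int


def irls_logistic(
    X: pd.DataFrame | np.ndarray,
    y: Sequence[int],
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Maximum-likelihood logistic fit by iteratively reweighted least squares.

    Convergence: successive log-likelihood change below *tol* (default 1e-8)
    within *max_iter* (default 25) Newton steps.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        mat = X.to_numpy(dtype=float)
    else:
        mat = np.asarray(X, dtype=float)
        names = [f"x{i}" for i in range(mat.shape[1])]
    yv = np.asarray(y, dtype=float)
    if set(np.unique(yv)) - {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    if yv.min() == yv.max():
        raise DegenerateInputError("response contains a single outcome class")
    n, p = mat.shape
    rank = np.linalg.matrix_rank(mat)
    if rank < p:
        _, _, piv = _qr(mat, mode="economic", pivoting=True)
        culprits = [names[j] for j in piv[rank:]]
        raise RankDeficiencyError(
            f"design matrix is rank deficient (rank {rank} < {p}); "
            f"collinear column(s): {culprits}",
            columns=culprits,
        )

    beta = np.zeros(p)
    ll_prev = -np.inf
    converged = False
    ll = -np.inf
    it = 0
    for it in range(1, max_iter + 1):
        eta = mat @ beta
        mu = expit(eta)
        mu_c = np.clip(mu, 1e-12, 1 - 1e-12)
        w = mu_c * (1 - mu_c)
        h = (mat * w[:, None]).T @ mat
        g = mat.T @ (yv - mu)
        try:
            beta = beta + np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            raise SeparationError(
                "Newton step failed: information matrix is singular "
                "(complete or quasi-complete separation)"
            ) from None
        mu_new = np.clip(expit(mat @ beta), 1e-12, 1 - 1e-12)
        ll = float(yv @ np.log(mu_new) + (1 - yv) @ np.log(1 - mu_new))
        if abs(ll - ll_prev) < tol:
            converged = True
            break
        ll_prev = ll

    if np.max(np.abs(beta)) > 25 or ll > -1e-4:
        raise SeparationError(
            "complete separation detected: the likelihood is unbounded "
            f"(max |coefficient| = {np.max(np.abs(beta)):.1f})"
        )
    mu = np.clip(expit(mat @ beta), 1e-12, 1 - 1e-12)
    w = mu * (1 - mu)
    cov = np.linalg.inv((mat * w[:, None]).T @ mat)
    return LogisticFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(np.sqrt(np.diag(cov)), index=names),
        cov_params=pd.DataFrame(cov, index=names, columns=names),
        loglik=ll,
        converged=converged,
        n_iter=it,
        n_obs=n,
    )


def build_design(
    records: Sequence[AdmissionRecord],
    variables: Sequence[str],
    drop_constant: bool = False,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Intercept + dummy design over declared reference levels, plus 0/1 deaths.

    Records whose outcome is neither death nor discharge, or with any covariate
    unobserved, are omitted (complete-case). With ``drop_constant=True``,
    zero-variance dummy columns are dropped with a warning instead of raising
    a rank error downstream.
    """
    rows = []
    yv = []
    for r in records:
        if r.outcome not in (Outcome.DIED, Outcome.DISCHARGED):
            continue
        cats = {v: TABLE1_VARIABLES[v].accessor(r) for v in variables}
        if any(c is None for c in cats.values()):
            continue
        rows.append(cats)
        yv.append(1.0 if r.outcome is Outcome.DIED else 0.0)
    if not rows:
        raise DegenerateInputError("no usable records for the logistic design")
    X = pd.DataFrame({"intercept": np.ones(len(rows))})
    for v in variables:
        var = TABLE1_VARIABLES[v]
        col = [row[v] for row in rows]
        for cat in var.categories[1:]:
            X[f"{v}[{cat}]"] = np.fromiter(
                (1.0 if c == cat else 0.0 for c in col), float, len(col)
            )
    dropped = []
    for name in list(X.columns[1:]):
        if X[name].nunique() == 1:
            dropped.append(name)
            del X[name]
    if dropped:
        if not drop_constant:
            # constant dummies are structurally absent categories, never
            # informative; dropping silently would hide design degeneracy
            warnings.warn(
                f"dropping constant design column(s): {dropped}", stacklevel=2
            )
    return X, np.asarray(yv), dropped


def fit_logistic(
    records: Sequence[AdmissionRecord],
    covariates: Sequence[str],
    tol: float = 1e-8,
    max_iter: int = 25,
) -> LogisticFit:
    """Logistic regression of in-hospital death on the named variables."""
    X, y, _ = build_design(records, covariates)
    return irls_logistic(X, y, tol=tol, max_iter=max_iter)


_ADJUSTERS = ("age_band", "sex")


def adjusted_or(
    records: Sequence[AdmissionRecord],
    variable: str,
    reference_category: str | None = None,
) -> list[OrEstimate]:
    """Age- and sex-adjusted OR per non-reference category of *variable*.

    One logistic fit per exposure: death ~ exposure + age band + sex. When an
    adjuster is constant in the data its dummies are dropped (with a warning),
    so the adjusted estimate degrades gracefully toward the crude one.
    """
    var = TABLE1_VARIABLES[variable]
    ref = reference_category or var.reference
    if ref != var.reference:
        raise ValueError(
            "adjusted_or uses the declared reference level "
            f"({var.reference!r}) for dummy coding"
        )
    variables = [variable] + [a for a in _ADJUSTERS if a != variable]
    X, y, _ = build_design(records, variables, drop_constant=False)
    fit = irls_logistic(X, y)
    out = []
    for cat in var.categories[1:]:
        name = f"{variable}[{cat}]"
        if name not in fit.params.index:
            continue
        b, se = float(fit.params[name]), float(fit.bse[name])
        out.append(
            OrEstimate(
                math.exp(b),
                (math.exp(b - _Z95 * se), math.exp(b + _Z95 * se)),
                "adjusted",
                f"{variable}={cat}",
                f"{variable}={ref}",
                se,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Table 1

TABLE1_COLUMNS = [
    "variable",
    "category",
    "n_all",
    "pct_all",
    "n_died",
    "pct_died",
    "n_discharged",
    "pct_discharged",
    "or",
    "or_lo",
    "or_hi",
    "aor",
    "aor_lo",
    "aor_hi",
]


def build_table1(
    records: Sequence[AdmissionRecord],
    adjusted: bool = True,
    haldane: bool = False,
) -> pd.DataFrame:
    """Descriptive table stratified by outcome with crude and adjusted ORs.

    Returns unrounded values; :func:`round_table1` applies the 1-decimal
    presentation rounding. Variables whose ORs cannot be estimated (zero
    cells, separation, a degenerate design) keep their counts and leave the
    OR columns empty. Signs are reported as their "present" row only.
    """
    records = [
        r for r in records if r.outcome in (Outcome.DIED, Outcome.DISCHARGED)
    ]
    if not records:
        raise DegenerateInputError("cannot build a descriptive table for an empty cohort")
    n = len(records)
    n_died = sum(r.outcome is Outcome.DIED for r in records)
    n_disc = n - n_died
    rows = [
        {
            "variable": "overall",
            "category": "all",
            "n_all": n,
            "pct_all": 100.0,
            "n_died": n_died,
            "pct_died": 100.0 * n_died / n,
            "n_discharged": n_disc,
            "pct_discharged": 100.0 * n_disc / n,
        }
    ]
    for name, var in TABLE1_VARIABLES.items():
        counts = _counts(records, var)
        tot_d = sum(d for d, _ in counts.values())
        tot_s = sum(s for _, s in counts.values())
        if tot_d + tot_s == 0:
            continue
        crude = {}
        adj = {}
        try:
            crude = {
                e.exposure_label.split("=", 1)[1]: e
                for e in categorical_or(records, name, haldane=haldane)
            }
        except (ZeroCellError, DegenerateInputError):
            pass
        if adjusted:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    adj = {
                        e.exposure_label.split("=", 1)[1]: e
                        for e in adjusted_or(records, name)
                    }
            except (SeparationError, RankDeficiencyError, DegenerateInputError):
                pass
        categories = var.categories
        if categories == ("absent", "present"):
            categories = ("present",)  # sign rows mirror the printed table
        for cat in categories:
            d, s = counts[cat]
            if d + s == 0:
                continue
            row = {
                "variable": name,
                "category": cat,
                "n_all": d + s,
                "pct_all": 100.0 * (d + s) / (tot_d + tot_s),
                "n_died": d,
                "pct_died": (100.0 * d / tot_d) if tot_d else np.nan,
                "n_discharged": s,
                "pct_discharged": (100.0 * s / tot_s) if tot_s else np.nan,
            }
            ce, ae = crude.get(cat), adj.get(cat)
            if ce is not None:
                row |= {"or": ce.odds_ratio, "or_lo": ce.ci95[0], "or_hi": ce.ci95[1]}
            if ae is not None:
                row |= {"aor": ae.odds_ratio, "aor_lo": ae.ci95[0], "aor_hi": ae.ci95[1]}
            rows.append(row)
    return pd.DataFrame(rows, columns=TABLE1_COLUMNS)


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (the table's presentation convention)."""
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return x
    q = 10**decimals
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


def round_table1(table: pd.DataFrame, decimals: int = 1) -> pd.DataFrame:
    """Presentation copy of a Table-1 frame, percentages and ORs to 1 decimal."""
    out = table.copy()
    for col in out.columns:
        if col.startswith(("pct", "or", "aor")):
            out[col] = [
                round_half_away(v, decimals) if pd.notna(v) else v for v in out[col]
            ]
    return out
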