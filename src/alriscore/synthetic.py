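"""Seeded synthetic admission cohorts.

The real surveillance data behind the validation study are not deposited, so
this module generates stand-in cohorts with the same categorical structure:

* :func:`generate_cohort` draws covariate categories independently per
  variable from configurable prevalences, materializes plausible continuous
  measurements inside each category band, and draws in-hospital death from a
  logistic model whose coefficients are, by construction, the conditional
  odds ratios a correctly specified logistic refit should recover. The
  intercept is calibrated by bisection so the expected case fatality rate
  over the drawn covariates matches ``target_cfr`` (tolerance 1e-6).
  Missingness is injected completely at random per field.

* :func:`generate_flowchart_fixture` is a deterministic cohort reproducing
  the study's inclusion flow chart exactly: 2261 eligible admissions, 60 with
  missing required fields (4 missing both weight-derived z-scores, 16 missing
  WAZ only, 38 missing WLZ only, 2 missing the "vomits everything" flag),
  19 with an outcome other than death or discharge (5 absconded, 14
  transferred), leaving 2182 analysable admissions of whom 152 died (7.0%
  case fatality). Within the analysable set, every descriptive variable
  carries the published outcome-stratified category counts exactly (variables
  are assigned independently of each other), so crude odds ratios recomputed
  from the fixture equal the published ones.

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

import math
from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import numpy as np
from pydantic import BaseModel, Field, field_validator, model_validator
from scipy.optimize import brentq
from scipy.special import expit

from .errors import CalibrationError, DegenerateInputError
from .records import SIGN_FLAGS, AdmissionRecord, ConsciousLevel, Outcome, Sex
from .scoring import ScoreRegistry, compute_score, load_score_definitions

__all__ = [
    "GeneratorConfig",
    "VARIABLE_CATEGORIES",
    "table1_like_config",
    "generate_cohort",
    "generate_flowchart_fixture",
    "model_implied_auroc",
]

#: categories per generator variable, reference level first
VARIABLE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "age_band": ("band_2_5", "band_6_12", "band_13_24"),
    "sex": ("female", "male"),
    "resp_rate": ("below_cutoff", "above_0_9", "above_10_19", "above_20_plus"),
    "muac": ("normal", "moderate", "severe"),
    "waz": ("normal", "moderate", "severe"),
    "wlz": ("normal", "moderate", "severe"),
    "conscious_level": ("normal", "agitated", "lethargic", "prostrate", "unconscious"),
    "spo2": ("gt92", "90_92", "lt90"),
    **{flag: ("absent", "present") for flag in SIGN_FLAGS},
}

_AGE_BANDS = {"band_2_5": (2, 5), "band_6_12": (6, 12), "band_13_24": (13, 24)}

# Overall column of the published descriptive table, as prevalences.
_TABLE1_PREVALENCES: dict[str, dict[str, float]] = {
    "age_band": {"band_2_5": 863 / 2182, "band_6_12": 766 / 2182, "band_13_24": 553 / 2182},
    "sex": {"female": 934 / 2182, "male": 1248 / 2182},
    "resp_rate": {
        "below_cutoff": 759 / 2182,
        "above_0_9": 618 / 2182,
        "above_10_19": 465 / 2182,
        "above_20_plus": 340 / 2182,
    },
    "muac": {"normal": 1316 / 2182, "moderate": 401 / 2182, "severe": 465 / 2182},
    "waz": {"normal": 1410 / 2182, "moderate": 418 / 2182, "severe": 354 / 2182},
    "wlz": {"normal": 1763 / 2182, "moderate": 300 / 2182, "severe": 119 / 2182},
    "conscious_level": {
        "normal": 1583 / 2182,
        "agitated": 67 / 2182,
        "lethargic": 335 / 2182,
        "prostrate": 163 / 2182,
        "unconscious": 34 / 2182,
    },
    "spo2": {"gt92": 1778 / 2182, "90_92": 120 / 2182, "lt90": 284 / 2182},
    "chest_indrawing": {"absent": 38 / 2182, "present": 2144 / 2182},
    "convulsion": {"absent": 2092 / 2182, "present": 90 / 2182},
    "cough": {"absent": 128 / 2182, "present": 2054 / 2182},
    "crackles": {"absent": 1049 / 2182, "present": 1133 / 2182},
    "cyanosis": {"absent": 2153 / 2182, "present": 29 / 2182},
    "decreased_skin_turgor": {"absent": 2145 / 2182, "present": 37 / 2182},
    "deep_breathing": {"absent": 1702 / 2182, "present": 480 / 2182},
    "diarrhea": {"absent": 1873 / 2182, "present": 309 / 2182},
    "head_nodding": {"absent": 1807 / 2182, "present": 375 / 2182},
    "nasal_flaring": {"absent": 750 / 2182, "present": 1432 / 2182},
    "pallor": {"absent": 1795 / 2182, "present": 387 / 2182},
    "sunken_eye": {"absent": 2098 / 2182, "present": 84 / 2182},
    "vomiting": {"absent": 1748 / 2182, "present": 434 / 2182},
    "vomits_everything": {"absent": 2055 / 2182, "present": 127 / 2182},
    "unable_to_drink": {"absent": 1938 / 2182, "present": 244 / 2182},
    "wheeze": {"absent": 1810 / 2182, "present": 372 / 2182},
}

# Published age/sex-adjusted odds ratios, used as the conditional effects of
# the default outcome model (log scale).
_TABLE1_LOG_ORS: dict[str, dict[str, float]] = {
    "age_band": {"band_6_12": math.log(0.6), "band_13_24": math.log(0.5)},
    "sex": {"male": math.log(0.7)},
    "resp_rate": {
        "above_0_9": math.log(1.0),
        "above_10_19": math.log(1.1),
        "above_20_plus": math.log(2.3),
    },
    "muac": {"moderate": math.log(2.6), "severe": math.log(7.4)},
    "waz": {"moderate": math.log(2.5), "severe": math.log(5.3)},
    "wlz": {"moderate": math.log(2.9), "severe": math.log(3.5)},
    "conscious_level": {
        "agitated": math.log(7.1),
        "lethargic": math.log(2.8),
        "prostrate": math.log(7.3),
        "unconscious": math.log(19.4),
    },
    "spo2": {"90_92": math.log(1.5), "lt90": math.log(6.4)},
    "chest_indrawing": {"present": math.log(0.2)},
    "convulsion": {"present": math.log(2.5)},
    "cough": {"present": math.log(0.3)},
    "crackles": {"present": math.log(0.8)},
    "cyanosis": {"present": math.log(10.1)},
    "decreased_skin_turgor": {"present": math.log(8.8)},
    "deep_breathing": {"present": math.log(3.4)},
    "diarrhea": {"present": math.log(1.5)},
    "head_nodding": {"present": math.log(1.0)},
    "nasal_flaring": {"present": math.log(1.2)},
    "pallor": {"present": math.log(3.6)},
    "sunken_eye": {"present": math.log(4.5)},
    "vomiting": {"present": math.log(1.4)},
    "vomits_everything": {"present": math.log(2.6)},
    "unable_to_drink": {"present": math.log(3.2)},
    "wheeze": {"present": math.log(0.7)},
}

#: fields that can be made missing-at-random
MISSABLE_FIELDS = (
    "resp_rate",
    "spo2_percent",
    "conscious_level",
    "muac_cm",
    "waz",
    "wlz",
) + tuple(f"signs.{f}" for f in SIGN_FLAGS)


class GeneratorConfig(BaseModel):
    """Study-condition parameters of the synthetic cohort generator."""

    n_admissions: int = Field(gt=0)
    category_prevalences: dict[str, dict[str, float]]
    outcome_coefficients: dict[str, dict[str, float]] = Field(default_factory=dict)
    target_cfr: float = Field(gt=0.0, lt=1.0, default=0.07)
    date_range: tuple[date, date] = (date(2015, 1, 1), date(2024, 12, 31))
    missingness_rates: dict[str, float] = Field(default_factory=dict)
    seed: int = 0

    @field_validator("category_prevalences")
    @classmethod
    def _check_prevalences(cls, v):
        for var, prev in v.items():
            if var not in VARIABLE_CATEGORIES:
                raise ValueError(f"unknown variable {var!r}")
            unknown = set(prev) - set(VARIABLE_CATEGORIES[var])
            if unknown:
                raise ValueError(f"{var}: unknown categories {sorted(unknown)}")
            total = sum(prev.values())
            if abs(total - 1.0) > 1e-6:
                raise ValueError(f"{var}: prevalences sum to {total}, expected 1")
            if any(p < 0 for p in prev.values()):
                raise ValueError(f"{var}: negative prevalence")
        missing = set(VARIABLE_CATEGORIES) - set(v)
        if missing:
            raise ValueError(f"prevalences missing for variables {sorted(missing)}")
        return v

    @field_validator("outcome_coefficients")
    @classmethod
    def _check_coefficients(cls, v):
        for var, coeffs in v.items():
            if var not in VARIABLE_CATEGORIES:
                raise ValueError(f"unknown variable {var!r}")
            cats = VARIABLE_CATEGORIES[var]
            unknown = set(coeffs) - set(cats[1:])
            if unknown:
                raise ValueError(
                    f"{var}: coefficients for non-exposure categories {sorted(unknown)} "
                    f"(reference {cats[0]!r} is fixed at 0)"
                )
        return v

    @field_validator("missingness_rates")
    @classmethod
    def _check_missingness(cls, v):
        for f, rate in v.items():
            if f not in MISSABLE_FIELDS:
                raise ValueError(f"field {f!r} cannot be made missing")
            if not 0 <= rate <= 1:
                raise ValueError(f"{f}: missingness rate {rate} outside [0, 1]")
        return v

    @model_validator(mode="after")
    def _check_dates(self):
        if self.date_range[0] > self.date_range[1]:
            raise ValueError("date_range start is after its end")
        return self


def table1_like_config(
    n_admissions: int = 2182, seed: int = 0, **overrides
) -> GeneratorConfig:
    """Default config: published prevalences, adjusted ORs as conditional effects."""
    params = dict(
        n_admissions=n_admissions,
        category_prevalences={k: dict(v) for k, v in _TABLE1_PREVALENCES.items()},
        outcome_coefficients={k: dict(v) for k, v in _TABLE1_LOG_ORS.items()},
        target_cfr=0.07,
        seed=seed,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


def null_config(n_admissions: int, seed: int = 0, **overrides) -> GeneratorConfig:
    """Table-1-like covariates with an outcome independent of all of them."""
    return table1_like_config(
        n_admissions, seed=seed, outcome_coefficients={}, **overrides
    )


# ---------------------------------------------------------------------------
# Drawing machinery

def _draw_categories(
    rng: np.random.Generator, config: GeneratorConfig, n: int
) -> dict[str, np.ndarray]:
    cats = {}
    for var, levels in VARIABLE_CATEGORIES.items():
        prev = config.category_prevalences[var]
        p = np.array([prev.get(c, 0.0) for c in levels])
        cats[var] = rng.choice(len(levels), size=n, p=p / p.sum())
    return cats


def _linear_predictor(
    config: GeneratorConfig, cats: Mapping[str, np.ndarray]
) -> np.ndarray:
    n = len(next(iter(cats.values())))
    lp = np.zeros(n)
    for var, coeffs in config.outcome_coefficients.items():
        levels = VARIABLE_CATEGORIES[var]
        beta = np.array([coeffs.get(c, 0.0) for c in levels])
        lp += beta[cats[var]]
    return lp


def _calibrate_intercept(lp: np.ndarray, target_cfr: float) -> float:
    def gap(b0: float) -> float:
        return float(expit(b0 + lp).mean() - target_cfr)

    lo, hi = -40.0, 40.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise CalibrationError(
            f"target CFR {target_cfr} is unreachable for the configured coefficients"
        )
    return float(brentq(gap, lo, hi, xtol=1e-9))


def _materialize(
    rng: np.random.Generator,
    cats: Mapping[str, np.ndarray],
    outcomes: Sequence[Outcome],
    dates: Sequence[date],
    id_prefix: str = "SYN",
    id_start: int = 0,
) -> list[AdmissionRecord]:
    """Build records from category codes, drawing values inside each band."""
    n = len(outcomes)
    levels = {v: VARIABLE_CATEGORIES[v] for v in cats}

    age = np.empty(n, dtype=int)
    for k, band in enumerate(levels["age_band"]):
        mask = cats["age_band"] == k
        lo, hi = _AGE_BANDS[band]
        age[mask] = rng.integers(lo, hi + 1, size=int(mask.sum()))

    cutoff = np.where(age < 12, 40, 50)
    rr = np.empty(n, dtype=float)
    offsets = {
        "below_cutoff": (-15, 0),
        "above_0_9": (0, 10),
        "above_10_19": (10, 20),
        "above_20_plus": (20, 36),
    }
    for k, cat in enumerate(levels["resp_rate"]):
        mask = cats["resp_rate"] == k
        lo, hi = offsets[cat]
        rr[mask] = cutoff[mask] + rng.integers(lo, hi, size=int(mask.sum()))

    spo2 = np.empty(n, dtype=int)
    spo2_bands = {"gt92": (93, 101), "90_92": (90, 93), "lt90": (70, 90)}
    for k, cat in enumerate(levels["spo2"]):
        mask = cats["spo2"] == k
        lo, hi = spo2_bands[cat]
        spo2[mask] = rng.integers(lo, hi, size=int(mask.sum()))

    def continuous(var: str, bands: dict[str, tuple[float, float]], dec: int):
        out = np.empty(n, dtype=float)
        for k, cat in enumerate(levels[var]):
            mask = cats[var] == k
            lo, hi = bands[cat]
            out[mask] = np.round(rng.uniform(lo, hi, size=int(mask.sum())), dec)
        return out

    muac = continuous(
        "muac", {"normal": (12.5, 16.0), "moderate": (11.5, 12.449), "severe": (9.0, 11.449)}, 1
    )
    zbands = {"normal": (-1.99, 1.5), "moderate": (-2.99, -2.01), "severe": (-4.5, -3.01)}
    waz = continuous("waz", zbands, 2)
    wlz = continuous("wlz", zbands, 2)

    conscious = [ConsciousLevel(levels["conscious_level"][k]) for k in cats["conscious_level"]]
    sexes = [Sex(levels["sex"][k]) for k in cats["sex"]]
    sign_arrays = {flag: cats[flag].astype(bool) for flag in SIGN_FLAGS}

    records = []
    for i in range(n):
        records.append(
            AdmissionRecord(
                admission_id=f"{id_prefix}{id_start + i:06d}",
                age_months=int(age[i]),
                sex=sexes[i],
                admission_date=dates[i],
                outcome=outcomes[i],
                resp_rate=float(rr[i]),
                spo2_percent=int(spo2[i]),
                conscious_level=conscious[i],
                muac_cm=float(muac[i]),
                waz=float(waz[i]),
                wlz=float(wlz[i]),
                signs={f: bool(sign_arrays[f][i]) for f in SIGN_FLAGS},
                alri_discharge_dx=True,
                severe_alri_presentation=True,
            )
        )
    return records


def _draw_dates(rng: np.random.Generator, config_range: tuple[date, date], n: int):
    start, end = config_range
    span = (end - start).days + 1
    return [start + timedelta(days=int(d)) for d in rng.integers(0, span, size=n)]


def _apply_missingness(
    rng: np.random.Generator,
    records: list[AdmissionRecord],
    rates: Mapping[str, float],
) -> list[AdmissionRecord]:
    if not rates:
        return records
    out = []
    for r in records:
        changes = {}
        sign_changes = {}
        for field_name, rate in rates.items():
            if rate and rng.random() < rate:
                if field_name.startswith("signs."):
                    sign_changes[field_name.split(".", 1)[1]] = None
                else:
                    changes[field_name] = None
        if sign_changes:
            changes["signs"] = {**r.signs, **sign_changes}
        out.append(r.with_(**changes) if changes else r)
    return out


def generate_cohort(config: GeneratorConfig) -> list[AdmissionRecord]:
    """Draw a fully reproducible synthetic cohort under the logistic outcome model."""
    rng = np.random.default_rng(config.seed)
    n = config.n_admissions
    cats = _draw_categories(rng, config, n)
    lp = _linear_predictor(config, cats)
    b0 = _calibrate_intercept(lp, config.target_cfr)
    p = expit(b0 + lp)
    died = rng.random(n) < p
    outcomes = [Outcome.DIED if d else Outcome.DISCHARGED for d in died]
    dates = _draw_dates(rng, config.date_range, n)
    records = _materialize(rng, cats, outcomes, dates)
    return _apply_missingness(rng, records, config.missingness_rates)


def model_implied_auroc(
    config: GeneratorConfig,
    score_id: str,
    registry: ScoreRegistry | None = None,
    n_mc: int = 200_000,
    seed: int | None = None,
) -> float:
    """Monte-Carlo AUROC of a score under the generator's outcome model.

    Draws ``n_mc`` covariate profiles, scores each, and weights every profile
    by its death probability: the estimate is
    P(score_death > score_survivor) + 0.5 P(equal) under the model, which
    integrates out the Bernoulli outcome draw and so has lower Monte-Carlo
    error than scoring a simulated cohort of the same size.
    """
    registry = registry if registry is not None else load_score_definitions()
    definition = registry.require(score_id)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    cats = _draw_categories(rng, config, n_mc)
    lp = _linear_predictor(config, cats)
    b0 = _calibrate_intercept(lp, config.target_cfr)
    p = expit(b0 + lp)
    outcomes = [Outcome.DISCHARGED] * n_mc  # placeholder; outcome integrated out
    dates = [config.date_range[0]] * n_mc
    records = _materialize(rng, cats, outcomes, dates)
    totals = np.fromiter(
        (compute_score(r, definition).total for r in records), float, n_mc
    )
    w_pos, w_neg = p, 1.0 - p
    tot_pos, tot_neg = float(w_pos.sum()), float(w_neg.sum())
    if tot_pos <= 0 or tot_neg <= 0:
        raise DegenerateInputError("generated outcome distribution is degenerate")
    order = np.argsort(totals, kind="stable")
    s_sorted = totals[order]
    wp, wn = w_pos[order], w_neg[order]
    # group by distinct score value; positives beat all negatives below them
    num = 0.0
    cum_neg = 0.0
    i = 0
    while i < n_mc:
        j = i
        while j < n_mc and s_sorted[j] == s_sorted[i]:
            j += 1
        grp_pos = float(wp[i:j].sum())
        grp_neg = float(wn[i:j].sum())
        num += grp_pos * cum_neg + 0.5 * grp_pos * grp_neg
        cum_neg += grp_neg
        i = j
    return num / (tot_pos * tot_neg)


# ---------------------------------------------------------------------------
# Flow-chart fixture

# (deaths, discharges) per category among the 2182 analysable admissions.
_FIXTURE_COUNTS: dict[str, dict[str, tuple[int, int]]] = {
    "age_band": {"band_2_5": (80, 783), "band_6_12": (44, 722), "band_13_24": (28, 525)},
    "sex": {"female": (78, 856), "male": (74, 1174)},
    "resp_rate": {
        "below_cutoff": (46, 713),
        "above_0_9": (35, 583),
        "above_10_19": (30, 435),
        "above_20_plus": (41, 299),
    },
    "muac": {"normal": (37, 1279), "moderate": (29, 372), "severe": (86, 379)},
    "waz": {"normal": (63, 1347), "moderate": (35, 383), "severe": (54, 300)},
    "wlz": {"normal": (101, 1662), "moderate": (36, 264), "severe": (15, 104)},
    "conscious_level": {
        "normal": (58, 1525),
        "agitated": (14, 53),
        "lethargic": (30, 305),
        "prostrate": (36, 127),
        "unconscious": (14, 20),
    },
    "spo2": {"gt92": (78, 1700), "90_92": (8, 112), "lt90": (66, 218)},
    "chest_indrawing": {"present": (143, 2001)},
    "convulsion": {"present": (13, 77)},
    "cough": {"present": (129, 1925)},
    "crackles": {"present": (71, 1062)},
    "cyanosis": {"present": (12, 17)},
    "decreased_skin_turgor": {"present": (13, 24)},
    "deep_breathing": {"present": (70, 410)},
    "diarrhea": {"present": (27, 282)},
    "head_nodding": {"present": (28, 347)},
    "nasal_flaring": {"present": (105, 1327)},
    "pallor": {"present": (59, 328)},
    "sunken_eye": {"present": (18, 66)},
    "vomiting": {"present": (36, 398)},
    "vomits_everything": {"present": (17, 110)},
    "unable_to_drink": {"present": (42, 202)},
    "wheeze": {"present": (19, 353)},
}

_N_INCLUDED, _N_DIED = 2182, 152
_N_MISSING, _N_OTHER = 60, 19


def _exact_category_codes(
    rng: np.random.Generator, var: str, group_sizes: tuple[int, int]
) -> np.ndarray:
    """Category codes with exact per-outcome counts, shuffled within outcome."""
    levels = VARIABLE_CATEGORIES[var]
    spec = _FIXTURE_COUNTS[var]
    out = []
    for gi, size in enumerate(group_sizes):  # 0 = died, 1 = discharged
        if set(spec) == {"present"}:
            n_present = spec["present"][gi]
            codes = np.array([1] * n_present + [0] * (size - n_present))
        else:
            codes = np.concatenate(
                [np.full(spec[c][gi], k) for k, c in enumerate(levels)]
            )
            assert len(codes) == size
        rng.shuffle(codes)
        out.append(codes)
    return np.concatenate(out)


def generate_flowchart_fixture(seed: int = 0) -> list[AdmissionRecord]:
    """Deterministic 2261-admission cohort matching the inclusion flow chart."""
    rng = np.random.default_rng(seed)

    # -- 2182 complete, analysable admissions (152 deaths first, then discharges)
    group_sizes = (_N_DIED, _N_INCLUDED - _N_DIED)
    cats = {
        var: _exact_category_codes(rng, var, group_sizes) for var in VARIABLE_CATEGORIES
    }
    outcomes = [Outcome.DIED] * _N_DIED + [Outcome.DISCHARGED] * (
        _N_INCLUDED - _N_DIED
    )
    dates = _draw_dates(rng, (date(2015, 1, 1), date(2024, 12, 31)), _N_INCLUDED)
    complete = _materialize(rng, cats, outcomes, dates, id_prefix="ADM")

    # -- 60 otherwise-eligible admissions excluded for missing data
    cfg = table1_like_config(n_admissions=_N_MISSING, seed=seed)
    mcats = _draw_categories(rng, cfg, _N_MISSING)
    mdied = rng.random(_N_MISSING) < 0.07
    moutcomes = [Outcome.DIED if d else Outcome.DISCHARGED for d in mdied]
    mdates = _draw_dates(rng, (date(2015, 1, 1), date(2024, 12, 31)), _N_MISSING)
    missing = _materialize(rng, mcats, moutcomes, mdates, id_prefix="ADM", id_start=_N_INCLUDED)
    patched = []
    for i, r in enumerate(missing):
        if i < 4:  # weight not measured: both derived z-scores absent
            patched.append(r.with_(waz=None, wlz=None))
        elif i < 20:
            patched.append(r.with_(waz=None))
        elif i < 58:
            patched.append(r.with_(wlz=None))
        else:  # 2 records missing the vomits-everything flag
            patched.append(r.with_(signs={**r.signs, "vomits_everything": None}))
    missing = patched

    # -- 19 admissions with an outcome other than death or discharge
    ocats = _draw_categories(rng, cfg, _N_OTHER)
    ooutcomes = [Outcome.ABSCONDED] * 5 + [Outcome.TRANSFERRED] * 14
    odates = _draw_dates(rng, (date(2015, 1, 1), date(2024, 12, 31)), _N_OTHER)
    other = _materialize(
        rng, ocats, ooutcomes, odates, id_prefix="ADM", id_start=_N_INCLUDED + _N_MISSING
    )

    cohort = complete + missing + other
    order = rng.permutation(len(cohort))
    return [cohort[i] for i in order]
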