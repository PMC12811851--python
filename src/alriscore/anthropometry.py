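"""Nutrition-status and vital-sign categorization.

Malnutrition thresholds follow the standard anthropometric conventions: MUAC
below 12.5 cm is moderate and below 11.5 cm severe; weight-derived z-scores
below -2 are moderate and below -3 severe. All thresholds are strict
less-than on the lower side (a z-score of exactly -2 is *not* moderate).

Fast-breathing categories are relative to the WHO age-specific cutoff:
40 breaths/min for ages 2-11 months and 50 breaths/min from 12 months up.
"""

from __future__ import annotations

import math
from enum import Enum

from .errors import UnsupportedAgeError

__all__ = [
    "NutritionCategory",
    "RespRateCategory",
    "AgeBand",
    "classify_muac",
    "classify_zscore",
    "respiratory_rate_category",
    "age_band",
    "nutrition_points",
]


class NutritionCategory(str, Enum):
    NORMAL = "normal"
    MODERATE = "moderate"
    SEVERE = "severe"


class RespRateCategory(str, Enum):
    BELOW_CUTOFF = "below_cutoff"
    ABOVE_0_9 = "above_0_9"
    ABOVE_10_19 = "above_10_19"
    ABOVE_20_PLUS = "above_20_plus"


class AgeBand(str, Enum):
    BAND_2_5 = "band_2_5"
    BAND_6_12 = "band_6_12"
    BAND_13_24 = "band_13_24"
    BAND_25_59 = "band_25_59"


def classify_muac(muac_cm: float) -> NutritionCategory:
    """Classify mid-upper arm circumference: <11.5 severe, <12.5 moderate."""
    if not (muac_cm > 0) or not math.isfinite(muac_cm):
        raise ValueError(f"MUAC must be a positive length in cm, got {muac_cm}")
    if muac_cm < 11.5:
        return NutritionCategory.SEVERE
    if muac_cm < 12.5:
        return NutritionCategory.MODERATE
    return NutritionCategory.NORMAL


def classify_zscore(z: float) -> NutritionCategory:
    """Classify a weight-derived z-score: < -3 severe, < -2 moderate."""
    if not math.isfinite(z):
        raise ValueError(f"z-score must be finite, got {z}")
    if z < -3:
        return NutritionCategory.SEVERE
    if z < -2:
        return NutritionCategory.MODERATE
    return NutritionCategory.NORMAL


def who_rate_cutoff(age_months: int) -> int:
    """WHO fast-breathing cutoff: 40 bpm for 2-11 months, 50 bpm from 12 months."""
    if age_months < 2:
        raise UnsupportedAgeError(
            f"fast-breathing cutoffs are defined from 2 months, got {age_months}"
        )
    return 40 if age_months < 12 else 50


def respiratory_rate_category(resp_rate: float, age_months: int) -> RespRateCategory:
    """Band the respiratory rate by its excess over the age-specific cutoff."""
    if resp_rate < 0:
        raise ValueError(f"respiratory rate must be nonnegative, got {resp_rate}")
    excess = resp_rate - who_rate_cutoff(age_months)
    if excess < 0:
        return RespRateCategory.BELOW_CUTOFF
    if excess < 10:
        return RespRateCategory.ABOVE_0_9
    if excess < 20:
        return RespRateCategory.ABOVE_10_19
    return RespRateCategory.ABOVE_20_PLUS


def age_band(age_months: int) -> AgeBand:
    """Inclusive month bands 2-5, 6-12, 13-24, 25-59."""
    if not 2 <= age_months <= 59:
        raise ValueError(f"age_months must be within 2-59, got {age_months}")
    if age_months <= 5:
        return AgeBand.BAND_2_5
    if age_months <= 12:
        return AgeBand.BAND_6_12
    if age_months <= 24:
        return AgeBand.BAND_13_24
    return AgeBand.BAND_25_59


_NUTRITION_POINTS = {
    NutritionCategory.NORMAL: 0,
    NutritionCategory.MODERATE: 2,
    NutritionCategory.SEVERE: 3,
}


def nutrition_points(category: NutritionCategory) -> int:
    """Severity points added for malnutrition: 0 / 2 / 3."""
    return _NUTRITION_POINTS[NutritionCategory(category)]
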