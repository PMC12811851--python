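"""Declarative engine for point-based clinical severity scores.

A score is data, not code: a :class:`ScoreDefinition` lists components, each
of which names a registered *extractor* (a deterministic mapping from record
fields to a category) and a category -> integer-points table. The engine
evaluates any such definition against an :class:`~alriscore.records.AdmissionRecord`.
Eight definitions ship in ``data/score_definitions.yaml``: RISC (HIV-negative),
mRISC, the two RISC-Malawi variants (MUAC / WAZ), PERCH, PREPARE, ReSVinet and
a nutrition-augmented ReSVinet.

Components a retrospective dataset cannot assess at all (e.g. ReSVinet's apnea
and medical-intervention items) are declared under ``unavailable_components``
and contribute nothing; components whose fields are missing for an individual
record either raise (policy ``fail``, complete-case analysis) or contribute 0
and are listed as skipped (policy ``skip``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd
import yaml

from . import anthropometry as anthro
from .errors import CohortSchemaError, MissingDataError
from .records import SIGN_FLAGS, AdmissionRecord

__all__ = [
    "ComponentRule",
    "ScoreDefinition",
    "ScoreResult",
    "ScoreRegistry",
    "load_score_definitions",
    "serialize_registry",
    "compute_score",
    "compute_modified_resvinet",
    "compute_score_matrix",
    "EXTRACTORS",
]


# ---------------------------------------------------------------------------
# Extractors: named deterministic mappings record -> category string.

@dataclass(frozen=True)
class _Extractor:
    fn: Callable[[AdmissionRecord], str]
    categories: tuple[str, ...]
    fields: tuple[str, ...]  # record fields the extractor reads


def _nutrition(attr: str) -> _Extractor:
    classify = anthro.classify_muac if attr == "muac_cm" else anthro.classify_zscore

    def fn(r: AdmissionRecord) -> str:
        return classify(getattr(r, attr)).value

    return _Extractor(fn, ("normal", "moderate", "severe"), (attr,))


def _spo2_band(r: AdmissionRecord) -> str:
    s = r.spo2_percent
    if s < 90:
        return "lt90"
    if s <= 92:
        return "90_92"
    return "gt92"


def _resvinet_feeding(r: AdmissionRecord) -> str:
    # Severity of feeding intolerance; mild presentations are not separable
    # from normal in routinely collected signs and map to "normal".
    if r.signs["unable_to_drink"]:
        return "unable"
    if r.signs["vomits_everything"]:
        return "reduced"
    return "normal"


def _resvinet_resp_difficulty(r: AdmissionRecord) -> str:
    if r.signs["cyanosis"]:
        return "severe"
    if r.signs["chest_indrawing"]:
        return "moderate"
    if r.signs["nasal_flaring"] or r.signs["head_nodding"]:
        return "mild"
    return "none"


EXTRACTORS: dict[str, _Extractor] = {
    "muac_category": _nutrition("muac_cm"),
    "waz_category": _nutrition("waz"),
    "wlz_category": _nutrition("wlz"),
    "spo2_band": _Extractor(_spo2_band, ("gt92", "90_92", "lt90"), ("spo2_percent",)),
    "spo2_lt90": _Extractor(
        lambda r: "yes" if r.spo2_percent < 90 else "no",
        ("no", "yes"),
        ("spo2_percent",),
    ),
    "conscious_level": _Extractor(
        lambda r: r.conscious_level.value,
        ("normal", "agitated", "lethargic", "prostrate", "unconscious"),
        ("conscious_level",),
    ),
    "conscious_abnormal": _Extractor(
        lambda r: "normal" if r.conscious_level.value == "normal" else "abnormal",
        ("normal", "abnormal"),
        ("conscious_level",),
    ),
    "resp_rate_band": _Extractor(
        lambda r: anthro.respiratory_rate_category(r.resp_rate, r.age_months).value,
        tuple(c.value for c in anthro.RespRateCategory),
        ("resp_rate", "age_months"),
    ),
    "age_band": _Extractor(
        lambda r: anthro.age_band(r.age_months).value,
        tuple(b.value for b in anthro.AgeBand),
        ("age_months",),
    ),
    "sex": _Extractor(lambda r: r.sex.value, ("female", "male"), ("sex",)),
    "resvinet_feeding": _Extractor(
        _resvinet_feeding,
        ("normal", "reduced", "unable"),
        ("signs.unable_to_drink", "signs.vomits_everything"),
    ),
    "resvinet_resp_difficulty": _Extractor(
        _resvinet_resp_difficulty,
        ("none", "mild", "moderate", "severe"),
        (
            "signs.cyanosis",
            "signs.chest_indrawing",
            "signs.nasal_flaring",
            "signs.head_nodding",
        ),
    ),
}

# one binary extractor per clinical sign, e.g. "sign:wheeze"
for _flag in SIGN_FLAGS:
    EXTRACTORS[f"sign:{_flag}"] = _Extractor(
        (lambda r, f=_flag: "present" if r.signs[f] else "absent"),
        ("absent", "present"),
        (f"signs.{_flag}",),
    )


# ---------------------------------------------------------------------------
# Definitions

@dataclass(frozen=True)
class ComponentRule:
    """One score component: extractor plus category -> points table."""

    component_id: str
    extractor: str
    category_points: Mapping[str, int]
    required_fields: tuple[str, ...]

    @property
    def min_points(self) -> int:
        return min(self.category_points.values())

    @property
    def max_points(self) -> int:
        return max(self.category_points.values())


@dataclass(frozen=True)
class ScoreDefinition:
    """A complete point-based score."""

    score_id: str
    label: str
    components: tuple[ComponentRule, ...]
    theoretical_min: int
    theoretical_max: int
    unavailable_components: tuple[str, ...] = ()


@dataclass(frozen=True)
class ScoreResult:
    """Integer total for one record under one score."""

    score_id: str
    total: int
    components_used: tuple[str, ...]
    components_skipped_missing: tuple[str, ...] = ()


class ScoreRegistry(dict):
    """Mapping score_id -> ScoreDefinition, insertion ordered."""

    def require(self, score_id: str) -> ScoreDefinition:
        try:
            return self[score_id]
        except KeyError:
            raise CohortSchemaError(
                f"unknown score {score_id!r}; available: {sorted(self)}"
            ) from None


def _validate_component(score_id: str, raw: Mapping) -> ComponentRule:
    cid = raw.get("component_id")
    name = raw.get("extractor")
    if name not in EXTRACTORS:
        raise CohortSchemaError(
            f"score {score_id!r}, component {cid!r}: unknown extractor {name!r}"
        )
    ext = EXTRACTORS[name]
    points = dict(raw.get("category_points") or {})
    missing_cats = [c for c in ext.categories if c not in points]
    if missing_cats:
        raise CohortSchemaError(
            f"score {score_id!r}, component {cid!r}: no point value for "
            f"category {missing_cats[0]!r}"
        )
    unknown_cats = [c for c in points if c not in ext.categories]
    if unknown_cats:
        raise CohortSchemaError(
            f"score {score_id!r}, component {cid!r}: category {unknown_cats[0]!r} "
            f"is outside the extractor's range {ext.categories}"
        )
    req = tuple(raw.get("required_fields") or ())
    if not req:
        raise CohortSchemaError(
            f"score {score_id!r}, component {cid!r}: required_fields is empty"
        )
    return ComponentRule(cid, name, points, req)


def _validate_definition(raw: Mapping) -> ScoreDefinition:
    sid = raw.get("score_id")
    comps = tuple(_validate_component(sid, c) for c in raw.get("components", ()))
    ids = [c.component_id for c in comps]
    dupes = {i for i in ids if ids.count(i) > 1}
    if dupes:
        raise CohortSchemaError(
            f"score {sid!r}: duplicate component_id {sorted(dupes)[0]!r}"
        )
    tmin, tmax = raw.get("theoretical_min"), raw.get("theoretical_max")
    if tmin != sum(c.min_points for c in comps) or tmax != sum(
        c.max_points for c in comps
    ):
        raise CohortSchemaError(
            f"score {sid!r}: theoretical_min/max ({tmin}, {tmax}) do not equal the "
            f"sums of per-component extrema "
            f"({sum(c.min_points for c in comps)}, {sum(c.max_points for c in comps)})"
        )
    return ScoreDefinition(
        score_id=sid,
        label=raw.get("label", sid),
        components=comps,
        theoretical_min=tmin,
        theoretical_max=tmax,
        unavailable_components=tuple(raw.get("unavailable_components") or ()),
    )


def load_score_definitions(config_path: str | Path | None = None) -> ScoreRegistry:
    """Load and validate score definitions (bundled file by default)."""
    if config_path is None:
        text = (
            resources.files("alriscore").joinpath("data/score_definitions.yaml")
        ).read_text(encoding="utf-8")
    else:
        text = Path(config_path).read_text(encoding="utf-8")
    doc = yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "scores" not in doc:
        raise CohortSchemaError("definition file must contain a top-level 'scores' list")
    registry = ScoreRegistry()
    for raw in doc["scores"]:
        d = _validate_definition(raw)
        if d.score_id in registry:
            raise CohortSchemaError(f"duplicate score_id {d.score_id!r}")
        registry[d.score_id] = d
    return registry


def serialize_registry(registry: ScoreRegistry) -> str:
    """YAML text that reparses (via :func:`load_score_definitions`) to an equal registry."""
    doc = {
        "scores": [
            {
                "score_id": d.score_id,
                "label": d.label,
                "theoretical_min": d.theoretical_min,
                "theoretical_max": d.theoretical_max,
                "unavailable_components": list(d.unavailable_components),
                "components": [
                    {
                        "component_id": c.component_id,
                        "extractor": c.extractor,
                        "required_fields": list(c.required_fields),
                        "category_points": dict(c.category_points),
                    }
                    for c in d.components
                ],
            }
            for d in registry.values()
        ]
    }
    return yaml.safe_dump(doc, sort_keys=False)


# ---------------------------------------------------------------------------
# Evaluation

def _component_missing(record: AdmissionRecord, rule: ComponentRule) -> str | None:
    from .records import field_is_missing

    for f in rule.required_fields:
        if f == "age_months" or f == "sex":
            continue  # always present by record invariant
        if field_is_missing(record, f):
            return f
    return None


def compute_score(
    record: AdmissionRecord,
    definition: ScoreDefinition,
    missing_policy: str = "fail",
) -> ScoreResult:
    """Evaluate one score on one record.

    ``missing_policy="fail"`` raises :class:`MissingDataError` on the first
    component whose required field is absent; ``"skip"`` lets that component
    contribute 0 points and records it under ``components_skipped_missing``.
    """
    if missing_policy not in ("fail", "skip"):
        raise ValueError(f"missing_policy must be 'fail' or 'skip', got {missing_policy!r}")
    total = 0
    used: list[str] = []
    skipped: list[str] = []
    for rule in definition.components:
        absent = _component_missing(record, rule)
        if absent is not None:
            if missing_policy == "fail":
                raise MissingDataError(
                    f"score {definition.score_id!r}: component "
                    f"{rule.component_id!r} requires missing field {absent!r} "
                    f"(admission {record.admission_id})",
                    component=rule.component_id,
                    field=absent,
                )
            skipped.append(rule.component_id)
            continue
        category = EXTRACTORS[rule.extractor].fn(record)
        total += rule.category_points[category]
        used.append(rule.component_id)
    return ScoreResult(
        score_id=definition.score_id,
        total=total,
        components_used=tuple(used),
        components_skipped_missing=tuple(skipped),
    )


_NUTRITION_FIELD = {"muac": "muac_cm", "waz": "waz", "wlz": "wlz"}
_NUTRITION_CLASSIFY = {
    "muac": anthro.classify_muac,
    "waz": anthro.classify_zscore,
    "wlz": anthro.classify_zscore,
}


def compute_modified_resvinet(
    record: AdmissionRecord,
    nutrition_measure: str = "muac",
    registry: ScoreRegistry | None = None,
    missing_policy: str = "fail",
) -> ScoreResult:
    """ReSVinet total plus malnutrition points from the chosen measure.

    The three variants (``muac``, ``waz``, ``wlz``) differ only in the
    nutrition component: +2 points for moderate and +3 for severe malnutrition.
    """
    if nutrition_measure not in _NUTRITION_FIELD:
        raise ValueError(
            f"nutrition_measure must be one of {sorted(_NUTRITION_FIELD)}, "
            f"got {nutrition_measure!r}"
        )
    registry = registry if registry is not None else load_score_definitions()
    base = compute_score(record, registry.require("resvinet"), missing_policy)
    value = getattr(record, _NUTRITION_FIELD[nutrition_measure])
    if value is None:
        raise MissingDataError(
            f"modified ReSVinet: nutrition measure {nutrition_measure!r} is missing "
            f"(admission {record.admission_id})",
            component=f"nutrition_{nutrition_measure}",
            field=_NUTRITION_FIELD[nutrition_measure],
        )
    pts = anthro.nutrition_points(_NUTRITION_CLASSIFY[nutrition_measure](value))
    return ScoreResult(
        score_id="resvinet_modified",
        total=base.total + pts,
        components_used=base.components_used + (f"nutrition_{nutrition_measure}",),
        components_skipped_missing=base.components_skipped_missing,
    )


def required_fields_for(
    registry: ScoreRegistry, scores: Iterable[str] | None = None
) -> tuple[str, ...]:
    """Union of record fields required by the named scores (complete-case set).

    Mandatory record fields (age, sex) are omitted: they can never be missing.
    The nutrition-augmented ReSVinet is compared across all three malnutrition
    measures, so selecting it requires MUAC and both weight-derived z-scores.
    """
    chosen = list(scores) if scores is not None else list(registry)
    fields: set[str] = set()
    for sid in chosen:
        for rule in registry.require(sid).components:
            fields.update(rule.required_fields)
    if "resvinet_modified" in chosen:
        fields.update({"muac_cm", "waz", "wlz"})
    return tuple(sorted(fields - {"age_months", "sex"}))


def compute_score_matrix(
    records: Sequence[AdmissionRecord],
    registry: ScoreRegistry,
    missing_policy: str = "fail",
    scores: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Totals for every record x score, order-preserving on both axes."""
    score_ids = list(scores) if scores is not None else list(registry)
    defs = [registry.require(s) for s in score_ids]
    # compute_score errors already carry the admission_id context
    data = {
        d.score_id: [compute_score(r, d, missing_policy).total for r in records]
        for d in defs
    }
    return pd.DataFrame(
        data, index=pd.Index([r.admission_id for r in records], name="admission_id")
    )
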