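"""Admission-level domain records and cohort CSV round-trip I/O.

One :class:`AdmissionRecord` describes a single hospital admission of a young
child with a severe acute lower respiratory infection (ALRI) presentation:
demographics, vital signs, anthropometry (MUAC and weight-derived z-scores),
a fixed vocabulary of binary clinical signs, discharge-diagnosis flags and the
in-hospital outcome. Optional measurements use ``None`` for "not recorded";
every sign flag is tri-state (present / absent / missing).

Cohort files are plain UTF-8 CSV with ISO-8601 dates and the literal ``NA``
as the missing sentinel, so that ``read_cohort_csv(write_cohort_csv(x)) == x``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from datetime import date
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping

from .errors import CohortSchemaError, RecordValueError

__all__ = [
    "SIGN_FLAGS",
    "Sex",
    "Outcome",
    "ConsciousLevel",
    "AdmissionRecord",
    "make_signs",
    "read_cohort_csv",
    "write_cohort_csv",
    "field_is_missing",
]

#: Fixed vocabulary of binary clinical signs recorded at admission.
SIGN_FLAGS: tuple[str, ...] = (
    "chest_indrawing",
    "convulsion",
    "cough",
    "crackles",
    "cyanosis",
    "decreased_skin_turgor",
    "deep_breathing",
    "diarrhea",
    "head_nodding",
    "nasal_flaring",
    "pallor",
    "sunken_eye",
    "vomiting",
    "vomits_everything",
    "unable_to_drink",
    "wheeze",
)


class Sex(str, Enum):
    FEMALE = "female"
    MALE = "male"


class Outcome(str, Enum):
    DIED = "died"
    DISCHARGED = "discharged"
    ABSCONDED = "absconded"
    TRANSFERRED = "transferred"


class ConsciousLevel(str, Enum):
    NORMAL = "normal"
    AGITATED = "agitated"
    LETHARGIC = "lethargic"
    PROSTRATE = "prostrate"
    UNCONSCIOUS = "unconscious"


def make_signs(
    present: Iterable[str] = (),
    missing: Iterable[str] = (),
) -> dict[str, bool | None]:
    """Build a complete sign map: named flags present, others absent.

    Flags listed in *missing* are recorded as not collected (``None``).
    """
    present = set(present)
    missing = set(missing)
    unknown = (present | missing) - set(SIGN_FLAGS)
    if unknown:
        raise RecordValueError(f"unknown sign flag(s): {sorted(unknown)}")
    return {
        f: (None if f in missing else f in present) for f in SIGN_FLAGS
    }


@dataclass(frozen=True)
class AdmissionRecord:
    """A single admission with demographics, vitals, signs and outcome."""

    admission_id: str
    age_months: int
    sex: Sex
    admission_date: date
    outcome: Outcome
    resp_rate: float | None = None
    spo2_percent: int | None = None
    conscious_level: ConsciousLevel | None = None
    muac_cm: float | None = None
    waz: float | None = None
    wlz: float | None = None
    signs: Mapping[str, bool | None] = field(default_factory=lambda: make_signs())
    alri_discharge_dx: bool = True
    severe_alri_presentation: bool = True

    def __post_init__(self) -> None:
        if not 1 <= self.age_months <= 59:
            raise RecordValueError(
                f"age_months must be within 1-59, got {self.age_months}"
            )
        if self.spo2_percent is not None and not 0 <= self.spo2_percent <= 100:
            raise RecordValueError(
                f"spo2_percent must be within 0-100, got {self.spo2_percent}"
            )
        if set(self.signs) != set(SIGN_FLAGS):
            extra = set(self.signs) - set(SIGN_FLAGS)
            absent = set(SIGN_FLAGS) - set(self.signs)
            raise RecordValueError(
                f"signs must cover the fixed vocabulary exactly "
                f"(unexpected: {sorted(extra)}, missing: {sorted(absent)})"
            )

    def with_(self, **changes) -> "AdmissionRecord":
        """Return a copy with the given fields replaced."""
        return replace(self, **changes)


# ---------------------------------------------------------------------------
# CSV I/O

_SCALAR_COLUMNS = (
    "admission_id",
    "age_months",
    "sex",
    "admission_date",
    "outcome",
    "resp_rate",
    "spo2_percent",
    "conscious_level",
    "muac_cm",
    "waz",
    "wlz",
)
CSV_COLUMNS: tuple[str, ...] = (
    _SCALAR_COLUMNS + SIGN_FLAGS + ("alri_discharge_dx", "severe_alri_presentation")
)

_NA = "NA"


def _fmt(value) -> str:
    if value is None:
        return _NA
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, Enum):
        return value.value
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_enum(enum_cls, raw: str, row: int, column: str):
    try:
        return enum_cls(raw)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise RecordValueError(
            f"invalid value {raw!r}; expected one of: {allowed}", row=row, column=column
        ) from None


def _parse_opt(raw: str, conv, row: int, column: str):
    if raw == _NA or raw == "":
        return None
    try:
        return conv(raw)
    except (ValueError, TypeError):
        raise RecordValueError(
            f"cannot parse value {raw!r}", row=row, column=column
        ) from None


def _parse_bool(raw: str, row: int, column: str) -> bool | None:
    if raw == _NA or raw == "":
        return None
    if raw in ("1", "true", "True"):
        return True
    if raw in ("0", "false", "False"):
        return False
    raise RecordValueError(
        f"expected 1/0/NA, got {raw!r}", row=row, column=column
    )


def read_cohort_csv(path: str | Path) -> list[AdmissionRecord]:
    """Read a cohort CSV into admission records.

    Raises :class:`CohortSchemaError` when a required column is absent and
    :class:`RecordValueError` (naming the data row and column) for values
    outside the documented vocabularies.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing_cols = [c for c in CSV_COLUMNS if c not in header]
        if missing_cols:
            raise CohortSchemaError(
                f"{path.name}: missing required column(s): {missing_cols}"
            )
        records: list[AdmissionRecord] = []
        for i, row in enumerate(reader, start=1):
            records.append(_parse_row(row, i))
    return records


def _parse_row(row: Mapping[str, str], i: int) -> AdmissionRecord:
    age = _parse_opt(row["age_months"], int, i, "age_months")
    if age is None:
        raise RecordValueError("age_months is required", row=i, column="age_months")
    adm = _parse_opt(row["admission_date"], date.fromisoformat, i, "admission_date")
    if adm is None:
        raise RecordValueError(
            "admission_date is required", row=i, column="admission_date"
        )
    conscious_raw = row["conscious_level"]
    conscious = (
        None
        if conscious_raw in (_NA, "")
        else _parse_enum(ConsciousLevel, conscious_raw, i, "conscious_level")
    )
    dx = _parse_bool(row["alri_discharge_dx"], i, "alri_discharge_dx")
    severe = _parse_bool(row["severe_alri_presentation"], i, "severe_alri_presentation")
    if dx is None or severe is None:
        raise RecordValueError(
            "diagnosis flags are required", row=i, column="alri_discharge_dx"
        )
    try:
        return AdmissionRecord(
            admission_id=row["admission_id"],
            age_months=age,
            sex=_parse_enum(Sex, row["sex"], i, "sex"),
            admission_date=adm,
            outcome=_parse_enum(Outcome, row["outcome"], i, "outcome"),
            resp_rate=_parse_opt(row["resp_rate"], float, i, "resp_rate"),
            spo2_percent=_parse_opt(row["spo2_percent"], int, i, "spo2_percent"),
            conscious_level=conscious,
            muac_cm=_parse_opt(row["muac_cm"], float, i, "muac_cm"),
            waz=_parse_opt(row["waz"], float, i, "waz"),
            wlz=_parse_opt(row["wlz"], float, i, "wlz"),
            signs={f: _parse_bool(row[f], i, f) for f in SIGN_FLAGS},
            alri_discharge_dx=dx,
            severe_alri_presentation=severe,
        )
    except RecordValueError as exc:
        if exc.row is None:
            raise RecordValueError(str(exc), row=i) from None
        raise


def write_cohort_csv(records: Iterable[AdmissionRecord], path: str | Path) -> None:
    """Write records to CSV; output re-reads to identical field values."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    _fmt(getattr(r, c)) for c in _SCALAR_COLUMNS
                ]
                + [_fmt(r.signs[f]) for f in SIGN_FLAGS]
                + [_fmt(r.alri_discharge_dx), _fmt(r.severe_alri_presentation)]
            )


def field_is_missing(record: AdmissionRecord, field_name: str) -> bool:
    """True when the named field (scalar or ``signs.<flag>``) is not recorded."""
    if field_name.startswith("signs."):
        flag = field_name.split(".", 1)[1]
        if flag not in SIGN_FLAGS:
            raise RecordValueError(f"unknown sign flag {flag!r}")
        return record.signs[flag] is None
    if field_name in SIGN_FLAGS:
        return record.signs[field_name] is None
    if not hasattr(record, field_name):
        raise RecordValueError(f"unknown field {field_name!r}")
    return getattr(record, field_name) is None
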