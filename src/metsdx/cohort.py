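"""Cohort ingestion, eligibility filtering, and sex/age stratification.

The analysis cohort is a per-participant table of anthropometrics
(weight, height, waist circumference), blood pressure, a fasting lipid
and glucose panel in mg/dL, and prior diagnosis/treatment flags.
Records are filtered by fixed eligibility windows before any index or
diagnosis is computed, and every removal is attributed to exactly one
rule so the filter log partitions the input.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import pandas as pd

MALE = "male"
FEMALE = "female"

AGE_GROUPS = ("20-39", "40-59", ">=60")

#: Eligibility windows; boundary values are kept (the exclusion rules are
#: strict inequalities: glucose < 70 or > 500, TG > 1200, height < 1.30).
GLU_MIN = 70.0
GLU_MAX = 500.0
TG_MAX = 1200.0
HEIGHT_MIN = 1.30
AGE_MIN = 20

#: Canonical CSV column -> ParticipantRecord field.
CANONICAL_COLUMNS = {
    "id": "id",
    "sex": "sex",
    "age": "age",
    "weight_kg": "weight",
    "height_m": "height",
    "bmi": "bmi",
    "wc_cm": "wc",
    "sbp": "sbp",
    "dbp": "dbp",
    "chol_mgdl": "chol_total",
    "hdl_mgdl": "hdl",
    "tg_mgdl": "tg",
    "glu_mgdl": "glu",
    "dx_diabetes": "dx_diabetes",
    "dx_hypertension": "dx_hypertension",
    "tx_tg": "tx_triglycerides",
    "dx_chol": "dx_hypercholesterolemia",
}

REQUIRED_COLUMNS = (
    "id", "sex", "age", "weight_kg", "height_m", "wc_cm",
    "sbp", "dbp", "hdl_mgdl", "tg_mgdl", "glu_mgdl",
)
OPTIONAL_COLUMNS = ("bmi", "chol_mgdl")
FLAG_COLUMNS = ("dx_diabetes", "dx_hypertension", "tx_tg", "dx_chol")

_MALE_CODES = frozenset({"male", "m", "1", "hombre", "man"})
_FEMALE_CODES = frozenset({"female", "f", "2", "mujer", "woman"})
_TRUE_CODES = frozenset({"1", "true", "t", "yes", "y", "si", "sí"})


@dataclass(frozen=True)
class ParticipantRecord:
    """One survey subject.  ``None`` marks a missing value.

    Continuous fields carry the units of the source survey: weight kg,
    height m, waist circumference cm, blood pressure mmHg, and all
    biochemistry (total cholesterol, HDL, triglycerides, glucose) mg/dL.
    """

    id: str
    sex: Optional[str] = None
    age: Optional[int] = None
    weight: Optional[float] = None
    height: Optional[float] = None
    bmi: Optional[float] = None
    wc: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    chol_total: Optional[float] = None
    hdl: Optional[float] = None
    tg: Optional[float] = None
    glu: Optional[float] = None
    dx_diabetes: bool = False
    dx_hypertension: bool = False
    tx_triglycerides: bool = False
    dx_hypercholesterolemia: bool = False
    whtr: Optional[float] = None


@dataclass(frozen=True)
class Stratum:
    """Sex x age-group cell; exactly six strata exist."""

    sex: str
    age_group: str

    def __post_init__(self):
        if self.sex not in (MALE, FEMALE):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise ValueError(f"unknown age group {self.age_group!r}")

    @property
    def label(self) -> str:
        return f"{self.sex}_{self.age_group}"


def all_strata() -> list[Stratum]:
    return [Stratum(s, g) for s in (MALE, FEMALE) for g in AGE_GROUPS]


@dataclass
class FilterLog:
    """Partition of the input by the first eligibility rule each record fails.

    Rule order (fixed for deterministic attribution):
    age -> glucose -> triglycerides -> height -> missingness.
    """

    n_input: int = 0
    n_excluded_age: int = 0
    n_excluded_glucose: int = 0
    n_excluded_tg: int = 0
    n_excluded_height: int = 0
    n_eliminated_missing: int = 0
    n_kept: int = 0

    @property
    def n_removed(self) -> int:
        return (self.n_excluded_age + self.n_excluded_glucose
                + self.n_excluded_tg + self.n_excluded_height
                + self.n_eliminated_missing)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


def _parse_sex(raw, male_codes=_MALE_CODES, female_codes=_FEMALE_CODES):
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return None
    token = str(raw).strip().lower()
    if token in male_codes:
        return MALE
    if token in female_codes:
        return FEMALE
    return None


def _parse_bool(raw) -> bool:
    if raw is None or (isinstance(raw, float) and pd.isna(raw)):
        return False
    return str(raw).strip().lower() in _TRUE_CODES


def _parse_float(raw) -> Optional[float]:
    value = pd.to_numeric(raw, errors="coerce")
    return None if pd.isna(value) else float(value)


def load_cohort(path, column_map: Optional[Mapping[str, str]] = None,
                male_codes: Iterable[str] = _MALE_CODES,
                female_codes: Iterable[str] = _FEMALE_CODES) -> list[ParticipantRecord]:
    """Read a participant CSV into records.

    Parameters
    ----------
    path : str or file-like
        UTF-8 CSV with a header row and '.' decimal point.
    column_map : mapping, optional
        Maps canonical column names (keys of :data:`CANONICAL_COLUMNS`) to
        the names actually present in the file.

    Unparsable numeric cells become missing values.  Absent flag columns
    default every flag to ``False`` with a warning.  A required column
    that cannot be resolved is a hard error naming the canonical column.
    """
    frame = pd.read_csv(path, dtype=str)
    if frame.empty and frame.columns.empty:
        raise ValueError("empty cohort file: no header row")
    column_map = dict(column_map or {})

    def resolve(canonical: str) -> Optional[str]:
        name = column_map.get(canonical, canonical)
        return name if name in frame.columns else None

    for canonical in REQUIRED_COLUMNS:
        if resolve(canonical) is None:
            raise ValueError(f"required column {canonical!r} not found in cohort file")
    if frame.shape[0] == 0:
        raise ValueError("empty cohort file: header but no rows")

    missing_flags = [c for c in FLAG_COLUMNS if resolve(c) is None]
    if missing_flags:
        warnings.warn(
            "flag columns absent, defaulting to False: " + ", ".join(missing_flags),
            stacklevel=2,
        )

    male_codes = frozenset(str(c).lower() for c in male_codes)
    female_codes = frozenset(str(c).lower() for c in female_codes)

    records = []
    for _, row in frame.iterrows():
        values = {}
        for canonical, field_name in CANONICAL_COLUMNS.items():
            col = resolve(canonical)
            raw = row[col] if col is not None else None
            if canonical == "id":
                values[field_name] = "" if raw is None else str(raw)
            elif canonical == "sex":
                values[field_name] = _parse_sex(raw, male_codes, female_codes)
            elif canonical in FLAG_COLUMNS:
                values[field_name] = _parse_bool(raw)
            elif canonical == "age":
                parsed = _parse_float(raw)
                values[field_name] = None if parsed is None else int(parsed)
            else:
                values[field_name] = _parse_float(raw)
        records.append(ParticipantRecord(**values))
    return records


#: Fields a record must carry to survive elimination: the union of what the
#: ten indices and both diagnostic criteria consume.  BMI may be derived
#: from weight and height, so either BMI itself or the weight/height pair
#: suffices on that axis (height is independently required).
_REQUIRED_FIELDS = ("sex", "age", "height", "wc", "sbp", "dbp", "hdl", "tg", "glu")


def _is_missing_required(r: ParticipantRecord) -> bool:
    if any(getattr(r, f) is None for f in _REQUIRED_FIELDS):
        return True
    return r.bmi is None and r.weight is None


def apply_eligibility(records: Iterable[ParticipantRecord]) -> tuple[list[ParticipantRecord], FilterLog]:
    """Filter records by the eligibility windows; total, never raises.

    A record is counted once, against the first rule it fails, in the
    order age -> glucose -> TG -> height -> missingness.  Boundary values
    (glucose 70 and 500, TG 1200, height 1.30) are kept.
    """
    log = FilterLog()
    kept: list[ParticipantRecord] = []
    for r in records:
        log.n_input += 1
        if r.age is not None and r.age < AGE_MIN:
            log.n_excluded_age += 1
        elif r.glu is not None and (r.glu < GLU_MIN or r.glu > GLU_MAX):
            log.n_excluded_glucose += 1
        elif r.tg is not None and r.tg > TG_MAX:
            log.n_excluded_tg += 1
        elif r.height is not None and r.height < HEIGHT_MIN:
            log.n_excluded_height += 1
        elif _is_missing_required(r):
            log.n_eliminated_missing += 1
        else:
            kept.append(r)
            log.n_kept += 1
    return kept, log


def assign_stratum(record: ParticipantRecord) -> Stratum:
    """Map a kept record to its sex x age-group stratum.

    Age groups are closed-open on integer years: [20, 40), [40, 60), [60, inf).
    """
    if record.age is None or record.age < AGE_MIN:
        raise ValueError(f"record {record.id!r}: age {record.age!r} below inclusion minimum {AGE_MIN}")
    if record.sex not in (MALE, FEMALE):
        raise ValueError(f"record {record.id!r}: sex is missing or unknown")
    if record.age < 40:
        group = AGE_GROUPS[0]
    elif record.age < 60:
        group = AGE_GROUPS[1]
    else:
        group = AGE_GROUPS[2]
    return Stratum(record.sex, group)


def derive_anthropometrics(record: ParticipantRecord) -> ParticipantRecord:
    """Fill BMI (kg/m^2) when absent and attach the waist-to-height ratio.

    An already-present BMI is preserved unchanged.  WHtR uses waist and
    height in the same units: wc_cm / (100 * height_m).
    """
    if record.height is None or record.wc is None:
        raise ValueError(f"record {record.id!r}: height and wc required to derive anthropometrics")
    if record.height <= 0:
        raise ValueError(f"record {record.id!r}: non-positive height {record.height}")
    bmi = record.bmi
    if bmi is None:
        if record.weight is None:
            raise ValueError(f"record {record.id!r}: neither bmi nor weight present")
        bmi = record.weight / record.height ** 2
    whtr = record.wc / (100.0 * record.height)
    return replace(record, bmi=bmi, whtr=whtr)


def write_cohort_csv(records: Iterable[ParticipantRecord], path) -> None:
    """Write records in the canonical CSV schema (inverse of load_cohort)."""
    rows = []
    for r in records:
        rows.append({
            "id": r.id, "sex": r.sex, "age": r.age,
            "weight_kg": r.weight, "height_m": r.height, "bmi": r.bmi,
            "wc_cm": r.wc, "sbp": r.sbp, "dbp": r.dbp,
            "chol_mgdl": r.chol_total, "hdl_mgdl": r.hdl,
            "tg_mgdl": r.tg, "glu_mgdl": r.glu,
            "dx_diabetes": int(r.dx_diabetes),
            "dx_hypertension": int(r.dx_hypertension),
            "tx_tg": int(r.tx_triglycerides),
            "dx_chol": int(r.dx_hypercholesterolemia),
        })
    pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS)).to_csv(path, index=False)
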