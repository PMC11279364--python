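"""The ten surrogate insulin-resistance / obesity indices.

Each index is a pure function of a subject's anthropometrics and fasting
biochemistry.  Inputs arrive in survey units (biochemistry mg/dL, waist
cm, height m); the lipid-accumulation and visceral-adiposity indices
internally convert triglycerides and HDL to mmol/L.  Every index has an
orientation: SPISE falls with metabolic risk, all others rise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from .cohort import FEMALE, MALE, ParticipantRecord

HIGHER_IS_POSITIVE = "higher_is_positive"
LOWER_IS_POSITIVE = "lower_is_positive"

MARKER_IDS = (
    "SPISE", "METS_IR", "TG_HDL", "TYG", "LAP",
    "VAI", "METS_VF", "VAT", "ABSI", "BRI",
)

ORIENTATIONS: Mapping[str, str] = {m: HIGHER_IS_POSITIVE for m in MARKER_IDS}
ORIENTATIONS = {**ORIENTATIONS, "SPISE": LOWER_IS_POSITIVE}

# Molar conversion factors, mg/dL per mmol/L.
TG_MGDL_PER_MMOL = 88.57
CHOL_MGDL_PER_MMOL = 38.67


def mgdl_to_mmol(value: float, analyte: str) -> float:
    """Convert mg/dL to mmol/L for triglycerides or (HDL) cholesterol."""
    if value <= 0:
        raise ValueError(f"non-positive concentration {value}")
    if analyte == "triglycerides":
        return value / TG_MGDL_PER_MMOL
    if analyte == "cholesterol":
        return value / CHOL_MGDL_PER_MMOL
    raise ValueError(f"unknown analyte {analyte!r}")


def _require_positive(**values: float) -> None:
    for name, value in values.items():
        if value is None or value <= 0:
            raise ValueError(f"{name} must be strictly positive, got {value!r}")


def spise(hdl: float, tg: float, bmi: float) -> float:
    """600 * HDL^0.185 / (TG^0.2 * BMI^1.338), all mg/dL and kg/m^2.

    The power product TG^0.2 * BMI^1.338 is the whole denominator.
    Lower values indicate worse insulin sensitivity.
    """
    _require_positive(hdl=hdl, tg=tg, bmi=bmi)
    return 600.0 * hdl ** 0.185 / (tg ** 0.2 * bmi ** 1.338)


def mets_ir(glu: float, tg: float, bmi: float, hdl: float) -> float:
    """ln(2*Glu + TG) * BMI / ln(HDL), natural logs, mg/dL inputs."""
    _require_positive(glu=glu, tg=tg, bmi=bmi)
    if hdl is None or hdl <= 1:
        raise ValueError(f"hdl must exceed 1 mg/dL for a positive log denominator, got {hdl!r}")
    return math.log(2.0 * glu + tg) * bmi / math.log(hdl)


def tg_hdl(tg: float, hdl: float) -> float:
    """Triglyceride/HDL ratio, both mg/dL."""
    _require_positive(tg=tg, hdl=hdl)
    return tg / hdl


def tyg(tg: float, glu: float) -> float:
    """ln(TG * Glu) / 2, both mg/dL (values near 4.6-4.9, not the ~8.8 variant)."""
    _require_positive(tg=tg, glu=glu)
    return math.log(tg * glu) / 2.0


def lap(sex: str, wc: float, tg: float) -> float:
    """(WC - 65) * TG_mmol for men, (WC - 58) * TG_mmol for women.

    TG arrives in mg/dL and is converted internally.  Negative values are
    legitimate when the waist falls below the sex offset.
    """
    _require_positive(wc=wc, tg=tg)
    offset = 65.0 if sex == MALE else 58.0 if sex == FEMALE else None
    if offset is None:
        raise ValueError(f"unknown sex {sex!r}")
    return (wc - offset) * mgdl_to_mmol(tg, "triglycerides")


def vai(sex: str, wc: float, bmi: float, tg: float, hdl: float,
        women_as_printed: bool = False) -> float:
    """Visceral adiposity index; TG and HDL converted to mmol/L internally.

    Both sexes default to the product of the three factors (waist/BMI,
    TG, HDL) with sex-specific constants.  ``women_as_printed`` instead
    sums the three female factors, reproducing a typeset variant whose
    operators differ from the male form.
    """
    _require_positive(wc=wc, bmi=bmi, tg=tg, hdl=hdl)
    tg_mmol = mgdl_to_mmol(tg, "triglycerides")
    hdl_mmol = mgdl_to_mmol(hdl, "cholesterol")
    if sex == MALE:
        factors = (wc / (1.88 * bmi + 39.68), tg_mmol / 1.03, 1.31 / hdl_mmol)
    elif sex == FEMALE:
        factors = (wc / (1.89 * bmi + 36.58), tg_mmol / 0.81, 1.52 / hdl_mmol)
        if women_as_printed:
            return sum(factors)
    else:
        raise ValueError(f"unknown sex {sex!r}")
    return factors[0] * factors[1] * factors[2]


def mets_vf(mets_ir_value: float, whtr: float, sex: str, age: float) -> float:
    """4.466 + 0.011 ln(METS-IR)^3 + 3.239 ln(WHtR)^3 + 0.319*Sex + 0.594 ln(Age).

    Sex is 1 for men, 0 for women; cubes apply to the natural logs.
    """
    _require_positive(mets_ir_value=mets_ir_value, whtr=whtr, age=age)
    if sex not in (MALE, FEMALE):
        raise ValueError(f"unknown sex {sex!r}")
    sex_term = 1.0 if sex == MALE else 0.0
    return (4.466
            + 0.011 * math.log(mets_ir_value) ** 3
            + 3.239 * math.log(whtr) ** 3
            + 0.319 * sex_term
            + 0.594 * math.log(age))


def vat(mets_vf_value: float) -> float:
    """exp of the visceral-fat score: a strictly monotone transform of it."""
    if mets_vf_value is None or not math.isfinite(mets_vf_value):
        raise ValueError(f"mets_vf_value must be finite, got {mets_vf_value!r}")
    return math.exp(mets_vf_value)


def absi(wc: float, bmi: float, height: float) -> float:
    """Body shape index: WC_m / (BMI^(2/3) * height_m^(1/2))."""
    _require_positive(wc=wc, bmi=bmi, height=height)
    return (wc / 100.0) / (bmi ** (2.0 / 3.0) * height ** 0.5)


def bri(wc: float, height: float) -> float:
    """Body roundness index: 364.2 - 365.5 * body-ellipse eccentricity.

    Treats the waist as the minor circumference of an ellipse of height
    ``height``; requires wc_m / (pi * height) < 1.
    """
    _require_positive(wc=wc, height=height)
    wc_m = wc / 100.0
    semi_minor = wc_m / (2.0 * math.pi)
    semi_major = 0.5 * height
    ratio = (semi_minor / semi_major) ** 2
    if ratio >= 1.0:
        raise ValueError(f"degenerate body ellipse: wc/(pi*height) = {wc_m / (math.pi * height):.3f} >= 1")
    return 364.2 - 365.5 * math.sqrt(1.0 - ratio)


@dataclass(frozen=True)
class MarkerPanel:
    """All ten index values for one subject, keyed by marker id."""

    values: Mapping[str, float]
    orientations: Mapping[str, str] = None

    def __post_init__(self):
        if self.orientations is None:
            object.__setattr__(self, "orientations", dict(ORIENTATIONS))

    def __getitem__(self, marker: str) -> float:
        return self.values[marker]


def compute_panel(record: ParticipantRecord, women_as_printed: bool = False) -> MarkerPanel:
    """Compute the full ten-index panel for one eligible record.

    The record must already carry BMI and WHtR (see
    :func:`metsdx.cohort.derive_anthropometrics`).  Formula-level errors
    propagate annotated with the marker id.
    """
    if record.whtr is None or record.bmi is None:
        raise ValueError(f"record {record.id!r}: derive_anthropometrics must run before compute_panel")
    values: dict[str, float] = {}
    try:
        values["SPISE"] = spise(record.hdl, record.tg, record.bmi)
        values["METS_IR"] = mets_ir(record.glu, record.tg, record.bmi, record.hdl)
        values["TG_HDL"] = tg_hdl(record.tg, record.hdl)
        values["TYG"] = tyg(record.tg, record.glu)
        values["LAP"] = lap(record.sex, record.wc, record.tg)
        values["VAI"] = vai(record.sex, record.wc, record.bmi, record.tg,
                            record.hdl, women_as_printed=women_as_printed)
        values["METS_VF"] = mets_vf(values["METS_IR"], record.whtr, record.sex, record.age)
        values["VAT"] = vat(values["METS_VF"])
        values["ABSI"] = absi(record.wc, record.bmi, record.height)
        values["BRI"] = bri(record.wc, record.height)
    except ValueError as err:
        marker = next((m for m in MARKER_IDS if m not in values), "?")
        raise ValueError(f"marker {marker} failed for record {record.id!r}: {err}") from err
    return MarkerPanel(values=values)
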