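"""Rule-based metabolic syndrome diagnosis (ATP III and IDF).

Both criteria score five component booleans — central obesity, high
triglycerides, low HDL, high blood pressure, high glucose — against
fixed thresholds.  ATP III is positive with any three components; IDF
requires central obesity plus two of the remaining four.

Threshold conventions, as typeset in the source definitions:
HDL cut-offs are strict ('<'), everything else is inclusive ('>=');
the compound blood-pressure threshold 130/85 reads SBP >= 130 OR
DBP >= 85; prior hypertension or diabetes diagnoses satisfy the BP and
glucose components; the IDF TG component is also satisfied by
triglyceride-lowering treatment.  ATP III uses the older 110 mg/dL
glucose threshold, and its TG and HDL components carry no treatment
clause.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .cohort import FEMALE, MALE, ParticipantRecord

ATP_III = "ATP_III"
IDF = "IDF"
CRITERIA = (ATP_III, IDF)

COMPONENT_NAMES = ("central_obesity", "high_tg", "low_hdl", "high_bp", "high_glu")


@dataclass(frozen=True)
class MetSLabel:
    criterion: str
    components: Mapping[str, bool]
    positive: bool
    n_components: int


def _require(record: ParticipantRecord, *fields: str) -> None:
    for f in fields:
        if getattr(record, f) is None:
            raise ValueError(f"record {record.id!r}: field {f!r} required for diagnosis is missing")


def _common_components(record: ParticipantRecord) -> dict[str, bool]:
    _require(record, "sex", "tg", "hdl", "sbp", "dbp", "glu")
    hdl_cut = 40.0 if record.sex == MALE else 50.0
    return {
        "high_tg": record.tg >= 150.0,
        "low_hdl": record.hdl < hdl_cut,
        "high_bp": record.sbp >= 130.0 or record.dbp >= 85.0 or record.dx_hypertension,
    }


def atp_iii(record: ParticipantRecord) -> MetSLabel:
    """ATP III: positive iff at least 3 of the 5 components are present."""
    _require(record, "wc")
    components = _common_components(record)
    wc_cut = 102.0 if record.sex == MALE else 88.0
    components["central_obesity"] = record.wc >= wc_cut
    components["high_glu"] = record.glu >= 110.0 or record.dx_diabetes
    components = {name: components[name] for name in COMPONENT_NAMES}
    n = sum(components.values())
    return MetSLabel(ATP_III, components, positive=n >= 3, n_components=n)


def idf(record: ParticipantRecord) -> MetSLabel:
    """IDF: central obesity is mandatory, plus at least 2 of the other 4."""
    _require(record, "wc")
    components = _common_components(record)
    wc_cut = 90.0 if record.sex == MALE else 80.0
    components["central_obesity"] = record.wc >= wc_cut
    components["high_tg"] = components["high_tg"] or record.tx_triglycerides
    components["high_glu"] = record.glu >= 100.0 or record.dx_diabetes
    components = {name: components[name] for name in COMPONENT_NAMES}
    n = sum(components.values())
    others = n - int(components["central_obesity"])
    positive = components["central_obesity"] and others >= 2
    return MetSLabel(IDF, components, positive=positive, n_components=n)


def diagnose(record: ParticipantRecord, criterion: str) -> MetSLabel:
    if criterion == ATP_III:
        return atp_iii(record)
    if criterion == IDF:
        return idf(record)
    raise ValueError(f"unknown criterion {criterion!r}")
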