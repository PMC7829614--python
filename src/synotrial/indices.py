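"""Composite disease-activity indices and binary endpoint definitions.

Implements the 28-joint composite scores used in rheumatoid-arthritis
trials — CDAI, DAS28-ESR, DAS28-CRP — together with the EULAR response
classification and the binary endpoint flags evaluated at week 16:

* ``cdai50``      — CDAI improved by at least 50% from baseline (primary),
* ``cdai_lda``    — week-16 CDAI at or below 10.1 (low disease activity),
* ``cdai_mtr``    — major treatment response: ``cdai50`` and ``cdai_lda``,
* DAS28 low-disease-activity (<=3.2) and remission (<=2.6), both variants,
* EULAR good/moderate/none response for both DAS28 variants.

CDAI sums the tender and swollen 28-joint counts with the patient and
evaluator global assessments on 0-10 visual-analogue scales (range 0-76).
DAS28 uses the standard weighted formulas with the patient global on a
0-100 mm scale (GH):

    DAS28-ESR = 0.56*sqrt(TJC) + 0.28*sqrt(SJC) + 0.70*ln(ESR) + 0.014*GH
    DAS28-CRP = 0.56*sqrt(TJC) + 0.28*sqrt(SJC) + 0.36*ln(CRP+1)
                + 0.014*GH + 0.96
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

__all__ = [
    "ClinicalVisit",
    "IndexResult",
    "EndpointFlags",
    "cdai",
    "das28",
    "eular_response",
    "endpoint_flags",
    "CDAI_LDA_THRESHOLD",
    "DAS28_LDA_THRESHOLD",
    "DAS28_REMISSION_THRESHOLD",
]

# Comparison tolerance for threshold rules on one-decimal clinical inputs.
_TOL = 1e-9

CDAI_LDA_THRESHOLD = 10.1
DAS28_LDA_THRESHOLD = 3.2
DAS28_REMISSION_THRESHOLD = 2.6


@dataclass
class ClinicalVisit:
    """One clinical assessment (baseline or week 16) for one patient.

    The patient global assessment is carried on both scales used by the
    composite indices: 0-10 for CDAI and 0-100 mm VAS for DAS28 (GH), to
    avoid unit ambiguity. NaN marks an item not collected at the visit.
    """

    tjc28: float
    sjc28: float
    esr: float
    crp: float
    patient_global: float
    evaluator_global: float
    patient_global_vas100: float
    haq: float = math.nan
    facit: float = math.nan
    sf36_pcs: float = math.nan
    sf36_mcs: float = math.nan

    def validate(self) -> None:
        for name, value, lo, hi in [
            ("tjc28", self.tjc28, 0, 28),
            ("sjc28", self.sjc28, 0, 28),
            ("patient_global", self.patient_global, 0, 10),
            ("evaluator_global", self.evaluator_global, 0, 10),
            ("patient_global_vas100", self.patient_global_vas100, 0, 100),
        ]:
            if not math.isnan(value) and not (lo - _TOL <= value <= hi + _TOL):
                raise ValueError(f"{name}={value} outside [{lo}, {hi}]")
        if not math.isnan(self.crp) and self.crp < 0:
            raise ValueError(f"crp={self.crp} must be >= 0")


@dataclass
class IndexResult:
    cdai: float
    das28_esr: float
    das28_crp: float


@dataclass
class EndpointFlags:
    """Binary week-16 endpoint indicators for one patient.

    ``evaluable`` is False when the week-16 visit is absent; downstream
    population rules decide how unevaluable patients are handled.
    """

    cdai50: bool = False
    cdai_mtr: bool = False
    cdai_lda: bool = False
    das28_esr_lda: bool = False
    das28_crp_lda: bool = False
    das28_esr_rem: bool = False
    das28_crp_rem: bool = False
    eular_esr: Literal["good", "moderate", "none"] = "none"
    eular_crp: Literal["good", "moderate", "none"] = "none"
    evaluable: bool = True


def cdai(visit: ClinicalVisit) -> float:
    """Clinical Disease Activity Index: TJC28 + SJC28 + PtGA + EvGA (0-76)."""
    visit.validate()
    parts = (visit.tjc28, visit.sjc28, visit.patient_global, visit.evaluator_global)
    if any(math.isnan(p) for p in parts):
        return math.nan
    return float(sum(parts))


def das28(visit: ClinicalVisit, variant: Literal["esr", "crp"] = "esr") -> float:
    """28-joint Disease Activity Score, ESR or CRP variant.

    GH is the patient global on the 0-100 mm scale. The ESR variant
    requires ESR > 0 (its logarithm is taken).
    """
    visit.validate()
    joints = 0.56 * math.sqrt(visit.tjc28) + 0.28 * math.sqrt(visit.sjc28)
    gh = 0.014 * visit.patient_global_vas100
    if variant == "esr":
        if math.isnan(visit.esr) or math.isnan(visit.tjc28):
            return math.nan
        if visit.esr <= 0:
            raise ValueError(f"esr={visit.esr} must be > 0 for the ESR variant")
        return joints + 0.70 * math.log(visit.esr) + gh
    if variant == "crp":
        if math.isnan(visit.crp):
            return math.nan
        return joints + 0.36 * math.log(visit.crp + 1.0) + gh + 0.96
    raise ValueError(f"unknown DAS28 variant {variant!r}")


def eular_response(das_baseline: float, das_followup: float) -> str:
    """EULAR response category from DAS28 improvement and attained level.

    good:     improvement > 1.2 and attained <= 3.2
    moderate: improvement > 1.2 with attained > 3.2, or
              improvement in (0.6, 1.2] with attained <= 5.1
    none:     otherwise
    """
    if math.isnan(das_baseline) or math.isnan(das_followup):
        return "none"
    improvement = das_baseline - das_followup
    attained = das_followup
    if improvement > 1.2 + _TOL:
        return "good" if attained <= 3.2 + _TOL else "moderate"
    if improvement > 0.6 + _TOL and attained <= 5.1 + _TOL:
        return "moderate"
    return "none"


def endpoint_flags(
    baseline: ClinicalVisit, week16: Optional[ClinicalVisit]
) -> EndpointFlags:
    """Evaluate all binary week-16 endpoints for one patient.

    A ``None`` week-16 visit (dropout) yields flags marked unevaluable.
    A baseline CDAI of 0 cannot occur under the eligibility criteria
    (active disease); the response then evaluates true by the <=
    convention and a warning is emitted.
    """
    if week16 is None:
        return EndpointFlags(evaluable=False)

    cdai_b, cdai_w = cdai(baseline), cdai(week16)
    flags = EndpointFlags()
    if math.isnan(cdai_b) or math.isnan(cdai_w):
        flags.evaluable = False
        return flags
    if cdai_b <= 0:
        warnings.warn(
            "baseline CDAI is 0; CDAI50% evaluates true by convention",
            stacklevel=2,
        )
    flags.cdai50 = cdai_w <= 0.5 * cdai_b + _TOL
    flags.cdai_lda = cdai_w <= CDAI_LDA_THRESHOLD + _TOL
    flags.cdai_mtr = flags.cdai50 and flags.cdai_lda

    for variant in ("esr", "crp"):
        db = das28(baseline, variant)
        dw = das28(week16, variant)
        lda = (not math.isnan(dw)) and dw <= DAS28_LDA_THRESHOLD + _TOL
        rem = (not math.isnan(dw)) and dw <= DAS28_REMISSION_THRESHOLD + _TOL
        setattr(flags, f"das28_{variant}_lda", lda)
        setattr(flags, f"das28_{variant}_rem", rem)
        setattr(flags, f"eular_{variant}", eular_response(db, dw))
    return flags
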