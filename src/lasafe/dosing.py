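"""Maximum-safe-dose rule engine for local anesthetics.

The comprehensive calculation proceeds in four steps:

1. BMI and ideal body weight (Devine formula) from height, weight and sex.
2. Calculation weight (CW): one of five branch rules on (AW, IBW, BMI)
   selects AW, IBW or the 70 kg cap; CW never exceeds 70 kg.
3. Base maximum = CW × per-kg dose limit (mg).
4. Risk-factor reduction: one factor among {age ≥ 70, GFR < 50 mL/min,
   prothrombin time < 50%, LVEF ≤ 30%, pregnancy, major CYP1A2/3A
   inhibitor} cuts the maximum by 20%; two or more cut it by 30%.

A simplified calculation (actual- or ideal-weight × limit, no cap, no
reductions) is provided for secondary analyses. When the solution
concentration is known, the mg maximum converts to a maximum volume by
flooring to whole millilitres; a dose is an overdose when it strictly
exceeds the maximum in its own unit.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Literal, Optional

from .models import (
    AnestheticSpec,
    Anthropometrics,
    DoseMode,
    DoseResult,
    MixturePlan,
    PatientRecord,
    RiskAssessment,
    RiskFactor,
    Sex,
)

logger = logging.getLogger(__name__)

CM_PER_INCH = 2.54
#: Devine (1974) constants: base kg at 60 in plus kg per additional inch.
DEVINE_BASE = {Sex.MALE: 50.0, Sex.FEMALE: 45.5}
DEVINE_SLOPE = 2.3
#: Height validation bounds for the Devine line (cm). Below the lower bound
#: the linear extrapolation is clinically meaningless and is rejected;
#: between the bounds and 152.4 cm (60 in) it is extrapolated with a warning.
MIN_VALID_HEIGHT_CM = 130.0
DEVINE_REFERENCE_HEIGHT_CM = 60 * CM_PER_INCH  # 152.4

CW_CAP_KG = 70.0

GFR_THRESHOLD = 50.0  # mL/min, below → renal dysfunction
PT_THRESHOLD = 50.0  # %, below → hepatic dysfunction
LVEF_THRESHOLD = 30.0  # %, at or below → heart failure
AGE_THRESHOLD = 70  # years, at or above → age factor


class DoseConfigurationError(ValueError):
    """A drug definition is missing data required for the computation."""


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m² from weight (kg) and height (cm)."""
    if weight <= 0 or height <= 0:
        raise ValueError("weight and height must be strictly positive")
    return weight / (height / 100.0) ** 2


def compute_ibw_devine(sex: Sex, height: float) -> float:
    """Ideal body weight (kg) by the Devine formula.

    male: 50 + 2.3 kg per inch over 60 in; female: 45.5 + 2.3 kg per inch.
    Heights below 152.4 cm extrapolate the line downward; heights below
    130 cm are rejected as outside the validated range.
    """
    if height < MIN_VALID_HEIGHT_CM:
        raise ValueError(
            f"height {height} cm below validated range "
            f"(≥ {MIN_VALID_HEIGHT_CM} cm) for the Devine formula"
        )
    if height < DEVINE_REFERENCE_HEIGHT_CM:
        logger.warning(
            "height %.1f cm below the Devine reference of 152.4 cm; "
            "ideal body weight extrapolated downward",
            height,
        )
    inches = height / CM_PER_INCH
    return DEVINE_BASE[Sex(sex)] + DEVINE_SLOPE * (inches - 60.0)


def determine_calculation_weight(
    aw: float, ibw: float, bmi: float
) -> Anthropometrics:
    """Select the calculation weight (CW) from AW, IBW and BMI.

    Exactly one of five branch rules fires:

    1. AW ≤ 70, BMI < 30, IBW > AW  → CW = AW
    2. AW ≤ 70, BMI < 30, IBW ≤ AW  → CW = IBW
    3. AW ≤ 70, BMI ≥ 30            → CW = IBW
    4. AW > 70, IBW > 70            → CW = 70
    5. AW > 70, IBW ≤ 70            → CW = IBW

    The result is additionally capped at 70 kg.
    """
    if aw <= 0 or ibw <= 0 or bmi <= 0:
        raise ValueError("AW, IBW and BMI must be strictly positive")
    if aw <= CW_CAP_KG:
        if bmi < 30.0:
            if ibw > aw:
                cw, rule = aw, 1
            else:
                cw, rule = ibw, 2
        else:
            cw, rule = ibw, 3
    else:
        if ibw > CW_CAP_KG:
            cw, rule = CW_CAP_KG, 4
        else:
            cw, rule = ibw, 5
    return Anthropometrics(ibw=ibw, bmi=bmi, cw=min(cw, CW_CAP_KG), cw_rule=rule)


def assess_risk_factors(
    patient: PatientRecord, inhibitor_list: Iterable[str]
) -> RiskAssessment:
    """Flag dose-reduction factors and derive the adjustment multiplier."""
    inhibitors = {m.strip().lower() for m in inhibitor_list}
    present: set[RiskFactor] = set()
    if patient.age >= AGE_THRESHOLD:
        present.add(RiskFactor.AGE_GE_70)
    if patient.gfr is not None and patient.gfr < GFR_THRESHOLD:
        present.add(RiskFactor.RENAL)
    if patient.prothrombin_time is not None and patient.prothrombin_time < PT_THRESHOLD:
        present.add(RiskFactor.HEPATIC)
    if patient.lvef is not None and patient.lvef <= LVEF_THRESHOLD:
        present.add(RiskFactor.HEART_FAILURE)
    if patient.pregnant:
        present.add(RiskFactor.PREGNANCY)
    if any(m.strip().lower() in inhibitors for m in patient.medications):
        present.add(RiskFactor.CYP_INHIBITOR)
    if not present:
        factor = 1.0
    elif len(present) == 1:
        factor = 0.8
    else:
        factor = 0.7
    return RiskAssessment(
        factors_present=frozenset(present), adjustment_factor=factor
    )


def mg_to_max_volume(max_mg: float, concentration: float) -> int:
    """Maximum whole-mL volume delivering at most ``max_mg`` of drug."""
    if concentration <= 0:
        raise ValueError("concentration must be strictly positive")
    if max_mg < 0:
        raise ValueError("max_mg must be nonnegative")
    return int(math.floor(max_mg / concentration))


def patient_anthropometrics(patient: PatientRecord) -> Anthropometrics:
    """BMI, Devine IBW and calculation weight for one patient."""
    bmi = compute_bmi(patient.actual_weight, patient.height)
    ibw = compute_ibw_devine(patient.sex, patient.height)
    return determine_calculation_weight(patient.actual_weight, ibw, bmi)


def max_safe_dose(
    patient: PatientRecord,
    drug: AnestheticSpec,
    mode: DoseMode = DoseMode.COMPREHENSIVE,
    inhibitor_list: Iterable[str] = (),
) -> DoseResult:
    """Maximum safe dose of ``drug`` for ``patient`` under ``mode``.

    Comprehensive mode multiplies the capped calculation weight by the
    per-kg limit and applies the risk-factor reduction. The simplified
    modes multiply the bare actual or ideal weight by the limit with no
    cap and no reductions. The mg maximum is floored into whole mL when
    the drug's concentration is known.
    """
    if drug.dose_limit is None or drug.dose_limit <= 0:
        raise DoseConfigurationError(f"drug {drug.name!r} lacks a dose limit")
    mode = DoseMode(mode)
    trace: list[str] = []
    anthro = patient_anthropometrics(patient)
    trace.append(
        f"BMI={anthro.bmi:.1f} kg/m², IBW={anthro.ibw:.1f} kg (Devine), "
        f"AW={patient.actual_weight:.1f} kg"
    )
    if mode is DoseMode.COMPREHENSIVE:
        trace.append(
            f"CW rule {anthro.cw_rule} → CW={anthro.cw:.1f} kg (cap 70 kg)"
        )
        risk = assess_risk_factors(patient, inhibitor_list)
        if risk.factors_present:
            names = ", ".join(sorted(f.value for f in risk.factors_present))
            trace.append(
                f"risk factors [{names}] → ×{risk.adjustment_factor:.1f}"
            )
        else:
            trace.append("no risk factors → ×1.0")
        max_mg = anthro.cw * drug.dose_limit * risk.adjustment_factor
    elif mode is DoseMode.SIMPLIFIED_AW:
        trace.append("simplified: AW × dose limit")
        max_mg = patient.actual_weight * drug.dose_limit
    else:
        trace.append("simplified: IBW × dose limit")
        max_mg = anthro.ibw * drug.dose_limit
    trace.append(f"dose limit {drug.dose_limit} mg/kg → max {max_mg:.2f} mg")
    max_ml: Optional[int] = None
    if drug.concentration is not None:
        max_ml = mg_to_max_volume(max_mg, drug.concentration)
        trace.append(
            f"concentration {drug.concentration} mg/mL → floor {max_ml} mL"
        )
    return DoseResult(
        drug=drug.name, max_mg=max_mg, max_ml=max_ml, mode=mode, trace=tuple(trace)
    )


def max_safe_mixture(
    patient: PatientRecord,
    plan: MixturePlan,
    mode: DoseMode = DoseMode.COMPREHENSIVE,
    inhibitor_list: Iterable[str] = (),
) -> list[DoseResult]:
    """Per-component maxima under a fractional additive toxicity budget.

    Each component receives its proportion of that drug's own stand-alone
    maximum, so the budget shares Σ dose_i / standalone_max_i sum to one.
    """
    results: list[DoseResult] = []
    for comp in plan.components:
        alone = max_safe_dose(patient, comp.drug, mode, inhibitor_list)
        max_mg = alone.max_mg * comp.proportion
        trace = alone.trace + (
            f"mixture share {comp.proportion:.3f} of stand-alone "
            f"{alone.max_mg:.2f} mg → {max_mg:.2f} mg",
        )
        max_ml = (
            mg_to_max_volume(max_mg, comp.drug.concentration)
            if comp.drug.concentration is not None
            else None
        )
        results.append(
            DoseResult(
                drug=comp.drug.name,
                max_mg=max_mg,
                max_ml=max_ml,
                mode=DoseMode(mode),
                trace=trace,
            )
        )
    return results


def is_overdose(
    candidate: float,
    reference: DoseResult,
    unit: Literal["mg", "mL"],
    concentration: Optional[float] = None,
) -> bool:
    """True iff ``candidate`` strictly exceeds the reference in ``unit``.

    A candidate exactly equal to the maximum is safe. mL candidates compare
    against the floored maximum volume; if the reference carries no volume,
    ``concentration`` is used to derive one.
    """
    if unit == "mg":
        return candidate > reference.max_mg
    if reference.max_ml is not None:
        return candidate > reference.max_ml
    if concentration is None:
        raise ValueError(
            "mL candidate but reference has no volume and no concentration given"
        )
    return candidate > mg_to_max_volume(reference.max_mg, concentration)
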