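"""Domain types for local-anesthetic dose safety analysis.

All quantities are in clinical units: weights kg, heights cm, doses mg,
volumes mL, concentrations mg/mL, per-kg limits mg/kg. Organ-function
markers left as ``None`` mean "not reported", which the rule engine treats
as *no risk factor present* — never as a zero measurement.
"""

from __future__ import annotations

import enum
from typing import Literal, Optional, Union

from pydantic import BaseModel, ConfigDict, Field, model_validator


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"


class DoseMode(str, enum.Enum):
    """How the reference maximum is computed.

    COMPREHENSIVE applies the full rule chain (calculation weight capped at
    70 kg plus risk-factor reductions); the simplified modes multiply a bare
    weight (actual or ideal) by the per-kg limit.
    """

    COMPREHENSIVE = "comprehensive"
    SIMPLIFIED_AW = "simplified_aw"
    SIMPLIFIED_IBW = "simplified_ibw"


class RiskFactor(str, enum.Enum):
    AGE_GE_70 = "age≥70"
    RENAL = "renal"
    HEPATIC = "hepatic"
    HEART_FAILURE = "heart_failure"
    PREGNANCY = "pregnancy"
    CYP_INHIBITOR = "cyp_inhibitor"


class PatientRecord(BaseModel):
    """Demographics, anthropometrics and risk-factor state of one patient."""

    model_config = ConfigDict(frozen=True)

    age: int = Field(ge=0, description="years")
    sex: Sex
    height: float = Field(gt=0, description="cm")
    actual_weight: float = Field(gt=0, description="kg (AW)")
    gfr: Optional[float] = Field(default=None, description="mL/min")
    prothrombin_time: Optional[float] = Field(default=None, description="%")
    lvef: Optional[float] = Field(default=None, description="%")
    pregnant: bool = False
    medications: tuple[str, ...] = ()


class Anthropometrics(BaseModel):
    """Derived weights and the calculation-weight branch rule that fired."""

    model_config = ConfigDict(frozen=True)

    ibw: float = Field(description="ideal body weight, kg")
    bmi: float = Field(gt=0, description="kg/m²")
    cw: float = Field(gt=0, le=70.0, description="calculation weight, kg")
    cw_rule: int = Field(ge=1, le=5)


class AnestheticSpec(BaseModel):
    """One local anesthetic: per-kg toxicity limit and solution strength."""

    model_config = ConfigDict(frozen=True)

    name: str
    dose_limit: float = Field(gt=0, description="mg per kg of calculation weight")
    concentration: Optional[float] = Field(
        default=None, gt=0, description="mg per mL"
    )


class RiskAssessment(BaseModel):
    """Which dose-reduction factors are present and the resulting multiplier.

    The multiplier is 1.0 with no factors, 0.8 (a 20% reduction) with exactly
    one, and 0.7 (30%) with two or more.
    """

    model_config = ConfigDict(frozen=True)

    factors_present: frozenset[RiskFactor]
    adjustment_factor: float

    @model_validator(mode="after")
    def _factor_matches_count(self) -> "RiskAssessment":
        expected = {0: 1.0}.get(len(self.factors_present))
        if expected is None:
            expected = 0.8 if len(self.factors_present) == 1 else 0.7
        if self.adjustment_factor != expected:
            raise ValueError(
                f"adjustment_factor {self.adjustment_factor} inconsistent with "
                f"{len(self.factors_present)} risk factor(s)"
            )
        return self


class DoseResult(BaseModel):
    """Maximum safe dose with the rule trace that produced it."""

    model_config = ConfigDict(frozen=True)

    drug: str
    max_mg: float = Field(ge=0)
    max_ml: Optional[int] = Field(default=None, ge=0)
    mode: DoseMode
    trace: tuple[str, ...] = ()


class MixtureComponent(BaseModel):
    model_config = ConfigDict(frozen=True)

    drug: AnestheticSpec
    proportion: float = Field(gt=0, le=1.0, description="share of toxicity budget")


class MixturePlan(BaseModel):
    """Two-or-more anesthetics sharing one fractional toxicity budget."""

    model_config = ConfigDict(frozen=True)

    components: tuple[MixtureComponent, ...]

    @model_validator(mode="after")
    def _proportions_sum_to_one(self) -> "MixturePlan":
        total = sum(c.proportion for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"mixture proportions sum to {total}, expected 1")
        return self


# ---------------------------------------------------------------------------
# Candidate responses and their evaluation


class Abstention(BaseModel):
    model_config = ConfigDict(frozen=True)
    kind: Literal["abstention"] = "abstention"


class SingleValue(BaseModel):
    model_config = ConfigDict(frozen=True)
    kind: Literal["single"] = "single"
    value: float = Field(gt=0)


class ValueRange(BaseModel):
    model_config = ConfigDict(frozen=True)
    kind: Literal["range"] = "range"
    low: float = Field(gt=0)
    high: float = Field(gt=0)

    @model_validator(mode="after")
    def _ordered(self) -> "ValueRange":
        if self.low > self.high:
            raise ValueError("range low endpoint exceeds high endpoint")
        return self


Payload = Union[SingleValue, ValueRange, Abstention]


class CandidateResponse(BaseModel):
    """One respondent's answer to one vignette: value, range or abstention."""

    model_config = ConfigDict(frozen=True)

    vignette_id: str
    respondent_id: str
    payload: Payload = Field(discriminator="kind")
    unit: Literal["mg", "mL"]


class CaseEvaluation(BaseModel):
    """Safety classification of one candidate dose against one reference."""

    model_config = ConfigDict(frozen=True)

    vignette_id: str
    respondent_id: str
    status: Literal["safe", "unsafe", "missing"]
    candidate_value: Optional[float] = None
    reference_value: Optional[float] = None
    unit: Literal["mg", "mL"]
    drug: Optional[str] = None
    mixture: bool = False
    exceedance_pct: Optional[float] = None
    exceedance_abs: Optional[float] = None

    @model_validator(mode="after")
    def _exceedance_iff_unsafe(self) -> "CaseEvaluation":
        if self.status == "unsafe":
            if self.exceedance_pct is None or self.exceedance_abs is None:
                raise ValueError("unsafe case missing exceedance measures")
            if self.exceedance_pct <= 0 or self.exceedance_abs <= 0:
                raise ValueError("exceedance must be strictly positive")
        elif self.exceedance_pct is not None or self.exceedance_abs is not None:
            raise ValueError("exceedance present on a non-unsafe case")
        return self


class DrugStats(BaseModel):
    """Absolute exceedance statistics for one drug, in printed units."""

    model_config = ConfigDict(frozen=True)

    n_unsafe: int
    abs_mean: Optional[float] = None
    abs_sd: Optional[float] = None


class SubsetStats(BaseModel):
    model_config = ConfigDict(frozen=True)

    n_cases: int
    n_provided: int
    n_unsafe: int
    exceedance_mean: Optional[float] = None
    exceedance_sd: Optional[float] = None


class ModelSummary(BaseModel):
    """All per-respondent summary statistics over one evaluated panel."""

    model_config = ConfigDict(frozen=True)

    respondent_id: str
    n_vignettes: int
    n_provided: int
    n_unsafe: int
    unsafe_rate: Optional[float] = Field(
        default=None, description="% of provided responses that are unsafe"
    )
    exceedance_mean: Optional[float] = None
    exceedance_sd: Optional[float] = None
    per_drug: dict[str, DrugStats] = {}
    mixture_subset: Optional[SubsetStats] = None

    @model_validator(mode="after")
    def _counts_nested(self) -> "ModelSummary":
        if not (self.n_unsafe <= self.n_provided <= self.n_vignettes):
            raise ValueError("expected n_unsafe ≤ n_provided ≤ n_vignettes")
        if self.unsafe_rate is not None and not (0 <= self.unsafe_rate <= 100):
            raise ValueError("unsafe_rate outside [0, 100]")
        return self
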