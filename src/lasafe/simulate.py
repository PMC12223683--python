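"""Synthetic clinical vignettes and simulated respondents.

Real evaluation studies of dose-calculation aids use a fixed set of
hand-written vignettes whose patient details live in supplementary
material. This module generates structurally equivalent vignettes with
known ground truth so every pipeline stage — reference computation,
response grading, summary statistics — can be exercised end to end at any
scale. A panel of at least ten vignettes covers, by construction, all five
calculation-weight branch rules, patients with zero / one / two-or-more
risk factors, single-agent and two-agent mixture questions, and both mg
and mL framings. Simulated respondents abstain, answer with ranges,
overdose, and confuse units at controllable rates.

Patients are sampled from a plausible adult surgical population (age 18-90,
height 145-200 cm, weight 40-140 kg, sex 1:1); all downstream computation
consumes the structured record, the narrative text is cosmetic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Literal, Mapping, Optional, Sequence

import numpy as np

from .config import DrugCatalogue, load_catalogue
from .dosing import max_safe_dose, max_safe_mixture, patient_anthropometrics
from .evaluation import ReferenceDose
from .fixtures import load_fixtures  # noqa: F401  (re-exported fixture access)
from .models import (
    Abstention,
    AnestheticSpec,
    CandidateResponse,
    DoseMode,
    MixtureComponent,
    MixturePlan,
    PatientRecord,
    RiskFactor,
    Sex,
    SingleValue,
    ValueRange,
)

logger = logging.getLogger(__name__)

#: Risk factors the generator can plant, with the field values it uses.
_PLANTABLE = (
    RiskFactor.AGE_GE_70,
    RiskFactor.RENAL,
    RiskFactor.HEPATIC,
    RiskFactor.HEART_FAILURE,
    RiskFactor.PREGNANCY,
    RiskFactor.CYP_INHIBITOR,
)


@dataclass(frozen=True)
class PanelConfig:
    """Sampling ranges and prevalences for the vignette generator."""

    age_range: tuple[int, int] = (18, 90)
    height_range: tuple[float, float] = (145.0, 200.0)
    weight_range: tuple[float, float] = (40.0, 140.0)
    male_prob: float = 0.5
    risk_factor_prob: float = 0.15  # per-factor planting probability
    mixture_prob: float = 0.4
    ml_prob: float = 0.5
    catalogue: Optional[DrugCatalogue] = None

    def resolved_catalogue(self) -> DrugCatalogue:
        return self.catalogue if self.catalogue is not None else load_catalogue()


@dataclass(frozen=True)
class VignetteSpec:
    """One synthetic vignette: patient, drug(s), and question framing."""

    vignette_id: str
    patient: PatientRecord
    drugs: tuple[AnestheticSpec, ...]
    mixture_proportions: Optional[tuple[float, ...]]
    question_unit: Literal["mg", "mL"]
    narrative: str

    @property
    def mixture(self) -> bool:
        return len(self.drugs) > 1


@dataclass(frozen=True)
class BiasDistribution:
    """Multiplicative factor applied to the true maximum.

    With probability ``overdose_prob`` the factor is drawn uniformly from
    ``over_range`` (strictly above 1, an overdose); otherwise from
    ``under_range`` (at or below 1, safe). A ``constant`` short-circuits
    both draws.
    """

    overdose_prob: float = 0.5
    over_range: tuple[float, float] = (1.05, 3.0)
    under_range: tuple[float, float] = (0.4, 1.0)
    constant: Optional[float] = None

    def draw(self, rng: np.random.Generator) -> float:
        if self.constant is not None:
            return self.constant
        if rng.random() < self.overdose_prob:
            return float(rng.uniform(*self.over_range))
        return float(rng.uniform(*self.under_range))


@dataclass(frozen=True)
class RespondentProfile:
    """Behavioral model of one simulated respondent."""

    profile_id: str
    abstention_prob: float = 0.0
    range_prob: float = 0.0
    overdose_bias: BiasDistribution = field(default_factory=BiasDistribution)
    unit_confusion_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.abstention_prob, self.range_prob, self.unit_confusion_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("profile probabilities must lie in [0, 1]")


#: Ready-made respondent archetypes mirroring observed chatbot behaviors.
PROFILES: Mapping[str, RespondentProfile] = {
    "exact": RespondentProfile(
        profile_id="exact", overdose_bias=BiasDistribution(constant=1.0)
    ),
    "overdose_prone": RespondentProfile(
        profile_id="overdose_prone",
        overdose_bias=BiasDistribution(overdose_prob=0.8),
        range_prob=0.2,
    ),
    "cautious_abstainer": RespondentProfile(
        profile_id="cautious_abstainer",
        abstention_prob=0.7,
        range_prob=0.5,
        overdose_bias=BiasDistribution(overdose_prob=0.3),
    ),
    "unit_confused": RespondentProfile(
        profile_id="unit_confused",
        overdose_bias=BiasDistribution(constant=1.0),
        unit_confusion_prob=0.5,
    ),
}


def _sample_patient(rng: np.random.Generator, cfg: PanelConfig) -> PatientRecord:
    sex = Sex.MALE if rng.random() < cfg.male_prob else Sex.FEMALE
    return PatientRecord(
        age=int(rng.integers(cfg.age_range[0], cfg.age_range[1] + 1)),
        sex=sex,
        height=float(np.round(rng.uniform(*cfg.height_range), 1)),
        actual_weight=float(np.round(rng.uniform(*cfg.weight_range), 1)),
    )


def _plant_risk_factors(
    patient: PatientRecord,
    factors: Sequence[RiskFactor],
    rng: np.random.Generator,
    catalogue: DrugCatalogue,
) -> PatientRecord:
    """Return a copy of ``patient`` with exactly ``factors`` present."""
    age = patient.age if patient.age < 70 else int(rng.integers(18, 70))
    updates: dict = {
        "age": age,
        "gfr": None,
        "prothrombin_time": None,
        "lvef": None,
        "pregnant": False,
        "medications": (),
    }
    for factor in factors:
        if factor is RiskFactor.AGE_GE_70:
            updates["age"] = int(rng.integers(70, 91))
        elif factor is RiskFactor.RENAL:
            updates["gfr"] = float(np.round(rng.uniform(15, 49), 1))
        elif factor is RiskFactor.HEPATIC:
            updates["prothrombin_time"] = float(np.round(rng.uniform(20, 49), 1))
        elif factor is RiskFactor.HEART_FAILURE:
            updates["lvef"] = float(np.round(rng.uniform(15, 30), 1))
        elif factor is RiskFactor.PREGNANCY:
            updates["pregnant"] = True
            if RiskFactor.AGE_GE_70 not in factors:
                updates["age"] = min(updates["age"], int(rng.integers(18, 46)))
        elif factor is RiskFactor.CYP_INHIBITOR:
            drug = sorted(catalogue.cyp_inhibitors)[
                int(rng.integers(len(catalogue.cyp_inhibitors)))
            ]
            updates["medications"] = (drug,)
    sex = Sex.FEMALE if updates["pregnant"] else patient.sex
    return patient.model_copy(update={**updates, "sex": sex})


def _patient_with_cw_rule(
    rng: np.random.Generator, cfg: PanelConfig, target_rule: int, max_tries: int = 20000
) -> PatientRecord:
    for _ in range(max_tries):
        patient = _sample_patient(rng, cfg)
        if patient_anthropometrics(patient).cw_rule == target_rule:
            return patient
    raise RuntimeError(
        f"could not sample a patient hitting CW rule {target_rule}; "
        "check the configured anthropometric ranges"
    )


def _narrative(spec_id: str, patient: PatientRecord, drugs, unit: str) -> str:
    names = " + ".join(d.name for d in drugs)
    return (
        f"Vignette {spec_id}: a {patient.age}-year-old "
        f"{patient.sex.value} patient, {patient.height:.0f} cm, "
        f"{patient.actual_weight:.0f} kg, scheduled for a regional block "
        f"with {names}. What is the maximum safe dose in {unit}?"
    )


def generate_vignette_panel(
    n: int,
    config: Optional[PanelConfig] = None,
    seed: int = 0,
) -> list[VignetteSpec]:
    """Generate ``n`` vignettes, reproducible under ``seed``.

    For n ≥ 10 the first ten vignettes guarantee coverage of all five CW
    branch rules, 0/1/2+ risk factors, single and mixture questions, and
    both units; the remainder is sampled from the configured prevalences.
    """
    if n < 1:
        raise ValueError("n must be ≥ 1")
    cfg = config or PanelConfig()
    catalogue = cfg.resolved_catalogue()
    drug_names = sorted(catalogue.drugs)
    rng = np.random.default_rng(seed)
    if n < 10:
        logger.warning(
            "panel of %d vignettes cannot guarantee full coverage "
            "(needs ≥ 10); generating best-effort", n
        )

    # Coverage templates: (cw_rule, n_risk_factors, mixture, unit).
    templates: list[tuple[Optional[int], Optional[int], bool, str]] = [
        (1, 0, False, "mg"),
        (2, 1, False, "mL"),
        (3, 2, True, "mg"),
        (4, 0, True, "mL"),
        (5, 1, False, "mg"),
        (None, 2, True, "mL"),
        (None, 0, False, "mL"),
        (None, 1, True, "mg"),
        (None, None, False, "mL"),
        (None, None, True, "mg"),
    ]

    panel: list[VignetteSpec] = []
    for i in range(n):
        rule, n_risk, mixture, unit = (
            templates[i]
            if i < min(n, 10)
            else (
                None,
                None,
                bool(rng.random() < cfg.mixture_prob),
                "mL" if rng.random() < cfg.ml_prob else "mg",
            )
        )
        patient = (
            _patient_with_cw_rule(rng, cfg, rule)
            if rule is not None
            else _sample_patient(rng, cfg)
        )
        if n_risk is not None:
            chosen = [
                _PLANTABLE[j]
                for j in rng.choice(len(_PLANTABLE), size=n_risk, replace=False)
            ]
            patient = _plant_risk_factors(patient, chosen, rng, catalogue)
        else:
            chosen = [f for f in _PLANTABLE if rng.random() < cfg.risk_factor_prob]
            patient = _plant_risk_factors(patient, chosen, rng, catalogue)
        if mixture:
            pair = rng.choice(len(drug_names), size=2, replace=False)
            drugs = tuple(catalogue.drugs[drug_names[j]] for j in pair)
            split = float(np.round(rng.uniform(0.3, 0.7), 2))
            proportions: Optional[tuple[float, ...]] = (split, round(1 - split, 2))
        else:
            drugs = (catalogue.drugs[drug_names[int(rng.integers(len(drug_names)))]],)
            proportions = None
        vid = f"sv{i + 1:04d}"
        panel.append(
            VignetteSpec(
                vignette_id=vid,
                patient=patient,
                drugs=drugs,
                mixture_proportions=proportions,
                question_unit=unit,
                narrative=_narrative(vid, patient, drugs, unit),
            )
        )
    return panel


def compute_panel_references(
    panel: Sequence[VignetteSpec],
    mode: DoseMode = DoseMode.COMPREHENSIVE,
    catalogue: Optional[DrugCatalogue] = None,
) -> dict[str, ReferenceDose]:
    """Reference maximum for each vignette's first (questioned) drug.

    Mixture vignettes ask about the first component's share of the shared
    toxicity budget.
    """
    catalogue = catalogue or load_catalogue()
    refs: dict[str, ReferenceDose] = {}
    for vignette in panel:
        if vignette.mixture:
            plan = MixturePlan(
                components=tuple(
                    MixtureComponent(drug=d, proportion=p)
                    for d, p in zip(vignette.drugs, vignette.mixture_proportions)
                )
            )
            result = max_safe_mixture(
                vignette.patient, plan, mode, catalogue.cyp_inhibitors
            )[0]
        else:
            result = max_safe_dose(
                vignette.patient, vignette.drugs[0], mode, catalogue.cyp_inhibitors
            )
        refs[vignette.vignette_id] = ReferenceDose.from_dose_result(
            vignette.vignette_id, result, vignette.question_unit, vignette.mixture
        )
    return refs


@dataclass(frozen=True)
class SimulatedResponse:
    """A simulated answer plus the generator's own ground-truth label."""

    response: CandidateResponse
    true_status: Literal["safe", "unsafe", "missing"]
    bias: Optional[float]
    unit_flipped: bool


def simulate_responses(
    panel: Sequence[VignetteSpec],
    profile: RespondentProfile,
    references: Mapping[str, ReferenceDose],
) -> list[SimulatedResponse]:
    """Draw one answer per vignette according to the respondent profile.

    The answered value is the true reference (in the question's unit)
    times a bias draw; a bias above 1 is an overdose by construction and
    is recorded as the ground-truth label. Range answers place the value
    at the low endpoint, matching the lowest-dose normalization rule.
    Unit confusion flips the declared unit while keeping the number.
    """
    rng = np.random.default_rng(profile.seed)
    out: list[SimulatedResponse] = []
    for vignette in panel:
        ref = references[vignette.vignette_id]
        if rng.random() < profile.abstention_prob:
            out.append(
                SimulatedResponse(
                    response=CandidateResponse(
                        vignette_id=vignette.vignette_id,
                        respondent_id=profile.profile_id,
                        payload=Abstention(),
                        unit=vignette.question_unit,
                    ),
                    true_status="missing",
                    bias=None,
                    unit_flipped=False,
                )
            )
            continue
        bias = profile.overdose_bias.draw(rng)
        true_ref = ref.value_in(vignette.question_unit)
        value = true_ref * bias
        true_status = "unsafe" if value > true_ref else "safe"
        if rng.random() < profile.range_prob:
            payload = ValueRange(low=value, high=value * float(rng.uniform(1.0, 1.5)))
        else:
            payload = SingleValue(value=value)
        flipped = rng.random() < profile.unit_confusion_prob
        unit = vignette.question_unit
        if flipped:
            unit = "mg" if unit == "mL" else "mL"
        out.append(
            SimulatedResponse(
                response=CandidateResponse(
                    vignette_id=vignette.vignette_id,
                    respondent_id=profile.profile_id,
                    payload=payload,
                    unit=unit,
                ),
                true_status=true_status,
                bias=bias,
                unit_flipped=flipped,
            )
        )
    return out


def with_seed(profile: RespondentProfile, seed: int) -> RespondentProfile:
    """A copy of ``profile`` reseeded for a particular run."""
    return replace(profile, seed=seed)
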