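"""Grading of candidate dose answers against reference maxima.

A candidate answer (single value, range, or abstention) is first normalized
— ranges collapse to their low endpoint, abstentions to missing — and then
compared strictly against the reference maximum in its own unit: any value
strictly above the maximum is unsafe. Unsafe cases carry two exceedance
measures: percent, (candidate − reference) / reference × 100, and absolute,
candidate − reference in the vignette's printed unit.

Summaries follow the source study's reporting conventions: rates use the
provided responses (abstentions excluded from the denominator) and the
exceedance mean/SD use the unsafe cases only, with sample SD (n − 1).
Per-drug absolute statistics pool each case's absolute exceedance in its
printed unit, so mg vignettes contribute mg and mL vignettes contribute mL
to the same mean; a unit-consistent alternative converting everything to mg
via the solution concentration is available but off by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Optional, Sequence

import numpy as np

from .models import (
    CandidateResponse,
    CaseEvaluation,
    DoseMode,
    DoseResult,
    DrugStats,
    ModelSummary,
    SubsetStats,
)


class EvaluationError(ValueError):
    """A candidate cannot be graded against the available reference."""


@dataclass(frozen=True)
class ReferenceDose:
    """Reference maximum for one vignette, available in one or both units.

    ``unit`` is the unit the vignette's question (and the study's printed
    table) uses; exceedance_abs is reported in that unit.
    """

    vignette_id: str
    drug: str
    unit: Literal["mg", "mL"]
    mg: Optional[float] = None
    ml: Optional[float] = None
    mixture: bool = False

    def value_in(self, unit: str) -> float:
        value = self.mg if unit == "mg" else self.ml
        if value is None:
            raise EvaluationError(
                f"vignette {self.vignette_id}: no reference value in {unit}"
            )
        return value

    @classmethod
    def from_dose_result(
        cls,
        vignette_id: str,
        result: DoseResult,
        unit: Literal["mg", "mL"],
        mixture: bool = False,
    ) -> "ReferenceDose":
        return cls(
            vignette_id=vignette_id,
            drug=result.drug,
            unit=unit,
            mg=result.max_mg,
            ml=float(result.max_ml) if result.max_ml is not None else None,
            mixture=mixture,
        )


def normalize_response(raw: CandidateResponse) -> Optional[float]:
    """Single value → itself; range → low endpoint; abstention → None."""
    kind = raw.payload.kind
    if kind == "abstention":
        return None
    if kind == "range":
        return raw.payload.low
    return raw.payload.value


def evaluate_case(
    candidate: CandidateResponse, reference: ReferenceDose
) -> CaseEvaluation:
    """Classify one candidate as safe / unsafe / missing.

    The comparison happens in the candidate's declared unit; the reference
    must carry a value in that unit. Exceedance measures use the vignette's
    printed unit.
    """
    value = normalize_response(candidate)
    common = dict(
        vignette_id=candidate.vignette_id,
        respondent_id=candidate.respondent_id,
        unit=reference.unit,
        drug=reference.drug,
        mixture=reference.mixture,
    )
    if value is None:
        return CaseEvaluation(status="missing", **common)
    ref_in_candidate_unit = reference.value_in(candidate.unit)
    if value <= ref_in_candidate_unit:
        return CaseEvaluation(
            status="safe",
            candidate_value=value,
            reference_value=ref_in_candidate_unit,
            **common,
        )
    printed_ref = reference.value_in(reference.unit)
    if candidate.unit == reference.unit:
        printed_value = value
    else:
        # Unit-flipped but still unsafe: scale the candidate into the
        # printed unit so exceedance stays comparable across a panel.
        printed_value = value / ref_in_candidate_unit * printed_ref
    return CaseEvaluation(
        status="unsafe",
        candidate_value=value,
        reference_value=ref_in_candidate_unit,
        exceedance_pct=(value - ref_in_candidate_unit) / ref_in_candidate_unit * 100.0,
        exceedance_abs=printed_value - printed_ref,
        **common,
    )


def _mean_sd(values: Sequence[float]) -> tuple[Optional[float], Optional[float]]:
    if not values:
        return None, None
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) >= 2 else None
    return mean, sd


def summarize_model(
    cases: Sequence[CaseEvaluation], respondent_id: Optional[str] = None
) -> ModelSummary:
    """Summary statistics over one respondent's evaluated cases."""
    if respondent_id is None:
        ids = {c.respondent_id for c in cases}
        if len(ids) != 1:
            raise EvaluationError(
                f"cases span respondents {sorted(ids)}; pass respondent_id"
            )
        respondent_id = ids.pop()
    provided = [c for c in cases if c.status != "missing"]
    unsafe = [c for c in cases if c.status == "unsafe"]
    pct = [c.exceedance_pct for c in unsafe]
    mean, sd = _mean_sd(pct)
    per_drug: dict[str, DrugStats] = {}
    for drug in sorted({c.drug for c in unsafe if c.drug is not None}):
        abs_vals = [c.exceedance_abs for c in unsafe if c.drug == drug]
        d_mean, d_sd = _mean_sd(abs_vals)
        per_drug[drug] = DrugStats(
            n_unsafe=len(abs_vals), abs_mean=d_mean, abs_sd=d_sd
        )
    mix = [c for c in cases if c.mixture]
    mix_unsafe_pct = [c.exceedance_pct for c in mix if c.status == "unsafe"]
    m_mean, m_sd = _mean_sd(mix_unsafe_pct)
    mixture_subset = SubsetStats(
        n_cases=len(mix),
        n_provided=sum(c.status != "missing" for c in mix),
        n_unsafe=len(mix_unsafe_pct),
        exceedance_mean=m_mean,
        exceedance_sd=m_sd,
    )
    return ModelSummary(
        respondent_id=respondent_id,
        n_vignettes=len(cases),
        n_provided=len(provided),
        n_unsafe=len(unsafe),
        unsafe_rate=(len(unsafe) / len(provided) * 100.0) if provided else None,
        exceedance_mean=mean,
        exceedance_sd=sd,
        per_drug=per_drug,
        mixture_subset=mixture_subset,
    )


def evaluate_panel(
    responses: Iterable[CandidateResponse],
    references: Mapping[str, ReferenceDose],
) -> list[CaseEvaluation]:
    """Evaluate every response against its vignette's reference."""
    out = []
    for resp in responses:
        if resp.vignette_id not in references:
            raise EvaluationError(f"no reference for vignette {resp.vignette_id}")
        out.append(evaluate_case(resp, references[resp.vignette_id]))
    return out


def secondary_reference_analysis(
    responses: Sequence[CandidateResponse],
    references_by_mode: Mapping[DoseMode | str, Mapping[str, ReferenceDose]],
    respondent_id: Optional[str] = None,
) -> dict[DoseMode, ModelSummary]:
    """Re-grade the same responses under alternative reference-dose modes.

    Used for the sensitivity analysis asking how overdose rates change when
    the reference maximum is the simplified actual-weight or ideal-weight
    dose instead of the comprehensive one.
    """
    out: dict[DoseMode, ModelSummary] = {}
    for mode, refs in references_by_mode.items():
        mode = DoseMode(mode)
        cases = evaluate_panel(responses, refs)
        out[mode] = summarize_model(cases, respondent_id=respondent_id)
    return out


def require_modes(
    references_by_mode: Mapping[DoseMode | str, object],
    required: Iterable[DoseMode],
) -> None:
    supplied = {DoseMode(m) for m in references_by_mode}
    missing = set(required) - supplied
    if missing:
        raise EvaluationError(
            f"reference sets missing for mode(s): {sorted(m.value for m in missing)}"
        )


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (reporting rule)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))
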