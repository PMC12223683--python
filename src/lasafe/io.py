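"""CSV/JSON serialization of patients, panels, responses and evaluations.

Column schemas are deliberately flat so files round-trip through any
spreadsheet: one row per vignette or response, mixture vignettes carrying
the second drug and the budget proportions in extra columns, medications
as a semicolon-separated list.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .config import DrugCatalogue
from .evaluation import ReferenceDose
from .models import (
    Abstention,
    CandidateResponse,
    CaseEvaluation,
    ModelSummary,
    PatientRecord,
    SingleValue,
    ValueRange,
)
from .simulate import SimulatedResponse, VignetteSpec


def patient_from_record(rec: dict) -> PatientRecord:
    meds = rec.get("medications")
    if meds is None or (isinstance(meds, float) and pd.isna(meds)):
        meds = ()
    if isinstance(meds, str):
        meds = tuple(m.strip() for m in meds.split(";") if m.strip())
    return PatientRecord(
        age=int(rec["age"]),
        sex=rec["sex"],
        height=float(rec["height"]),
        actual_weight=float(rec["weight"]),
        gfr=_opt_float(rec.get("gfr")),
        prothrombin_time=_opt_float(rec.get("prothrombin_time")),
        lvef=_opt_float(rec.get("lvef")),
        pregnant=_as_bool(rec.get("pregnant", False)),
        medications=tuple(meds),
    )


def _opt_float(value) -> Optional[float]:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return float(value)


def _as_bool(value) -> bool:
    if isinstance(value, str):
        return value.strip().lower() in {"1", "true", "yes"}
    return bool(value)


def read_patients(path: Path | str) -> list[PatientRecord]:
    """Patients from CSV or JSON (list of objects) with the flat schema."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path).to_dict(orient="records")
    return [patient_from_record(r) for r in records]


def panel_to_frame(panel: Sequence[VignetteSpec]) -> pd.DataFrame:
    rows = []
    for v in panel:
        p = v.patient
        rows.append(
            {
                "vignette_id": v.vignette_id,
                "age": p.age,
                "sex": p.sex.value,
                "height": p.height,
                "weight": p.actual_weight,
                "gfr": p.gfr,
                "prothrombin_time": p.prothrombin_time,
                "lvef": p.lvef,
                "pregnant": p.pregnant,
                "medications": ";".join(p.medications),
                "drug_1": v.drugs[0].name,
                "drug_2": v.drugs[1].name if v.mixture else None,
                "proportion_1": v.mixture_proportions[0] if v.mixture else None,
                "proportion_2": v.mixture_proportions[1] if v.mixture else None,
                "question_unit": v.question_unit,
                "narrative": v.narrative,
            }
        )
    return pd.DataFrame(rows)


def frame_to_panel(frame: pd.DataFrame, catalogue: DrugCatalogue) -> list[VignetteSpec]:
    panel = []
    for rec in frame.to_dict(orient="records"):
        patient = patient_from_record(rec)
        drugs = [catalogue.get(rec["drug_1"])]
        proportions = None
        if rec.get("drug_2") and not pd.isna(rec["drug_2"]):
            drugs.append(catalogue.get(rec["drug_2"]))
            proportions = (float(rec["proportion_1"]), float(rec["proportion_2"]))
        panel.append(
            VignetteSpec(
                vignette_id=str(rec["vignette_id"]),
                patient=patient,
                drugs=tuple(drugs),
                mixture_proportions=proportions,
                question_unit=rec["question_unit"],
                narrative=rec.get("narrative") or "",
            )
        )
    return panel


def responses_to_frame(
    responses: Sequence[CandidateResponse | SimulatedResponse],
) -> pd.DataFrame:
    rows = []
    for item in responses:
        sim = isinstance(item, SimulatedResponse)
        r = item.response if sim else item
        row = {
            "vignette_id": r.vignette_id,
            "respondent_id": r.respondent_id,
            "kind": r.payload.kind,
            "value": getattr(r.payload, "value", None),
            "low": getattr(r.payload, "low", None),
            "high": getattr(r.payload, "high", None),
            "unit": r.unit,
        }
        if sim:
            row["true_status"] = item.true_status
            row["unit_flipped"] = item.unit_flipped
        rows.append(row)
    return pd.DataFrame(rows)


def frame_to_responses(frame: pd.DataFrame) -> list[CandidateResponse]:
    out = []
    for rec in frame.to_dict(orient="records"):
        kind = rec["kind"]
        if kind == "abstention":
            payload = Abstention()
        elif kind == "range":
            payload = ValueRange(low=float(rec["low"]), high=float(rec["high"]))
        else:
            payload = SingleValue(value=float(rec["value"]))
        out.append(
            CandidateResponse(
                vignette_id=str(rec["vignette_id"]),
                respondent_id=str(rec["respondent_id"]),
                payload=payload,
                unit=rec["unit"],
            )
        )
    return out


def read_responses(path: Path | str) -> list[CandidateResponse]:
    path = Path(path)
    if path.suffix.lower() == ".json":
        frame = pd.DataFrame(json.loads(path.read_text()))
    else:
        frame = pd.read_csv(path)
    if frame.empty:
        return []
    return frame_to_responses(frame)


def references_to_frame(references: dict[str, ReferenceDose]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "vignette_id": r.vignette_id,
                "drug": r.drug,
                "unit": r.unit,
                "mg": r.mg,
                "ml": r.ml,
                "mixture": r.mixture,
            }
            for r in references.values()
        ]
    )


def frame_to_references(frame: pd.DataFrame) -> dict[str, ReferenceDose]:
    refs = {}
    for rec in frame.to_dict(orient="records"):
        vid = str(rec["vignette_id"])
        refs[vid] = ReferenceDose(
            vignette_id=vid,
            drug=rec["drug"],
            unit=rec["unit"],
            mg=_opt_float(rec.get("mg")),
            ml=_opt_float(rec.get("ml")),
            mixture=_as_bool(rec.get("mixture", False)),
        )
    return refs


def read_references(path: Path | str) -> dict[str, ReferenceDose]:
    return frame_to_references(pd.read_csv(path))


def cases_to_frame(cases: Sequence[CaseEvaluation]) -> pd.DataFrame:
    return pd.DataFrame([c.model_dump() for c in cases])


def summary_to_json(summaries: Sequence[ModelSummary], path: Path | str) -> None:
    Path(path).write_text(
        json.dumps([s.model_dump() for s in summaries], indent=2, default=str)
    )
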