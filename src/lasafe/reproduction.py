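"""Recomputation of the source study's published summary statistics.

``reproduce_results`` rebuilds every quantitative summary the study prints
— per-chatbot provision and overdose rates, mean/SD percent exceedance,
per-drug absolute exceedance, the mixture subset, and the overall
qualitative labels — from the shipped per-vignette and rating fixtures,
then flags each against the published value after rounding to the printed
precision. Nothing here feeds back into the computation: the published
numbers are comparison targets only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .evaluation import (
    ReferenceDose,
    evaluate_panel,
    round_half_up,
    summarize_model,
)
from .fixtures import RESPONDENTS, StudyFixtures, load_fixtures
from .models import Abstention, CandidateResponse, ModelSummary, SingleValue
from .qualitative import likert_label, overall_rating

#: Published values, rounded as printed, used only as pass/fail targets.
PUBLISHED = {
    "gemini": {
        "n_provided": 3,
        "provided_rate": 30,
        "mixture_exceedance_mean": 140,
        "mixture_exceedance_sd": 103,
        "overall_label": "fair",
    },
    "chatgpt": {
        "n_provided": 10,
        "n_unsafe": 9,
        "unsafe_rate": 90,
        "exceedance_mean": 198,
        "exceedance_sd": 196,
        "per_drug_abs_mean": {"lidocaine": 129, "levobupivacaine": 46, "ropivacaine": 70},
        "per_drug_abs_sd": {"lidocaine": 143, "levobupivacaine": 58, "ropivacaine": 67},
        "overall_label": "poor",
    },
    "copilot": {
        "n_provided": 9,
        "n_unsafe": 6,
        "unsafe_rate": 67,
        "exceedance_mean": 217,
        "exceedance_sd": 239,
        "per_drug_abs_mean": {"lidocaine": 129, "levobupivacaine": 52},
        "per_drug_abs_sd": {"lidocaine": 143, "levobupivacaine": 60},
        "overall_label": "poor",
    },
}


def table1_references(table1: pd.DataFrame) -> dict[str, ReferenceDose]:
    """Reference maxima keyed by vignette id, in each vignette's unit."""
    refs: dict[str, ReferenceDose] = {}
    for row in table1.itertuples():
        vid = str(row.vignette)
        refs[vid] = ReferenceDose(
            vignette_id=vid,
            drug=row.drug,
            unit=row.unit,
            mg=row.reference if row.unit == "mg" else None,
            ml=row.reference if row.unit == "mL" else None,
            mixture=bool(row.mixture),
        )
    return refs


def table1_responses(
    table1: pd.DataFrame, respondent: str
) -> list[CandidateResponse]:
    """One respondent's column of the per-vignette table as responses.

    The table stores already-normalized values (range answers were reduced
    to their low endpoint upstream); empty cells are abstentions.
    """
    out: list[CandidateResponse] = []
    for row in table1.itertuples():
        value = getattr(row, respondent)
        payload = Abstention() if pd.isna(value) else SingleValue(value=float(value))
        out.append(
            CandidateResponse(
                vignette_id=str(row.vignette),
                respondent_id=respondent,
                payload=payload,
                unit=row.unit,
            )
        )
    return out


def summarize_respondent(
    fixtures: StudyFixtures, respondent: str
) -> ModelSummary:
    refs = table1_references(fixtures.table1)
    cases = evaluate_panel(table1_responses(fixtures.table1, respondent), refs)
    return summarize_model(cases, respondent_id=respondent)


@dataclass(frozen=True)
class Check:
    name: str
    computed: Optional[float | str]
    published: float | str
    passed: bool


def _rounded(value: Optional[float]) -> Optional[int]:
    return None if value is None else round_half_up(value)


def reproduce_results(fixtures: Optional[StudyFixtures] = None) -> list[Check]:
    """Recompute all published summary statistics and flag agreement."""
    fixtures = fixtures or load_fixtures()
    checks: list[Check] = []

    def add(name: str, computed, published) -> None:
        checks.append(Check(name, computed, published, computed == published))

    for resp in RESPONDENTS:
        summary = summarize_respondent(fixtures, resp)
        pub = PUBLISHED[resp]
        add(f"{resp}.n_provided", summary.n_provided, pub["n_provided"])
        if "unsafe_rate" in pub:
            add(f"{resp}.n_unsafe", summary.n_unsafe, pub["n_unsafe"])
            add(f"{resp}.unsafe_rate", _rounded(summary.unsafe_rate), pub["unsafe_rate"])
            add(
                f"{resp}.exceedance_mean",
                _rounded(summary.exceedance_mean),
                pub["exceedance_mean"],
            )
            add(
                f"{resp}.exceedance_sd",
                _rounded(summary.exceedance_sd),
                pub["exceedance_sd"],
            )
            for drug, mean in pub["per_drug_abs_mean"].items():
                add(
                    f"{resp}.{drug}.abs_mean",
                    _rounded(summary.per_drug[drug].abs_mean)
                    if drug in summary.per_drug
                    else None,
                    mean,
                )
            for drug, sd in pub["per_drug_abs_sd"].items():
                add(
                    f"{resp}.{drug}.abs_sd",
                    _rounded(summary.per_drug[drug].abs_sd)
                    if drug in summary.per_drug
                    else None,
                    sd,
                )
        else:
            add(
                f"{resp}.provided_rate",
                _rounded(summary.n_provided / summary.n_vignettes * 100),
                pub["provided_rate"],
            )
            mix = summary.mixture_subset
            add(
                f"{resp}.mixture_exceedance_mean",
                _rounded(mix.exceedance_mean),
                pub["mixture_exceedance_mean"],
            )
            add(
                f"{resp}.mixture_exceedance_sd",
                _rounded(mix.exceedance_sd),
                pub["mixture_exceedance_sd"],
            )
        scores = fixtures.table2[resp + "_score"].tolist()
        add(
            f"{resp}.overall_label",
            likert_label(overall_rating(scores)),
            pub["overall_label"],
        )
    return checks


def report_frame(checks: list[Check]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "statistic": [c.name for c in checks],
            "computed": [c.computed for c in checks],
            "published": [c.published for c in checks],
            "pass": [c.passed for c in checks],
        }
    )
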