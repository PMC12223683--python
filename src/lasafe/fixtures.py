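"""Published study data shipped with the package.

Two small tables from the source study are transcribed once into CSV and
guarded by checksums: the per-vignette dose table (reference maxima and the
three chatbot answers, with abstentions as empty cells) and the 8-criterion
consensus Likert ratings. ``load_fixtures`` is the only supported access
path; a checksum mismatch is a hard error because every reproduction
statistic downstream depends on these cells being intact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

TABLE1_FILENAME = "table1_vignettes.csv"
TABLE2_FILENAME = "table2_ratings.csv"

_CHECKSUMS = {
    TABLE1_FILENAME: "7ceff2f5dfb48aaf5e1f8a30dd1eae709ba6704a64388f183c255c1f8b4e99c6",
    TABLE2_FILENAME: "01a1862ed76fd73aff582bf672ebe4378a5d732041d3463b779bf37690ab7ea6",
}

RESPONDENTS = ("gemini", "chatgpt", "copilot")

LIKERT_LABELS = {
    1: "very poor",
    2: "poor",
    3: "fair",
    4: "good",
    5: "very good",
}
LIKERT_SCORES = {label: score for score, label in LIKERT_LABELS.items()}


class FixtureIntegrityError(RuntimeError):
    """A shipped data file does not match its recorded checksum."""


def _data_path(filename: str) -> Path:
    return Path(resources.files("lasafe.data") / filename)


def _verified_bytes(filename: str) -> bytes:
    raw = _data_path(filename).read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureIntegrityError(
            f"{filename}: checksum {digest} != expected {_CHECKSUMS[filename]}"
        )
    return raw


@dataclass(frozen=True)
class StudyFixtures:
    """The per-vignette dose table and the consensus rating table.

    ``table1`` has one row per vignette with columns ``vignette`` (int),
    ``drug``, ``unit`` (mg/mL), ``reference`` (float), ``mixture`` (bool)
    and one float column per respondent (NaN = abstention). ``table2`` is
    indexed by criterion with one integer Likert consensus score (1-5) per
    respondent.
    """

    table1: pd.DataFrame
    table2: pd.DataFrame


def load_fixtures() -> StudyFixtures:
    """Load and checksum-verify both study tables."""
    from io import BytesIO

    t1 = pd.read_csv(BytesIO(_verified_bytes(TABLE1_FILENAME)))
    t1["mixture"] = t1["mixture"].map({"yes": True, "no": False})
    for col in RESPONDENTS:
        t1[col] = pd.to_numeric(t1[col])
    t2 = pd.read_csv(BytesIO(_verified_bytes(TABLE2_FILENAME))).set_index("criterion")
    for col in RESPONDENTS:
        bad = set(t2[col]) - set(LIKERT_SCORES)
        if bad:
            raise FixtureIntegrityError(f"unknown Likert label(s) {bad} in table2")
        t2[col + "_score"] = t2[col].map(LIKERT_SCORES)
    return StudyFixtures(table1=t1, table2=t2)
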