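"""Drug catalogue and run configuration.

The per-kg dose limits are deliberately configuration, not code constants:
institutions disagree on them and the shipped values are literature
defaults. Loading without an explicit path falls back to the packaged
catalogue with a logged warning so a run never silently assumes limits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import yaml

from .models import AnestheticSpec

logger = logging.getLogger(__name__)

DEFAULT_CATALOGUE_FILENAME = "drug_catalogue.yaml"


@dataclass(frozen=True)
class DrugCatalogue:
    """Named anesthetic specs plus the CYP-inhibitor membership list."""

    drugs: dict[str, AnestheticSpec]
    cyp_inhibitors: frozenset[str]
    source: str

    def get(self, name: str) -> AnestheticSpec:
        key = name.strip().lower()
        if key not in self.drugs:
            raise KeyError(
                f"unknown anesthetic {name!r}; catalogue has {sorted(self.drugs)}"
            )
        return self.drugs[key]


def load_catalogue(path: Optional[Path | str] = None) -> DrugCatalogue:
    """Load a drug catalogue; default to the packaged one with a warning."""
    if path is None:
        path = Path(resources.files("lasafe.data") / DEFAULT_CATALOGUE_FILENAME)
        logger.warning(
            "no drug catalogue supplied; using packaged literature defaults at %s",
            path,
        )
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    drugs = {
        name.lower(): AnestheticSpec(
            name=name.lower(),
            dose_limit=spec["dose_limit_mg_per_kg"],
            concentration=spec.get("concentration_mg_per_ml"),
        )
        for name, spec in raw["drugs"].items()
    }
    inhibitors = frozenset(m.lower() for m in raw.get("cyp_inhibitors", []))
    return DrugCatalogue(drugs=drugs, cyp_inhibitors=inhibitors, source=str(path))


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs to be reproducible."""

    catalogue_path: Optional[Path] = None
    output_dir: Path = Path("lasafe_out")
    seed: int = 0
    n_vignettes: int = 10
    report_precision: int = 0
    mode: str = "comprehensive"
    profile_name: str = "overdose_prone"
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise ValueError("seed must be a nonnegative integer")
        if self.catalogue_path is not None and not Path(self.catalogue_path).exists():
            raise FileNotFoundError(self.catalogue_path)
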