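"""End-to-end runs: simulate → compute references → evaluate → report.

Every run writes its artifacts (panel, references, responses, case table,
summary JSON) plus a run log carrying the seed, configuration, package
version and fixture checksums, so any report can be regenerated from its
log alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Sequence

from . import __version__
from .config import RunConfig, load_catalogue
from .evaluation import evaluate_panel, summarize_model
from .fixtures import _CHECKSUMS
from .io import (
    cases_to_frame,
    panel_to_frame,
    references_to_frame,
    responses_to_frame,
    summary_to_json,
)
from .models import DoseMode
from .reproduction import report_frame, reproduce_results
from .simulate import (
    PROFILES,
    PanelConfig,
    compute_panel_references,
    generate_vignette_panel,
    simulate_responses,
    with_seed,
)

logger = logging.getLogger(__name__)

DISCLAIMER = (
    "Research use only: not a medical device; not for clinical dosing decisions."
)


def _write_log(config: RunConfig, out_dir: Path, extra: dict) -> None:
    log = {
        "package_version": __version__,
        "seed": config.seed,
        "mode": config.mode,
        "n_vignettes": config.n_vignettes,
        "profile": config.profile_name,
        "fixture_checksums": dict(_CHECKSUMS),
        "disclaimer": DISCLAIMER,
        **extra,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2))


def run_pipeline(config: RunConfig) -> Path:
    """Simulated-panel pipeline; returns the output directory."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    catalogue = load_catalogue(config.catalogue_path)
    panel_cfg = PanelConfig(catalogue=catalogue)
    panel = generate_vignette_panel(config.n_vignettes, panel_cfg, seed=config.seed)
    references = compute_panel_references(
        panel, DoseMode(config.mode), catalogue=catalogue
    )
    profile = with_seed(PROFILES[config.profile_name], config.seed + 1)
    simulated = simulate_responses(panel, profile, references)
    cases = evaluate_panel([s.response for s in simulated], references)
    summary = summarize_model(cases, respondent_id=profile.profile_id)

    panel_to_frame(panel).to_csv(out_dir / "panel.csv", index=False)
    references_to_frame(references).to_csv(out_dir / "references.csv", index=False)
    responses_to_frame(simulated).to_csv(out_dir / "responses.csv", index=False)
    cases_to_frame(cases).to_csv(out_dir / "cases.csv", index=False)
    summary_to_json([summary], out_dir / "summary.json")
    _write_log(config, out_dir, {"catalogue": catalogue.source})
    logger.info("pipeline artifacts written to %s", out_dir)
    return out_dir


def run_reproduction(out_dir: Path | str) -> Path:
    """Recompute the published summary statistics and write the report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    checks = reproduce_results()
    frame = report_frame(checks)
    frame.to_csv(out_dir / "reproduction_report.csv", index=False)
    payload = {
        "disclaimer": DISCLAIMER,
        "all_pass": bool(frame["pass"].all()),
        "checks": frame.to_dict(orient="records"),
    }
    (out_dir / "reproduction_report.json").write_text(json.dumps(payload, indent=2))
    return out_dir


def evaluate_files(
    references_path: Path | str,
    responses_path: Path | str,
    out_dir: Path | str,
) -> Sequence:
    """Grade a response file against a reference file; write reports."""
    from .io import read_references, read_responses

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    references = read_references(references_path)
    responses = read_responses(responses_path)
    summaries = []
    by_respondent: dict[str, list] = {}
    for r in responses:
        by_respondent.setdefault(r.respondent_id, []).append(r)
    all_cases = []
    for respondent_id, resp in sorted(by_respondent.items()):
        cases = evaluate_panel(resp, references)
        all_cases.extend(cases)
        summaries.append(summarize_model(cases, respondent_id=respondent_id))
    cases_to_frame(all_cases).to_csv(out_dir / "cases.csv", index=False)
    summary_to_json(summaries, out_dir / "summary.json")
    return summaries
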