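"""End-to-end pipeline: simulate (or ingest) → classify → summarize → recommend.

A single :class:`RunConfig` drives the whole run; any omitted block falls back
to documented defaults (0.6%/1.0% threshold fractions, the printed rank
thresholds, the benchmark synthetic design). Every bundle carries a
provenance JSON — config hash, seed, package version, and the threshold
fractions actually used — because cutoff fractions are run-tailored and a
detection table is meaningless without them. Outputs are byte-identical under
a fixed config and seed. A failure in any stage removes the partial outputs
it wrote and re-raises with the stage name.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .framework import (
    check_negative_controls,
    histories_from_detections,
    recommend_action,
    escalate,
    verify_positive_controls,
)
from .io import (
    RunManifest,
    read_manifest,
    read_tally_table,
    write_detection_table,
    write_manifest,
    write_tally_table,
)
from .rank import RankThresholds
from .simulate import SimParams, add_controls, random_panel, simulate_run, study_design
from .summaries import cumulative_curves, replicate_profile, site_species_matrix
from .thresholds import ThresholdConfig, classify_run

logger = logging.getLogger("ednadetect")


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs have been removed."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class RunConfig(BaseModel):
    """Full configuration of one pipeline run."""

    mode: Literal["simulate", "ingest"] = "simulate"
    seed: int = 0
    out_dir: str = "results/run"
    manifest_path: Optional[str] = None
    tallies_path: Optional[str] = None  # required in ingest mode
    sim: Optional[SimParams] = None
    thresholds: ThresholdConfig = Field(default_factory=ThresholdConfig)
    rank_thresholds: RankThresholds = Field(default_factory=RankThresholds)
    log_level: str = "INFO"

    def config_hash(self) -> str:
        # hash the scientific configuration only, not filesystem locations
        doc = self.model_dump(mode="json", exclude={"out_dir", "manifest_path", "tallies_path"})
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode("utf-8")
        ).hexdigest()[:16]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from JSON or YAML (by file suffix)."""
    text = Path(path).read_text(encoding="utf-8")
    if str(path).endswith((".yaml", ".yml")):
        doc = yaml.safe_load(text)
    else:
        doc = json.loads(text)
    return RunConfig.model_validate(doc)


def _actions_table(detections, manifest) -> "pd.DataFrame":
    import pandas as pd

    histories = histories_from_detections(detections)
    rows = []
    for (site, taxon), hist in sorted(histories.items()):
        effective = escalate(hist)
        actions = recommend_action(effective)
        rows.append(
            dict(
                site_id=site,
                taxon=taxon,
                effective_category=effective,
                actions="|".join(sorted(actions)),
            )
        )
    return pd.DataFrame(rows, columns=["site_id", "taxon", "effective_category", "actions"])


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Execute the configured pipeline; returns {artifact name: path}."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    artifacts: dict[str, str] = {}

    def emit(name: str, filename: str, writer) -> None:
        path = out_dir / filename
        writer(path)
        written.append(path)
        artifacts[name] = str(path)

    stage = "configure"
    try:
        stage = "inputs"
        if config.mode == "ingest":
            if not config.tallies_path or not config.manifest_path:
                raise ValueError("ingest mode requires tallies_path and manifest_path")
            manifest = read_manifest(config.manifest_path)
            tallies = read_tally_table(config.tallies_path, manifest)
            truth = None
        else:
            if config.manifest_path:
                manifest = read_manifest(config.manifest_path)
                params = config.sim or SimParams(
                    taxa=random_panel(manifest, seed=config.seed)
                )
            else:
                manifest, default_params = study_design(seed=config.seed)
                params = config.sim or default_params
            params = params.model_copy(update={"seed": config.seed})
            stage = "simulate"
            truth, tallies = simulate_run(manifest, params)
            if any(c.kind == "positive" and c.expected_taxa for c in manifest.controls):
                tallies, truth = add_controls(tallies, manifest, params, truth)
            emit("manifest", "manifest.json", lambda p: write_manifest(manifest, p))
            emit("tallies", "tallies.tsv", lambda p: write_tally_table(tallies, p))
            emit("truth", "truth.json", lambda p: truth.to_json(p))

        stage = "classify"
        thresholds, detections = classify_run(tallies, manifest, config.thresholds)
        emit("detections", "detections.csv", lambda p: write_detection_table(detections, p))
        emit(
            "thresholds",
            "thresholds.json",
            lambda p: Path(p).write_text(
                json.dumps(thresholds.to_dict(), indent=2, sort_keys=True) + "\n"
            ),
        )

        stage = "summarize"
        profile = replicate_profile(detections, manifest)
        matrix = site_species_matrix(detections, manifest)
        curves = cumulative_curves(detections, manifest)
        emit("replicate_profile", "replicate_profile.csv",
             lambda p: profile.to_csv(p, index=False, lineterminator="\n"))
        emit("site_species_matrix", "site_species_matrix.csv",
             lambda p: matrix.to_csv(p, lineterminator="\n"))
        emit("cumulative_curves", "cumulative_curves.csv",
             lambda p: curves.to_csv(p, index=False, lineterminator="\n"))

        stage = "recommend"
        actions = _actions_table(detections, manifest)
        emit("actions", "actions.csv",
             lambda p: actions.to_csv(p, index=False, lineterminator="\n"))
        qc = {
            "negative_control_flags": [
                vars(f) for f in check_negative_controls(detections, manifest)
            ]
            if manifest.control_ids("negative")
            else [],
            "positive_controls": [
                {
                    "sample_id": r.sample_id,
                    "plate": r.plate,
                    "n_expected": len(r.expected),
                    "n_detected": len(r.detected),
                    "missing": list(r.missing),
                }
                for r in (
                    verify_positive_controls(detections, manifest)
                    if any(c.kind == "positive" and c.expected_taxa for c in manifest.controls)
                    else []
                )
            ],
        }
        emit("control_qc", "control_qc.json",
             lambda p: Path(p).write_text(json.dumps(qc, indent=2, sort_keys=True) + "\n"))

        stage = "provenance"
        prov = {
            "config_sha256": config.config_hash(),
            "seed": config.seed,
            "mode": config.mode,
            "package_version": __version__,
            "drop_frac": config.thresholds.drop_frac,
            "low_frac": config.thresholds.low_frac,
            "total_reads": thresholds.total_reads,
            "cutoff_drop": thresholds.cutoff_drop,
            "cutoff_low": thresholds.cutoff_low,
        }
        emit("provenance", "provenance.json",
             lambda p: Path(p).write_text(json.dumps(prov, indent=2, sort_keys=True) + "\n"))
    except (ValueError, ValidationError, StageError, OSError) as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, StageError):
            raise
        raise StageError(stage, exc) from exc
    return artifacts
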