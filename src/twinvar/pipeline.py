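"""End-to-end orchestration: read -> filter -> adjust -> scan -> validate -> report.

The pipeline is deterministic given its inputs and configuration; the run
manifest (config hash, input checksums, seed, stage timings, funnel counts)
suffices to reproduce a run exactly.  Any stage failure aborts with the
stage named, and whatever was already written is moved to a quarantine
directory so partial output is never mistaken for a completed run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from pathlib import Path

import yaml

from . import __version__
from .cells import estimate_cell_proportions, adjust_for_cells, CellReference
from .io import (
    BetaMatrix,
    ProbeAnnotation,
    TwinvarError,
    read_annotation,
    read_beta_matrix,
    read_detection_p,
    read_sample_sheet,
    write_bed,
    write_results,
)
from .preprocessing import run_filters
from .scan import identify_outlier_cotwin, scan
from .validation import profile_pairs, validate_candidates

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "StageError", "run_pipeline"]


class StageError(TwinvarError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclasses.dataclass
class PipelineConfig:
    beta_path: str
    sample_sheet_path: str
    output_dir: str
    detection_p_path: str | None = None
    annotation_path: str | None = None
    cell_reference_path: str | None = None
    # stage toggles
    detection_filter: bool = True
    autosome_filter: bool = True
    completeness_filter: bool = True
    cell_adjustment: bool = True
    # thresholds
    detection_threshold: float = 1e-4
    q_threshold: float = 0.05
    range_threshold_pp: float = 10.0
    z_threshold: float = 3.0
    shared_diff_threshold_pp: float = 5.0
    ridge: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        flat = {}
        for key, value in raw.items():
            if isinstance(value, dict):  # flat key/value with optional sections
                flat.update(value)
            else:
                flat[key] = value
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(flat) - known
        if unknown:
            raise TwinvarError(f"unknown config keys: {sorted(unknown)}")
        return cls(**flat)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def validate_paths(self) -> None:
        required = {"beta_path": self.beta_path, "sample_sheet_path": self.sample_sheet_path}
        optional = {
            "detection_p_path": self.detection_p_path,
            "annotation_path": self.annotation_path,
            "cell_reference_path": self.cell_reference_path,
        }
        for name, p in {**required, **{k: v for k, v in optional.items() if v}}.items():
            if p is None or not Path(p).exists():
                raise TwinvarError(f"config error: {name} {p!r} does not exist")


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclasses.dataclass
class PipelineResult:
    results: pd.DataFrame
    validation: pd.DataFrame
    funnel: dict
    manifest: dict
    output_dir: Path


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage and write the full artifact set to ``output_dir``."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    config.validate_paths()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    manifest: dict = {
        "twinvar_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "input_checksums": {},
    }

    def stage(name):
        class _Timer:
            def __enter__(self_):
                self_.t0 = time.perf_counter()
                logger.info("stage %s: start", name)

            def __exit__(self_, exc_type, exc, tb):
                timings[name] = round(time.perf_counter() - self_.t0, 4)
                if exc is not None:
                    _quarantine(outdir)
                    raise StageError(name, exc) from exc

        return _Timer()

    with stage("read"):
        beta = read_beta_matrix(config.beta_path)
        sheet = read_sample_sheet(config.sample_sheet_path)
        detp = read_detection_p(config.detection_p_path) if config.detection_p_path else None
        annotation = read_annotation(config.annotation_path) if config.annotation_path else None
        reference = None
        if config.cell_reference_path:
            ref_df = pd.read_csv(config.cell_reference_path, index_col=0)
            reference = CellReference(ref_df)
        for key in ("beta_path", "sample_sheet_path", "detection_p_path",
                    "annotation_path", "cell_reference_path"):
            p = getattr(config, key)
            if p:
                manifest["input_checksums"][key] = _sha256(p)

    with stage("filter"):
        beta, report = run_filters(
            beta, detp, annotation, sheet,
            detection_threshold=config.detection_threshold,
            enable_detection=config.detection_filter,
            enable_autosome=config.autosome_filter,
            enable_complete=config.completeness_filter,
        )
        manifest["filter_report"] = dataclasses.asdict(report)

    n_clipped = 0
    if config.cell_adjustment and reference is not None:
        with stage("adjust"):
            proportions = estimate_cell_proportions(beta, reference)
            adj = adjust_for_cells(beta, proportions, ridge=config.ridge)
            beta = adj.adjusted
            n_clipped = adj.n_clipped
            proportions.values.to_csv(outdir / "cell_proportions.csv")
    manifest["adjustment_clipped"] = n_clipped

    with stage("scan"):
        # drop probes that still carry missing values outside the discordant
        # subset only for attribution/validation readouts; the scan itself
        # uses the discordant columns, complete after the funnel
        result = scan(
            beta, sheet,
            q_threshold=config.q_threshold,
            range_threshold_pp=config.range_threshold_pp,
        )
        manifest["scan_funnel"] = result.funnel
        manifest["pi0"] = result.pi0

        attributions = []
        disc = sheet.discordant_samples()
        for probe in result.outlier_probes():
            pair_id, sample_id, dev, tied = identify_outlier_cotwin(
                beta.values.loc[probe, disc], sheet
            )
            attributions.append(
                {"probe_id": probe, "pair_id": pair_id, "sample_id": sample_id,
                 "deviation_pp": dev, "tied": tied}
            )
        attribution = pd.DataFrame(
            attributions,
            columns=["probe_id", "pair_id", "sample_id", "deviation_pp", "tied"],
        )

    with stage("validate"):
        candidates = result.outlier_probes()
        if candidates:
            profiles, tidy = profile_pairs(
                beta, sheet, candidates,
                z_threshold=config.z_threshold,
                shared_diff_threshold_pp=config.shared_diff_threshold_pp,
            )
            validation = validate_candidates(candidates, profiles)
        else:
            profiles = pd.DataFrame(
                columns=["probe_id", "pair_id", "pair_class", "value_a", "value_b",
                         "intrapair_diff_pp", "pattern"]
            )
            tidy = pd.DataFrame(
                columns=["probe_id", "pair_id", "sample_id", "role", "status",
                         "pair_class", "beta"]
            )
            validation = pd.DataFrame(
                columns=["probe_id", "n_validation_pairs", "n_normative",
                         "n_shared_outlier", "n_discordant_outlier", "validated",
                         "snv_suspect", "offending_pairs"]
            )
        manifest["n_validated"] = int(validation["validated"].sum()) if len(validation) else 0

    with stage("report"):
        results_table = write_results(result.stats, annotation, outdir / "results.tsv")
        validation.to_csv(outdir / "validation.tsv", sep="\t", index=False)
        profiles.to_csv(outdir / "pair_profiles.tsv", sep="\t", index=False)
        tidy.to_csv(outdir / "pair_profiles_tidy.tsv", sep="\t", index=False)
        attribution.to_csv(outdir / "outlier_attribution.tsv", sep="\t", index=False)
        if annotation is not None and candidates:
            write_bed(candidates, annotation, outdir / "outliers.bed")
        funnel = {**manifest.get("filter_report", {}), **result.funnel}
        with open(outdir / "funnel.json", "w") as fh:
            json.dump(funnel, fh, indent=2)

    manifest["stage_timings_s"] = timings
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)

    return PipelineResult(
        results=results_table,
        validation=validation,
        funnel=funnel,
        manifest=manifest,
        output_dir=outdir,
    )


def _quarantine(outdir: Path) -> None:
    """Move partial outputs aside so failed runs are never mistaken for complete."""
    partial = [p for p in outdir.iterdir() if p.is_file()] if outdir.exists() else []
    if not partial:
        return
    qdir = outdir / "_quarantine"
    qdir.mkdir(exist_ok=True)
    for p in partial:
        shutil.move(str(p), qdir / p.name)
    logger.error("moved %d partial outputs to %s", len(partial), qdir)
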