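"""Probe-filtering funnel applied before any statistics.

Three filters run in a fixed order — detection quality, autosome
restriction, completeness over a named sample subset — each producing a
probe set that is a subset of its input.  The :class:`FilterReport` records
the per-stage removals so the funnel reconciles exactly.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from pathlib import Path

from .io import (
    AUTOSOMES,
    BetaMatrix,
    DetectionPMatrix,
    MatrixFormatError,
    ProbeAnnotation,
    SampleSheet,
    ValueRangeError,
)

logger = logging.getLogger(__name__)

__all__ = ["FilterReport", "filter_by_detection", "filter_autosomes", "filter_complete", "run_filters"]


@dataclasses.dataclass
class FilterReport:
    """Per-stage probe counts for the filtering funnel (applied sequentially)."""

    input_probe_count: int
    removed_by_detection: int = 0
    removed_sex_chromosomes: int = 0
    removed_missing: int = 0
    output_probe_count: int = 0

    def reconciles(self) -> bool:
        removed = (
            self.removed_by_detection
            + self.removed_sex_chromosomes
            + self.removed_missing
        )
        return self.output_probe_count == self.input_probe_count - removed

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    def log(self) -> None:
        logger.info(
            "filter funnel: %d probes in -> detection -%d -> sex chromosomes -%d "
            "-> missing -%d -> %d probes out",
            self.input_probe_count,
            self.removed_by_detection,
            self.removed_sex_chromosomes,
            self.removed_missing,
            self.output_probe_count,
        )


def filter_by_detection(
    beta: BetaMatrix, detp: DetectionPMatrix, threshold: float = 1e-4
) -> BetaMatrix:
    """Drop probes with poor detection quality in any sample.

    A probe is removed when its detection p-value exceeds ``threshold`` in at
    least one sample (the strictest any-sample rule); samples are untouched.
    """
    if not (0 < threshold <= 1):
        raise ValueRangeError(f"detection threshold {threshold} outside (0, 1]")
    if not detp.matches(beta):
        raise MatrixFormatError("detection-p matrix does not match beta matrix layout")
    fails = (detp.values.to_numpy() > threshold).any(axis=1)
    return BetaMatrix(beta.values.loc[~fails])


def filter_autosomes(
    beta: BetaMatrix,
    annotation: ProbeAnnotation,
    unannotated: str = "drop",
) -> BetaMatrix:
    """Keep only probes annotated to chromosomes 1-22.

    Sex-chromosome probes confound mixed-sex cohorts and are removed.
    Probes absent from the annotation follow the ``unannotated`` policy:
    ``"drop"`` (default, with a warning) or ``"error"``.
    """
    chroms = annotation.chromosomes_for(beta.probe_ids)
    unknown = chroms.isna()
    if unknown.any():
        if unannotated == "error":
            raise KeyError(
                f"{int(unknown.sum())} probes missing from annotation "
                f"(first: {beta.probe_ids[unknown][:3].tolist()})"
            )
        warnings.warn(
            f"dropping {int(unknown.sum())} probes absent from annotation",
            stacklevel=2,
        )
    keep = chroms.isin(AUTOSOMES).to_numpy()
    return BetaMatrix(beta.values.loc[keep])


def filter_complete(beta: BetaMatrix, samples: list | None = None, sheet: SampleSheet | None = None) -> BetaMatrix:
    """Drop probes with a missing value in any of the named samples.

    By default the subset is every individual from a diagnosis-discordant
    pair (the samples the variance scan uses), taken from ``sheet``.
    """
    if samples is None:
        if sheet is None:
            raise ValueError("provide either an explicit sample list or a sample sheet")
        samples = sheet.discordant_samples()
    unknown = [s for s in samples if s not in beta.sample_ids]
    if unknown:
        raise KeyError(f"unknown sample ids: {unknown[:5]}")
    has_missing = beta.values[samples].isna().any(axis=1).to_numpy()
    return BetaMatrix(beta.values.loc[~has_missing])


def run_filters(
    beta: BetaMatrix,
    detp: DetectionPMatrix | None,
    annotation: ProbeAnnotation | None,
    sheet: SampleSheet,
    detection_threshold: float = 1e-4,
    enable_detection: bool = True,
    enable_autosome: bool = True,
    enable_complete: bool = True,
) -> tuple[BetaMatrix, FilterReport]:
    """Apply the full funnel (detection -> autosome -> completeness)."""
    report = FilterReport(input_probe_count=beta.shape[0])
    if enable_detection and detp is not None:
        n0 = beta.shape[0]
        beta = filter_by_detection(beta, detp, detection_threshold)
        report.removed_by_detection = n0 - beta.shape[0]
    if enable_autosome and annotation is not None:
        n0 = beta.shape[0]
        beta = filter_autosomes(beta, annotation)
        report.removed_sex_chromosomes = n0 - beta.shape[0]
    if enable_complete:
        n0 = beta.shape[0]
        beta = filter_complete(beta, sheet=sheet)
        report.removed_missing = n0 - beta.shape[0]
    report.output_probe_count = beta.shape[0]
    report.log()
    return beta, report
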