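"""Core data types and tabular I/O for methylation-array pipelines.

The central container is :class:`BetaMatrix`, a probe-by-sample matrix of
DNA methylation fractions (beta values) in ``[0, 1]``.  Companion tables are
the per-sample :class:`SampleSheet` describing the twin-pair design, a
:class:`ProbeAnnotation` table with genomic coordinates (1-based, as printed
by array manifests), and an optional :class:`DetectionPMatrix` of per-call
detection p-values.

All delimited-text readers accept an empty cell or ``"NA"`` as the missing
token; writers emit ``"NA"``.  Values outside the documented domain raise,
they are never clamped silently.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TwinvarError",
    "MatrixFormatError",
    "ValueRangeError",
    "SampleSheetError",
    "BetaMatrix",
    "DetectionPMatrix",
    "SampleSheet",
    "ProbeAnnotation",
    "compute_beta_from_intensities",
    "read_beta_matrix",
    "read_detection_p",
    "read_sample_sheet",
    "read_annotation",
    "write_beta_matrix",
    "write_results",
    "write_bed",
]

MISSING_TOKENS = ("", "NA")

RESULT_COLUMNS = [
    "probe_id", "F", "df1", "df2", "p", "q",
    "affected_range_pct", "healthy_range_pct", "range_diff_pp",
    "mean_beta", "outlier_flag",
    "chromosome", "position", "gene_name", "gene_region",
]

AUTOSOMES = tuple(str(c) for c in range(1, 23))
ALLOWED_CHROMOSOMES = AUTOSOMES + ("X", "Y")


class TwinvarError(Exception):
    """Base class for all package errors."""


class MatrixFormatError(TwinvarError):
    """Structural problem in a matrix table (duplicates, shape mismatch)."""


class ValueRangeError(TwinvarError):
    """A value lies outside its documented domain."""


class SampleSheetError(TwinvarError):
    """Sample sheet violates the twin-pair design contract."""


def _check_unique(labels: Iterable, what: str) -> None:
    labels = pd.Index(labels)
    if labels.has_duplicates:
        dups = labels[labels.duplicated()].unique().tolist()
        raise MatrixFormatError(f"duplicate {what}: {dups[:5]}")


def _locate_out_of_range(values: pd.DataFrame, lo: float, hi: float) -> tuple | None:
    arr = values.to_numpy(dtype=float)
    bad = (arr < lo) | (arr > hi)  # NaN compares False: missing allowed
    if bad.any():
        i, j = np.argwhere(bad)[0]
        return values.index[i], values.columns[j], arr[i, j]
    return None


@dataclasses.dataclass
class BetaMatrix:
    """Probe-by-sample methylation fractions.

    ``values`` is a DataFrame indexed by probe id with sample ids as columns.
    Missing entries (NaN) are permitted until the completeness filter runs.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        hit = _locate_out_of_range(self.values, 0.0, 1.0)
        if hit is not None:
            probe, sample, v = hit
            raise ValueRangeError(
                f"beta value {v!r} outside [0, 1] at probe {probe!r}, sample {sample!r}"
            )

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_probes(self, probes: Sequence) -> "BetaMatrix":
        return BetaMatrix(self.values.loc[list(probes)])

    def subset_samples(self, samples: Sequence) -> "BetaMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"unknown sample ids: {missing[:5]}")
        return BetaMatrix(self.values[list(samples)])


@dataclasses.dataclass
class DetectionPMatrix:
    """Per-call detection p-values, same layout as the companion BetaMatrix."""

    values: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "probe ids")
        _check_unique(self.values.columns, "sample ids")
        hit = _locate_out_of_range(self.values, 0.0, 1.0)
        if hit is not None:
            probe, sample, v = hit
            raise ValueRangeError(
                f"detection p {v!r} outside [0, 1] at probe {probe!r}, sample {sample!r}"
            )

    def matches(self, beta: BetaMatrix) -> bool:
        return self.values.index.equals(beta.probe_ids) and self.values.columns.equals(
            beta.sample_ids
        )


ROLES = ("twin_a", "twin_b")
STATUSES = ("affected", "healthy")
PAIR_CLASSES = ("discordant", "concordant", "healthy")
SEXES = ("female", "male", "unknown")


@dataclasses.dataclass
class SampleSheet:
    """Per-sample metadata for a monozygotic-twin cohort.

    Each pair id occurs exactly twice (roles ``twin_a``/``twin_b``).  The
    pair class is implied by the co-twins' affection statuses: discordant
    pairs have one affected member, concordant pairs two, healthy pairs none.
    """

    table: pd.DataFrame  # columns: sample_id, pair_id, role, status, pair_class, sex

    REQUIRED = ("sample_id", "pair_id", "role", "status")

    def __post_init__(self) -> None:
        t = self.table
        for col in self.REQUIRED:
            if col not in t.columns:
                raise SampleSheetError(f"sample sheet missing column {col!r}")
        if "sex" not in t.columns:
            t = t.assign(sex="unknown")
        _check_unique(t["sample_id"], "sample ids")
        bad_status = set(t["status"]) - set(STATUSES)
        if bad_status:
            raise SampleSheetError(f"unknown status values: {sorted(bad_status)}")
        bad_role = set(t["role"]) - set(ROLES)
        if bad_role:
            raise SampleSheetError(f"unknown role values: {sorted(bad_role)}")

        derived = {}
        for pair_id, grp in t.groupby("pair_id", sort=False):
            if len(grp) != 2 or set(grp["role"]) != set(ROLES):
                raise SampleSheetError(
                    f"pair {pair_id!r} must have exactly two members with distinct roles"
                )
            n_affected = (grp["status"] == "affected").sum()
            derived[pair_id] = PAIR_CLASSES[{1: 0, 2: 1, 0: 2}[n_affected]]

        if "pair_class" in t.columns and t["pair_class"].notna().all():
            for pair_id, grp in t.groupby("pair_id", sort=False):
                stated = set(grp["pair_class"])
                if stated != {derived[pair_id]}:
                    raise SampleSheetError(
                        f"pair {pair_id!r} stated class {sorted(stated)} contradicts "
                        f"statuses (implied {derived[pair_id]!r})"
                    )
        else:
            t = t.assign(pair_class=t["pair_id"].map(derived))
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> pd.Index:
        return pd.Index(self.table["sample_id"])

    def samples_where(self, **conditions) -> list:
        mask = pd.Series(True, index=self.table.index)
        for col, val in conditions.items():
            mask &= self.table[col] == val
        return self.table.loc[mask, "sample_id"].tolist()

    def discordant_samples(self) -> list:
        """All individuals belonging to diagnosis-discordant pairs."""
        return self.samples_where(pair_class="discordant")

    def pair_class_counts(self) -> dict:
        pairs = self.table.drop_duplicates("pair_id")
        return pairs["pair_class"].value_counts().to_dict()

    def pairs_of_class(self, pair_class: str) -> list:
        pairs = self.table.drop_duplicates("pair_id")
        return pairs.loc[pairs["pair_class"] == pair_class, "pair_id"].tolist()


@dataclasses.dataclass
class ProbeAnnotation:
    """Probe genomic annotation: chromosome, 1-based position, gene context."""

    table: pd.DataFrame  # columns: probe_id, chromosome, position, gene_name, gene_region

    def __post_init__(self) -> None:
        t = self.table
        for col in ("probe_id", "chromosome", "position"):
            if col not in t.columns:
                raise MatrixFormatError(f"annotation missing column {col!r}")
        for col in ("gene_name", "gene_region"):
            if col not in t.columns:
                t = t.assign(**{col: ""})
        _check_unique(t["probe_id"], "probe ids")
        t = t.assign(
            chromosome=t["chromosome"].astype(str).str.removeprefix("chr"),
            gene_name=t["gene_name"].fillna(""),
            gene_region=t["gene_region"].fillna(""),
        )
        bad = set(t["chromosome"]) - set(ALLOWED_CHROMOSOMES)
        if bad:
            raise ValueRangeError(f"unknown chromosomes: {sorted(bad)[:5]}")
        if (t["position"] < 1).any():
            raise ValueRangeError("positions must be >= 1 (1-based coordinates)")
        self.table = t.set_index("probe_id", drop=False)

    def chromosomes_for(self, probes: Sequence) -> pd.Series:
        return self.table["chromosome"].reindex(probes)


def compute_beta_from_intensities(M: float, U: float, alpha: float = 0.0) -> float:
    """Methylation fraction from fluorescence intensities: ``M / (M + U + alpha)``.

    ``M`` and ``U`` are the methylated and unmethylated channel intensities
    and ``alpha`` a non-negative offset stabilising low-intensity calls.
    """
    if M < 0 or U < 0 or alpha < 0:
        raise ValueRangeError("intensities and offset must be non-negative")
    denom = M + U + alpha
    if denom == 0:
        raise ValueRangeError("undefined beta: M + U + alpha is zero")
    return M / denom


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "," if str(path).endswith(".csv") else "\t"


def _read_matrix(path: str | Path, delimiter: str | None) -> pd.DataFrame:
    sep = _infer_delimiter(path, delimiter)
    df = pd.read_csv(
        path, sep=sep, index_col=0, na_values=list(MISSING_TOKENS),
        keep_default_na=False,
    )
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise MatrixFormatError(f"{path}: non-numeric cell ({exc})") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def read_beta_matrix(path: str | Path, delimiter: str | None = None) -> BetaMatrix:
    """Read a probe-by-sample beta matrix from delimited text.

    The first column holds probe ids and the header row sample ids.  Empty
    cells and ``NA`` become missing entries.
    """
    return BetaMatrix(_read_matrix(path, delimiter))


def read_detection_p(path: str | Path, delimiter: str | None = None) -> DetectionPMatrix:
    return DetectionPMatrix(_read_matrix(path, delimiter))


def read_sample_sheet(path: str | Path) -> SampleSheet:
    df = pd.read_csv(path, dtype=str, na_values=list(MISSING_TOKENS), keep_default_na=False)
    return SampleSheet(df)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    df = pd.read_csv(path, na_values=list(MISSING_TOKENS), keep_default_na=False)
    df["position"] = df["position"].astype(int)
    return ProbeAnnotation(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    beta.values.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def write_detection_p(detp: DetectionPMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    detp.values.to_csv(path, sep=sep, na_rep="NA", index_label="probe_id")


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def write_results(
    stats: pd.DataFrame,
    annotation: ProbeAnnotation | None,
    path: str | Path,
) -> pd.DataFrame:
    """Write the per-probe scan table, one row per probe, sorted by (q, p).

    ``stats`` is the frame produced by :func:`twinvar.scan.scan`; annotation
    columns are joined when available and left empty otherwise.
    """
    out = stats.copy()
    if annotation is not None:
        ann = annotation.table[["chromosome", "position", "gene_name", "gene_region"]]
        out = out.join(ann, on="probe_id")
    for col in ("chromosome", "position", "gene_name", "gene_region"):
        if col not in out.columns:
            out[col] = ""
    out = out.rename(columns={"outlier": "outlier_flag"})
    out = out[RESULT_COLUMNS].sort_values(["q", "p", "probe_id"], kind="mergesort")
    try:
        out.to_csv(path, sep="\t", index=False, na_rep="NA")
    except OSError as exc:
        raise TwinvarError(f"cannot write results to {path}: {exc}") from exc
    return out


def write_bed(
    probes: Sequence, annotation: ProbeAnnotation, path: str | Path, name_prefix: str = ""
) -> None:
    """Export probe loci as BED (0-based half-open single-base intervals).

    Internal coordinates are 1-based; each probe becomes the interval
    ``[position - 1, position)`` on its chromosome.
    """
    rows = []
    ann = annotation.table
    for probe in probes:
        if probe not in ann.index:
            raise KeyError(f"probe {probe!r} missing from annotation")
        rec = ann.loc[probe]
        pos = int(rec["position"])
        rows.append((f"chr{rec['chromosome']}", pos - 1, pos, f"{name_prefix}{probe}"))
    try:
        with open(path, "w") as fh:
            for chrom, start, end, name in rows:
                fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
    except OSError as exc:
        raise TwinvarError(f"cannot write BED to {path}: {exc}") from exc
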