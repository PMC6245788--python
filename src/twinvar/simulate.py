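"""Synthetic monozygotic-twin methylation cohorts with ground truth.

The generator emulates the statistical structure a discordant-twin variance
scan has to cope with:

* per-probe baseline means drawn from a three-component mixture
  (hypo- / intermediate / hyper-methylated, centers 0.05 / 0.50 / 0.92) —
  the bimodal-with-shoulder shape typical of genome-wide CpG panels;
* a shared within-pair deviation on the logit scale — MZ co-twins carry the
  same genetic background and early environment, so their baseline levels
  move together;
* per-sample leukocyte composition drawn from a Dirichlet, with a subset of
  probes whose betas track one cell type's proportion (the confounding the
  average-cell adjustment exists to remove);
* independent per-call measurement noise on the beta scale; and
* rare large single-co-twin deviations — the epigenetic outliers — injected
  into one designated affected co-twin per outlier probe, with the sign
  pointing away from the nearer boundary so the full shift is realisable
  in [0, 1].

Everything is reproducible from the seed, and the injected effects are
recorded in a :class:`TwinTruth` manifest.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .cells import CellReference
from .io import (
    BetaMatrix,
    DetectionPMatrix,
    ProbeAnnotation,
    SampleSheet,
    TwinvarError,
)

__all__ = ["SimulationConfig", "TwinTruth", "Cohort", "generate_cohort", "generate_cell_reference", "write_cohort"]

#: typical whole-blood mean fractions for (B, CD4T, CD8T, Mono, NK, Gran)
BLOOD_PROPORTIONS = (0.06, 0.16, 0.09, 0.08, 0.06, 0.55)
CELL_TYPE_NAMES = ("Bcell", "CD4T", "CD8T", "Mono", "NK", "Gran")


class ConfigError(TwinvarError):
    """Impossible or inconsistent simulation configuration."""


@dataclasses.dataclass
class SimulationConfig:
    """Knobs of the cohort generator; defaults mirror the study design."""

    n_probes: int = 10_000
    n_discordant: int = 6
    n_concordant: int = 4
    n_healthy: int = 7
    # baseline three-component mixture over probe means
    baseline_centers: tuple = (0.05, 0.50, 0.92)
    baseline_weights: tuple = (0.45, 0.20, 0.35)
    baseline_logit_sd: float = 0.4
    pair_effect_sd: float = 0.25  # logit scale, shared by both co-twins
    noise_sd: float = 0.005  # beta scale, per call
    n_outlier_probes: int = 20
    outlier_delta: float = 0.3  # beta-scale single-co-twin shift
    # composition confounding
    n_celltypes: int = 6
    dirichlet_concentration: float = 60.0
    affected_dirichlet_scale: float = 1.0  # < 1: affected blood counts more variable
    n_composition_probes: int = 200
    composition_effect: float = 0.15  # beta shift per unit proportion deviation
    # nuisance structure
    frac_sex_chromosome: float = 0.02
    missing_rate: float = 0.001
    detection_fail_rate: float = 0.001
    seed: int = 0

    def validate(self) -> None:
        if self.n_outlier_probes > self.n_probes:
            raise ConfigError("more outlier probes than probes")
        if self.n_composition_probes > self.n_probes:
            raise ConfigError("more composition probes than probes")
        if self.n_outlier_probes and self.n_discordant < 1:
            raise ConfigError("outlier injection needs at least one discordant pair")
        if not np.isclose(sum(self.baseline_weights), 1.0):
            raise ConfigError("baseline mixture weights must sum to 1")
        if not 2 <= self.n_celltypes <= len(BLOOD_PROPORTIONS):
            raise ConfigError(
                f"n_celltypes must lie in [2, {len(BLOOD_PROPORTIONS)}]"
            )
        for name in ("noise_sd", "pair_effect_sd", "outlier_delta"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")


@dataclasses.dataclass
class TwinTruth:
    """Ground-truth manifest: exactly the injected effects, nothing else."""

    outlier_probe_ids: list
    carriers: dict  # probe id -> affected sample id carrying the shift
    deltas: dict  # probe id -> signed beta-scale shift
    composition_probe_ids: list
    composition_effects: dict  # probe id -> (cell type, effect)
    seed: int
    n_clipped: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "TwinTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclasses.dataclass
class Cohort:
    beta: BetaMatrix
    sheet: SampleSheet
    detection_p: DetectionPMatrix
    truth: TwinTruth
    annotation: ProbeAnnotation
    proportions: pd.DataFrame  # true per-sample cell proportions (samples x K)


def _build_sheet(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    rows = []
    spec = [
        ("D", config.n_discordant, ("affected", "healthy")),
        ("C", config.n_concordant, ("affected", "affected")),
        ("H", config.n_healthy, ("healthy", "healthy")),
    ]
    for prefix, n_pairs, statuses in spec:
        for k in range(1, n_pairs + 1):
            pair = f"{prefix}{k}"
            sex = rng.choice(["female", "male"])
            for role, status in zip(("twin_a", "twin_b"), statuses):
                rows.append(
                    {
                        "sample_id": f"{pair}_{role[-1]}",
                        "pair_id": pair,
                        "role": role,
                        "status": status,
                        "sex": sex,
                    }
                )
    return pd.DataFrame(rows)


def generate_cell_reference(
    K: int = 6,
    n_reference_probes: int = 100,
    separation: float = 0.5,
    seed: int = 0,
) -> CellReference:
    """Synthetic reference beta matrix with identifiable, well-separated columns.

    The first K probes form a scaled identity block (one discriminating probe
    per type at ``0.5 + separation/2`` against ``0.5 - separation/2``), which
    guarantees full column rank and a pairwise column distance of at least
    ``separation * sqrt(2)``; remaining probes carry independent per-type
    levels.  This stands in for an experimentally sorted-cell reference panel
    and is labelled synthetic throughout.
    """
    if K < 2:
        raise ConfigError("reference needs at least 2 cell types")
    if n_reference_probes < K:
        raise ConfigError("need at least K reference probes")
    if separation < 0.05 or separation > 0.9:
        raise ConfigError("separation must lie in [0.05, 0.9] for an identifiable reference")
    rng = np.random.default_rng(seed)
    hi, lo = 0.5 + separation / 2, 0.5 - separation / 2
    R = np.full((n_reference_probes, K), lo)
    R[:K, :K][np.diag_indices(K)] = hi
    if n_reference_probes > K:
        R[K:] = rng.uniform(0.05, 0.95, size=(n_reference_probes - K, K))
    types = list(CELL_TYPE_NAMES[:K]) + [f"type{j}" for j in range(len(CELL_TYPE_NAMES), K)]
    probes = [f"refcg{j:05d}" for j in range(n_reference_probes)]
    return CellReference(pd.DataFrame(R, index=probes, columns=types))


def generate_cohort(
    config: SimulationConfig, reference: CellReference | None = None
) -> Cohort:
    """Generate a full synthetic cohort (betas, sheet, detection p, truth).

    When a :class:`CellReference` is supplied its probes are embedded in the
    matrix with betas equal to the reference-weighted mixture plus noise, so
    reference-based deconvolution can be exercised end to end.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    sheet_df = _build_sheet(config, rng)
    sheet = SampleSheet(sheet_df)
    samples = sheet.sample_ids.tolist()
    n_samples = len(samples)
    pair_ids = sheet_df["pair_id"].unique().tolist()
    pair_index = sheet_df["pair_id"].map({p: i for i, p in enumerate(pair_ids)}).to_numpy()

    P = config.n_probes
    probes = [f"cg{j:08d}" for j in range(P)]

    # baseline probe means from the three-component mixture, on the logit scale
    comp = rng.choice(len(config.baseline_centers), size=P, p=config.baseline_weights)
    mu_logit = logit(np.asarray(config.baseline_centers)[comp]) + rng.normal(
        0.0, config.baseline_logit_sd, size=P
    )

    # shared within-pair deviation (MZ identity): probes x pairs, expanded to samples
    pair_dev = rng.normal(0.0, config.pair_effect_sd, size=(P, len(pair_ids)))
    beta = expit(mu_logit[:, None] + pair_dev[:, pair_index])

    # per-sample cell composition
    K = config.n_celltypes
    base = np.asarray(BLOOD_PROPORTIONS[:K], dtype=float)
    base = base / base.sum()
    alpha = base * config.dirichlet_concentration
    W = np.empty((n_samples, K))
    affected_mask = (sheet_df["status"] == "affected").to_numpy()
    for i in range(n_samples):
        a = alpha * (config.affected_dirichlet_scale if affected_mask[i] else 1.0)
        W[i] = rng.dirichlet(a)

    # composition-tracking probes
    comp_idx = rng.choice(P, size=config.n_composition_probes, replace=False)
    comp_types = rng.integers(0, K, size=config.n_composition_probes)
    comp_signs = rng.choice([-1.0, 1.0], size=config.n_composition_probes)
    composition_effects = {}
    for j, k, s in zip(comp_idx, comp_types, comp_signs):
        effect = float(s * config.composition_effect)
        beta[j] += effect * (W[:, k] - base[k])
        composition_effects[probes[j]] = [CELL_TYPE_NAMES[k], effect]

    beta += rng.normal(0.0, config.noise_sd, size=beta.shape)

    # inject single-co-twin outliers into affected discordant co-twins
    eligible = np.setdiff1d(np.arange(P), comp_idx)
    out_idx = rng.choice(eligible, size=config.n_outlier_probes, replace=False)
    affected_disc = sheet.samples_where(pair_class="discordant", status="affected")
    col_of = {s: i for i, s in enumerate(samples)}
    carriers, deltas = {}, {}
    for j in out_idx:
        carrier = affected_disc[rng.integers(0, len(affected_disc))]
        sign = 1.0 if expit(mu_logit[j]) <= 0.5 else -1.0
        beta[j, col_of[carrier]] += sign * config.outlier_delta
        carriers[probes[j]] = carrier
        deltas[probes[j]] = float(sign * config.outlier_delta)

    n_clipped = int(((beta < 0) | (beta > 1)).sum())
    beta = np.clip(beta, 0.0, 1.0)

    # embed reference probes: pure mixtures of the reference columns
    all_probes = list(probes)
    if reference is not None:
        if reference.values.shape[1] != K:
            raise ConfigError("reference cell-type count differs from simulated composition")
        R = reference.values.to_numpy(dtype=float)
        ref_beta = np.clip(R @ W.T + rng.normal(0.0, config.noise_sd, (R.shape[0], n_samples)), 0, 1)
        beta = np.vstack([beta, ref_beta])
        all_probes += reference.probe_ids.tolist()

    # missingness (outlier probes exempt so truth survives the funnel)
    if config.missing_rate > 0:
        miss = rng.random(beta.shape) < config.missing_rate
        miss[out_idx] = False
        beta = np.where(miss, np.nan, beta)

    # detection p-values: near zero, with a small failure fraction
    detp = rng.uniform(0.0, 1e-6, size=beta.shape)
    if config.detection_fail_rate > 0:
        fails = rng.random(beta.shape) < config.detection_fail_rate
        fails[out_idx] = False
        detp = np.where(fails, rng.uniform(2e-4, 1e-2, size=beta.shape), detp)

    # annotation: sex-chromosome fraction exercises the autosome filter;
    # injected effects stay autosomal
    n_total = len(all_probes)
    chroms = rng.choice([str(c) for c in range(1, 23)], size=n_total)
    sex_mask = rng.random(n_total) < config.frac_sex_chromosome
    protected = np.zeros(n_total, dtype=bool)
    protected[out_idx] = True
    protected[comp_idx] = True
    if reference is not None:
        protected[P:] = True
    sex_mask &= ~protected
    chroms[sex_mask] = rng.choice(["X", "Y"], size=int(sex_mask.sum()))
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "probe_id": all_probes,
                "chromosome": chroms,
                "position": rng.integers(10_000, 200_000_000, size=n_total),
                "gene_name": "",
                "gene_region": "",
            }
        )
    )

    truth = TwinTruth(
        outlier_probe_ids=[probes[j] for j in sorted(out_idx)],
        carriers=carriers,
        deltas=deltas,
        composition_probe_ids=[probes[j] for j in sorted(comp_idx)],
        composition_effects=composition_effects,
        seed=config.seed,
        n_clipped=n_clipped,
    )
    values = pd.DataFrame(beta, index=all_probes, columns=samples)
    return Cohort(
        beta=BetaMatrix(values),
        sheet=sheet,
        detection_p=DetectionPMatrix(pd.DataFrame(detp, index=all_probes, columns=samples)),
        truth=truth,
        annotation=annotation,
        proportions=pd.DataFrame(W, index=samples, columns=[CELL_TYPE_NAMES[k] for k in range(K)]),
    )


def write_cohort(cohort: Cohort, outdir: str | Path) -> dict:
    """Write the cohort in the formats the pipeline readers consume."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "beta": outdir / "beta.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "sample_sheet": outdir / "sample_sheet.csv",
        "annotation": outdir / "annotation.csv",
        "truth": outdir / "truth.json",
    }
    cohort.beta.values.to_csv(paths["beta"], sep="\t", na_rep="NA", index_label="probe_id")
    cohort.detection_p.values.to_csv(
        paths["detection_p"], sep="\t", na_rep="NA", index_label="probe_id"
    )
    cohort.sheet.table.to_csv(paths["sample_sheet"], index=False)
    cohort.annotation.table.to_csv(paths["annotation"], index=False)
    cohort.truth.to_json(paths["truth"])
    return {k: str(v) for k, v in paths.items()}
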