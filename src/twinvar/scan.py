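"""Genome-wide one-tailed variance scan for epigenetic outliers.

At each CpG probe the sample variance of the affected co-twins from the
diagnosis-discordant pairs is compared with that of their healthy co-twins
by the variance-ratio statistic

    F = S_affected^2 / S_healthy^2,

which follows an F distribution with (n-1, m-1) degrees of freedom under
the null of equal variances.  The test is one-tailed in the upper tail: it
detects only *excess* variance in the affected group, because a rare large
single-co-twin deviation (an epigenetic outlier) inflates the group
variance without moving its mean.  Multiplicity is handled with Storey
q-values, and significant probes must additionally show an affected-group
beta range exceeding the healthy-group range by more than a percentage-point
threshold (default 10 pp) — differences that size are reliably measured by
the array and plausibly functional.

The affected group is always the numerator: increased variance in healthy
samples is a known feature of population methylation data and must not
produce hits.  Co-twins are treated as independent samples in the F
statistic; the pairing makes the test conservative, never anticonservative.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
import pandas as pd
from scipy import interpolate
from scipy import stats as sps

from .io import BetaMatrix, SampleSheet, TwinvarError, ValueRangeError

logger = logging.getLogger(__name__)

__all__ = [
    "FTestResult",
    "ScanResult",
    "variance_f_test",
    "storey_qvalues",
    "apply_outlier_rule",
    "beta_range",
    "scan",
    "identify_outlier_cotwin",
]

LAMBDA_GRID = np.arange(0.05, 0.951, 0.05)


@dataclasses.dataclass
class FTestResult:
    F: float
    df1: int
    df2: int
    p: float
    degenerate: bool = False  # both variances zero: F undefined


@dataclasses.dataclass
class ScanResult:
    """Per-probe statistics plus the funnel bookkeeping of a scan."""

    stats: pd.DataFrame
    pi0: float
    funnel: dict
    n_zero_denominator: int = 0
    n_degenerate: int = 0

    def outlier_probes(self) -> list:
        return self.stats.loc[self.stats["outlier"], "probe_id"].tolist()


def _group_array(values) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueRangeError("each group needs at least 2 values")
    if np.isnan(arr).any():
        raise ValueRangeError("missing values in group (run the completeness filter first)")
    if (arr < 0).any() or (arr > 1).any():
        raise ValueRangeError("beta values must lie in [0, 1]")
    return arr


def variance_f_test(affected, healthy) -> FTestResult:
    """One-tailed F-test for excess variance in the affected group.

    Returns the variance ratio ``F = S_affected^2 / S_healthy^2``, its
    degrees of freedom ``(n-1, m-1)`` and the upper-tail p-value
    ``P(F_{n-1,m-1} >= F)``.

    Zero healthy variance with positive affected variance yields
    ``F = inf, p = 0``; two zero variances yield the degenerate result
    ``p = 1`` with ``F`` undefined (NaN) — a genome-scale scan must not
    abort on constant probes.
    """
    x = _group_array(affected)
    y = _group_array(healthy)
    df1, df2 = x.size - 1, y.size - 1
    sx2 = x.var(ddof=1)
    sy2 = y.var(ddof=1)
    if sy2 == 0.0:
        if sx2 == 0.0:
            return FTestResult(F=float("nan"), df1=df1, df2=df2, p=1.0, degenerate=True)
        return FTestResult(F=float("inf"), df1=df1, df2=df2, p=0.0)
    F = sx2 / sy2
    p = float(sps.f.sf(F, df1, df2))
    return FTestResult(F=float(F), df1=df1, df2=df2, p=p)


def storey_qvalues(pvalues, pi0: float | None = None) -> tuple[np.ndarray, float]:
    """FDR q-values with a smoother-based estimate of the null proportion.

    pi0 is estimated from the shape of the p-value histogram: for each
    lambda on the grid {0.05, 0.10, ..., 0.95}, pi0(lambda) =
    #{p > lambda} / (m (1 - lambda)); a cubic smoothing spline through these
    points is evaluated at the largest lambda and truncated to (0, 1].
    q-values are the step-up transform q_(i) = min_{j >= i} pi0 m p_(j) / j,
    returned in the original order.  Forcing ``pi0=1`` reproduces
    Benjamini-Hochberg adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size < 1:
        raise ValueRangeError("p-value vector must be 1-D and non-empty")
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueRangeError("p-values must lie in [0, 1]")
    m = p.size

    if pi0 is None:
        if m < LAMBDA_GRID.size:
            warnings.warn(
                "too few p-values to estimate pi0; falling back to pi0 = 1",
                stacklevel=2,
            )
            pi0 = 1.0
        else:
            counts = np.array([(p > lam).mean() / (1.0 - lam) for lam in LAMBDA_GRID])
            spline = interpolate.UnivariateSpline(LAMBDA_GRID, counts, k=3)
            pi0 = float(spline(LAMBDA_GRID[-1]))
            if not np.isfinite(pi0) or pi0 <= 0:
                warnings.warn(
                    "pi0 smoother returned a non-positive estimate; "
                    "falling back to pi0 = 1",
                    stacklevel=2,
                )
                pi0 = 1.0
            pi0 = min(pi0, 1.0)
    elif not (0 < pi0 <= 1):
        raise ValueRangeError("pi0 must lie in (0, 1]")

    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def apply_outlier_rule(
    q, range_diff_pp, q_threshold: float = 0.05, range_threshold_pp: float = 10.0
) -> np.ndarray:
    """The two-part outlier call: ``q <= q_threshold`` and a strictly
    greater-than range-difference requirement in percentage points."""
    q = np.asarray(q, dtype=float)
    range_diff_pp = np.asarray(range_diff_pp, dtype=float)
    return (q <= q_threshold) & (range_diff_pp > range_threshold_pp)


def beta_range(values) -> float:
    """Spread of a group's betas in percent: ``(max - min) * 100``."""
    arr = np.asarray(values, dtype=float)
    if arr.size < 1:
        raise ValueRangeError("beta_range needs at least one value")
    return float((np.nanmax(arr) - np.nanmin(arr)) * 100.0)


def _scan_groups(sheet: SampleSheet) -> tuple[list, list]:
    affected = sheet.samples_where(pair_class="discordant", status="affected")
    healthy = sheet.samples_where(pair_class="discordant", status="healthy")
    if len(affected) < 2 or len(healthy) < 2:
        raise TwinvarError(
            "scan needs at least 2 affected and 2 healthy discordant-pair individuals"
        )
    return affected, healthy


def scan(
    beta: BetaMatrix,
    sheet: SampleSheet,
    q_threshold: float = 0.05,
    range_threshold_pp: float = 10.0,
) -> ScanResult:
    """Run the per-probe variance scan over all probes in ``beta``.

    A probe is called an outlier locus when ``q <= q_threshold`` *and* the
    affected-minus-healthy range difference strictly exceeds
    ``range_threshold_pp`` percentage points.  The funnel (tested ->
    significant -> range-filtered) is recorded in the result.
    """
    affected_ids, healthy_ids = _scan_groups(sheet)
    X = beta.values[affected_ids].to_numpy(dtype=float)  # probes x n
    Y = beta.values[healthy_ids].to_numpy(dtype=float)  # probes x m
    if np.isnan(X).any() or np.isnan(Y).any():
        raise TwinvarError(
            "missing values among discordant-pair samples; run filter_complete first"
        )
    n, m = X.shape[1], Y.shape[1]
    df1, df2 = n - 1, m - 1

    sx2 = X.var(axis=1, ddof=1)
    sy2 = Y.var(axis=1, ddof=1)
    zero_den = sy2 == 0.0
    degenerate = zero_den & (sx2 == 0.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        F = sx2 / sy2
    F[zero_den & ~degenerate] = np.inf
    F[degenerate] = np.nan

    p = np.ones(beta.shape[0])
    ok = ~zero_den
    p[ok] = sps.f.sf(F[ok], df1, df2)
    p[zero_den & ~degenerate] = 0.0
    p[degenerate] = 1.0

    if int(zero_den.sum()):
        logger.info(
            "scan: %d probes with zero healthy variance (%d fully degenerate)",
            int(zero_den.sum()),
            int(degenerate.sum()),
        )

    q, pi0 = storey_qvalues(p)

    aff_range = (X.max(axis=1) - X.min(axis=1)) * 100.0
    hea_range = (Y.max(axis=1) - Y.min(axis=1)) * 100.0
    range_diff = aff_range - hea_range
    mean_beta = np.hstack([X, Y]).mean(axis=1)

    significant = q <= q_threshold
    outlier = apply_outlier_rule(q, range_diff, q_threshold, range_threshold_pp)

    stats = pd.DataFrame(
        {
            "probe_id": beta.probe_ids,
            "F": F,
            "df1": df1,
            "df2": df2,
            "p": p,
            "q": q,
            "affected_range_pct": aff_range,
            "healthy_range_pct": hea_range,
            "range_diff_pp": range_diff,
            "mean_beta": mean_beta,
            "outlier": outlier,
        }
    ).reset_index(drop=True)

    funnel = {
        "n_tested": int(beta.shape[0]),
        "n_significant": int(significant.sum()),
        "n_significant_range_filtered_out": int((significant & ~outlier).sum()),
        "n_outliers": int(outlier.sum()),
    }
    logger.info(
        "scan funnel: %(n_tested)d tested -> %(n_significant)d significant "
        "-> %(n_outliers)d past range filter",
        funnel,
    )
    return ScanResult(
        stats=stats,
        pi0=pi0,
        funnel=funnel,
        n_zero_denominator=int(zero_den.sum()),
        n_degenerate=int(degenerate.sum()),
    )


def identify_outlier_cotwin(
    probe_values: pd.Series, sheet: SampleSheet
) -> tuple[str, str, float, bool]:
    """Attribute an outlier probe to the affected co-twin driving it.

    ``probe_values`` maps discordant-pair sample ids to betas at one probe.
    Returns ``(pair_id, sample_id, deviation_pp, tied)`` for the affected
    co-twin with the largest absolute deviation from the median of all
    discordant-pair samples; ties resolve to the lexicographically smallest
    sample id and are flagged.
    """
    disc = sheet.discordant_samples()
    vals = probe_values.reindex(disc).astype(float)
    center = float(np.median(vals))
    affected = sheet.samples_where(pair_class="discordant", status="affected")
    dev = (vals.reindex(affected) - center).abs() * 100.0
    best = dev.max()
    winners = sorted(dev.index[dev == best])
    sample_id = winners[0]
    pair_id = sheet.table.set_index("sample_id").loc[sample_id, "pair_id"]
    return str(pair_id), str(sample_id), float(dev[sample_id]), len(winners) > 1
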