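"""Reference-based cell-type deconvolution and "average cell" adjustment.

Whole-blood methylation is a mixture over leukocyte subtypes, so
between-sample differences in cell composition masquerade as methylation
differences.  Following the reference-based deconvolution idea, per-sample
proportions of K cell types are estimated by constrained least squares
against a reference beta matrix over discriminating probes, and each probe
is then regressed on the (centered) proportions; the adjusted value is the
fit at the cohort-mean composition plus the residual — the beta value of an
"average cell".

Proportions are non-negative and sum to at most one; the remainder absorbs
unmodelled types (e.g. granulocyte contamination in a six-type mononuclear
reference).
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .io import BetaMatrix, TwinvarError, ValueRangeError, _check_unique

__all__ = [
    "CellReference",
    "CellProportions",
    "AdjustmentResult",
    "InsufficientReferenceError",
    "ConditioningError",
    "estimate_cell_proportions",
    "adjust_for_cells",
]

# weight on the simplex-constraint row of the augmented NNLS system; large
# enough that the sum constraint binds to ~1e-10 while leaving the fit
# numerically well scaled
_CONSTRAINT_WEIGHT = 1e6

MAD_SCALE = 1.4826  # MAD -> s.d. under normality


class InsufficientReferenceError(TwinvarError):
    """Too few reference probes overlap the cohort matrix."""


class ConditioningError(TwinvarError):
    """Reference matrix is rank-deficient on the shared probes."""


@dataclasses.dataclass
class CellReference:
    """Reference methylation profiles: discriminating probes x K cell types."""

    values: pd.DataFrame  # index: probe ids, columns: cell-type labels

    def __post_init__(self) -> None:
        if self.values.shape[1] < 2:
            raise ValueRangeError("cell reference needs at least 2 cell types")
        _check_unique(self.values.index, "reference probe ids")
        _check_unique(self.values.columns, "cell-type labels")
        arr = self.values.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
            raise ValueRangeError("reference betas must be finite and in [0, 1]")

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns

    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index


@dataclasses.dataclass
class CellProportions:
    """Estimated per-sample cell-type proportions (samples x types)."""

    values: pd.DataFrame

    SUM_TOLERANCE = 1e-6

    def __post_init__(self) -> None:
        arr = self.values.to_numpy(dtype=float)
        if (arr < -self.SUM_TOLERANCE).any():
            raise ValueRangeError("proportions must be non-negative")
        if (arr.sum(axis=1) > 1 + self.SUM_TOLERANCE).any():
            raise ValueRangeError("per-sample proportions must sum to <= 1")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cell_types(self) -> pd.Index:
        return self.values.columns


@dataclasses.dataclass
class AdjustmentResult:
    adjusted: BetaMatrix
    n_clipped: int


def _solve_sample(R: np.ndarray, b: np.ndarray, constraint: str) -> np.ndarray:
    """Constrained least squares for one sample's proportions.

    min ||R w - b||^2  s.t.  w >= 0 and sum(w) <= 1 (or == 1).

    Encoded as NNLS on an augmented system: a heavily weighted row enforces
    sum(w) + s = 1 with a non-negative slack s (dropped in equality mode).
    """
    n, K = R.shape
    scale = _CONSTRAINT_WEIGHT
    if constraint == "le1":
        A = np.zeros((n + 1, K + 1))
        A[:n, :K] = R
        A[n, :] = scale
        t = np.concatenate([b, [scale]])
        w, _ = nnls(A, t)
        return w[:K]
    if constraint == "eq1":
        A = np.vstack([R, np.full((1, K), scale)])
        t = np.concatenate([b, [scale]])
        w, _ = nnls(A, t)
        return w
    raise ValueError(f"unknown constraint mode {constraint!r}")


def estimate_cell_proportions(
    beta: BetaMatrix, reference: CellReference, constraint: str = "le1"
) -> CellProportions:
    """Estimate cell-type proportions for every sample in ``beta``.

    For each sample the proportions minimise the squared deviation between
    the sample's betas at the shared reference probes and the
    reference-weighted mixture, subject to non-negativity and a unit-sum
    bound (``constraint="le1"``, default) or equality (``"eq1"``).
    """
    shared = reference.probe_ids.intersection(beta.probe_ids)
    if len(shared) < len(reference.probe_ids):
        warnings.warn(
            f"{len(reference.probe_ids) - len(shared)} reference probes absent "
            "from the beta matrix; estimating on the overlap",
            stacklevel=2,
        )
    if len(shared) < 2:
        raise InsufficientReferenceError(
            f"only {len(shared)} reference probes shared with the beta matrix"
        )
    R_full = reference.values.loc[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R_full) < reference.values.shape[1]:
        raise ConditioningError("reference matrix is rank-deficient on shared probes")
    B = beta.values.loc[shared].to_numpy(dtype=float)

    out = np.empty((beta.shape[1], reference.values.shape[1]))
    for j, sample in enumerate(beta.sample_ids):
        b = B[:, j]
        ok = ~np.isnan(b)
        if ok.sum() < 2:
            raise InsufficientReferenceError(
                f"sample {sample!r} has {int(ok.sum())} non-missing reference probes"
            )
        out[j] = _solve_sample(R_full[ok], b[ok], constraint)
    out = np.clip(out, 0.0, None)
    return CellProportions(
        pd.DataFrame(out, index=beta.sample_ids.copy(), columns=reference.cell_types.copy())
    )


# singular values of the centered proportion matrix below this absolute
# cutoff carry no composition information (proportions are O(1) quantities)
_SV_CUTOFF = 1e-10


def _composition_fit(Xc: np.ndarray, B: np.ndarray, ridge: float, project_onto=None):
    """Composition-explained part of each probe's betas (probes x samples).

    Least-squares (optionally ridge-shrunk) fit of B's rows on the centered
    proportion columns via SVD, with an absolute singular-value cutoff so a
    constant or collinear composition contributes exactly nothing.  When
    ``project_onto`` is given, coefficients are fit on ``Xc`` but evaluated
    on it (used when a probe is fit on a subset of samples: robust
    exclusions or missing entries).  In that case ``Xc`` and ``B`` are
    re-centered on the fitting subset so the probe's mean level cannot leak
    into the composition coefficients.
    """
    if project_onto is not None:
        Xc = Xc - Xc.mean(axis=0, keepdims=True)
        B = B - B.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    keep = s > _SV_CUTOFF
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    if not keep.any():
        target = Xc if project_onto is None else project_onto
        return np.zeros((B.shape[0], target.shape[0]))
    shrink = s**2 / (s**2 + ridge) if ridge > 0 else np.ones_like(s)
    if project_onto is None:
        # fitted values: B @ U diag(shrink) U^T
        return (B @ U) * shrink @ U.T
    coef = ((B @ U) * (shrink / s)) @ Vt  # probes x K
    return coef @ project_onto.T


def adjust_for_cells(
    beta: BetaMatrix,
    proportions: CellProportions,
    ridge: float = 0.0,
    robust: bool = True,
    robust_z: float = 4.0,
) -> AdjustmentResult:
    """Remove between-sample cell-composition variance probe by probe.

    Each probe's betas are regressed on the centered proportion columns
    (optionally ridge-penalised with ``ridge`` >= 0 on the composition
    coefficients); the adjusted value is the fitted value at the cohort-mean
    composition plus the residual.  Values leaving [0, 1] are clipped and
    counted.

    With ``robust=True`` (default) observations further than ``robust_z``
    robust z-units from the first-pass fit are excluded when the
    coefficients are re-estimated, so a rare extreme single-sample value —
    exactly what the downstream variance scan detects — cannot distort the
    composition fit and smear itself across the cohort.
    """
    missing = [s for s in beta.sample_ids if s not in proportions.sample_ids]
    if missing:
        raise KeyError(f"samples absent from proportions: {missing[:5]}")
    if ridge < 0:
        raise ValueRangeError("ridge penalty must be >= 0")

    W = proportions.values.loc[beta.sample_ids].to_numpy(dtype=float)
    Xc = W - W.mean(axis=0, keepdims=True)  # n_samples x K, centered
    B = beta.values.to_numpy(dtype=float)  # probes x samples

    fit = _composition_fit(Xc, B, ridge)

    if robust:
        # single gross outliers must not leak into the composition fit: a
        # high-leverage extreme value drags the fitted surface for every
        # sample, inflating the comparison group's variance and laundering
        # the very signal the variance scan looks for.  Observations beyond
        # `robust_z` robust z-units of the first-pass fit are excluded from
        # coefficient estimation (the fit is still evaluated at them).
        resid = (B - B.mean(axis=1, keepdims=True)) - fit
        scale = MAD_SCALE * np.median(np.abs(resid), axis=1, keepdims=True)
        flagged = np.abs(resid) > robust_z * np.where(scale > 0, scale, np.inf)
        K = Xc.shape[1]
        for i in np.flatnonzero(flagged.any(axis=1)):
            ok = ~flagged[i]
            if ok.sum() < K + 2:
                continue
            fit[i] = _composition_fit(Xc[ok], B[i : i + 1, ok], ridge, project_onto=Xc)[0]

    adjusted = B - fit

    # probes with missing entries: refit on their observed samples only
    # (no robust pass; the completeness filter runs before adjustment)
    incomplete = np.flatnonzero(np.isnan(B).any(axis=1))
    for i in incomplete:
        ok = ~np.isnan(B[i])
        fit_i = _composition_fit(Xc[ok], B[i : i + 1, ok], ridge, project_onto=Xc)
        adjusted[i] = B[i] - fit_i[0]

    n_clipped = int(((adjusted < 0) | (adjusted > 1)).sum())
    adjusted = np.clip(adjusted, 0.0, 1.0)
    out = pd.DataFrame(adjusted, index=beta.probe_ids.copy(), columns=beta.sample_ids.copy())
    # preserve missingness of the input
    out = out.where(~beta.values.isna())
    return AdjustmentResult(adjusted=BetaMatrix(out), n_clipped=n_clipped)
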