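import numpy as np
import pandas as pd
import pytest

from twinvar.cells import (
    AdjustmentResult,
    CellReference,
    ConditioningError,
    InsufficientReferenceError,
    adjust_for_cells,
    estimate_cell_proportions,
)
from twinvar.io import BetaMatrix
from twinvar.simulate import generate_cell_reference

from conftest import make_beta


def grid_search_mixture(R, b, step=0.001):
    """Independent oracle for a 3-type deconvolution: dense (w1, w2) grid with
    the optimal w3 in closed form (1-D least squares clipped to the simplex)."""
    assert R.shape[1] == 3
    w1 = np.arange(0, 1 + step / 2, step)
    W1, W2 = np.meshgrid(w1, w1, indexing="ij")
    ok = (W1 + W2) <= 1 + 1e-12
    W1, W2 = W1[ok], W2[ok]
    resid = b[:, None] - np.outer(R[:, 0], W1) - np.outer(R[:, 1], W2)
    c3 = R[:, 2]
    w3 = (c3 @ resid) / (c3 @ c3)
    w3 = np.clip(w3, 0.0, 1.0 - W1 - W2)
    sse = ((resid - np.outer(c3, w3)) ** 2).sum(axis=0)
    i = int(np.argmin(sse))
    return np.array([W1[i], W2[i], w3[i]])


@pytest.fixture(scope="module")
def reference():
    return generate_cell_reference(K=6, n_reference_probes=80, seed=5)


def mixture_beta(reference, W, samples=None):
    R = reference.values.to_numpy()
    B = np.clip(R @ W.T, 0, 1)
    samples = samples or [f"s{i}" for i in range(W.shape[0])]
    return BetaMatrix(pd.DataFrame(B, index=reference.probe_ids, columns=samples))


def test_vertex_recovery(reference):
    # a sample equal to reference column k gets proportion 1 for type k
    K = reference.values.shape[1]
    W = np.eye(K)
    est = estimate_cell_proportions(mixture_beta(reference, W), reference)
    assert np.allclose(est.values.to_numpy(), np.eye(K), atol=1e-8)


def test_noiseless_mixture_recovery_vs_grid_oracle():
    ref3 = generate_cell_reference(K=3, n_reference_probes=40, seed=6)
    W = np.array([[0.6, 0.4, 0.0], [0.2, 0.3, 0.5], [0.1, 0.0, 0.8]])
    beta = mixture_beta(ref3, W)
    est = estimate_cell_proportions(beta, ref3).values.to_numpy()
    assert np.abs(est - W).max() < 1e-6
    R = ref3.values.to_numpy()
    for i in range(W.shape[0]):
        oracle = grid_search_mixture(R, beta.values.to_numpy()[:, i])
        assert np.abs(est[i] - oracle).max() <= 0.001 + 1e-9


def test_noiseless_recovery_full_reference(reference):
    rng = np.random.default_rng(7)
    W = rng.dirichlet(np.ones(6) * 2, size=8)
    est = estimate_cell_proportions(mixture_beta(reference, W), reference)
    assert np.abs(est.values.to_numpy() - W).max() <= 1e-6


def test_proportion_invariants(small_cohort):
    cohort, reference = small_cohort
    est = estimate_cell_proportions(cohort.beta, reference)
    arr = est.values.to_numpy()
    assert (arr >= 0).all()
    assert (arr.sum(axis=1) <= 1 + 1e-6).all()


def test_missing_reference_probes(reference):
    # all-missing sample -> insufficient reference
    vals = pd.DataFrame(
        np.nan, index=reference.probe_ids, columns=["s0"]
    )
    with pytest.raises(InsufficientReferenceError):
        estimate_cell_proportions(BetaMatrix(vals), reference)
    # no overlap at all
    beta = make_beta(np.full((3, 2), 0.5), probes=["a", "b", "c"])
    with pytest.raises(InsufficientReferenceError):
        with pytest.warns(UserWarning):
            estimate_cell_proportions(beta, reference)


def test_rank_deficient_reference_rejected():
    R = np.tile(np.linspace(0.1, 0.9, 10)[:, None], (1, 3))  # identical columns
    ref = CellReference(pd.DataFrame(R, index=[f"r{i}" for i in range(10)],
                                     columns=["t1", "t2", "t3"]))
    beta = BetaMatrix(pd.DataFrame(R[:, :1], index=ref.probe_ids, columns=["s0"]))
    with pytest.raises(ConditioningError):
        estimate_cell_proportions(beta, ref)


def proportions_frame(W, samples, types=None):
    from twinvar.cells import CellProportions
    types = types or [f"t{k}" for k in range(W.shape[1])]
    return CellProportions(pd.DataFrame(W, index=samples, columns=types))


def test_adjust_noop_when_composition_constant():
    n = 8
    beta = make_beta(np.random.default_rng(0).uniform(0.2, 0.8, (20, n)))
    W = np.tile([0.3, 0.3, 0.4], (n, 1))
    props = proportions_frame(W, beta.sample_ids.tolist())
    out = adjust_for_cells(beta, props)
    assert np.allclose(out.adjusted.values.to_numpy(), beta.values.to_numpy(), atol=1e-12)
    assert out.n_clipped == 0


def test_adjustment_removes_composition_effect():
    rng = np.random.default_rng(42)
    n = 30
    W = rng.dirichlet([4, 3, 3], size=n)
    noise_sd = 0.005
    y = 0.3 + 0.4 * W[:, 0] + rng.normal(0, noise_sd, n)
    beta = make_beta(y[None, :])
    props = proportions_frame(W, beta.sample_ids.tolist())
    adjusted = adjust_for_cells(beta, props).adjusted.values.to_numpy()[0]
    # refit the composition model on adjusted values: slope ~ 0
    Xc = W - W.mean(axis=0)
    coef = np.linalg.lstsq(Xc, adjusted - adjusted.mean(), rcond=None)[0]
    assert abs(coef[0]) < 10 * noise_sd
    # between-sample spread attributable to composition is gone
    assert adjusted.std() < y.std()


def test_adjustment_idempotent():
    # residuals are orthogonal to the centered proportions, so (absent
    # clipping) re-adjusting adjusted data is a fixed point
    rng = np.random.default_rng(3)
    n = 16
    W = rng.dirichlet([5, 5, 5, 5], size=n)
    B = rng.uniform(0.2, 0.6, (25, n)) + 0.2 * W[:, 0]
    beta = make_beta(B)
    props = proportions_frame(W, beta.sample_ids.tolist())
    first = adjust_for_cells(beta, props)
    assert first.n_clipped == 0
    twice = adjust_for_cells(first.adjusted, props).adjusted
    assert np.allclose(first.adjusted.values.to_numpy(), twice.values.to_numpy(), atol=1e-10)


def test_clipping_counted():
    # a near-1 observation at a composition the fitted trend predicts low:
    # removing the composition effect pushes it above 1, which is clipped
    rng = np.random.default_rng(9)
    n = 40
    w0 = rng.uniform(0.0, 0.9, n)
    W = np.column_stack([w0, 1 - w0])
    y = 0.2 + 0.85 * w0 + rng.normal(0, 0.002, n)
    w0[0] = 0.05
    W[0] = (0.05, 0.95)
    y[0] = 0.99
    beta = make_beta(np.clip(y, 0, 1)[None, :])
    props = proportions_frame(W, beta.sample_ids.tolist())
    out = adjust_for_cells(beta, props)
    assert out.n_clipped >= 1
    assert out.adjusted.values.to_numpy().max() <= 1.0


def test_missing_sample_in_proportions_rejected():
    beta = make_beta(np.full((2, 3), 0.5))
    props = proportions_frame(np.full((2, 2), 0.5), beta.sample_ids.tolist()[:2])
    with pytest.raises(KeyError):
        adjust_for_cells(beta, props)
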