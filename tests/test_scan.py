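import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate, special
from statsmodels.stats.multitest import multipletests

from twinvar.io import TwinvarError, ValueRangeError
from twinvar.scan import (
    apply_outlier_rule,
    beta_range,
    identify_outlier_cotwin,
    scan,
    storey_qvalues,
    variance_f_test,
)

from conftest import make_beta, make_sheet


def f_upper_tail_oracle(f, df1, df2):
    """Upper tail of the F distribution by numerical integration of its density."""
    const = (
        special.gamma((df1 + df2) / 2)
        / (special.gamma(df1 / 2) * special.gamma(df2 / 2))
        * (df1 / df2) ** (df1 / 2)
    )

    def density(x):
        return const * x ** (df1 / 2 - 1) * (1 + df1 * x / df2) ** (-(df1 + df2) / 2)

    if f < 1:
        # better conditioned as 1 minus the (finite-domain) lower tail
        val, err = integrate.quad(density, 0, f, limit=400, epsabs=1e-12, epsrel=1e-12)
        val = 1.0 - val
    else:
        val, err = integrate.quad(density, f, np.inf, limit=400, epsabs=1e-12, epsrel=1e-12)
    assert err < 1e-9
    return val


def scale_to_group(z, var):
    """Center a standard-normal-ish vector at 0.5 with the requested variance."""
    z = np.asarray(z, dtype=float)
    z = (z - z.mean()) / z.std(ddof=1)
    return 0.5 + z * np.sqrt(var)


def test_identical_groups_give_half():
    g = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    res = variance_f_test(g, g)
    assert res.F == 1.0
    assert res.p == 0.5  # median of F_{5,5}
    assert (res.df1, res.df2) == (5, 5)


def test_f_test_against_integration_oracle():
    rng = np.random.default_rng(10)
    z1, z2 = rng.normal(size=6), rng.normal(size=6)
    for target_F in (0.25, 1.0, 4.0):
        x = scale_to_group(z1, 0.01 * target_F)
        y = scale_to_group(z2, 0.01)
        res = variance_f_test(x, y)
        assert res.F == pytest.approx(target_F, rel=1e-9)
        assert abs(res.p - f_upper_tail_oracle(res.F, 5, 5)) <= 1e-8
    # frozen oracle values for the 6-vs-6 design
    assert f_upper_tail_oracle(4.0, 5, 5) == pytest.approx(0.0771886, abs=1e-6)
    assert f_upper_tail_oracle(0.25, 5, 5) == pytest.approx(0.9228114, abs=1e-6)


def test_antisymmetry_under_group_exchange():
    rng = np.random.default_rng(2)
    x = np.clip(rng.normal(0.5, 0.05, 6), 0, 1)
    y = np.clip(rng.normal(0.5, 0.02, 6), 0, 1)
    fwd = variance_f_test(x, y)
    rev = variance_f_test(y, x)
    assert fwd.F * rev.F == pytest.approx(1.0, rel=1e-12)
    assert fwd.p + rev.p == pytest.approx(1.0, abs=1e-12)


def test_zero_variance_conventions():
    const = [0.3] * 6
    varied = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
    res = variance_f_test(varied, const)
    assert np.isinf(res.F) and res.p == 0.0
    res = variance_f_test(const, const)
    assert res.degenerate and res.p == 1.0 and np.isnan(res.F)
    with pytest.raises(ValueRangeError):
        variance_f_test([0.5], const)


@settings(deadline=None, derandomize=True, max_examples=50)
@given(st.floats(min_value=0.0, max_value=0.35), st.floats(min_value=0.001, max_value=0.3))
def test_increasing_a_deviation_never_decreases_F(base_dev, extra):
    x = np.array([0.4, 0.45, 0.5, 0.55, 0.6, 0.5 + base_dev])
    y = np.array([0.4, 0.45, 0.5, 0.55, 0.6, 0.5])
    x2 = x.copy()
    x2[-1] = min(1.0, 0.5 + base_dev + extra)
    f1 = variance_f_test(x, y).F
    f2 = variance_f_test(x2, y).F
    assert f2 >= f1 - 1e-12


def test_storey_qvalues_examples():
    q, pi0 = storey_qvalues([0.001, 0.01, 0.5, 0.8], pi0=1.0)
    assert np.allclose(q, [0.004, 0.02, 2 / 3, 0.8])
    with pytest.warns(UserWarning):
        q, pi0 = storey_qvalues([1.0, 1.0, 1.0])
    assert pi0 == 1.0 and np.all(q == 1.0)
    with pytest.warns(UserWarning):
        q, pi0 = storey_qvalues([0.05])
    assert q[0] == pytest.approx(0.05) and pi0 == 1.0
    with pytest.raises(ValueRangeError):
        storey_qvalues([0.5, 1.5])


def brute_force_bh(p):
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [
            m * p[order[j - 1]] / j for j in range(rank_pos, m + 1)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


@pytest.mark.parametrize("trial", range(20))
def test_qvalues_match_bruteforce_bh_when_pi0_is_one(trial):
    rng = np.random.default_rng(trial)
    n = int(rng.integers(1, 60))
    p = rng.uniform(size=n) ** rng.uniform(0.5, 2)
    q, _ = storey_qvalues(p, pi0=1.0)
    assert np.allclose(q, brute_force_bh(p), atol=1e-14)
    assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)


@settings(deadline=None, derandomize=True, max_examples=40)
@given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=40))
def test_q_monotone_in_p(pvals):
    p = np.asarray(pvals)
    q, _ = storey_qvalues(p, pi0=1.0)
    order = np.argsort(p, kind="mergesort")
    assert (np.diff(q[order]) >= -1e-14).all()


def test_beta_range():
    assert beta_range([0.2, 0.6, 0.35]) == pytest.approx(40.0)
    assert beta_range([0.5, 0.5]) == 0.0
    # a published-scale example: affected range 32.9, healthy 1.6 -> 31.3 pp
    assert 32.9 - 1.6 == pytest.approx(31.3)


def make_scan_input(n_null=400, outliers=(), noise_sd=0.01, seed=0):
    sheet = make_sheet(6, 0, 0)
    samples = sheet.sample_ids.tolist()
    rng = np.random.default_rng(seed)
    values = np.clip(rng.normal(0.5, noise_sd, (n_null, len(samples))), 0, 1)
    affected = sheet.samples_where(status="affected")
    for i, delta in outliers:
        j = samples.index(affected[i % len(affected)])
        values[i, j] = min(1.0, values[i, j] + delta)
    return make_beta(values, samples=samples), sheet


def test_scan_flags_injected_outlier_and_records_funnel():
    beta, sheet = make_scan_input(outliers=[(0, 0.4), (1, 0.35)])
    res = scan(beta, sheet)
    assert res.funnel["n_tested"] == 400
    flagged = set(res.outlier_probes())
    assert {"cg00000", "cg00001"} <= flagged
    stats = res.stats.set_index("probe_id")
    assert (stats.loc[list(flagged), "range_diff_pp"] > 10).all()


def test_scan_significant_but_range_filtered():
    # a modest 6-pp shift reaches significance but fails the 10-pp range rule
    beta, sheet = make_scan_input(noise_sd=0.002, outliers=[(0, 0.06)])
    res = scan(beta, sheet)
    stats = res.stats.set_index("probe_id")
    probe = stats.loc["cg00000"]
    assert probe["q"] <= 0.05 and probe["range_diff_pp"] <= 10
    assert not probe["outlier"]
    assert res.funnel["n_significant_range_filtered_out"] >= 1


def test_scan_never_flags_excess_healthy_variance():
    sheet = make_sheet(6, 0, 0)
    samples = sheet.sample_ids.tolist()
    rng = np.random.default_rng(5)
    values = np.clip(rng.normal(0.5, 0.005, (200, len(samples))), 0, 1)
    healthy = sheet.samples_where(status="healthy")
    # inject big single-co-twin deviations into HEALTHY co-twins only
    for i in range(0, 200, 10):
        values[i, samples.index(healthy[i % 6])] += 0.4
    beta = make_beta(np.clip(values, 0, 1), samples=samples)
    res = scan(beta, sheet)
    assert res.funnel["n_outliers"] == 0


def test_scan_rejects_missing_values():
    beta, sheet = make_scan_input(n_null=10)
    beta.values.iloc[0, 0] = np.nan
    with pytest.raises(TwinvarError, match="missing"):
        scan(beta, sheet)


def test_outlier_rule_thresholds():
    q = np.array([0.039, 0.049, 0.04])
    diff = np.array([33.2, 14.4, 8.0])
    assert apply_outlier_rule(q, diff).tolist() == [True, True, False]
    # strictly-greater-than semantics at the boundary
    assert apply_outlier_rule([0.01], [10.0]).tolist() == [False]


def test_identify_outlier_cotwin():
    sheet = make_sheet(3, 0, 0)
    disc = sheet.discordant_samples()
    values = pd.Series(0.05, index=disc)
    values["D2_a"] = 0.40
    pair, sample, dev, tied = identify_outlier_cotwin(values, sheet)
    assert (pair, sample, tied) == ("D2", "D2_a", False)
    assert dev == pytest.approx(35.0)
    # tie resolves to the lexicographically smaller sample id and is flagged
    values["D1_a"] = 0.40
    pair, sample, dev, tied = identify_outlier_cotwin(values, sheet)
    assert (pair, sample, tied) == ("D1", "D1_a", True)


def test_identify_outlier_cotwin_matches_truth(small_cohort):
    cohort, _ = small_cohort
    disc = cohort.sheet.discordant_samples()
    for probe, carrier in cohort.truth.carriers.items():
        vals = cohort.beta.values.loc[probe, disc]
        _, sample, _, _ = identify_outlier_cotwin(vals, cohort.sheet)
        assert sample == carrier
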