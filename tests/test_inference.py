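"""Linear-scale tests, moments, rank correlations, cluster-wise regression."""

import numpy as np
import pytest
from scipy import stats

from tempoclust.inference import (
    anova_oneway,
    clusterwise_z,
    fit_regression,
    moments,
    se_kurtosis,
    se_skewness,
    spearman_rho,
    two_group_compare,
)


def test_anova_hand_computed_sums_of_squares():
    # groups {1,2,3} and {2,3,4}: SSB = 1.5, SSW = 4, F = 1.5 on (1, 4) df
    res = anova_oneway([1, 2, 3, 2, 3, 4], ["a", "a", "a", "b", "b", "b"])
    assert res.F == pytest.approx(1.5)
    assert (res.df1, res.df2) == (1, 4)
    assert res.eta_sq == pytest.approx(1.5 / 5.5)


def test_identical_groups_zero_effect():
    res = anova_oneway([1, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
    assert res.eta_sq == pytest.approx(0.0)
    assert res.F == pytest.approx(0.0)


def test_anova_matches_scipy_on_random_inputs(rng):
    for _ in range(10):
        k = rng.integers(2, 5)
        groups = [rng.normal(rng.normal(), 1.0, rng.integers(5, 30)) for _ in range(k)]
        values = np.concatenate(groups)
        labels = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
        res = anova_oneway(values, labels, with_tukey=False)
        ref = stats.f_oneway(*groups)
        assert res.F == pytest.approx(ref.statistic, abs=1e-8, rel=1e-8)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-8, rel=1e-8)


def test_tukey_matches_scipy(rng):
    groups = [rng.normal(m, 1.0, 12) for m in (0.0, 0.4, 1.0)]
    values = np.concatenate(groups)
    labels = np.concatenate([[i] * 12 for i in range(3)])
    res = anova_oneway(values, labels)
    ref = stats.tukey_hsd(*groups)
    for row in res.tukey:
        i, j = row["group_a"], row["group_b"]
        assert row["p_adj"] == pytest.approx(ref.pvalue[i, j], abs=1e-8)


def test_tukey_not_below_unadjusted_t(rng):
    groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.3, 0.8, 1.2)]
    values = np.concatenate(groups)
    labels = np.concatenate([[i] * 10 for i in range(4)])
    res = anova_oneway(values, labels)
    for row in res.tukey:
        a = groups[row["group_a"]]
        b = groups[row["group_b"]]
        t_p = stats.ttest_ind(a, b).pvalue
        assert row["p_adj"] >= t_p - 1e-10


def test_two_groups_f_equals_t_squared(rng):
    y = rng.normal(0, 1, 40)
    g = np.repeat(["x", "y"], 20)
    t, p_t, _ = two_group_compare(y, g)
    res = anova_oneway(y, g, with_tukey=False)
    assert res.F == pytest.approx(t * t, abs=1e-10)
    assert res.p == pytest.approx(p_t, abs=1e-10)


def test_equal_means_zero_t_and_d():
    t, p, d = two_group_compare([1, 2, 3, 1, 2, 3], ["a", "a", "a", "b", "b", "b"])
    assert t == 0.0 and d == 0.0


def test_shifted_copies_give_d_equal_shift_over_sd(rng):
    a = rng.normal(0, 2, 50)
    shift = 1.7
    y = np.concatenate([a, a + shift])
    g = np.repeat(["a", "b"], 50)
    t, _, d = two_group_compare(y, g)
    assert d == pytest.approx(-shift / a.std(ddof=1), rel=1e-12)


def test_ttest_matches_scipy(rng):
    a, b = rng.normal(0, 1, 15), rng.normal(0.5, 1, 20)
    y = np.concatenate([a, b])
    g = np.repeat(["a", "b"], [15, 20])
    t, p, _ = two_group_compare(y, g)
    ref = stats.ttest_ind(a, b)
    assert t == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_spearman_extremes_and_scipy_tie_agreement(rng):
    assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40])[0] == 1.0
    assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10])[0] == -1.0
    x = rng.integers(1, 4, 30).astype(float)  # tie-heavy
    y = rng.integers(1, 6, 30).astype(float)
    rho, p = spearman_rho(x, y)
    ref = stats.spearmanr(x, y)
    assert rho == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-8)


def test_spearman_constant_flagged():
    with pytest.warns(UserWarning):
        rho, _ = spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
    assert np.isnan(rho)


def test_moment_standard_errors_at_study_size():
    assert round(se_skewness(3576), 2) == 0.04
    assert round(se_kurtosis(3576), 2) == 0.08


def test_mirrored_sample_has_zero_skewness():
    m = moments([-3.0, -1.0, 0.0, 1.0, 3.0])
    assert m.skewness == pytest.approx(0.0, abs=1e-12)


def test_normal_sample_moments_within_4se(rng):
    x = rng.normal(0, 1, 10000)
    m = moments(x)
    assert abs(m.skewness) < 4 * m.se_skewness
    assert abs(m.kurtosis) < 4 * m.se_kurtosis


def test_clusterwise_z_basic_and_locality():
    z = clusterwise_z([400, 500, 600], [0, 0, 0])
    np.testing.assert_allclose(z, [-1, 0, 1])
    z2 = clusterwise_z([400, 500, 600, 900, 1100], [0, 0, 0, 1, 1])
    np.testing.assert_allclose(z2[:3], [-1, 0, 1])
    z3 = clusterwise_z([400, 500, 600, 10, 2000], [0, 0, 0, 1, 1])
    np.testing.assert_allclose(z3[:3], z2[:3])


def test_clusterwise_z_standardizes_each_cluster(rng):
    y = rng.normal(500, 60, 200)
    lab = rng.integers(0, 3, 200)
    z = clusterwise_z(y, lab)
    for k in range(3):
        assert z[lab == k].mean() == pytest.approx(0.0, abs=1e-12)
        assert z[lab == k].std(ddof=1) == pytest.approx(1.0, rel=1e-12)


def test_regression_perfect_single_predictor(rng):
    x = rng.normal(0, 1, 100)
    res = fit_regression(2.0 * x, {"x": x, "noise": np.linspace(0, 1, 100)})
    assert res.r_squared == pytest.approx(1.0)
    assert res.coefficients["x"] == pytest.approx(2.0 * x.std(ddof=1), rel=1e-9)


def test_regression_single_predictor_beta_sq_equals_r2(rng):
    x = rng.normal(0, 1, 200)
    y = 0.3 * x + rng.normal(0, 1, 200)
    res = fit_regression(y, {"x": x})
    assert res.coefficients["x"] ** 2 == pytest.approx(
        res.r_squared * np.var(y, ddof=1), rel=1e-9
    )


def test_regression_null_r2_near_zero(rng):
    y = rng.normal(0, 1, 5000)
    X = {f"p{i}": rng.normal(0, 1, 5000) for i in range(4)}
    res = fit_regression(y, X)
    assert res.r_squared < 0.01


def test_regression_invariant_to_cluster_constants(rng):
    iti = rng.normal(500, 60, 300)
    lab = rng.integers(0, 3, 300)
    x = {"a": rng.normal(0, 1, 300)}
    z1 = clusterwise_z(iti, lab)
    shifted = iti + np.array([0, 400, 900])[lab]
    z2 = clusterwise_z(shifted, lab)
    r1 = fit_regression(z1, x)
    r2 = fit_regression(z2, x)
    assert r1.coefficients["a"] == pytest.approx(r2.coefficients["a"], abs=1e-10)
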