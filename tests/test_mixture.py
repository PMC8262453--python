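"""Constrained-mixture EM: recovery, constraints, BIC selection, oracles."""

import numpy as np
import pytest

from tempoclust.mixture import (
    assign_clusters,
    fit_em,
    n_covariance_params,
    select_model,
)


def _sklearn_loglik(model, X):
    """Independent log-likelihood oracle: score my parameters with sklearn."""
    from scipy.linalg import cholesky
    from sklearn.mixture import GaussianMixture

    gm = GaussianMixture(model.K, covariance_type="full")
    gm.fit(X)  # only to initialize internal shapes
    gm.weights_ = model.weights
    gm.means_ = model.means
    precisions = np.array([np.linalg.inv(c) for c in model.covariances])
    gm.precisions_cholesky_ = np.array([cholesky(p, lower=True) for p in precisions])
    return gm.score(X) * X.shape[0]


def test_degenerate_identical_points():
    X = np.tile([5.0, 1.0], (20, 1))
    m = fit_em(X, K=1, family="EII")
    np.testing.assert_allclose(m.means[0], [5.0, 1.0])
    assert m.weights[0] == pytest.approx(1.0)
    assert m.covariances[0][0, 0] > 0  # clamped at the variance floor


def test_two_blob_eii_recovery(rng):
    X = np.vstack(
        [
            rng.normal([500, 0.05], 10.0, (200, 2)),
            rng.normal([1000, 0.05], 10.0, (200, 2)),
        ]
    )
    m = fit_em(X, K=2, family="EII", seed=0)
    assert m.converged
    assert m.means[0, 0] == pytest.approx(500, rel=0.02)
    assert m.means[1, 0] == pytest.approx(1000, rel=0.02)
    # EII constraint: one shared spherical covariance
    for cov in m.covariances:
        np.testing.assert_allclose(cov, m.covariances[0])
        assert cov[0, 0] == pytest.approx(cov[1, 1])
        assert cov[0, 1] == 0.0


@pytest.mark.parametrize("family", ["EII", "VII", "EEI", "VEI", "EVI", "VVI", "EEE", "VVV"])
def test_loglik_matches_reference_gmm(rng, family):
    X = np.vstack(
        [
            rng.normal([0, 0], 1.0, (80, 2)),
            rng.normal([5, 3], 1.5, (70, 2)),
            rng.normal([-4, 6], 0.8, (60, 2)),
        ]
    )
    m = fit_em(X, K=3, family=family, seed=1)
    assert m.log_likelihood == pytest.approx(_sklearn_loglik(m, X), abs=1e-6)


def test_vvv_matches_sklearn_fit_quality(rng):
    # unconstrained family should reach (at least) sklearn's solution quality
    from sklearn.mixture import GaussianMixture

    X = np.vstack(
        [rng.normal([0, 0], 1.0, (120, 2)), rng.normal([6, 4], 1.2, (100, 2))]
    )
    m = fit_em(X, K=2, family="VVV", seed=2)
    gm = GaussianMixture(2, covariance_type="full", n_init=5, random_state=0).fit(X)
    assert m.log_likelihood >= gm.score(X) * X.shape[0] - 1.0
    order = np.argsort(gm.means_[:, 0])
    np.testing.assert_allclose(m.means, gm.means_[order], rtol=0.05, atol=0.3)


def test_em_loglik_monotone(rng):
    # refitting from the final parameters cannot lower the log-likelihood
    X = rng.normal(0, 1, (150, 2))
    m1 = fit_em(X, K=3, family="VVI", seed=3, max_iter=5)
    m2 = fit_em(X, K=3, family="VVI", seed=3, max_iter=200)
    assert m2.log_likelihood >= m1.log_likelihood - 1e-9


def test_labels_sorted_by_mean_iti(rng):
    X = np.vstack(
        [rng.normal([900, 0.05], 20, (50, 2)), rng.normal([300, 0.05], 20, (50, 2))]
    )
    m = fit_em(X, K=2, family="EEI", seed=0)
    assert m.means[0, 0] < m.means[1, 0]


def test_eii_lambda_recovery(rng):
    lam_true = 9.0
    centers = np.array([[0, 0], [20, 0], [0, 20], [20, 20]])
    X = np.vstack(
        [rng.normal(c, np.sqrt(lam_true), (500, 2)) for c in centers]
    )
    m = fit_em(X, K=4, family="EII", seed=0)
    assert m.lambda_ == pytest.approx(lam_true, rel=0.10)


def test_responsibilities_normalized_and_peaked(rng):
    X = np.vstack(
        [rng.normal([300, 0.05], 15, (60, 2)), rng.normal([900, 0.05], 15, (60, 2))]
    )
    m = fit_em(X, K=2, family="EII", seed=0)
    labels, resp = assign_clusters(m, X)
    np.testing.assert_allclose(resp.sum(axis=1), 1.0, atol=1e-12)
    lab_at_mean, resp_at_mean = assign_clusters(m, m.means[0][None, :])
    assert lab_at_mean[0] == 0
    assert resp_at_mean[0, 0] > 0.99


def test_one_blob_selects_k1(rng):
    X = rng.normal([500, 0.05], [30, 0.01], (300, 2))
    res = select_model(X, k_max=4, seed=0)
    assert res.selected.K == 1


def test_bic_table_reproducible(rng):
    X = np.vstack(
        [rng.normal([300, 0.05], 15, (80, 2)), rng.normal([900, 0.06], 15, (80, 2))]
    )
    t1 = select_model(X, k_max=3, seed=5).table
    t2 = select_model(X, k_max=3, seed=5).table
    assert t1 == t2


def test_selected_maximizes_bic(cleaned_points):
    _, pts, _ = cleaned_points
    res = select_model(pts, k_max=5, seed=11)
    best = max(r["bic"] for r in res.table if r["converged"])
    assert res.selected.bic == pytest.approx(best)


def test_parameter_counts():
    assert n_covariance_params("EII", 6, 2) == 1
    assert n_covariance_params("VVV", 3, 2) == 9
    assert n_covariance_params("EEI", 4, 2) == 2
    assert n_covariance_params("VEI", 4, 2) == 5


def test_family_constraints_hold(rng):
    X = rng.normal(0, 1, (200, 2)) * [3.0, 1.0]
    m_vei = fit_em(X, K=2, family="VEI", seed=0)
    shapes = []
    for cov in m_vei.covariances:
        diag = np.diagonal(cov)
        shapes.append(diag / np.prod(diag) ** 0.5)  # det-normalized shape
    np.testing.assert_allclose(shapes[0], shapes[1], rtol=1e-6)
    m_evi = fit_em(X, K=2, family="EVI", seed=0)
    vols = [np.prod(np.diagonal(c)) ** 0.5 for c in m_evi.covariances]
    assert vols[0] == pytest.approx(vols[1], rel=1e-6)


def test_too_few_points_rejected():
    with pytest.raises(ValueError):
        fit_em(np.zeros((2, 2)), K=3)
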