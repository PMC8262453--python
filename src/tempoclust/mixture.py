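"""Covariance-constrained bivariate Gaussian mixtures for tempo clustering.

Participants are clustered on (mean ITI, CV) with an EM algorithm whose
M-step enforces one of eight covariance families, named with the standard
three-letter geometry codes (volume / shape / orientation):

====== =============================================
EII    spherical, equal volume: Sigma_k = lambda * I
VII    spherical, varying volume: lambda_k * I
EEI    diagonal, equal volume and shape
VEI    diagonal, varying volume, equal shape
EVI    diagonal, equal volume, varying shape
VVI    diagonal, fully varying
EEE    one shared full covariance
VVV    unconstrained full covariance per component
====== =============================================

Closed-form M-steps follow the classical eigenvalue-decomposition treatment
of parsimonious Gaussian mixtures; VEI alternates between volume and shape
updates.  Model selection maximizes BIC in the 2*loglik - p*log(N)
convention, so "best" is the largest value.  Components are always reported
sorted by ascending mean ITI, making cluster labels reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from tempoclust.datatypes import DEFAULT_FAMILIES

_LOG_2PI = np.log(2.0 * np.pi)

__all__ = [
    "MixtureModel",
    "ModelSearchResult",
    "fit_em",
    "select_model",
    "assign_clusters",
    "n_covariance_params",
]


@dataclass
class MixtureModel:
    K: int
    family: str
    weights: np.ndarray  # (K,), simplex
    means: np.ndarray  # (K, d), sorted by ascending first coordinate
    covariances: np.ndarray  # (K, d, d)
    log_likelihood: float
    bic: float
    n_params: int
    assignments: np.ndarray  # (N,) arg-max responsibility
    n_iter: int
    converged: bool

    @property
    def lambda_(self) -> float:
        """Shared spherical variance for EII; mean diagonal otherwise."""
        return float(np.mean(np.diagonal(self.covariances, axis1=1, axis2=2)))


@dataclass
class ModelSearchResult:
    table: list[dict] = field(default_factory=list)  # (K, family, bic, converged)
    selected: MixtureModel | None = None


def n_covariance_params(family: str, K: int, d: int) -> int:
    full = d * (d + 1) // 2
    return {
        "EII": 1,
        "VII": K,
        "EEI": d,
        "VEI": K + (d - 1),
        "EVI": 1 + K * (d - 1),
        "VVI": K * d,
        "EEE": full,
        "VVV": K * full,
    }[family]


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """Log density of N(mean, cov) at the rows of X; cov is (d, d) SPD."""
    d = X.shape[1]
    diff = X - mean
    if np.allclose(cov, np.diag(np.diagonal(cov))):
        v = np.diagonal(cov)
        return -0.5 * (d * _LOG_2PI + np.sum(np.log(v)) + np.sum(diff**2 / v, axis=1))
    L = np.linalg.cholesky(cov)
    sol = np.linalg.solve(L, diff.T)
    logdet = 2.0 * np.sum(np.log(np.diagonal(L)))
    return -0.5 * (d * _LOG_2PI + logdet + np.sum(sol**2, axis=0))


def _component_log_densities(X, weights, means, covs) -> np.ndarray:
    K = weights.size
    d = X.shape[1]
    diag = np.diagonal(covs, axis1=1, axis2=2)  # (K, d)
    offdiag = covs - diag[:, None, :] * np.eye(d)
    if not offdiag.any():
        # all-diagonal families: one broadcasted pass over components
        diff = X[:, None, :] - means[None, :, :]  # (N, K, d)
        quad = np.sum(diff**2 / diag[None, :, :], axis=2)
        logdet = np.sum(np.log(diag), axis=1)
        return np.log(weights)[None, :] - 0.5 * (d * _LOG_2PI + logdet[None, :] + quad)
    out = np.empty((X.shape[0], K))
    for k in range(K):
        out[:, k] = np.log(weights[k]) + _log_gaussian(X, means[k], covs[k])
    return out


def _e_step(X, weights, means, covs):
    log_wp = _component_log_densities(X, weights, means, covs)
    m = log_wp.max(axis=1, keepdims=True)
    log_norm = m[:, 0] + np.log(np.exp(log_wp - m).sum(axis=1))
    resp = np.exp(log_wp - log_norm[:, None])
    return resp, float(log_norm.sum())


def _m_step(X, resp, family, floor):
    """Weighted means + family-constrained covariance update.

    ``floor`` is a per-dimension variance floor (d-vector); diagonal entries
    are clamped to it, full covariances get a floor*I ridge when needed.
    """
    N, d = X.shape
    K = resp.shape[1]
    nk = resp.sum(axis=0)
    weights = nk / N
    means = (resp.T @ X) / nk[:, None]

    # per-component scatter: diagonal part always, full part on demand
    diff_all = X[:, None, :] - means[None, :, :]  # (N, K, d)
    Wdiag = np.einsum("nk,nkd->kd", resp, diff_all**2)

    covs = np.zeros((K, d, d))
    if family == "EII":
        lam = max(Wdiag.sum() / (N * d), floor.mean())
        for k in range(K):
            covs[k] = lam * np.eye(d)
    elif family == "VII":
        for k in range(K):
            lam = max(Wdiag[k].sum() / (nk[k] * d), floor.mean())
            covs[k] = lam * np.eye(d)
    elif family == "EEI":
        diag = np.maximum(Wdiag.sum(axis=0) / N, floor)
        for k in range(K):
            covs[k] = np.diag(diag)
    elif family == "VVI":
        for k in range(K):
            covs[k] = np.diag(np.maximum(Wdiag[k] / nk[k], floor))
    elif family == "VEI":
        # alternate: shape B (diag, det 1) shared; volume lambda_k per component
        lam = np.maximum(Wdiag.sum(axis=1) / (nk * d), floor.mean())
        B = np.ones(d)
        for _ in range(8):
            B = (Wdiag / lam[:, None]).sum(axis=0)
            B = np.maximum(B, 1e-300)
            B = B / np.prod(B) ** (1.0 / d)
            lam = np.maximum((Wdiag / B).sum(axis=1) / (nk * d), floor.mean())
        for k in range(K):
            covs[k] = np.diag(np.maximum(lam[k] * B, floor))
    elif family == "EVI":
        # shape B_k per component (det 1), shared volume lambda
        dets = np.prod(np.maximum(Wdiag, 1e-300), axis=1) ** (1.0 / d)
        lam = max(dets.sum() / N, floor.mean())
        for k in range(K):
            Bk = np.maximum(Wdiag[k], 1e-300) / dets[k]
            covs[k] = np.diag(np.maximum(lam * Bk, floor))
    elif family == "EEE":
        W = np.zeros((d, d))
        for k in range(K):
            diff = X - means[k]
            W += (diff * resp[:, k][:, None]).T @ diff
        cov = W / N
        cov = _ridge_spd(cov, floor)
        for k in range(K):
            covs[k] = cov
    elif family == "VVV":
        for k in range(K):
            diff = X - means[k]
            Wk = (diff * resp[:, k][:, None]).T @ diff
            covs[k] = _ridge_spd(Wk / nk[k], floor)
    else:
        raise ValueError(f"unknown covariance family {family!r}")
    return weights, means, covs


def _ridge_spd(cov: np.ndarray, floor: np.ndarray) -> np.ndarray:
    """Ensure a full covariance stays positive definite above the floor."""
    cov = np.array(cov, dtype=float)
    min_eig = np.min(np.linalg.eigvalsh(cov))
    ridge = floor.mean()
    if min_eig < ridge:
        cov += (ridge - min_eig) * np.eye(cov.shape[0])
    return cov


def ward_init_labels(X: np.ndarray, k_max: int, max_points: int = 4000) -> dict[int, np.ndarray]:
    """Hard initial partitions for K = 1..k_max from Ward agglomeration.

    The tree is built once and cut at every K, which initializes all model
    sizes consistently and avoids the classic k-means failure on multimodal
    data (splitting heavy modes while merging small distant ones).  For
    very large N the tree is built on an evenly strided subsample and
    labels are extended by nearest centroid.
    """
    from scipy.cluster.hierarchy import fcluster, linkage

    N = X.shape[0]
    if N > max_points:
        idx = np.linspace(0, N - 1, max_points).astype(int)
        order = np.argsort(X[:, 0], kind="stable")
        sub_idx = order[idx]
    else:
        sub_idx = np.arange(N)
    Z = linkage(X[sub_idx], method="ward")
    out = {}
    for K in range(1, k_max + 1):
        sub_lab = fcluster(Z, K, criterion="maxclust") - 1
        if N > max_points:
            centroids = np.array([X[sub_idx][sub_lab == k].mean(axis=0) for k in range(K)])
            d2 = ((X[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
            out[K] = d2.argmin(axis=1)
        else:
            out[K] = sub_lab
    return out


def _init_params(X, K, family, floor, rng, perturb=0.0, init_labels=None):
    """Family-consistent initialization.

    With ``init_labels`` given (e.g. a Ward cut), parameters start from that
    hard partition; otherwise a deterministic quantile split on the first
    coordinate with 10 Lloyd refinements is used.  Either way the starting
    covariances come from one family M-step, so the constraint holds from
    the first EM iteration and monotonicity is guaranteed throughout.
    """
    N, d = X.shape
    if init_labels is not None and perturb == 0.0:
        lab = np.asarray(init_labels)
    else:
        order = np.argsort(X[:, 0], kind="stable")
        blocks = np.array_split(order, K)
        means = np.array([X[b].mean(axis=0) for b in blocks])
        if perturb > 0:
            scale = X.std(axis=0) * perturb
            means = means + rng.normal(0.0, 1.0, means.shape) * scale
        lab = np.zeros(N, dtype=int)
        for _ in range(10):
            d2 = ((X[:, None, :] - means[None, :, :]) ** 2).sum(axis=2)
            lab = d2.argmin(axis=1)
            for k in range(K):
                sel = lab == k
                if sel.any():
                    means[k] = X[sel].mean(axis=0)
    resp = np.full((N, K), 1e-6)
    resp[np.arange(N), lab] = 1.0
    resp /= resp.sum(axis=1, keepdims=True)
    return _m_step(X, resp, family, floor)


def _sort_by_first_mean(weights, means, covs, resp):
    order = np.argsort(means[:, 0], kind="stable")
    return weights[order], means[order], covs[order], resp[:, order]


def fit_em(
    points,
    K: int,
    family: str = "EII",
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int = 0,
    n_retries: int = 5,
    return_responsibilities: bool = False,
    init_labels=None,
):
    """Fit a K-component constrained Gaussian mixture by EM.

    The log-likelihood is monotone non-decreasing across iterations;
    convergence is declared when its relative change drops below ``tol``.
    Degenerate runs (a component's weight collapsing) are restarted with a
    perturbed initialization up to ``n_retries`` times, after which the last
    fit is returned flagged ``converged=False``.
    """
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    N, d = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("points must be finite")
    if N < K:
        raise ValueError(f"need at least K={K} points, got {N}")
    rng = np.random.default_rng(seed)
    floor = np.maximum(X.var(axis=0), 1e-300) * 1e-6

    best = None
    for attempt in range(n_retries + 1):
        weights, means, covs = _init_params(
            X, K, family, floor, rng, perturb=0.2 * attempt, init_labels=init_labels
        )
        ll_prev = -np.inf
        converged = False
        degenerate = False
        n_iter = 0
        resp = None
        for n_iter in range(1, max_iter + 1):
            resp, ll = _e_step(X, weights, means, covs)
            if ll < ll_prev - 1e-6 * max(1.0, abs(ll_prev)):
                degenerate = True  # monotonicity violated: numerical trouble
                break
            if np.any(resp.sum(axis=0) < 1e-8):
                degenerate = True
                break
            weights, means, covs = _m_step(X, resp, family, floor)
            if np.any(weights < 1e-10):
                degenerate = True
                break
            if ll - ll_prev < tol * max(1.0, abs(ll)):
                converged = True
                ll_prev = ll
                break
            ll_prev = ll
        if not degenerate and resp is not None:
            resp, ll_final = _e_step(X, weights, means, covs)
            model = (weights, means, covs, resp, ll_final, n_iter, converged)
            if best is None or ll_final > best[4]:
                best = model
            break  # retries are reserved for degenerate runs

    if best is None:
        # all attempts degenerate: fall back to a single flat responsibility fit
        weights, means, covs = _init_params(X, K, family, floor, rng)
        resp, ll_final = _e_step(X, weights, means, covs)
        best = (weights, means, covs, resp, ll_final, 0, False)

    weights, means, covs, resp, ll, n_iter, converged = best
    weights, means, covs, resp = _sort_by_first_mean(weights, means, covs, resp)
    p = (K - 1) + K * d + n_covariance_params(family, K, d)
    model = MixtureModel(
        K=K,
        family=family,
        weights=weights,
        means=means,
        covariances=covs,
        log_likelihood=ll,
        bic=2.0 * ll - p * np.log(N),
        n_params=p,
        assignments=resp.argmax(axis=1),
        n_iter=n_iter,
        converged=converged,
    )
    if return_responsibilities:
        return model, resp
    return model


def select_model(
    points,
    k_max: int = 9,
    families=DEFAULT_FAMILIES,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> ModelSearchResult:
    """Fit every (K <= k_max, family) pair; select the BIC-maximal converged fit."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] <= k_max:
        raise ValueError("need N > k_max")
    result = ModelSearchResult()
    best_bic = -np.inf
    init = ward_init_labels(X, k_max)
    for family in families:
        for K in range(1, k_max + 1):
            model = fit_em(
                X, K, family, tol=tol, max_iter=max_iter, seed=seed, init_labels=init[K]
            )
            result.table.append(
                {
                    "K": K,
                    "family": family,
                    "bic": model.bic,
                    "log_likelihood": model.log_likelihood,
                    "converged": model.converged,
                }
            )
            if model.converged and model.bic > best_bic:
                best_bic = model.bic
                result.selected = model
    if result.selected is None:
        raise RuntimeError("no mixture fit converged")
    return result


def assign_clusters(model: MixtureModel, points) -> tuple[np.ndarray, np.ndarray]:
    """Hard assignments + posterior responsibilities under a fitted model."""
    X = np.asarray(points, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    resp, _ = _e_step(X, model.weights, model.means, model.covariances)
    return resp.argmax(axis=1), resp
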