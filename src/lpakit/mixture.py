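"""Finite Gaussian mixture (latent profile) estimation by EM.

A latent profile model treats each patient's indicator vector x_i in R^p as
drawn from one of K multivariate normal components ("profiles") with mixing
weights pi_k. The E-step posterior

    tau_ik = pi_k N(x_i; mu_k, Sigma_k) / sum_j pi_j N(x_i; mu_j, Sigma_j)

is the probability that patient i belongs to profile k; modal assignment
takes the argmax row-wise. Six covariance families are supported, crossing
shape (spherical / diagonal / full) with whether components share one
covariance (equal) or have their own (varying). Binary and ordinal
indicators are treated as numeric Gaussians, as is conventional in latent
profile analysis of mixed routine data; this is a deliberate model
misspecification that the documentation discusses.

All densities are computed in log space with log-sum-exp normalisation, and
covariances are kept positive definite by an eigenvalue floor of
1e-6 times the mean diagonal element.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.cluster import KMeans

FAMILIES = (
    "spherical_equal",
    "spherical_varying",
    "diagonal_equal",
    "diagonal_varying",
    "full_equal",
    "full_varying",
)

_LOG2PI = np.log(2.0 * np.pi)
COV_FLOOR_FRAC = 1e-6


@dataclass
class MixtureParams:
    """Parameters of a K-component Gaussian mixture over p indicators.

    ``covariances`` has a family-dependent shape: scalars per component for
    spherical families, (K, p) variance rows for diagonal families, and
    (K, p, p) matrices for full families; "equal" families repeat one shared
    covariance across components.
    """

    K: int
    p: int
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    family: str

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown covariance family {self.family!r}")
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        if self.weights.shape != (self.K,) or self.means.shape != (self.K, self.p):
            raise ValueError("weights/means shapes inconsistent with (K, p)")
        if abs(self.weights.sum() - 1.0) > 1e-10 or np.any(self.weights <= 0):
            raise ValueError("mixing weights must be positive and sum to 1")

    def full_covariances(self) -> np.ndarray:
        """Covariances expanded to shape (K, p, p) regardless of family."""
        K, p = self.K, self.p
        if self.family.startswith("spherical"):
            return np.einsum("k,ij->kij", self.covariances, np.eye(p))
        if self.family.startswith("diagonal"):
            return np.stack([np.diag(v) for v in self.covariances])
        return self.covariances

    def n_parameters(self) -> int:
        """Free parameters: (K-1) weights + K*p means + covariance terms."""
        K, p = self.K, self.p
        cov = {
            "spherical_equal": 1,
            "spherical_varying": K,
            "diagonal_equal": p,
            "diagonal_varying": K * p,
            "full_equal": p * (p + 1) // 2,
            "full_varying": K * p * (p + 1) // 2,
        }[self.family]
        return (K - 1) + K * p + cov

    def permuted(self, order: np.ndarray) -> "MixtureParams":
        order = np.asarray(order)
        cov = self.covariances
        if cov.ndim >= 1 and cov.shape[0] == self.K:
            cov = cov[order]
        return MixtureParams(
            K=self.K,
            p=self.p,
            weights=self.weights[order],
            means=self.means[order],
            covariances=cov,
            family=self.family,
        )


def n_parameters(K: int, p: int, family: str) -> int:
    """Free-parameter count of a (K, p, family) mixture without fitting it."""
    dummy = MixtureParams(
        K=K,
        p=p,
        weights=np.full(K, 1.0 / K),
        means=np.zeros((K, p)),
        covariances=_unit_cov(K, p, family),
        family=family,
    )
    return dummy.n_parameters()


def _unit_cov(K: int, p: int, family: str) -> np.ndarray:
    if family.startswith("spherical"):
        return np.ones(K)
    if family.startswith("diagonal"):
        return np.ones((K, p))
    return np.stack([np.eye(p)] * K)


# ---------------------------------------------------------------------------
# log densities

def _floor_value(diag_mean: float) -> float:
    return COV_FLOOR_FRAC * max(diag_mean, np.finfo(float).tiny)


def _regularize_variances(var: np.ndarray) -> tuple[np.ndarray, bool]:
    """Floor (co)variance diagonals at 1e-6 x the mean diagonal element."""
    floor = _floor_value(float(np.mean(var)))
    if np.all(var >= floor):
        return var, False
    return np.maximum(var, floor), True


def _regularize_full(cov: np.ndarray) -> tuple[np.ndarray, bool]:
    floor = _floor_value(float(np.mean(np.diag(cov))))
    w, v = np.linalg.eigh(cov)
    if w.min() >= floor:
        return cov, False
    w = np.maximum(w, floor)
    return (v * w) @ v.T, True


def log_component_densities(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """log N(x_i; mu_k, Sigma_k) as an (n, K) array."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    K = params.K
    out = np.empty((n, K))
    fam = params.family
    if fam.startswith("full"):
        from scipy.linalg import solve_triangular

        for k in range(K):
            cov = params.covariances[k]
            chol = np.linalg.cholesky(cov)
            diff = X - params.means[k]
            # solve L z = diff^T  -> quadratic form = ||z||^2
            z = solve_triangular(chol, diff.T, lower=True)
            quad = np.sum(z * z, axis=0)
            logdet = 2.0 * np.sum(np.log(np.diag(chol)))
            out[:, k] = -0.5 * (p * _LOG2PI + logdet + quad)
        return out
    if fam.startswith("diagonal"):
        var = params.covariances  # (K, p)
        for k in range(K):
            diff = X - params.means[k]
            quad = np.sum(diff * diff / var[k], axis=1)
            out[:, k] = -0.5 * (p * _LOG2PI + np.sum(np.log(var[k])) + quad)
        return out
    var = params.covariances  # (K,)
    for k in range(K):
        diff = X - params.means[k]
        quad = np.sum(diff * diff, axis=1) / var[k]
        out[:, k] = -0.5 * (p * _LOG2PI + p * np.log(var[k]) + quad)
    return out


def _log_resp(X: np.ndarray, params: MixtureParams) -> tuple[np.ndarray, float]:
    """Log responsibilities and the observed-data log-likelihood."""
    logdens = log_component_densities(X, params) + np.log(params.weights)
    m = logdens.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.sum(np.exp(logdens - m), axis=1))
    return logdens - lse[:, None], float(lse.sum())


def e_step(X: np.ndarray, params: MixtureParams) -> np.ndarray:
    """Posterior profile-membership probabilities tau (n x K).

    Computed in log space and normalised by log-sum-exp, so extreme
    densities never produce NaNs; each row sums to 1.
    """
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    if X.ndim != 2 or X.shape[1] != params.p:
        raise ValueError(f"data must be 2-D with {params.p} columns")
    log_tau, _ = _log_resp(X, params)
    return np.exp(log_tau)


# ---------------------------------------------------------------------------
# M-step

def _m_step(
    X: np.ndarray, tau: np.ndarray, family: str
) -> tuple[MixtureParams, bool]:
    n, p = X.shape
    K = tau.shape[1]
    nk = tau.sum(axis=0)
    nk = np.maximum(nk, 10 * np.finfo(float).tiny)
    weights = nk / n
    weights = weights / weights.sum()
    means = (tau.T @ X) / nk[:, None]

    regularized = False
    if family.startswith("full"):
        covs = np.empty((K, p, p))
        for k in range(K):
            diff = X - means[k]
            covs[k] = (tau[:, k, None] * diff).T @ diff / nk[k]
        if family == "full_equal":
            pooled = np.einsum("k,kij->ij", nk / n, covs)
            pooled, reg = _regularize_full(pooled)
            covs = np.stack([pooled] * K)
            regularized |= reg
        else:
            for k in range(K):
                covs[k], reg = _regularize_full(covs[k])
                regularized |= reg
    else:
        var = np.empty((K, p))
        for k in range(K):
            diff = X - means[k]
            var[k] = (tau[:, k] @ (diff * diff)) / nk[k]
        if family == "diagonal_equal":
            pooled = (nk / n) @ var
            pooled, regularized = _regularize_variances(pooled)
            var = np.tile(pooled, (K, 1))
        elif family == "diagonal_varying":
            var, regularized = _regularize_variances(var)
        elif family == "spherical_equal":
            s = float(np.mean((nk / n) @ var))
            var = np.full(K, max(s, np.finfo(float).tiny))
        else:  # spherical_varying
            var = np.maximum(var.mean(axis=1), np.finfo(float).tiny)
        covs = var

    params = MixtureParams(
        K=K, p=p, weights=weights, means=means, covariances=covs, family=family
    )
    return params, regularized


# ---------------------------------------------------------------------------
# solutions

@dataclass
class ProfileSolution:
    """A fitted mixture: parameters, posteriors, assignment and diagnostics."""

    params: MixtureParams
    tau: np.ndarray
    labels: np.ndarray
    loglik: float
    n: int
    n_iter: int
    converged: bool
    final_rel_change: float
    ll_trace: np.ndarray
    regularized: bool = False

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def n_parameters(self) -> int:
        return self.params.n_parameters()

    def reordered(self, order: np.ndarray) -> "ProfileSolution":
        """Relabel profiles; log-likelihood and fit statistics are unchanged."""
        order = np.asarray(order)
        inv = np.empty_like(order)
        inv[order] = np.arange(len(order))
        return ProfileSolution(
            params=self.params.permuted(order),
            tau=self.tau[:, order],
            labels=inv[self.labels],
            loglik=self.loglik,
            n=self.n,
            n_iter=self.n_iter,
            converged=self.converged,
            final_rel_change=self.final_rel_change,
            ll_trace=self.ll_trace,
            regularized=self.regularized,
        )

    def to_json(self, path: str | Path | None = None) -> dict:
        d = {
            "family": self.params.family,
            "K": self.params.K,
            "p": self.params.p,
            "weights": self.params.weights.tolist(),
            "means": self.params.means.tolist(),
            "covariances": self.params.covariances.tolist(),
            "loglik": self.loglik,
            "n": self.n,
            "n_parameters": self.n_parameters,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "final_rel_change": self.final_rel_change,
            "regularized": self.regularized,
        }
        if path is not None:
            Path(path).write_text(json.dumps(d, indent=2))
        return d


def _kmeans_init(X: np.ndarray, K: int, family: str, seed: int) -> MixtureParams:
    n, p = X.shape
    if K == 1:
        tau = np.ones((n, 1))
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed).fit(X)
        tau = np.zeros((n, K))
        tau[np.arange(n), km.labels_] = 1.0
        # guard against empty clusters
        empty = tau.sum(axis=0) == 0
        if empty.any():
            tau[:, empty] = 1e-3
            tau /= tau.sum(axis=1, keepdims=True)
    params, _ = _m_step(X, tau, family)
    return params


def _run_em(
    X: np.ndarray,
    init: MixtureParams,
    tol: float,
    max_iter: int,
) -> ProfileSolution:
    params = init
    ll_trace = []
    prev = -np.inf
    prev_params = init
    converged = False
    rel = np.inf
    regularized = False
    for it in range(1, max_iter + 1):
        log_tau, ll = _log_resp(X, params)
        if ll < prev - 1e-9 * max(1.0, abs(prev)):
            # Exact EM is monotone; the covariance floor can push a nearly
            # degenerate update downhill. Revert to the best iterate and
            # stop there, keeping the recorded trace non-decreasing.
            params = prev_params
            converged = True
            break
        ll_trace.append(ll)
        rel = abs(ll - prev) / (abs(ll) + 1e-300)
        if rel < tol:
            converged = True
            break
        prev = ll
        prev_params = params
        params, reg = _m_step(X, np.exp(log_tau), params.family)
        regularized |= reg
    log_tau, ll = _log_resp(X, params)
    tau = np.exp(log_tau)
    return ProfileSolution(
        params=params,
        tau=tau,
        labels=np.argmax(tau, axis=1),
        loglik=ll,
        n=X.shape[0],
        n_iter=len(ll_trace),
        converged=converged,
        final_rel_change=rel,
        ll_trace=np.asarray(ll_trace),
        regularized=regularized,
    )


def _closed_form_k1(X: np.ndarray, family: str) -> ProfileSolution:
    """K=1 has an analytic MLE; no EM iterations are needed."""
    n, p = X.shape
    tau = np.ones((n, 1))
    params, reg = _m_step(X, tau, family)
    _, ll = _log_resp(X, params)
    return ProfileSolution(
        params=params,
        tau=tau,
        labels=np.zeros(n, dtype=int),
        loglik=ll,
        n=n,
        n_iter=1,
        converged=True,
        final_rel_change=0.0,
        ll_trace=np.asarray([ll]),
        regularized=reg,
    )


def fit_mixture(
    data,
    K: int,
    family: str = "diagonal_varying",
    n_starts: int = 8,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 1000,
    init_params: MixtureParams | None = None,
    order_by: np.ndarray | None = None,
) -> ProfileSolution:
    """Fit a K-profile Gaussian mixture by EM with seeded k-means starts.

    The best log-likelihood over ``n_starts`` initialisations is kept (plus
    ``init_params`` as an extra warm start when given). Convergence is a
    relative log-likelihood change below ``tol``. Profiles are relabelled in
    ascending order of the sum of their means over the ``order_by`` columns
    (all columns when omitted) so that labels are deterministic; profile 0
    is always the lowest-mean profile.

    ``data`` may be an ndarray or a DataFrame (its values are used; callers
    should pass only indicator columns).
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    if X.ndim != 2:
        raise ValueError("data must be 2-D")
    n, p = X.shape
    if not np.all(np.isfinite(X)):
        raise ValueError("data must be finite")
    if K < 1 or n <= K:
        raise ValueError("need K >= 1 and n > K")
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")

    if K == 1:
        best = _closed_form_k1(X, family)
    else:
        if n_starts < 1 and init_params is None:
            raise ValueError("need n_starts >= 1 or an explicit init_params")
        seeds = np.random.SeedSequence(seed).generate_state(max(n_starts, 0))
        inits = [_kmeans_init(X, K, family, int(s % (2**31 - 1))) for s in seeds]
        if init_params is not None:
            inits.append(init_params)
        best = None
        for init in inits:
            try:
                sol = _run_em(X, init, tol=tol, max_iter=max_iter)
            except np.linalg.LinAlgError:
                continue
            if best is None or sol.loglik > best.loglik:
                best = sol
        if best is None:
            raise RuntimeError("every EM start failed (singular covariance)")

    cols = np.arange(p) if order_by is None else np.asarray(order_by)
    order = np.argsort(best.params.means[:, cols].sum(axis=1), kind="stable")
    return best.reordered(order)


def sample_from_params(
    params: MixtureParams, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n observations from a fitted mixture (parametric bootstrap)."""
    labels = rng.choice(params.K, size=n, p=params.weights)
    X = np.empty((n, params.p))
    covs = params.full_covariances()
    for k in range(params.K):
        idx = np.where(labels == k)[0]
        if idx.size:
            X[idx] = rng.multivariate_normal(
                params.means[k], covs[k], size=idx.size, method="cholesky"
            )
    return X


# ---------------------------------------------------------------------------
# fit statistics

@dataclass
class FitStatistics:
    """Information criteria and classification diagnostics for one solution.

    Two BIC conventions are reported: ``bic_mclust`` = 2*LL - d*log(n)
    (larger is better, the convention used by model-based-clustering
    software and by this package's model selection) and classical
    ``bic`` = -2*LL + d*log(n) (smaller is better). ``entropy_normalized``
    is 1 - (sum of posterior Shannon entropies)/(n log K), 1 for perfectly
    crisp assignment, defined as 1 when K = 1.
    """

    loglik: float
    n_parameters: int
    n: int
    K: int
    aic: float
    bic_mclust: float
    bic: float
    entropy_raw: float
    entropy_normalized: float
    expected_classification_error: float
    mean_max_posterior: float


def fit_statistics(solution: ProfileSolution) -> FitStatistics:
    ll = solution.loglik
    d = solution.n_parameters
    n = solution.n
    K = solution.K
    tau = solution.tau
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(tau > 0, tau * np.log(tau), 0.0)
    raw = float(-plogp.sum())
    norm = 1.0 if K == 1 else 1.0 - raw / (n * np.log(K))
    max_tau = tau.max(axis=1)
    return FitStatistics(
        loglik=ll,
        n_parameters=d,
        n=n,
        K=K,
        aic=2.0 * ll - 2.0 * d,
        bic_mclust=2.0 * ll - d * np.log(n),
        bic=-2.0 * ll + d * np.log(n),
        entropy_raw=raw,
        entropy_normalized=float(norm),
        expected_classification_error=float(np.mean(1.0 - max_tau)),
        mean_max_posterior=float(np.mean(max_tau)),
    )


# ---------------------------------------------------------------------------
# distributional diagnostics

def mardia_coefficients(data) -> dict:
    """Mardia's multivariate skewness and kurtosis with test statistics.

    Using the ML (divide-by-n) covariance S and centred data Y,
    b1p = mean over all pairs (i, j) of (y_i' S^-1 y_j)^3 and
    b2p = mean of (y_i' S^-1 y_i)^2. The skewness statistic n*b1p/6 is
    asymptotically chi-square with p(p+1)(p+2)/6 df; the kurtosis statistic
    (b2p - p(p+2)) / sqrt(8 p (p+2) / n) is asymptotically standard normal.
    """
    X = np.asarray(getattr(data, "values", data), dtype=float)
    n, p = X.shape
    if n <= p:
        raise ValueError("need n > p for Mardia's coefficients")
    Y = X - X.mean(axis=0)
    S = (Y.T @ Y) / n
    try:
        Sinv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise ValueError("sample covariance is singular") from exc
    cond = np.linalg.cond(S)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError("sample covariance is singular (ill-conditioned)")

    W = Y @ Sinv  # (n, p)
    # accumulate sum of (y_i' S^-1 y_j)^3 in row blocks to bound memory
    total = 0.0
    block = max(1, int(2e7) // max(n, 1))
    for start in range(0, n, block):
        G = W[start : start + block] @ Y.T
        total += float(np.sum(G**3))
    b1p = total / (n * n)
    d2 = np.einsum("ij,ij->i", W, Y)
    b2p = float(np.mean(d2**2))

    from scipy import stats as sps

    skew_stat = n * b1p / 6.0
    skew_df = p * (p + 1) * (p + 2) // 6
    skew_p = float(sps.chi2.sf(skew_stat, skew_df))
    kurt_stat = (b2p - p * (p + 2)) / np.sqrt(8.0 * p * (p + 2) / n)
    kurt_p = float(2.0 * sps.norm.sf(abs(kurt_stat)))
    return {
        "skewness": float(b1p),
        "skewness_statistic": float(skew_stat),
        "skewness_df": skew_df,
        "skewness_p": skew_p,
        "kurtosis": float(b2p),
        "kurtosis_statistic": float(kurt_stat),
        "kurtosis_p": kurt_p,
        "n": n,
        "p": p,
    }
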