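"""Gaussian mixture EM: oracles, closed forms, invariants."""

import numpy as np
import pytest
from scipy import stats as sps

from lpakit import cohort
from lpakit.mixture import (
    FAMILIES,
    MixtureParams,
    ProfileSolution,
    e_step,
    fit_mixture,
    fit_statistics,
    mardia_coefficients,
    sample_from_params,
)


def random_params(rng, K=2, p=2, family="full_varying"):
    w = rng.dirichlet(np.ones(K) * 5)
    means = rng.normal(size=(K, p))
    if family.startswith("full"):
        covs = []
        for _ in range(K):
            A = rng.normal(size=(p, p))
            covs.append(A @ A.T + np.eye(p))
        covs = np.stack(covs)
    elif family.startswith("diagonal"):
        covs = rng.uniform(0.5, 2.0, size=(K, p))
    else:
        covs = rng.uniform(0.5, 2.0, size=K)
    return MixtureParams(K=K, p=p, weights=w, means=means, covariances=covs, family=family)


class TestEStep:
    def test_single_class_gives_ones(self, rng):
        params = random_params(rng, K=1, p=3)
        X = rng.normal(size=(8, 3))
        tau = e_step(X, params)
        assert np.all(tau == 1.0)

    def test_symmetric_point_is_half_half(self):
        params = MixtureParams(
            K=2, p=1, weights=np.array([0.5, 0.5]),
            means=np.array([[-1.0], [1.0]]), covariances=np.array([1.0, 1.0]),
            family="spherical_varying",
        )
        tau = e_step(np.array([[0.0]]), params)
        assert tau[0] == pytest.approx([0.5, 0.5], abs=1e-14)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_matches_bayes_rule_oracle(self, rng, family):
        """tau must equal the explicit multivariate-normal Bayes formula."""
        params = random_params(rng, K=3, p=2, family=family)
        X = rng.normal(size=(5, 2))
        covs = params.full_covariances()
        dens = np.stack(
            [
                params.weights[k] * sps.multivariate_normal.pdf(X, params.means[k], covs[k])
                for k in range(3)
            ],
            axis=1,
        )
        oracle = dens / dens.sum(axis=1, keepdims=True)
        assert np.max(np.abs(e_step(X, params) - oracle)) <= 1e-12

    def test_rows_sum_to_one_even_for_remote_points(self, rng):
        params = random_params(rng, K=2, p=2)
        X = rng.normal(size=(4, 2)) + 1e4  # density underflow territory
        tau = e_step(X, params)
        assert np.all(np.isfinite(tau))
        assert np.allclose(tau.sum(axis=1), 1.0, atol=1e-10)

    def test_nonfinite_rejected(self, rng):
        params = random_params(rng)
        with pytest.raises(ValueError, match="finite"):
            e_step(np.array([[np.nan, 0.0]]), params)


class TestFitMixture:
    def test_two_point_closed_form(self):
        """{-1,+1} with K=1: mu=0, sigma^2=1, LL = -(1 + log 2pi)."""
        X = np.array([[-1.0], [1.0]])
        sol = fit_mixture(X, 1, family="spherical_varying")
        assert sol.params.means[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert sol.params.covariances[0] == pytest.approx(1.0, rel=1e-12)
        assert sol.loglik == pytest.approx(-(1 + np.log(2 * np.pi)), rel=1e-12)

    def test_k1_mean_is_sample_mean(self, rng):
        X = rng.normal(size=(40, 3))
        for family in FAMILIES:
            sol = fit_mixture(X, 1, family=family)
            assert np.allclose(sol.params.means[0], X.mean(axis=0), atol=1e-12)

    def test_separated_clusters_recovered(self, rng):
        X = np.vstack(
            [rng.normal(0.0, 0.5, size=(100, 1)), rng.normal(10.0, 0.5, size=(100, 1))]
        )
        truth = np.repeat([0, 1], 100)
        sol = fit_mixture(X, 2, family="diagonal_varying", seed=0)
        tol = 3 * 0.5 / np.sqrt(100)
        assert abs(sol.params.means[0, 0] - 0.0) < tol
        assert abs(sol.params.means[1, 0] - 10.0) < tol
        assert np.mean(sol.labels == truth) == 1.0

    def test_loglik_trace_monotone_nondecreasing(self, small_cohort):
        X = small_cohort[cohort.INDICATORS].to_numpy(dtype=float)
        for family in ("diagonal_varying", "full_varying"):
            sol = fit_mixture(X, 2, family=family, seed=1, n_starts=2)
            diffs = np.diff(sol.ll_trace)
            assert np.all(diffs >= -1e-6 * np.abs(sol.ll_trace[:-1]))

    def test_deterministic_given_seed(self, small_cohort):
        X = small_cohort[cohort.INDICATORS].to_numpy(dtype=float)
        a = fit_mixture(X, 2, seed=5)
        b = fit_mixture(X, 2, seed=5)
        assert a.loglik == b.loglik
        assert np.array_equal(a.labels, b.labels)

    def test_posterior_rows_sum_to_one(self, small_cohort):
        X = small_cohort[cohort.INDICATORS].to_numpy(dtype=float)
        sol = fit_mixture(X, 3, seed=2)
        assert np.allclose(sol.tau.sum(axis=1), 1.0, atol=1e-10)
        assert np.array_equal(sol.labels, np.argmax(sol.tau, axis=1))

    def test_needs_more_points_than_components(self):
        with pytest.raises(ValueError, match="n > K"):
            fit_mixture(np.zeros((2, 1)), 2)

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(60, 2))
        X[:30] += 4.0
        sol = fit_mixture(X, 2, family="full_varying", seed=3)
        flipped = sol.reordered(np.array([1, 0]))
        assert flipped.loglik == sol.loglik
        assert np.allclose(flipped.tau, sol.tau[:, [1, 0]])
        assert np.allclose(flipped.params.means, sol.params.means[[1, 0]])
        fs, fsf = fit_statistics(sol), fit_statistics(flipped)
        assert fs.bic_mclust == fsf.bic_mclust
        assert fs.entropy_raw == pytest.approx(fsf.entropy_raw, rel=1e-12)

    def test_profiles_ordered_by_requested_columns(self, small_cohort, order_by_teams):
        X = small_cohort[cohort.INDICATORS].to_numpy(dtype=float)
        sol = fit_mixture(X, 2, seed=1, order_by=order_by_teams)
        totals = sol.params.means[:, order_by_teams].sum(axis=1)
        assert totals[0] < totals[1]

    def test_parameter_recovery_on_gaussian_cohort(self, rng):
        """Fitted means recover generating means within 3 MC SEs."""
        means = np.array([[0.0, 0.0], [6.0, -4.0]])
        sd = 1.0
        n_k = 400
        X = np.vstack([rng.normal(means[k], sd, size=(n_k, 2)) for k in range(2)])
        sol = fit_mixture(X, 2, family="diagonal_varying", seed=0, order_by=[0])
        tol = 4 * sd / np.sqrt(n_k)
        assert np.all(np.abs(sol.params.means - means) < tol)

    def test_profile_ordering_on_calibrated_cohort(self, full_cohort, order_by_teams):
        """On the service-use cohort the first profile is the low-use one."""
        X = full_cohort[cohort.INDICATORS].to_numpy(dtype=float)
        sol = fit_mixture(X, 2, seed=0, order_by=order_by_teams)
        i_nurse = cohort.INDICATORS.index("nurse")
        i_psy = cohort.INDICATORS.index("psychology")
        assert sol.params.means[0, i_nurse] < sol.params.means[1, i_nurse]
        assert sol.params.means[0, i_psy] < sol.params.means[1, i_psy]
        # low-use profile is the larger one
        assert np.mean(sol.labels == 0) > 0.5


class TestFitStatistics:
    def test_two_point_bic(self):
        X = np.array([[-1.0], [1.0]])
        sol = fit_mixture(X, 1, family="spherical_varying")
        fs = fit_statistics(sol)
        ll = -(1 + np.log(2 * np.pi))
        assert fs.n_parameters == 2
        assert fs.bic_mclust == pytest.approx(2 * ll - 2 * np.log(2), rel=1e-10)
        assert fs.bic_mclust == pytest.approx(-7.062, abs=5e-4)
        assert fs.bic == pytest.approx(-fs.bic_mclust, rel=1e-12)
        assert fs.aic == pytest.approx(2 * ll - 4, rel=1e-10)

    def _manual_solution(self, tau):
        n, K = tau.shape
        params = MixtureParams(
            K=K, p=1, weights=np.full(K, 1 / K), means=np.zeros((K, 1)),
            covariances=np.ones(K), family="spherical_varying",
        )
        return ProfileSolution(
            params=params, tau=tau, labels=np.argmax(tau, axis=1), loglik=0.0,
            n=n, n_iter=1, converged=True, final_rel_change=0.0,
            ll_trace=np.array([0.0]),
        )

    def test_hard_posteriors(self):
        tau = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 0.0]])
        fs = fit_statistics(self._manual_solution(tau))
        assert fs.entropy_normalized == 1.0
        assert fs.expected_classification_error == 0.0
        assert fs.mean_max_posterior == 1.0

    def test_uniform_posteriors(self):
        tau = np.full((10, 2), 0.5)
        fs = fit_statistics(self._manual_solution(tau))
        assert fs.entropy_normalized == pytest.approx(0.0, abs=1e-12)
        assert fs.expected_classification_error == pytest.approx(0.5)

    def test_k1_entropy_defined_as_one(self):
        tau = np.ones((5, 1))
        fs = fit_statistics(self._manual_solution(tau))
        assert fs.entropy_normalized == 1.0


class TestMardia:
    def test_symmetric_two_point_skewness_zero_kurtosis_one(self):
        res = mardia_coefficients(np.array([[-1.0], [1.0]]))
        assert res["skewness"] == pytest.approx(0.0, abs=1e-12)
        assert res["kurtosis"] == pytest.approx(1.0, rel=1e-12)

    def test_matches_double_sum_oracle(self, rng):
        X = rng.normal(size=(6, 2))
        res = mardia_coefficients(X)
        n, p = X.shape
        Y = X - X.mean(axis=0)
        S = Y.T @ Y / n
        Sinv = np.linalg.inv(S)
        b1 = 0.0
        for i in range(n):
            for j in range(n):
                b1 += (Y[i] @ Sinv @ Y[j]) ** 3
        b1 /= n * n
        b2 = np.mean([(Y[i] @ Sinv @ Y[i]) ** 2 for i in range(n)])
        assert res["skewness"] == pytest.approx(b1, abs=1e-10)
        assert res["kurtosis"] == pytest.approx(b2, abs=1e-10)

    def test_singular_covariance_rejected(self):
        X = np.ones((10, 2))
        X[:, 1] = X[:, 0]  # perfectly collinear
        with pytest.raises(ValueError, match="singular"):
            mardia_coefficients(X)

    def test_gaussian_data_not_flagged(self, rng):
        X = rng.normal(size=(2000, 3))
        res = mardia_coefficients(X)
        assert res["kurtosis"] == pytest.approx(3 * 5, rel=0.1)  # p(p+2)
        assert res["skewness_p"] > 1e-4


class TestSampling:
    def test_sample_from_params_moments(self, rng):
        params = MixtureParams(
            K=2, p=2, weights=np.array([0.3, 0.7]),
            means=np.array([[0.0, 0.0], [5.0, 5.0]]),
            covariances=np.array([[1.0, 1.0], [2.0, 0.5]]),
            family="diagonal_varying",
        )
        X = sample_from_params(params, 20_000, rng)
        expected_mean = 0.3 * 0.0 + 0.7 * 5.0
        assert X[:, 0].mean() == pytest.approx(expected_mean, abs=0.1)
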