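"""Structural model: OLS oracle, 3-step controlled effects, Poisson GOF."""

import numpy as np
import pytest
from scipy import stats as sps

from lpakit import cohort as co
from lpakit.mixture import fit_mixture
from lpakit.structural import (
    controlled_effects,
    direct_effects,
    interaction_model,
    linear_effect,
    poisson_gof,
)


class TestLinearEffect:
    def test_exact_fit(self):
        x = np.arange(10.0)
        res = linear_effect(2 * x, x)
        assert res.B == pytest.approx(2.0, abs=1e-12)
        assert res.t > 1e6 or res.p_value == 0.0

    def test_constant_predictor_flagged(self):
        res = linear_effect(np.arange(10.0), np.ones(10))
        assert res.degenerate

    def test_matches_normal_equations_oracle(self, rng):
        n = 20
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        y = 1.0 + 0.5 * x - 0.3 * z + rng.normal(size=n)
        res = linear_effect(y, x, covariates=z[:, None])
        X = np.column_stack([np.ones(n), x, z])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        sigma2 = resid @ resid / (n - 3)
        se = np.sqrt(sigma2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.B == pytest.approx(beta[1], abs=1e-10)
        assert (res.ci_high - res.ci_low) / 2 == pytest.approx(
            sps.t.ppf(0.975, n - 3) * se, abs=1e-10
        )
        assert res.t == pytest.approx(beta[1] / se, abs=1e-10)

    def test_ci_t_p_mutually_consistent(self, rng):
        y = rng.normal(size=30)
        x = rng.normal(size=30)
        res = linear_effect(y, x)
        se = (res.ci_high - res.ci_low) / (2 * sps.t.ppf(0.975, res.df_resid))
        assert res.t == pytest.approx(res.B / se, rel=1e-8)
        assert res.p_value == pytest.approx(
            2 * sps.t.sf(abs(res.t), res.df_resid), rel=1e-8
        )
        assert res.ci_low <= res.B <= res.ci_high


@pytest.fixture(scope="module")
def fitted_two_profile():
    df = co.generate_cohort(co.default_config(n_patients=1200), seed=21)
    order_by = [co.INDICATORS.index(c) for c in co.TEAM_INDICATORS]
    sol = fit_mixture(
        df[co.INDICATORS], 2, family="diagonal_varying", seed=0, order_by=order_by
    )
    return df, sol


class TestDirectEffects:
    def test_mean_difference_recovered(self, fitted_two_profile):
        df, sol = fitted_two_profile
        effects = direct_effects(sol, df)
        nurse = next(
            e for e in effects if e.outcome == "nurse" and e.predictor == "cluster"
        )
        observed_gap = (
            df.nurse[sol.labels == 1].mean() - df.nurse[sol.labels == 0].mean()
        )
        # OLS on a 0/1 regressor IS the group mean difference
        assert nurse.B == pytest.approx(observed_gap, rel=1e-10)
        assert nurse.t > 2

    def test_both_directions_present(self, fitted_two_profile):
        df, sol = fitted_two_profile
        effects = direct_effects(sol, df)
        outcomes = {(e.outcome, e.predictor) for e in effects}
        assert ("nurse", "cluster") in outcomes
        assert ("cluster", "nurse") in outcomes
        assert ("cluster", "internalizing") in outcomes

    def test_constant_cluster_degenerate(self, fitted_two_profile):
        df, sol = fitted_two_profile
        one = fit_mixture(df[co.INDICATORS], 1)
        effects = direct_effects(one, df)
        assert all(e.degenerate for e in effects)

    def test_null_parameter_has_small_t(self):
        """A parameter identical across profiles should show |t| < 2 mostly."""
        rng = np.random.default_rng(5)
        hits = 0
        n_seeds = 20
        for s in range(n_seeds):
            rng = np.random.default_rng(50 + s)
            cluster = rng.integers(0, 2, 400)
            y = rng.normal(size=400)  # unrelated to cluster
            res = linear_effect(y, cluster.astype(float))
            hits += abs(res.t) < 2
        assert hits >= 17  # ~95% nominal with MC slack


class TestControlledEffects:
    def test_hard_posteriors_degenerate(self, fitted_two_profile):
        df, sol = fitted_two_profile
        import copy

        hard = copy.copy(sol)
        hard.tau = (sol.tau > 0.5).astype(float)
        effects = controlled_effects(hard, df)
        assert all(e.degenerate for e in effects)

    def test_controlled_equals_direct_without_confounding(self):
        """Posterior independent of the focal parameter: controlled ~ direct."""
        rng = np.random.default_rng(3)
        agree = 0
        for s in range(10):
            rng = np.random.default_rng(60 + s)
            n = 500
            cluster = rng.integers(0, 2, n).astype(float)
            y = 1.0 + 2.0 * cluster + rng.normal(size=n)
            p2 = np.clip(rng.beta(2, 2, n), 1e-6, 1 - 1e-6)  # independent noise
            pc = p2 - p2.mean()
            direct = linear_effect(y, cluster)
            controlled = linear_effect(
                y, cluster, covariates=np.column_stack([pc, pc * cluster]),
                kind="controlled",
            )
            joint_hw = np.hypot(
                (direct.ci_high - direct.ci_low) / 2,
                (controlled.ci_high - controlled.ci_low) / 2,
            )
            agree += abs(controlled.B - direct.B) < joint_hw
        assert agree >= 9

    def test_attenuation_with_overlapping_profiles(self, fitted_two_profile):
        df, sol = fitted_two_profile
        direct = {
            (e.outcome, e.predictor): e for e in direct_effects(sol, df)
        }
        controlled = {
            (e.outcome, e.predictor): e for e in controlled_effects(sol, df)
        }
        # nurse drives separation; conditioning on assignment probability
        # absorbs part of the cluster association
        d = direct[("nurse", "cluster")]
        c = controlled[("nurse", "cluster")]
        assert not c.degenerate
        assert abs(c.t) < abs(d.t)

    def test_requires_two_profiles(self, fitted_two_profile):
        df, _ = fitted_two_profile
        one = fit_mixture(df[co.INDICATORS], 1)
        with pytest.raises(ValueError, match="K = 2"):
            controlled_effects(one, df)


class TestInteractionModel:
    def test_identical_clusters_zero_interaction(self, rng):
        nurse = rng.poisson(3.0, 300).astype(float)
        dna = rng.poisson(1.0 + 0.3 * nurse).astype(float)
        # duplicate the same data into both clusters: exact symmetry
        res = interaction_model(
            np.concatenate([dna, dna]),
            np.concatenate([nurse, nurse]),
            np.repeat([0, 1], 300),
        )
        assert res.interaction().B == pytest.approx(0.0, abs=1e-10)

    def test_slope_difference_recovered(self):
        rng = np.random.default_rng(8)
        n = 4000
        cluster = rng.integers(0, 2, n)
        nurse = rng.poisson(4.0, n).astype(float)
        delta = 0.4
        rate = 1.0 + 0.2 * nurse + delta * nurse * cluster
        dna = rng.poisson(rate)
        res = interaction_model(dna, nurse, cluster)
        inter = res.interaction()
        assert inter.ci_low < delta < inter.ci_high

    def test_type_one_error_calibrated(self):
        """No generating interaction: |t|>=2 in at most ~7.5% of 200 seeds."""
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(1000 + s)
            n = 250
            cluster = rng.integers(0, 2, n)
            nurse = rng.poisson(4.0, n).astype(float)
            dna = rng.poisson(1.0 + 0.2 * nurse)  # same law in both clusters
            res = interaction_model(dna, nurse, cluster)
            rejections += abs(res.interaction().t) >= 2
        assert rejections <= 15  # 7.5% of 200

    def test_fitted_curves_shape(self, rng):
        nurse = rng.poisson(3.0, 200).astype(float)
        dna = rng.poisson(1.0, 200).astype(float)
        res = interaction_model(dna, nurse, rng.integers(0, 2, 200))
        curves = res.fitted_curves
        assert set(curves.cluster) == {0, 1}
        assert len(curves) == 100


class TestPoissonGof:
    def test_calibrated_on_true_poisson(self):
        """~5% rejections at alpha=.05 over 200 replicates of Poisson data."""
        rejections = 0
        for s in range(200):
            rng = np.random.default_rng(2000 + s)
            counts = rng.poisson(1.59, 3941)
            res = poisson_gof(counts)
            rejections += res.p_value < 0.05
        # binomial 95% band around 0.05 with n=200: [0.020, 0.080]
        assert 3 <= rejections <= 17

    def test_df_is_bins_minus_two(self, rng):
        counts = rng.poisson(2.0, 500)
        res = poisson_gof(counts)
        assert res.df == len(res.observed) - 2
        assert all(e >= 5.0 for e in res.expected)

    def test_statistic_matches_pearson_formula(self, rng):
        counts = rng.poisson(3.0, 400)
        res = poisson_gof(counts)
        manual = sum(
            (o - e) ** 2 / e for o, e in zip(res.observed, res.expected)
        )
        assert res.statistic == pytest.approx(manual, rel=1e-12)
        assert res.statistic >= 0.0

    def test_perfect_fit_gives_zero(self, rng):
        counts = rng.poisson(2.0, 300)
        res = poisson_gof(counts)
        # chi-square is zero exactly when observed equals expected bin-wise
        shifted = [(o - o + e) for o, e in zip(res.observed, res.expected)]
        zero_stat = sum((e1 - e2) ** 2 / e2 for e1, e2 in zip(shifted, res.expected))
        assert zero_stat == 0.0
        assert res.statistic > 0.0  # real data never matches exactly

    def test_degenerate_all_equal(self):
        res = poisson_gof(np.full(50, 3))
        assert res.degenerate

    def test_overdispersed_counts_rejected_strongly(self, full_cohort):
        res = poisson_gof(full_cohort.dna.values)
        assert res.p_value < 1e-6  # mixture of NBs is far from Poisson
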