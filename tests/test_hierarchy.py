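import math

import numpy as np
import pytest
from scipy import integrate, stats

from powerep import (
    BetaParams,
    IGParams,
    NormalParams,
    OriginalUpdated,
    PointMass,
    ReplicationPair,
    StudySummary,
    UnitInformation,
    I2_from_alpha,
    alpha_from_I2,
    alpha_from_tau2,
    bf01_effect,
    bfdc_ig,
    bfdc_ig_limit,
    bfdc_partial,
    bfdc_point,
    hier_marginal_likelihood,
    hier_replication_posterior,
    ig_implied_alpha_prior,
    matched_I2_prior_density,
    matched_tau2_prior_density,
    shrinkage_factor,
    tau2_from_alpha,
    theta_posterior_fixed_alpha,
)


class TestParameterMaps:
    def test_tau2_alpha_anchor_points(self):
        assert alpha_from_tau2(0.0, 0.05) == 1.0
        assert alpha_from_tau2(0.0025 / 2.0, 0.05) == pytest.approx(0.5)
        assert tau2_from_alpha(1.0, 0.05) == 0.0
        assert math.isinf(tau2_from_alpha(0.0, 0.05))

    def test_I2_alpha_anchor_points(self):
        assert alpha_from_I2(0.0) == 1.0
        assert alpha_from_I2(0.5) == pytest.approx(1.0 / 3.0)
        assert I2_from_alpha(1.0) == 0.0

    def test_roundtrips(self):
        rng = np.random.default_rng(3)
        for a in rng.uniform(1e-6, 1.0, 100):
            assert alpha_from_tau2(tau2_from_alpha(a, 0.05), 0.05) == pytest.approx(
                a, abs=1e-14
            )
            assert alpha_from_I2(I2_from_alpha(a)) == pytest.approx(a, abs=1e-15)


class TestFixedParameterCorrespondence:
    def test_zero_heterogeneity_pools_completely(self, labels):
        hp = hier_replication_posterior(labels[2], 0.0)
        pp = theta_posterior_fixed_alpha(labels[2], 1.0)
        assert hp.mean == pytest.approx(pp.mean, abs=1e-15)
        assert hp.variance == pytest.approx(pp.variance, abs=1e-15)

    def test_huge_heterogeneity_discards_original(self, labels):
        hp = hier_replication_posterior(labels[2], 1e12)
        assert hp.mean == pytest.approx(0.21, abs=1e-6)
        assert hp.variance == pytest.approx(0.0036, rel=1e-6)

    @pytest.mark.parametrize("alpha", [0.3, alpha_from_tau2(0.00125, 0.05)])
    def test_exact_match_at_mapped_parameters(self, labels, alpha):
        pair = labels[3]
        tau2 = tau2_from_alpha(alpha, pair.original.se)
        hp = hier_replication_posterior(pair, tau2)
        pp = theta_posterior_fixed_alpha(pair, alpha)
        assert abs(hp.mean - pp.mean) < 1e-12
        assert abs(hp.variance - pp.variance) < 1e-12

    def test_match_on_random_draws(self, random_pairs):
        rng = np.random.default_rng(5)
        for pair in random_pairs:
            for a in rng.uniform(1e-3, 1.0, 5):
                tau2 = tau2_from_alpha(float(a), pair.original.se)
                hp = hier_replication_posterior(pair, tau2)
                pp = theta_posterior_fixed_alpha(pair, float(a))
                assert abs(hp.mean - pp.mean) < 1e-12
                assert abs(hp.variance - pp.variance) < 1e-12


class TestMatchedPriors:
    def test_uniform_alpha_gives_shrinkage_like_tau2_prior(self):
        so = 0.05
        t = np.array([0.0, 0.001, 0.01])
        val = matched_tau2_prior_density(t, BetaParams(1, 1), so)
        ref = 2 * so**2 / (2 * t + so**2) ** 2
        assert np.allclose(val, ref, rtol=1e-12)

    @pytest.mark.parametrize("x,y", [(1, 1), (2, 1), (1, 2), (2, 3)])
    def test_tau2_prior_integrates_to_one(self, x, y):
        so = 0.05
        prior = BetaParams(x, y)

        def g(u):  # u = tau2/(tau2 + so^2)
            t = so**2 * u / (1 - u)
            return matched_tau2_prior_density(t, prior, so) * so**2 / (1 - u) ** 2

        val, _ = integrate.quad(g, 0, 1, limit=200)
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("x,y", [(1, 1), (1, 2), (2, 3)])
    def test_I2_prior_integrates_to_one(self, x, y):
        val, _ = integrate.quad(
            lambda i2: matched_I2_prior_density(i2, BetaParams(x, y)), 0, 1, limit=200
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_uniform_alpha_I2_density_value_at_zero(self):
        assert matched_I2_prior_density(0.0, BetaParams(1, 1)) == pytest.approx(2.0)

    def test_tau2_density_matches_transformed_beta_draws(self):
        rng = np.random.default_rng(17)
        x, y, so = 1.0, 2.0, 0.05
        draws = (1.0 / rng.beta(x, y, 100_000) - 1.0) * so**2 / 2.0
        grid = np.quantile(draws, np.linspace(0.005, 0.995, 200))
        emp = np.searchsorted(np.sort(draws), grid) / draws.size
        # numeric CDF of the matched density
        cdf = np.array(
            [
                integrate.quad(
                    lambda t: matched_tau2_prior_density(t, BetaParams(x, y), so),
                    0,
                    g,
                    limit=200,
                )[0]
                for g in grid
            ]
        )
        assert np.max(np.abs(emp - cdf)) < 0.01


class TestTestCorrespondences:
    def test_point_null_reduces_to_replication_density(self, labels):
        pair = labels[2]
        val = hier_marginal_likelihood(pair, PointMass(0.0), PointMass(0.0))
        assert val == pytest.approx(stats.norm.pdf(0.21, 0, 0.06), rel=1e-12)

    def test_complete_discounting_test_reconstructed_exactly(self, labels):
        for pair in labels.values():
            k2 = 2.0
            s = shrinkage_factor(pair.original.se, k2)
            num = hier_marginal_likelihood(pair, NormalParams(0.0, k2), PointMass(0.0))
            den = hier_marginal_likelihood(
                pair,
                NormalParams(s * pair.original.estimate, s * pair.original.variance),
                PointMass(0.0),
            )
            assert num / den == pytest.approx(
                bfdc_point(pair, UnitInformation(k2)).value, abs=1e-12
            )

    def test_partial_discounting_test_reconstructed_by_quadrature(self, labels):
        for pair in labels.values():
            num = hier_marginal_likelihood(pair, OriginalUpdated(), BetaParams(1, 2))
            den = hier_marginal_likelihood(pair, OriginalUpdated(), PointMass(0.0))
            assert num / den == pytest.approx(bfdc_partial(pair, 2.0).value, rel=1e-6)

    def test_generalized_replication_test_reconstructed(self, labels):
        prior = BetaParams(1, 1)
        for pair in labels.values():
            num = hier_marginal_likelihood(pair, PointMass(0.0), PointMass(0.0))
            den = hier_marginal_likelihood(pair, OriginalUpdated(), prior)
            assert num / den == pytest.approx(bf01_effect(pair, prior).value, rel=1e-6)


class TestRandomParameterCorrespondence:
    def hier_theta_marginal(self, thetas, pair, prior):
        """Replication-effect marginal under the matched heterogeneity prior."""
        o = pair.original

        def dens(theta):
            def integrand(t):
                cond = hier_replication_posterior(pair, t)
                w = stats.norm.pdf(
                    pair.replication.estimate,
                    o.estimate,
                    math.sqrt(pair.replication.variance + o.variance + 2 * t),
                )
                return (
                    stats.norm.pdf(theta, cond.mean, cond.sd)
                    * w
                    * matched_tau2_prior_density(t, prior, o.se)
                )

            def sub(u):
                t = o.variance * u / (1 - u)
                return integrand(t) * o.variance / (1 - u) ** 2

            val, _ = integrate.quad(sub, 0, 1, limit=200)
            return val

        vals = np.array([dens(t) for t in thetas])
        norm, _ = integrate.quad(
            lambda u: stats.norm.pdf(
                pair.replication.estimate,
                o.estimate,
                math.sqrt(
                    pair.replication.variance
                    + o.variance
                    + 2 * o.variance * u / (1 - u)
                ),
            )
            * matched_tau2_prior_density(o.variance * u / (1 - u), prior, o.se)
            * o.variance
            / (1 - u) ** 2,
            0,
            1,
            limit=200,
        )
        return vals / norm

    @pytest.mark.parametrize("rep,x,y", [(2, 1.0, 1.0), (3, 2.0, 1.5)])
    def test_theta_marginals_match(self, labels, rep, x, y):
        from powerep import theta_marginal_density

        pair, prior = labels[rep], BetaParams(x, y)
        anchor = theta_posterior_fixed_alpha(pair, 1.0)
        thetas = np.linspace(anchor.mean - 4 * anchor.sd, anchor.mean + 4 * anchor.sd, 21)
        power_route = theta_marginal_density(thetas, pair, prior)
        hier_route = self.hier_theta_marginal(thetas, pair, prior)
        assert np.max(np.abs(hier_route / power_route - 1.0)) < 1e-5


class TestInverseGammaTest:
    def test_vanishing_scale_collapses_hypotheses(self, labels):
        bf = bfdc_ig(labels[1], IGParams(1.0, 1e-10))
        assert bf.value == pytest.approx(1.0, abs=1e-3)

    def test_consistent_evidence_for_compatibility_on_se_ladder(self):
        values = []
        for eps in (1e-2, 1e-3, 1e-4):
            pair = ReplicationPair(StudySummary(0.21, eps), StudySummary(0.21, eps))
            values.append(bfdc_ig(pair, IGParams(1.0, 1.0)).value)
        assert values[0] < 1
        assert values[0] > values[1] > values[2]

    def test_numerator_matches_monte_carlo(self, labels):
        pair = labels[1]
        ig = IGParams(1.0, 0.5)
        rng = np.random.default_rng(23)
        taus = stats.invgamma.rvs(ig.q, scale=ig.r, size=100_000, random_state=rng)
        draws = stats.norm.pdf(
            pair.replication.estimate,
            pair.original.estimate,
            np.sqrt(pair.replication.variance + pair.original.variance + 2 * taus),
        )
        mc, mc_se = float(np.mean(draws)), float(np.std(draws) / math.sqrt(draws.size))
        den = stats.norm.pdf(
            pair.replication.estimate,
            pair.original.estimate,
            math.sqrt(pair.replication.variance + pair.original.variance),
        )
        closed = bfdc_ig(pair, ig).value * den
        assert abs(closed - mc) <= 3 * mc_se

    def test_limit_classification(self):
        cls, _ = bfdc_ig_limit(0.21, 0.21, IGParams(1, 1))
        assert cls == "zero"
        cls, _ = bfdc_ig_limit(0.3, 0.21, IGParams(1, 1))
        assert cls == "infinite"

    def test_limit_prefactor_arithmetic(self):
        _, pref = bfdc_ig_limit(2.21, 0.21, IGParams(0.5, 1e-300))
        # q=1/2, r~0, delta=2: Gamma(1) * 1^{-1} / sqrt(4 pi)
        assert pref == pytest.approx(1.0 / math.sqrt(4 * math.pi), rel=1e-9)


class TestImpliedAlphaPrior:
    @pytest.mark.parametrize("q,r", [(1.0, 1.0), (2.0, 0.5)])
    def test_integrates_to_one(self, q, r):
        so = 1.0
        val, _ = integrate.quad(
            lambda a: ig_implied_alpha_prior(a, IGParams(q, r), so), 0, 1, limit=400
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_matches_transformed_ig_draws(self):
        q, r, so = 1.0, 1.0, 1.0
        rng = np.random.default_rng(29)
        taus = stats.invgamma.rvs(q, scale=r, size=100_000, random_state=rng)
        alphas = np.sort(so**2 / (2 * taus + so**2))
        grid = np.quantile(alphas, np.linspace(0.01, 0.99, 100))
        emp = np.searchsorted(alphas, grid) / alphas.size
        cdf = np.array(
            [
                integrate.quad(
                    lambda a: ig_implied_alpha_prior(a, IGParams(q, r), so),
                    1e-12,
                    g,
                    limit=400,
                )[0]
                for g in grid
            ]
        )
        assert np.max(np.abs(emp - cdf)) < 0.01

    def test_small_original_se_pushes_mass_to_zero(self):
        ig = IGParams(1.0, 1.0)
        masses = []
        for so in (1.0, 0.3, 0.05):
            val, _ = integrate.quad(
                lambda a: ig_implied_alpha_prior(a, ig, so), 1e-12, 0.05, limit=400
            )
            masses.append(val)
        assert masses[0] < masses[1] < masses[2]
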