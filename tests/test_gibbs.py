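"""Sampler unit tests: starting values, determinism, equivariances, and
agreement with an independent general-purpose MCMC implementation."""

import math
import warnings

import numpy as np
import pytest

import dwirepeat as dr
from dwirepeat import gibbs as G

from conftest import FAST_CHAIN


def _table(P, mu=1.0, sa=0.2, sab=0.05, se1=0.02, se2=0.02, seed=0):
    return dr.simulate_table(
        dr.SimulationSpec(P=P, mu=mu, sigma_a=sa, sigma_ab=sab,
                          sigma_eps_1=se1, sigma_eps_2=se2, seed=seed)
    )


class TestInitState:
    def test_constant_data_floors_the_sigmas(self):
        Y = np.full((4, 2, 2), 7.0)
        st = G.init_state(Y)
        assert st.mu == 7.0
        np.testing.assert_array_equal(st.a, 0.0)
        np.testing.assert_array_equal(st.b, 0.0)
        assert 0 < st.sigma_a <= 1e-5 * 7.0
        assert 0 < st.sigma_eps[0] <= 1e-5 * 7.0

    def test_moment_start_near_truth_at_p50(self):
        table = _table(P=50, sa=1.0, sab=0.01, se1=0.01, se2=0.01, seed=4)
        st = G.init_state(table)
        assert abs(st.sigma_a - 1.0) / 1.0 < 0.5

    def test_single_patient_centering(self):
        st = G.init_state(_table(P=1, seed=3))
        assert st.a[0] == 0.0


class TestConditionals:
    def test_zero_residuals_leave_prior_scale(self):
        """With a state that interpolates the data exactly, the error-variance
        conditional scale reduces to the prior scale."""
        Y = np.zeros((3, 2, 2))
        Y += 2.0
        state = G.ModelState(2.0, np.zeros(3), np.zeros(3), 0.1, 0.1, np.array([0.1, 0.1]))
        priors = G.Priors(ig_scale=0.123)
        shape, scale = G.conditional_variance("eps1", state, Y, priors)
        assert scale == pytest.approx(0.123)
        assert shape == pytest.approx(priors.ig_shape + 3.0)

    def test_observer_swap_symmetry_of_conditionals(self):
        Y = _table(P=6, se1=0.02, se2=0.05, seed=9).to_array()
        Ys = Y[:, ::-1, :]
        st = G.init_state(Y)
        sts = G.init_state(Ys)
        np.testing.assert_allclose(sts.b, -st.b, rtol=1e-12)
        priors = G.default_priors(Y)
        # mu conditional invariant under relabeling
        m1, s1 = G.conditional_mu(Y, st.a, st.b, st.sigma_eps, priors)
        m2, s2 = G.conditional_mu(Ys, sts.a, sts.b, sts.sigma_eps, priors)
        assert m2 == pytest.approx(m1, rel=1e-12) and s2 == pytest.approx(s1, rel=1e-12)
        # bias conditional means negate, spread unchanged
        mb1, sb1 = G.conditional_reader_bias(Y, st.mu, st.a, st.sigma_ab, st.sigma_eps)
        mb2, sb2 = G.conditional_reader_bias(Ys, sts.mu, sts.a, sts.sigma_ab, sts.sigma_eps)
        np.testing.assert_allclose(mb2, -mb1, rtol=1e-10)
        assert sb2 == pytest.approx(sb1, rel=1e-12)
        # error-variance conditionals swap
        sh1, sc1 = G.conditional_variance("eps1", st, Y, priors)
        sh2, sc2 = G.conditional_variance("eps2", sts, Ys, priors)
        assert (sh1, sc1) == pytest.approx((sh2, sc2), rel=1e-10)


class TestRunChain:
    def test_bitwise_determinism(self):
        table = _table(P=9, seed=17)
        cfg = dr.ChainConfig(seed=17, **FAST_CHAIN)
        c1 = dr.run_chain(table, config=cfg)
        c2 = dr.run_chain(table, config=cfg)
        assert c1.draws.equals(c2.draws)

    def test_warns_when_retained_below_recommended(self):
        table = _table(P=3, seed=1)
        with pytest.warns(UserWarning, match="retained draws"):
            dr.run_chain(table, config=dr.ChainConfig(n_iterations=600, burn_in=100, thin=1, seed=0))

    def test_location_equivariance(self):
        Y = _table(P=12, seed=21).to_array()
        cfg = dr.ChainConfig(n_iterations=3000, burn_in=500, thin=1, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = dr.run_chain(Y, config=cfg)
            shifted = dr.run_chain(Y + 10.0, config=cfg)
        np.testing.assert_allclose(shifted.array("mu"), base.array("mu") + 10.0, atol=1e-9)
        for name in ("sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"):
            np.testing.assert_allclose(shifted.array(name), base.array(name), rtol=1e-9)

    def test_scale_equivariance(self):
        Y = _table(P=12, seed=21).to_array()
        c = 1000.0
        cfg = dr.ChainConfig(n_iterations=3000, burn_in=500, thin=1, seed=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            base = dr.run_chain(Y, config=cfg)
            scaled = dr.run_chain(c * Y, config=cfg)
        for name in ("mu", "sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"):
            np.testing.assert_allclose(scaled.array(name), c * base.array(name), rtol=1e-9)
        # ICC chains are unit-free
        icc_base = dr.icc_inter(base.array("sigma_a"), base.array("sigma_ab"))
        icc_scaled = dr.icc_inter(scaled.array("sigma_a"), scaled.array("sigma_ab"))
        np.testing.assert_allclose(icc_scaled, icc_base, rtol=1e-9)

    def test_prior_sensitivity_is_small_when_identified(self):
        table = _table(P=50, seed=8)
        cfg = dr.ChainConfig(seed=2, **FAST_CHAIN)
        p1 = G.default_priors(table)
        p2 = G.Priors(p1.mu_mean, p1.mu_sd, p1.ig_shape, p1.ig_scale / 2.0)
        c1 = dr.run_chain(table, priors=p1, config=cfg)
        c2 = dr.run_chain(table, priors=p2, config=cfg)
        for name in ("sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"):
            m1 = dr.kde_mode(c1.array(name))
            m2 = dr.kde_mode(c2.array(name))
            assert abs(m2 - m1) / m1 < 0.05

    def test_rhat_near_one_for_stationary_chains(self):
        table = _table(P=20, seed=30)
        # mu mixes slowest (strong coupling with the patient effects under the
        # systematic scan), so the diagnostic needs full-length chains
        cfg = dr.ChainConfig(seed=9, n_chains=2, **FAST_CHAIN)
        chain = dr.run_chain(table, config=cfg)
        rhat = chain.rhat()
        for name in ("sigma_a", "sigma_ab", "sigma_eps_1", "sigma_eps_2"):
            assert rhat[name] == pytest.approx(1.0, abs=0.05)
        assert rhat["mu"] < 1.5  # slow but convergent

    def test_numerical_failure_carries_block_name(self):
        Y = _table(P=3, seed=1).to_array()
        state = G.init_state(Y)
        bad = G.Priors(mu_mean=math.inf)
        with pytest.raises(G.NumericalError, match="mu"):
            G.gibbs_step(state, Y, bad, np.random.default_rng(0))


class TestAgainstIndependentSampler:
    def test_posterior_means_match_affine_invariant_ensemble_mcmc(self):
        """Dual route: the Gibbs chain against emcee run on the joint
        log-posterior written directly from the model definition."""
        emcee = pytest.importorskip("emcee")
        P = 3
        table = _table(P=P, seed=5)
        Y = table.to_array()
        priors = G.Priors(mu_mean=0.0, mu_sd=10.0, ig_shape=1e-3,
                          ig_scale=1e-3 * float(np.var(Y)))
        cfg = dr.ChainConfig(n_iterations=22_000, burn_in=2_000, thin=2, seed=8)
        chain = dr.run_chain(Y, priors=priors, config=cfg)

        sign = np.array([1.0, -1.0])
        log2pi = math.log(2.0 * math.pi)
        lg = math.lgamma(priors.ig_shape)

        def logpost(th):
            mu, a, b = th[0], th[1:1 + P], th[1 + P:1 + 2 * P]
            u = th[1 + 2 * P:]          # log variances: a, ab, eps1, eps2
            v = np.exp(u)
            mean = mu + a[:, None, None] + (sign * b[:, None])[:, :, None]
            r2 = ((Y - mean) ** 2).sum(axis=(0, 2))          # per observer
            ll = -0.5 * (2 * P) * (u[2] + u[3] + 2 * log2pi) - 0.5 * (r2 / v[2:4]).sum()
            lp = -0.5 * (a @ a) / v[0] - 0.5 * P * (u[0] + log2pi)
            lp += -0.5 * (b @ b) / v[1] - 0.5 * P * (u[1] + log2pi)
            lp += -0.5 * ((mu - priors.mu_mean) / priors.mu_sd) ** 2
            # InvGamma(shape, scale) on each variance, with log-Jacobian u
            lp += np.sum(
                priors.ig_shape * math.log(priors.ig_scale) - lg
                - (priors.ig_shape + 1.0) * u - priors.ig_scale / v + u
            )
            return ll + lp

        ndim = 1 + 2 * P + 4
        st = G.init_state(Y)
        center = np.concatenate([
            [st.mu], st.a, st.b,
            np.log([st.sigma_a**2, st.sigma_ab**2, st.sigma_eps[0]**2, st.sigma_eps[1]**2]),
        ])
        rng = np.random.default_rng(99)
        p0 = center + 0.05 * rng.standard_normal((40, ndim))
        sampler = emcee.EnsembleSampler(40, ndim, logpost)
        sampler.run_mcmc(p0, 4000, progress=False)
        flat = sampler.get_chain(discard=1500, thin=5, flat=True)
        reference = {
            "mu": flat[:, 0],
            "sigma_a": np.exp(flat[:, 1 + 2 * P] / 2),
            "sigma_ab": np.exp(flat[:, 2 + 2 * P] / 2),
            "sigma_eps_1": np.exp(flat[:, 3 + 2 * P] / 2),
            "sigma_eps_2": np.exp(flat[:, 4 + 2 * P] / 2),
        }
        for name, ref in reference.items():
            g = chain.array(name)
            # both samplers carry Monte-Carlo error; 0.25 posterior SD is ~3x
            # the combined MCSE at these effective sample sizes
            assert abs(g.mean() - ref.mean()) < 0.25 * g.std(), name
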