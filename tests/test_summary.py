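import math

import numpy as np
import pandas as pd
import pytest

import dwirepeat as dr
from dwirepeat.gibbs import ChainConfig, PosteriorChain, Priors
from dwirepeat.summary import PCT_REPEATABILITY_FACTOR, SummaryStat


class TestKdeMode:
    def test_constant_draws_returned_verbatim(self):
        assert dr.kde_mode(np.full(50, 5.0)) == 5.0

    def test_normal_mode_matches_mean(self):
        # sharp component: the KDE-mode sampling scatter is ~0.134 * sd *
        # (n/1e5)^(-1/4), so +/-0.05 is a >3-sigma bound only for small sd
        rng = np.random.default_rng(1)
        x = rng.normal(5.0, 0.1, size=10**5)
        assert dr.kde_mode(x, max_draws=10**5) == pytest.approx(5.0, abs=0.05)

    def test_gamma_mode_matches_analytic_maximizer(self):
        rng = np.random.default_rng(2)
        shape, scale = 5.0, 0.2
        x = rng.gamma(shape, scale, size=10**5)
        assert dr.kde_mode(x, max_draws=10**5) == pytest.approx((shape - 1) * scale, abs=0.25)

    def test_operator_matches_independent_kde_implementation(self):
        """Same bandwidth, same grid: argmax must agree with scipy's KDE."""
        from scipy.stats import gaussian_kde

        rng = np.random.default_rng(8)
        x = rng.normal(5.0, 1.0, size=10**4)
        sd = x.std(ddof=1)
        iqr = np.subtract(*np.percentile(x, [75, 25]))
        h = 0.9 * min(sd, iqr / 1.34) * x.size ** (-0.2)
        grid = np.linspace(x.min(), x.max(), 1000)
        reference = grid[np.argmax(gaussian_kde(x, bw_method=h / sd)(grid))]
        spacing = grid[1] - grid[0]
        assert abs(dr.kde_mode(x) - reference) <= spacing + 1e-12

    def test_mixture_mode_in_dominant_component(self):
        rng = np.random.default_rng(3)
        n = 10**5
        comp = rng.random(n) < 0.8
        x = np.where(comp, rng.normal(0.0, 0.1, n), rng.normal(3.0, 0.1, n))
        assert dr.kde_mode(x, max_draws=n) == pytest.approx(0.0, abs=0.05)

    def test_downsampling_is_seeded_and_deterministic(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=30_000)
        assert dr.kde_mode(x, seed=11) == dr.kde_mode(x, seed=11)


class TestCredibleInterval:
    def test_uniform_order_statistics(self):
        rng = np.random.default_rng(5)
        lo, hi = dr.credible_interval(rng.random(10**6))
        assert lo == pytest.approx(0.025, abs=0.002)
        assert hi == pytest.approx(0.975, abs=0.002)

    def test_constant_draws(self):
        assert dr.credible_interval(np.full(10, 3.0)) == (3.0, 3.0)

    def test_linear_interpolation_on_integers(self):
        lo, hi = dr.credible_interval(np.arange(1, 101, dtype=float))
        assert lo == pytest.approx(3.475)
        assert hi == pytest.approx(97.525)


class TestIccCovPct:
    @pytest.mark.parametrize(
        "sa, sab, expected",
        [(1.0, 1.0, 0.5), (1.0, 0.0, 1.0), (2.0, 1.0, 0.8)],
    )
    def test_icc_inter(self, sa, sab, expected):
        assert dr.icc_inter(sa, sab) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "sa, se, expected",
        [(1.0, 0.0, 1.0), (1.0, 1.0, 0.5), (1.0, 3.0, 0.1)],
    )
    def test_icc_intra(self, sa, se, expected):
        assert dr.icc_intra(sa, se) == pytest.approx(expected)

    def test_icc_undefined_when_both_components_vanish(self):
        with pytest.raises(ValueError):
            dr.icc_inter(0.0, 0.0)

    @pytest.mark.parametrize("sigma, mu, expected", [(0.0, 2.0, 0.0), (0.1, 2.0, 0.05)])
    def test_cov(self, sigma, mu, expected):
        assert dr.cov(sigma, mu) == pytest.approx(expected)

    def test_cov_negative_mean_flagged_absolute(self):
        with pytest.warns(UserWarning, match="negative-mean"):
            assert dr.cov(1.0, -2.0) == pytest.approx(0.5)

    def test_cov_zero_mean_draws_excluded_with_count(self):
        with pytest.warns(UserWarning, match="excluded 1"):
            out = dr.cov(np.array([1.0, 1.0]), np.array([2.0, 0.0]))
        np.testing.assert_allclose(out, [0.5])

    @pytest.mark.parametrize(
        "cov_value, expected, tol",
        [
            (0.0, 0.0, 1e-12),
            (1.0, 277.186, 1e-3),
            (0.0319, 8.84, 0.005),
            (0.0881, 24.4, 0.05),
        ],
    )
    def test_pct_repeatability(self, cov_value, expected, tol):
        assert dr.pct_repeatability(cov_value) == pytest.approx(expected, abs=tol)

    def test_pct_repeatability_is_linear(self):
        a, b = 0.013, 0.07
        assert dr.pct_repeatability(a + b) == pytest.approx(
            dr.pct_repeatability(a) + dr.pct_repeatability(b)
        )
        assert PCT_REPEATABILITY_FACTOR == pytest.approx(100 * 1.96 * math.sqrt(2))


def _constant_chain(mu, sa, sab, se1, se2, n=200):
    draws = pd.DataFrame(
        {
            "chain": 0,
            "iteration": np.arange(n),
            "mu": mu,
            "sigma_a": sa,
            "sigma_ab": sab,
            "sigma_eps_1": se1,
            "sigma_eps_2": se2,
        }
    )
    return PosteriorChain(draws=draws, config=ChainConfig(), priors=Priors(), metric="m")


class TestSummarizeReport:
    def test_constant_chain_gives_point_summaries(self):
        rep = dr.summarize_report(_constant_chain(mu=1.0, sa=2.0, sab=1.0, se1=0.5, se2=0.25))
        assert rep.icc_inter == SummaryStat(0.8, 0.8, 0.8)
        assert rep.sigma_ab.mode == 1.0
        assert rep.cov_inter.mode == pytest.approx(1.0)
        assert rep.icc_intra[0].mode == pytest.approx(4.0 / 4.25)

    def test_transform_applied_per_draw_before_summarizing(self, recovery_chain):
        """Mode of the ICC chain, not ICC of the sigma modes."""
        rep = dr.summarize_report(recovery_chain)
        icc_chain = dr.icc_inter(recovery_chain.array("sigma_a"), recovery_chain.array("sigma_ab"))
        assert rep.icc_inter.mode == dr.kde_mode(icc_chain, seed=recovery_chain.config.seed)

    def test_icc_bounds_lie_in_unit_interval(self, recovery_chain):
        rep = dr.summarize_report(recovery_chain)
        for s in (rep.icc_inter, *rep.icc_intra):
            assert 0.0 <= s.ci_low <= s.ci_high <= 1.0

    def test_report_round_trips_through_json(self, recovery_chain):
        rep = dr.summarize_report(recovery_chain)
        back = dr.RepeatabilityReport.from_json(rep.to_json())
        assert back == rep

    def test_display_scaling_flags_keys(self, recovery_chain):
        rep = dr.summarize_report(recovery_chain)
        d = rep.to_dict(display_scale_100=True)
        assert d["sigma_ab_x100"]["mode"] == pytest.approx(100 * rep.sigma_ab.mode)
        assert d["icc_inter"]["mode"] == rep.icc_inter.mode  # ICC never rescaled
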