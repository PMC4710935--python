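"""Monte Carlo probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from esacea import (
    CEAConfig,
    DistFamily,
    load_table3_fixture,
    PSASpec,
    ParamDist,
    ceac,
    default_spec,
    icer_distribution,
    quadrant_of,
    sample_draws,
)
from esacea.psa import PSAResult

BASE_ICER = -6457.5


def fixed_spec(n=1000, seed=0, **overrides):
    dists = dict(
        cost_epob=ParamDist(DistFamily.FIXED, 3288.49),
        cost_cera=ParamDist(DistFamily.FIXED, 3030.19),
        eff_epob=ParamDist(DistFamily.FIXED, 0.55),
        eff_cera=ParamDist(DistFamily.FIXED, 0.59),
    )
    dists.update(overrides)
    return PSASpec(n_iterations=n, seed=seed, **dists)


class TestParamDist:
    def test_lognormal_mean_sd_parameterization(self):
        rng = np.random.default_rng(0)
        d = ParamDist(DistFamily.LOGNORMAL, 3288.49, 200.0)
        x = d.sample(rng, 200_000)
        assert x.mean() == pytest.approx(3288.49, rel=0.005)
        assert x.std() == pytest.approx(200.0, rel=0.02)
        assert (x > 0).all()

    def test_lognormal_nonpositive_mean_rejected(self):
        with pytest.raises(ValueError, match="positive mean"):
            ParamDist(DistFamily.LOGNORMAL, -5.0, 1.0)

    def test_zero_scale_collapses_to_fixed(self):
        rng = np.random.default_rng(0)
        assert (ParamDist(DistFamily.NORMAL, 0.5, 0.0).sample(rng, 10) == 0.5).all()

    def test_beta_moments(self):
        rng = np.random.default_rng(1)
        x = ParamDist(DistFamily.BETA, 0.65, 0.05).sample(rng, 200_000)
        assert x.mean() == pytest.approx(0.65, abs=0.002)
        assert ((x >= 0) & (x <= 1)).all()


def test_paired_bootstrap_correlation_declared_but_unimplemented(config):
    from esacea import Correlation

    spec = fixed_spec(n=10)
    spec.correlation = Correlation.PAIRED_BOOTSTRAP
    with pytest.raises(NotImplementedError):
        sample_draws(spec, config)


class TestQuadrants:
    @pytest.mark.parametrize(
        "dc,de,quadrant",
        [
            (100.0, 0.1, "NE"),
            (-100.0, 0.1, "SE"),
            (-100.0, -0.1, "SW"),
            (100.0, -0.1, "NW"),
            # axis points: adjacent quadrant clockwise
            (0.0, 0.1, "SE"),
            (0.0, -0.1, "NW"),
            (100.0, 0.0, "NE"),
            (-100.0, 0.0, "SW"),
        ],
    )
    def test_assignment(self, dc, de, quadrant):
        assert quadrant_of(dc, de) == quadrant


class TestSampleDraws:
    def test_degenerate_all_fixed(self, config):
        res = sample_draws(fixed_spec(n=2000), config)
        assert res.n_draws == 2000
        assert np.allclose(res.delta_cost, -258.30)
        assert np.allclose(res.delta_eff, 0.04)
        assert res.quadrant_shares["SE"] == 1.0
        assert np.allclose(res.icers, BASE_ICER)

    def test_zero_sd_equals_fixed(self, config):
        spec = fixed_spec(
            n=500,
            cost_cera=ParamDist(DistFamily.LOGNORMAL, 3030.19, 0.0),
            eff_cera=ParamDist(DistFamily.NORMAL, 0.59, 0.0),
        )
        res = sample_draws(spec, config)
        assert np.allclose(res.icers, BASE_ICER)

    def test_reproducibility(self, config):
        spec = default_spec(*load_table3_fixture(), config, n_iterations=2000, seed=11)
        a = sample_draws(spec, config)
        b = sample_draws(spec, config)
        assert np.array_equal(a.delta_cost, b.delta_cost)
        assert np.array_equal(a.delta_eff, b.delta_eff)
        assert a.quadrant_shares == b.quadrant_shares

    def test_quadrant_shares_sum_to_one(self, table3, config):
        spec = default_spec(*table3, config, n_iterations=5000, seed=3)
        res = sample_draws(spec, config)
        assert sum(res.quadrant_shares.values()) == pytest.approx(1.0, abs=0)

    def test_normal_effectiveness_share_matches_closed_form(self, config):
        """Independent normal effectiveness, fixed costs: the probability of a
        positive effectiveness gain has the closed form Phi(dE / (sd*sqrt(2)))."""
        sd = 0.02
        expected = norm.cdf(0.04 / (sd * math.sqrt(2)))
        spec = fixed_spec(
            n=20_000, seed=42,
            eff_epob=ParamDist(DistFamily.NORMAL, 0.55, sd),
            eff_cera=ParamDist(DistFamily.NORMAL, 0.59, sd),
        )
        res = sample_draws(spec, config)
        share = float(np.mean(res.delta_eff > 0))
        se = math.sqrt(expected * (1 - expected) / spec.n_iterations)
        assert abs(share - expected) < 4 * se


class TestCeac:
    def test_degenerate_dominant_draws(self, config):
        res = sample_draws(fixed_spec(n=100), config)
        curve = ceac(res, [0.0, 5000.0, 9276.0, 50000.0])
        assert (curve.probability == 1.0).all()

    def test_lambda_zero_is_cost_saving_fraction(self, table3, config):
        spec = default_spec(*table3, config, n_iterations=4000, seed=9)
        res = sample_draws(spec, config)
        curve = ceac(res, [0.0])
        assert curve.probability.iloc[0] == pytest.approx(
            float(np.mean(res.delta_cost < 0))
        )

    def test_nmb_tie_excluded(self):
        res = PSAResult(
            delta_cost=np.array([-1.0, 1.0]),
            delta_eff=np.array([0.01, 0.01]),
            icers=np.array([-100.0, 100.0]),
            quadrant_shares={"NE": 0.5, "SE": 0.5, "SW": 0.0, "NW": 0.0},
            icer_quantiles=(math.nan,) * 3,
            undefined_share=0.0,
        )
        # at lambda=100: NMB = 2 for the first draw, exactly 0 for the second
        curve = ceac(res, [100.0])
        assert curve.probability.iloc[0] == 0.5


class TestIcerDistribution:
    def test_degenerate(self, config):
        res = sample_draws(fixed_spec(n=200), config)
        summary = icer_distribution(res, BASE_ICER)
        for key in ("q2.5", "median", "q97.5"):
            assert summary[key] == pytest.approx(BASE_ICER)
        assert summary["share_within_10pct"] == 1.0
        assert summary["undefined_share"] == 0.0

    def test_symmetric_two_point_median(self):
        res = PSAResult(
            delta_cost=np.array([100.0, 300.0]),
            delta_eff=np.array([0.1, 0.1]),
            icers=np.array([1000.0, 3000.0]),
            quadrant_shares={"NE": 1.0, "SE": 0.0, "SW": 0.0, "NW": 0.0},
            icer_quantiles=tuple(np.quantile([1000.0, 3000.0], [0.025, 0.5, 0.975])),
            undefined_share=0.0,
        )
        assert icer_distribution(res, 2000.0)["median"] == pytest.approx(2000.0)

    def test_normal_proxy_quantiles_match_closed_form(self, config):
        """ICER draws that are an affine image of a normal variable have
        quantiles matching the analytic normal quantiles."""
        mu_c, sd_c = 500.0, 50.0
        spec = fixed_spec(
            n=4000, seed=5,
            cost_epob=ParamDist(DistFamily.FIXED, 3000.0),
            cost_cera=ParamDist(DistFamily.NORMAL, 3000.0 + mu_c, sd_c),
            eff_epob=ParamDist(DistFamily.FIXED, 0.55),
            eff_cera=ParamDist(DistFamily.FIXED, 0.65),
        )
        res = sample_draws(spec, config)
        # ICER = delta_cost / 0.1 ~ Normal(5000, 500)
        summary = icer_distribution(res, 5000.0)
        se = 500.0 / math.sqrt(4000)
        analytic = norm.ppf([0.025, 0.5, 0.975], loc=5000.0, scale=500.0)
        # quantile SEs: se / density ratio; a loose 3-sigma band on the median
        assert summary["median"] == pytest.approx(analytic[1], abs=3 * se * 1.26)
        assert summary["q2.5"] == pytest.approx(analytic[0], rel=0.05)
        assert summary["q97.5"] == pytest.approx(analytic[2], rel=0.05)

    def test_zero_delta_eff_counted_undefined(self, config):
        spec = fixed_spec(n=50, eff_cera=ParamDist(DistFamily.FIXED, 0.55))
        res = sample_draws(spec, config)
        assert res.undefined_share == 1.0
        assert math.isnan(icer_distribution(res, BASE_ICER)["share_within_10pct"])
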