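"""Distribution parameterization: constructors, round trips, quantiles, fits."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aquarisk.distributions import (
    LognormalSpec,
    TriangularSpec,
    UniformSpec,
    fit_lognormal,
    lognormal_from_mean_sd,
    lognormal_from_median_p95,
    quantile,
    spec_from_dict,
)


class TestMomentMatching:
    def test_nitrate_implied_median(self):
        # mean 112, SD 74 implies median mean^2/sqrt(mean^2+sd^2) ~ 93.4,
        # consistent with the observed network median of 93 mg/L
        spec = lognormal_from_mean_sd(112.0, 74.0)
        closed_form = 112.0**2 / math.sqrt(112.0**2 + 74.0**2)
        assert spec.median == pytest.approx(closed_form, rel=1e-12)
        assert spec.median == pytest.approx(93.4456, abs=1e-3)

    def test_unit_lognormal_round_trip(self):
        spec = lognormal_from_mean_sd(math.exp(0.5), math.sqrt(math.e * (math.e - 1)))
        assert spec.mu == pytest.approx(0.0, abs=1e-12)
        assert spec.sigma == pytest.approx(1.0, abs=1e-12)

    def test_zero_sd_gives_point_mass(self):
        spec = lognormal_from_mean_sd(5.0, 0.0)
        assert spec.degenerate
        assert spec.median == pytest.approx(5.0)
        draws = spec.sample(4, np.random.default_rng(0))
        assert np.allclose(draws, 5.0, rtol=1e-15)
        assert len(set(draws)) == 1  # literally constant

    @pytest.mark.parametrize("mean,sd", [(0.0, 1.0), (-3.0, 1.0), (2.0, -0.1)])
    def test_invalid_moments_rejected(self, mean, sd):
        with pytest.raises(ValueError):
            lognormal_from_mean_sd(mean, sd)

    @given(
        mean=st.floats(1e-3, 1e4),
        cv=st.floats(1e-3, 5.0),
    )
    def test_mean_sd_round_trip_exact(self, mean, cv):
        sd = mean * cv
        spec = lognormal_from_mean_sd(mean, sd)
        assert spec.mean == pytest.approx(mean, rel=1e-10)
        assert spec.sd == pytest.approx(sd, rel=1e-10)


class TestMedianP95:
    @pytest.mark.parametrize(
        "median,p95,mu,sigma",
        [(80.0, 100.0, 4.3820, 0.1357), (12.5, 20.0, 2.5257, 0.2858)],
    )
    def test_body_weight_parameterization(self, median, p95, mu, sigma):
        spec = lognormal_from_median_p95(median, p95)
        assert spec.mu == pytest.approx(mu, abs=5e-4)
        assert spec.sigma == pytest.approx(sigma, abs=5e-4)

    @given(median=st.floats(0.5, 500.0), ratio=st.floats(1.01, 10.0))
    def test_quantile_round_trip(self, median, ratio):
        spec = lognormal_from_median_p95(median, median * ratio)
        assert spec.quantile(0.5) == pytest.approx(median, rel=1e-6)
        assert spec.quantile(0.95) == pytest.approx(median * ratio, rel=1e-6)

    def test_zero_spread_rejected(self):
        for m in (1.0, 80.0):
            with pytest.raises(ValueError):
                lognormal_from_median_p95(m, m)


class TestFit:
    def test_parameter_recovery_on_simulated_data(self, rng):
        draws = rng.lognormal(1.0, 0.5, 10_000)
        spec = fit_lognormal(draws)
        assert spec.mu == pytest.approx(1.0, abs=0.02)
        assert spec.sigma == pytest.approx(0.5, abs=0.02)

    def test_three_point_hand_case(self):
        spec = fit_lognormal([1.0, math.e, math.e**2])
        assert spec.mu == pytest.approx(1.0, abs=1e-12)
        assert spec.sigma == pytest.approx(1.0, abs=1e-12)  # sample log-sd, ddof=1

    def test_identical_values_degenerate(self):
        spec = fit_lognormal([7.0, 7.0, 7.0])
        assert spec.degenerate
        assert spec.median == pytest.approx(7.0)

    def test_too_few_detected_values(self):
        with pytest.raises(ValueError, match="lognormal_from_mean_sd"):
            fit_lognormal([5.0, 4.0, 3.0], censored=[False, True, True])

    def test_censor_substitution_enters_fit(self):
        # censored entries carry the LOD; half-LOD substitution shifts mu down
        full = fit_lognormal([2.0, 4.0, 8.0], censored=[False, False, True],
                             censor_policy="full_lod")
        half = fit_lognormal([2.0, 4.0, 8.0], censored=[False, False, True],
                             censor_policy="half_lod")
        assert half.mu < full.mu


class TestQuantiles:
    def test_body_weight_p95_matches_declared(self):
        spec = lognormal_from_median_p95(80.0, 100.0)
        assert quantile(spec, 0.95) == pytest.approx(100.0, rel=1e-6)

    def test_uniform_midpoint(self):
        assert quantile(UniformSpec(0.5, 2.0), 0.5) == pytest.approx(1.25)

    @pytest.mark.parametrize(
        "spec",
        [
            LognormalSpec(1.3, 0.4),
            UniformSpec(0.25, 1.0),
            TriangularSpec(0.5, 1.0, 2.0),
        ],
        ids=["lognormal", "uniform", "triangular"],
    )
    def test_median_is_p50(self, spec):
        assert quantile(spec, 0.5) == pytest.approx(spec.median, rel=1e-12)

    @pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
    def test_probability_domain(self, p):
        with pytest.raises(ValueError):
            quantile(LognormalSpec(0.0, 1.0), p)

    def test_triangular_quantiles_match_sample(self, rng):
        spec = TriangularSpec(0.5, 1.0, 2.0)
        draws = spec.sample(200_000, rng)
        for p in (0.1, 0.5, 0.9):
            assert np.quantile(draws, p) == pytest.approx(spec.quantile(p), rel=0.02)


class TestSerialization:
    @pytest.mark.parametrize(
        "spec",
        [LognormalSpec(0.3, 0.7), UniformSpec(0.5, 2.0), TriangularSpec(1, 2, 3)],
        ids=["lognormal", "uniform", "triangular"],
    )
    def test_dict_round_trip(self, spec):
        assert spec_from_dict(spec.to_dict()) == spec

    def test_unknown_tag(self):
        with pytest.raises(ValueError):
            spec_from_dict({"type": "beta", "a": 1, "b": 2})
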