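"""Growth-rate estimation, Ratkowsky fitting and the ramp protocol."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from aletools.growth import (
    GrowthModelError,
    GrowthRatePoint,
    RampProtocol,
    RatkowskyFit,
    compute_growth_rate,
    determine_max_tolerated_temperature,
    estimate_c,
    estimate_linear,
    fit_ratkowsky,
    growth_rate_curve,
    ratkowsky_mu,
)
from aletools.io_formats import ODTimeSeries
from aletools.simulate import (
    PopulationModel,
    make_sim_provider,
    simulate_growth_experiment,
)


def series_of(readings, strain="s"):
    return ODTimeSeries(strain, tuple(readings))


def sample_points(fit, fractions=(0.25, 0.35, 0.45, 0.55, 0.65, 0.75, 0.85,
                                  0.90, 0.94, 0.97, 0.99)):
    """Noise-free growth-rate points sampled from a generating model."""
    temps = [fit.t_min + f * (fit.t_max - fit.t_min) for f in fractions]
    return [GrowthRatePoint(t, ratkowsky_mu(fit, t), 4) for t in temps]


def make_fit(b, c, t_min, t_max):
    return RatkowskyFit(b=b, c=c, t_min=t_min, t_max=t_max, sse=0.0,
                        n_points_linear=0, n_points_supra=0)


class TestComputeGrowthRate:
    def test_doubling_in_two_days(self):
        s = series_of([(0, 0.5, 35, 1), (2, 1.0, 35, 1)])
        assert compute_growth_rate(s, 35).mu == pytest.approx(math.log(2) / 2)

    def test_no_growth_is_zero(self):
        s = series_of([(0, 0.5, 35, 1), (2, 0.5, 35, 1)])
        assert compute_growth_rate(s, 35).mu == 0.0

    def test_invariant_under_od_rescaling(self):
        readings = [(0, 0.4, 35, 1), (1, 0.6, 35, 1), (2, 0.9, 35, 1)]
        mu1 = compute_growth_rate(series_of(readings), 35).mu
        scaled = [(t, 7.3 * od, T, d) for t, od, T, d in readings]
        assert compute_growth_rate(series_of(scaled), 35).mu == pytest.approx(mu1)

    def test_dilution_unwound(self):
        # OD doubles daily; diluted 4x before the day-2 reading
        s = series_of([(0, 0.5, 35, 1), (1, 1.0, 35, 1), (2, 0.5, 35, 4.0)])
        assert compute_growth_rate(s, 35).mu == pytest.approx(math.log(2))

    def test_plateau_absent_raises(self):
        s = series_of([(0, 0.5, 35, 1), (1, 1.0, 35, 1)])
        with pytest.raises(GrowthModelError, match="no readings"):
            compute_growth_rate(s, 40)

    def test_noise_free_simulation_round_trip(self):
        true = make_fit(0.0025, 0.3, 3.0, 46.0)
        model = PopulationModel(strains=(("s", true),))
        (series,) = simulate_growth_experiment(model, [30.0], noise_sigma=0.0,
                                               seed=0)
        assert compute_growth_rate(series, 30.0).mu == pytest.approx(
            ratkowsky_mu(true, 30.0), abs=1e-12
        )


class TestEstimateLinear:
    def test_exact_line(self):
        pts = [GrowthRatePoint(13, 0.25, 3), GrowthRatePoint(23, 1.00, 3)]
        b, t_min = estimate_linear(pts)
        assert b == pytest.approx(0.0025)
        assert t_min == pytest.approx(3.0)

    def test_duplicated_points_leave_estimate_unchanged(self):
        pts = [GrowthRatePoint(13, 0.25, 3), GrowthRatePoint(23, 1.00, 3)]
        assert estimate_linear(pts) == pytest.approx(estimate_linear(pts * 2))

    def test_six_point_recovery(self):
        b_true, t_min_true = 0.0035, 2.8
        pts = [
            GrowthRatePoint(T, b_true * (T - t_min_true) ** 2, 3)
            for T in (10, 15, 20, 25, 30, 35)
        ]
        b, t_min = estimate_linear(pts)
        assert abs(b - b_true) < 1e-9
        assert abs(t_min - t_min_true) < 1e-6

    def test_equal_temperatures_rejected(self):
        pts = [GrowthRatePoint(20, 0.3, 3), GrowthRatePoint(20, 0.4, 3)]
        with pytest.raises(GrowthModelError):
            estimate_linear(pts)

    def test_decreasing_rates_rejected(self):
        pts = [GrowthRatePoint(10, 1.0, 3), GrowthRatePoint(20, 0.25, 3)]
        with pytest.raises(GrowthModelError, match="slope"):
            estimate_linear(pts)


class TestEstimateC:
    def test_exact_inversion_single_point(self):
        true = make_fit(0.0025, 0.3, 3.0, 46.0)
        pts = [GrowthRatePoint(44.0, ratkowsky_mu(true, 44.0), 3)]
        assert estimate_c(pts, true.b, true.t_min, true.t_max) == pytest.approx(
            0.3, abs=1e-12
        )

    def test_point_above_ceiling_skipped_then_error(self):
        # mu >= b*(T - t_min)^2 is unusable; with no other point this errors
        pts = [GrowthRatePoint(44.0, 0.0025 * 41**2 * 1.5, 3)]
        with pytest.raises(GrowthModelError, match="no usable"):
            estimate_c(pts, 0.0025, 3.0, 46.0)

    def test_four_point_noise_free_recovery(self):
        true = make_fit(0.0025, 0.3, 3.0, 46.0)
        pts = [GrowthRatePoint(T, ratkowsky_mu(true, T), 3)
               for T in (42.0, 43.0, 44.0, 45.0)]
        c = estimate_c(pts, true.b, true.t_min, true.t_max)
        assert abs(c - 0.3) < 1e-9


class TestRatkowskyMu:
    def test_zero_at_cardinal_temperatures(self):
        fit = make_fit(0.0025, 0.3, 3.0, 46.0)
        assert ratkowsky_mu(fit, 3.0) == 0.0
        assert ratkowsky_mu(fit, 46.0) == 0.0

    def test_hand_evaluated_value(self):
        fit = make_fit(0.0025, 0.3, 3.0, 46.0)
        expected = 0.0025 * 41**2 * (1 - math.exp(-0.6))
        assert ratkowsky_mu(fit, 44.0) == pytest.approx(expected, rel=1e-12)

    @given(
        b=st.floats(0.001, 0.01),
        c=st.floats(0.05, 0.5),
        t_min=st.floats(0, 10),
        t_max=st.floats(40, 50),
        frac=st.floats(1e-6, 1 - 1e-6),
    )
    @settings(derandomize=True, max_examples=100)
    def test_positive_strictly_inside_range(self, b, c, t_min, t_max, frac):
        fit = make_fit(b, c, t_min, t_max)
        T = t_min + frac * (t_max - t_min)
        inside = t_min < T < t_max
        mu = ratkowsky_mu(fit, T)
        assert (mu > 0) == inside or mu == 0 and not inside
        assert ratkowsky_mu(fit, t_min - 1.0) == 0.0
        assert ratkowsky_mu(fit, t_max + 1.0) == 0.0


class TestFitRatkowsky:
    def test_noise_free_parameter_recovery(self):
        true = make_fit(0.0035, 0.25, 2.8, 45.5)
        fit = fit_ratkowsky(sample_points(true))
        assert abs(fit.b - true.b) < 1e-6
        assert abs(fit.t_min - true.t_min) < 1e-6
        assert abs(fit.c - true.c) < 1e-3
        assert abs(fit.t_max - true.t_max) < 1e-3

    def test_predicted_rate_vanishes_at_fitted_cardinals(self):
        fit = fit_ratkowsky(sample_points(make_fit(0.003, 0.2, 4.0, 44.0)))
        assert ratkowsky_mu(fit, fit.t_min) == 0.0
        assert ratkowsky_mu(fit, fit.t_max) == 0.0

    def test_mix_curve_lies_between_member_curves(self):
        # a pooled culture grows at the average of its members' rates, so the
        # fitted mix curve must sit between the member curves everywhere
        a = make_fit(0.0030, 0.25, 3.0, 44.5)
        b = make_fit(0.0030, 0.25, 3.0, 45.5)
        model = PopulationModel(strains=(("a", a), ("b", b)),
                                mix_proportions=(0.5, 0.5))
        temps = [round(3.0 + f * (44.5 - 3.0), 3) for f in
                 (0.25, 0.4, 0.55, 0.7, 0.8, 0.88, 0.93, 0.97, 0.99)]
        series = simulate_growth_experiment(model, temps, noise_sigma=0.0,
                                            seed=0)
        mix = next(s for s in series if s.strain_id == "mix")
        fit = fit_ratkowsky(growth_rate_curve(mix))
        for T in np.linspace(10, 44.0, 30):
            lo = min(ratkowsky_mu(a, T), ratkowsky_mu(b, T))
            hi = max(ratkowsky_mu(a, T), ratkowsky_mu(b, T))
            assert lo - 5e-3 <= ratkowsky_mu(fit, T) <= hi + 5e-3

    def test_too_few_points_rejected(self):
        true = make_fit(0.003, 0.2, 4.0, 44.0)
        with pytest.raises(GrowthModelError):
            fit_ratkowsky(sample_points(true, fractions=(0.3, 0.6, 0.9)))


class TestMaxToleratedTemperature:
    def test_threshold_crossing_from_generating_model(self):
        # pick a model whose rate crosses 0.05/day between 45.0 and 45.1
        true = make_fit(0.0025, 0.3, 3.0, 45.13)
        assert ratkowsky_mu(true, 45.0) > 0.05 > ratkowsky_mu(true, 45.1)
        provider = make_sim_provider(true, noise_sigma=0.0, seed=0)
        protocol = RampProtocol(start_temp=44.0, stability_threshold=0.05)
        assert determine_max_tolerated_temperature(provider, protocol) == 45.0

    def test_zero_threshold_returns_t_max_on_grid(self):
        true = make_fit(0.0025, 0.3, 3.0, 45.67)
        provider = make_sim_provider(true, noise_sigma=0.0, seed=0)
        protocol = RampProtocol(start_temp=44.0, stability_threshold=0.0)
        assert determine_max_tolerated_temperature(provider, protocol) == 45.6

    def test_ordering_follows_generating_t_max(self):
        protocol = RampProtocol(start_temp=43.0, stability_threshold=0.05)
        results = []
        for t_max in (44.8, 45.8):
            provider = make_sim_provider(make_fit(0.003, 0.25, 3.0, t_max),
                                         noise_sigma=0.0, seed=0)
            results.append(
                determine_max_tolerated_temperature(provider, protocol)
            )
        assert results[0] < results[1]

    def test_unstable_at_start_raises(self):
        true = make_fit(0.0025, 0.3, 3.0, 44.0)
        provider = make_sim_provider(true, noise_sigma=0.0, seed=0)
        protocol = RampProtocol(start_temp=46.0, stability_threshold=0.05)
        with pytest.raises(GrowthModelError, match="not viable"):
            determine_max_tolerated_temperature(provider, protocol)
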