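"""Waveform functionals: decline rates, cost bounds, rhythmicity, similarity."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rhythmdeg.synthetic import WaveformSpec, make_profile
from rhythmdeg.waveform import (
    CostSummary,
    PeriodicProfile,
    RateSeries,
    alpha_D,
    atp_payoff_fraction,
    cg,
    degradation_floor,
    half_life,
    log_decline_rate,
    min_constant_rate,
    similarity_S,
    synthesis_cost,
    synthesis_from_balance,
)

OMEGA = 2 * math.pi / 24


def sinusoid(b, mean=1.0):
    return PeriodicProfile.from_callable(
        lambda t: mean * (1 + b * np.sin(OMEGA * t)),
        dfun=lambda t: mean * b * OMEGA * np.cos(OMEGA * t))


class TestLogDecline:
    def test_constant_profile_zero_everywhere(self):
        prof = PeriodicProfile.constant(2.5)
        assert np.allclose(log_decline_rate(prof, np.linspace(0, 24, 25)), 0)

    def test_exponential_segment_recovers_rate(self):
        # forced decay segment evaluated away from the wrap point
        prof = PeriodicProfile(lambda t: np.exp(-0.1 * np.asarray(t)),
                               lambda t: -0.1 * np.exp(-0.1 * np.asarray(t)))
        assert log_decline_rate(prof, 12.0) == pytest.approx(0.1, rel=1e-12)

    def test_sinusoid_peak_matches_closed_form(self):
        # dense-grid oracle agrees with b*omega/sqrt(1-b^2)
        b = 0.5
        prof = sinusoid(b)
        tt = np.linspace(0, 24, 100_001)
        oracle = np.max(-prof.derivative(tt) / prof(tt))
        closed = b * OMEGA / math.sqrt(1 - b ** 2)
        assert oracle == pytest.approx(closed, rel=1e-6)
        assert min_constant_rate(prof) == pytest.approx(closed, rel=1e-8)
        assert min_constant_rate(prof) == pytest.approx(0.15115, abs=5e-5)

    @pytest.mark.parametrize("b_lo,b_hi", [(0.2, 0.4), (0.4, 0.6), (0.6, 0.8)])
    def test_sharper_waveform_larger_minimum_rate(self, b_lo, b_hi):
        assert min_constant_rate(sinusoid(b_hi)) > min_constant_rate(sinusoid(b_lo))

    def test_floor_zero_on_rising_phase_and_bounds_feasible_rate(self):
        prof = sinusoid(0.5)
        rising = 3.0  # x' > 0 there
        falling = 15.0
        assert degradation_floor(prof, rising) == 0.0
        assert degradation_floor(prof, falling) == pytest.approx(
            log_decline_rate(prof, falling))
        # any r matching the floor pointwise keeps g >= 0
        # (tolerance covers linear resampling error around the floor's kink)
        rates = RateSeries.from_callable(lambda t: degradation_floor(prof, t))
        g = synthesis_from_balance(prof, rates)
        assert g.rates.min() >= -1e-4


class TestCost:
    def test_constant_profile_cg_zero(self):
        assert cg(PeriodicProfile.constant(3.0)) == 0.0

    def test_sinusoid_cg_and_scaling(self):
        prof = sinusoid(0.5)
        assert cg(prof) == pytest.approx(0.15115, abs=5e-5)
        assert cg(prof.scaled(3.0)) == pytest.approx(3 * cg(prof), rel=1e-9)

    def test_constant_inputs_cost_is_product(self):
        prof = PeriodicProfile.constant(2.0)
        summary = synthesis_cost(prof, RateSeries.constant(0.25))
        assert summary.mean_degradation == pytest.approx(0.5, rel=1e-9)
        assert summary.mean_synthesis == pytest.approx(0.5, rel=1e-9)
        assert summary.per_period_amount == pytest.approx(12.0, rel=1e-9)

    def test_min_constant_rate_cost_equals_cg(self, sin_profile):
        r = RateSeries.constant(min_constant_rate(sin_profile))
        summary = synthesis_cost(sin_profile, r)
        assert summary.mean_degradation == pytest.approx(summary.cg, rel=1e-6)

    def test_pointwise_floor_costs_at_most_cg(self, rng):
        # 100 random synthetic profiles: floor-following cost never beats cg
        for _ in range(100):
            spec = WaveformSpec(rel_amplitude=float(rng.uniform(0.1, 0.85)),
                                sharpness=float(rng.uniform(1, 3)),
                                asymmetry=float(rng.uniform(-0.7, 0.7)),
                                phase=float(rng.uniform(0, 24)))
            prof = make_profile(spec)
            floor = RateSeries.from_callable(lambda t: degradation_floor(prof, t))
            assert synthesis_cost(prof, floor).mean_degradation <= cg(prof) * (1 + 1e-6)

    def test_balance_identity_mean_g_equals_mean_rx(self, sin_profile):
        rates = RateSeries.from_callable(
            lambda t: 0.4 + 0.2 * np.cos(OMEGA * np.asarray(t) + 1.0))
        summary = synthesis_cost(sin_profile, rates)
        rel = abs(summary.mean_synthesis - summary.mean_degradation)
        assert rel / summary.mean_degradation < 1e-6

    def test_negative_g_flagged_not_raised(self, sin_profile):
        summary = synthesis_cost(sin_profile, RateSeries.constant(0.0))
        assert isinstance(summary, CostSummary)
        assert not summary.feasible
        assert summary.min_g < 0


class TestAlphaD:
    def test_examples(self):
        assert alpha_D(RateSeries.constant(0.7)) == 0.0
        r = RateSeries.from_callable(lambda t: 1.0 + 0.3 * np.cos(OMEGA * np.asarray(t)))
        assert alpha_D(r) == pytest.approx(0.6 / 1.3, abs=1e-4)
        # a 62.5% trough-to-peak increase means peak/trough = 1.625
        r = RateSeries(np.array([0.0, 12.0]), np.array([1.625, 1.0]))
        assert alpha_D(r) == pytest.approx(0.625 / 1.625, rel=1e-12)

    def test_all_zero_rates_undefined(self):
        with pytest.raises(ValueError):
            alpha_D(RateSeries.constant(0.0))

    @given(st.floats(0.1, 100.0))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_scale_invariance(self, factor):
        base = RateSeries(np.arange(0, 24, 1.0),
                          1.0 + 0.5 * np.sin(OMEGA * np.arange(0, 24, 1.0)))
        scaled = RateSeries(base.times, factor * base.rates)
        assert alpha_D(scaled) == pytest.approx(alpha_D(base), rel=1e-9)


class TestSimilarity:
    def test_identical_and_ratio(self):
        r = RateSeries.constant(0.5)
        assert similarity_S(r, r) == pytest.approx(1.0)
        assert similarity_S(RateSeries.constant(1.0),
                            RateSeries.constant(2.0)) == pytest.approx(0.5)

    def test_symmetry_and_quadrature_oracle(self, rng):
        for _ in range(10):
            tt = np.arange(0, 24, 0.25)
            a = RateSeries(tt, rng.uniform(0.1, 1.0, len(tt)))
            b = RateSeries(tt, rng.uniform(0.1, 1.0, len(tt)))
            s_ab = similarity_S(a, b)
            assert s_ab == pytest.approx(similarity_S(b, a), rel=1e-12)
            # fine-grid quadrature oracle
            tq = np.arange(0, 24, 0.005)
            oracle = (np.trapezoid(np.minimum(a(tq), b(tq)), tq)
                      / np.trapezoid(np.maximum(a(tq), b(tq)), tq))
            assert similarity_S(a, b, step=0.005) == pytest.approx(oracle, abs=1e-6)
            assert s_ab == pytest.approx(oracle, abs=5e-3)  # default 0.05 h grid
            # invariance under common rescaling
            a2 = RateSeries(tt, 7.3 * a.rates)
            b2 = RateSeries(tt, 7.3 * b.rates)
            assert similarity_S(a2, b2) == pytest.approx(s_ab, rel=1e-12)

    def test_zero_series_undefined(self):
        z = RateSeries.constant(0.0)
        with pytest.raises(ValueError):
            similarity_S(z, z)


class TestBalanceAndHalfLife:
    def test_synthesis_from_balance_constant(self):
        prof = PeriodicProfile.constant(2.0)
        g = synthesis_from_balance(prof, RateSeries.constant(0.3))
        assert np.allclose(g.rates, 0.6)

    def test_zero_rate_gives_derivative(self, sin_profile):
        g = synthesis_from_balance(sin_profile, RateSeries.constant(0.0))
        expect = sin_profile.derivative(g.times)
        assert np.allclose(g.rates, expect, atol=1e-9)
        assert g.rates.min() < 0  # falling phase infeasible without degradation

    def test_half_life_examples_and_involution(self):
        assert half_life(math.log(2)) == pytest.approx(1.0, rel=1e-12)
        assert half_life(1.3) == pytest.approx(0.5332, abs=5e-4)
        assert half_life(2.6) == pytest.approx(half_life(1.3) / 2, rel=1e-12)
        for r in (0.01, 0.7, 13.0):
            assert half_life(half_life(r)) == pytest.approx(r, rel=1e-12)
        with pytest.raises(ValueError):
            half_life(0.0)

    @pytest.mark.parametrize("n,N,expect", [(4, 100, 0.01), (0, 50, 0.0),
                                            (1, 500, 5e-4)])
    def test_atp_payoff(self, n, N, expect):
        assert atp_payoff_fraction(n, N) == pytest.approx(expect, rel=1e-12)


class TestPeriodicProfileContract:
    def test_modulo_evaluation_and_wrap_continuity(self, sin_profile):
        t = 7.3
        assert sin_profile(t) == pytest.approx(sin_profile(t + 24), rel=1e-12)
        assert sin_profile(t) == pytest.approx(sin_profile(t - 48), rel=1e-12)
        eps = 1e-6
        assert sin_profile.derivative(eps) == pytest.approx(
            sin_profile.derivative(24 - eps), abs=1e-3)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            PeriodicProfile.from_callable(lambda t: np.sin(OMEGA * np.asarray(t)))

    @given(b=st.floats(0.05, 0.85), sharp=st.floats(1.0, 3.5),
           asym=st.floats(-0.8, 0.8), phase=st.floats(0.0, 24.0))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_generated_profiles_valid(self, b, sharp, asym, phase):
        prof = make_profile(WaveformSpec(rel_amplitude=b, sharpness=sharp,
                                         asymmetry=asym, phase=phase))
        tt = np.linspace(0, 48, 97)
        assert np.all(prof(tt) > 0)
        assert np.allclose(prof(tt), prof(tt + 24), rtol=1e-9)

    def test_csv_round_trip(self, tmp_path, sin_profile):
        path = tmp_path / "profile.csv"
        sin_profile.to_csv(path, step=0.25)
        back = PeriodicProfile.read_csv(path)
        tt = np.linspace(0, 24, 49)
        assert np.allclose(back(tt), sin_profile(tt), rtol=1e-5)
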