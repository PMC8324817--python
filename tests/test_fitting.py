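"""Empirical pipeline: ingestion, smoothing, rE construction, scans."""

import numpy as np
import pytest
from scipy.stats import kstest

from rhythmdeg.fitting import (
    EmpiricalSeries,
    build_empirical_rate_profile,
    cost_similarity_association,
    fit_profile_spline,
    moving_average,
    normalize_series,
    read_timeseries,
    sample_parameters,
    scan,
    ScanRecord,
    tim_stage,
)
from rhythmdeg.synthetic import (WaveformSpec, make_degradation_truth,
                                 make_noisy_timeseries, make_profile)
from rhythmdeg.waveform import PeriodicProfile, argmax_decline, similarity_S


def series(times, values, reps=None, **kw):
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    reps = np.ones(len(times), dtype=int) if reps is None else np.asarray(reps)
    return EmpiricalSeries(times, values, reps, **kw)


class TestReadTimeseries:
    def test_two_column_and_shuffled(self, tmp_path):
        p = tmp_path / "ts.csv"
        p.write_text("time_h,value\n12,2.0\n0,1.0\n6,1.5\n")
        s = read_timeseries(p)
        assert np.array_equal(s.times, [0, 6, 12])
        assert np.array_equal(s.replicates, [1, 1, 1])

    def test_empty_and_duplicates_rejected(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text("time_h,value\n")
        with pytest.raises(ValueError):
            read_timeseries(empty)
        dup = tmp_path / "dup.csv"
        dup.write_text("time_h,value,replicate\n0,1,1\n0,2,1\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_timeseries(dup)

    def test_unparseable_row_reports_line(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("time_h,value\n0,1.0\nsix,2.0\n")
        with pytest.raises(ValueError, match="line"):
            read_timeseries(bad)


class TestMovingAverage:
    def test_constant_unchanged(self):
        s = series([0, 3, 6, 9], [2, 2, 2, 2])
        out = moving_average(s, 3.0)
        assert np.allclose(out.values, 2.0)

    def test_three_point_toy(self):
        s = series([0, 1, 2], [1, 4, 1])
        out = moving_average(s, 2.0)
        assert out.values[1] == pytest.approx(2.0)

    def test_small_window_recovers_replicate_means(self):
        s = series([0, 0, 6, 6], [1, 3, 2, 4], reps=[1, 2, 1, 2])
        out = moving_average(s, 0.5)
        assert np.allclose(out.values, [2.0, 3.0])

    def test_window_wider_than_span_rejected(self):
        with pytest.raises(ValueError):
            moving_average(series([0, 3], [1, 2]), 10.0)

    def test_periodic_wrap(self):
        s = series([0, 6, 12, 18], [1, 2, 3, 2], periodic=True)
        out = moving_average(s, 13.0)
        # t=0 window wraps: {18, 0, 6} -> (2+1+2)/3
        assert out.values[0] == pytest.approx(5 / 3)


class TestSplineAndNormalize:
    def test_interpolating_spline_reproduces_samples(self):
        tt = np.arange(0, 24, 2.0)
        vals = 2.0 + np.sin(2 * np.pi * tt / 24)
        prof = fit_profile_spline(series(tt, vals), smoothing=0.0)
        assert np.allclose(prof(tt), vals, atol=1e-6)

    def test_constant_data_constant_profile(self):
        tt = np.arange(0, 24, 3.0)
        for s in (0.0, 5.0):
            prof = fit_profile_spline(series(tt, np.full(len(tt), 3.0)),
                                      smoothing=s)
            assert np.allclose(prof(np.linspace(0, 24, 49)), 3.0, rtol=1e-6)

    def test_residual_nondecreasing_in_smoothing(self, rng):
        tt = np.arange(0, 24, 1.5)
        vals = 2 + np.sin(2 * np.pi * tt / 24) + rng.normal(0, 0.15, len(tt))
        resid = []
        for s in (0.0, 0.5, 2.0, 8.0):
            prof = fit_profile_spline(series(tt, vals), smoothing=s)
            resid.append(np.sum((prof(tt) - vals) ** 2))
        assert all(b >= a - 1e-9 for a, b in zip(resid, resid[1:]))

    def test_normalize_modes(self):
        s = series([0, 6, 18], [1.0, 3.0, 2.0])
        at = normalize_series(s, "at_time", 18.0)
        assert at.values[2] == pytest.approx(1.0)
        # scaling input leaves at_time output unchanged
        s2 = series([0, 6, 18], [7.0, 21.0, 14.0])
        assert np.allclose(normalize_series(s2, "at_time", 18.0).values,
                           at.values)
        to = normalize_series(s, "to_value", 100.0)
        assert np.allclose(to.values, s.values / 100.0)
        with pytest.raises(ValueError):
            normalize_series(s, "at_time", 3.0)


class TestTimStage:
    def test_peak_phase_matches_generator_truth(self):
        prof = make_profile(WaveformSpec(rel_amplitude=0.5, phase=4.0))
        abundance = make_noisy_timeseries(prof, np.arange(0, 24, 1.5), 0.0, 2,
                                          seed=1)
        ubiq = series([0, 6, 12, 18], [1.0, 0.4, 0.2, 0.6],
                      kind="ubiquitinated_fraction")
        res = tim_stage(abundance, ubiq, {"smoothing": 0.001})
        truth = argmax_decline(prof)
        diff = abs(res["peak_phase_h"] - truth)
        assert min(diff, 24 - diff) < 0.5
        assert not res["degenerate"]

    def test_constant_abundance_flagged_degenerate(self):
        abundance = series(np.arange(0, 24, 3.0), np.full(8, 2.0))
        ubiq = series([0, 12], [1.0, 0.5])
        res = tim_stage(abundance, ubiq)
        assert res["degenerate"]

    def test_ubiq_rescaled_to_one_at_reference(self):
        prof = make_profile(WaveformSpec(rel_amplitude=0.3))
        abundance = make_noisy_timeseries(prof, np.arange(0, 24, 2.0), 0.0, 1,
                                          seed=0)
        ubiq = series([0, 0, 12], [80.0, 120.0, 40.0], reps=[1, 2, 1])
        res = tim_stage(abundance, ubiq)
        out = res["ubiq_rescaled"]
        assert out.values[out.times == 0].mean() == pytest.approx(1.0)


class TestEmpiricalRateProfile:
    def test_points_above_floor_give_piecewise_linear(self):
        prof = PeriodicProfile.constant(1.0)  # floor is 0 everywhere
        pts = series([4.0, 12.0], [0.2, 0.6], kind="rate")
        rE = build_empirical_rate_profile(pts, prof)
        assert rE(8.0) == pytest.approx(0.4, abs=1e-6)
        # left of the span the continued segment falls below the smallest
        # observed rate and is clamped there; right of it the terminal
        # segment keeps rising
        assert rE(0.0) == pytest.approx(0.2, abs=1e-9)
        assert rE(20.0) == pytest.approx(0.6 + 0.05 * 8, abs=1e-6)

    def test_floor_wins_where_points_dip_below(self):
        prof = make_profile(WaveformSpec(rel_amplitude=0.6))
        from rhythmdeg.waveform import degradation_floor
        t_fall = float(np.argmax([degradation_floor(prof, t)
                                  for t in np.arange(0, 24, 0.1)])) * 0.1
        floor_peak = degradation_floor(prof, t_fall)
        pts = series([t_fall, (t_fall + 12) % 24], [floor_peak / 10] * 2,
                     kind="rate")
        rE = build_empirical_rate_profile(pts, prof)
        assert rE(t_fall) == pytest.approx(floor_peak, rel=1e-2)

    def test_everywhere_at_least_floor_and_min_rate(self):
        prof = make_profile(WaveformSpec(rel_amplitude=0.5))
        pts = series([2.0, 9.0, 17.0], [0.05, 0.3, 0.1], kind="rate")
        rE = build_empirical_rate_profile(pts, prof)
        from rhythmdeg.waveform import degradation_floor
        tt = rE.times
        assert np.all(rE.rates >= np.asarray(degradation_floor(prof, tt)) - 1e-9)
        assert np.all(rE.rates >= 0.05 - 1e-12)


class TestSampling:
    RANGES = {"u_bar": {"low": 0.01, "high": 1.0, "scale": "log"},
              "r0": {"low": 0.5, "high": 2.0, "scale": "linear"}}

    def test_seed_reproducibility_and_bounds(self):
        a = sample_parameters(self.RANGES, 50, seed=7)
        b = sample_parameters(self.RANGES, 50, seed=7)
        assert a == b
        assert all(0.01 <= s["u_bar"] <= 1.0 for s in a)
        assert all(0.5 <= s["r0"] <= 2.0 for s in a)

    def test_linear_scale_uniformity(self):
        draws = [s["r0"] for s in sample_parameters(self.RANGES, 10_000, seed=3)]
        stat = kstest(draws, "uniform", args=(0.5, 1.5))
        assert stat.pvalue > 0.01

    def test_degenerate_range_constant(self):
        r = {"q": {"low": 5.0, "high": 5.0, "scale": "linear"}}
        assert all(s["q"] == 5.0 for s in sample_parameters(r, 5, seed=0))

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            sample_parameters({"q": {"low": 2.0, "high": 1.0}}, 3, seed=0)


BASE_SAMPLE = {"u_bar": 0.22, "a0": 234.9, "a1": 17880.6, "a2": 15347.2,
               "q": 262.2, "r0": 1.3}


class TestScan:
    def test_self_similarity_is_one(self, sin_profile):
        from rhythmdeg.params import UbParams
        sim, _ = make_degradation_truth(sin_profile, UbParams(**BASE_SAMPLE))
        rE = sim.rate_series()
        records = scan(sin_profile, [dict(BASE_SAMPLE, _index=0)], rE=rE)
        assert records[0].feasible
        assert records[0].S == pytest.approx(1.0, abs=1e-3)

    def test_order_insensitive_and_infeasible_tagged(self, sin_profile):
        scarce = dict(BASE_SAMPLE, u_bar=1e-4)
        samples = [dict(BASE_SAMPLE, _index=0), dict(scarce, _index=1)]
        fwd = scan(sin_profile, samples)
        rev = scan(sin_profile, samples[::-1])
        by_idx_f = {r.index: (r.feasible, r.cost) for r in fwd}
        by_idx_r = {r.index: (r.feasible, r.cost) for r in rev}
        assert by_idx_f == by_idx_r
        assert by_idx_f[1][0] is False


class TestCostSimilarity:
    def _records(self, S, cost):
        return [ScanRecord(index=i, sample={}, feasible=True, S=s, cost=c)
                for i, (s, c) in enumerate(zip(S, cost))]

    def test_perfect_anticorrelation(self, rng):
        S = rng.uniform(0, 1, 30)
        res = cost_similarity_association(self._records(S, 1 - S))
        assert res["spearman_rho"] == pytest.approx(-1.0)

    def test_monotone_transform_invariance(self, rng):
        S = rng.uniform(0, 1, 30)
        cost = rng.uniform(0, 1, 30)
        r1 = cost_similarity_association(self._records(S, cost))
        r2 = cost_similarity_association(self._records(S, np.exp(3 * cost)))
        assert r1["spearman_rho"] == pytest.approx(r2["spearman_rho"], abs=1e-12)

    def test_independent_inputs_small_rho(self, rng):
        S = rng.uniform(0, 1, 200)
        cost = rng.uniform(0, 1, 200)
        res = cost_similarity_association(self._records(S, cost))
        assert abs(res["spearman_rho"]) < 0.2

    def test_constant_input_flagged(self):
        res = cost_similarity_association(self._records(np.full(12, 0.5),
                                                        np.arange(12.0)))
        assert res["flag"] == "constant-input"
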