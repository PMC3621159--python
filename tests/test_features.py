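"""Feature extraction: beat statistics, closure times, driver estimation."""

import numpy as np
import pytest

from cvsid import CirculationParams
from cvsid.driver import GaussianDriver, SampledDriver
from cvsid.features import (ConvergenceSetPoints, FeatureConfig,
                            end_diastolic_volume, estimate_driver, gedv,
                            extract_setpoints, max_ascending_gradient,
                            stroke_volume, valve_closure_from_pressures,
                            waveform_amplitude, waveform_mean)
from cvsid.model import Engine, WaveformSet


class TestBeatStatistics:
    def test_mean_of_constant_and_triangle(self):
        assert waveform_mean(np.full(100, 80.0)) == pytest.approx(80.0)
        tri = np.concatenate([np.linspace(60, 100, 51),
                              np.linspace(100, 60, 51)[1:]])
        assert waveform_mean(tri) == pytest.approx(80.0, rel=1e-3)

    def test_mean_matches_quadrature_on_simulated_beat(self, default_params,
                                                       truth_beat):
        T = truth_beat.T
        coarse = waveform_mean(truth_beat["P_ao"], truth_beat.t, period=T)
        fine = Engine(default_params).sample_beats(
            truth_beat.meta["state0"], 1, 2000.0)
        dense = waveform_mean(fine["P_ao"], fine.t, period=T)
        assert coarse == pytest.approx(dense, rel=1e-3)

    def test_amplitude(self):
        assert waveform_amplitude(np.full(10, 7.0)) == 0.0
        tr = np.array([80.0, 60.0, 100.0, 90.0])
        assert waveform_amplitude(tr) == pytest.approx(40.0)

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            waveform_mean(np.array([]))
        with pytest.raises(ValueError):
            waveform_amplitude(np.array([]))


class TestMaxAscendingGradient:
    def test_constant_slope_ramp(self):
        fs = 200.0
        ramp = np.linspace(0.0, 100.0, int(0.5 * fs) + 1)
        # wrap-around fall is negative, so the max is the ascending slope
        assert max_ascending_gradient(ramp, fs) == pytest.approx(200.0,
                                                                 rel=1e-2)

    def test_constant_trace(self):
        assert max_ascending_gradient(np.full(50, 5.0), 200.0) == \
            pytest.approx(0.0, abs=1e-9)

    def test_sine_closed_form(self):
        fs, A, f = 200.0, 20.0, 2.0
        t = np.arange(int(fs / f)) / fs
        tr = A * np.sin(2 * np.pi * f * t)
        assert max_ascending_gradient(tr, fs) == pytest.approx(
            A * 2 * np.pi * f, rel=0.02)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            max_ascending_gradient(np.array([1.0, 2.0]), 200.0)


class TestVolumes:
    def test_stroke_volume_averages_both_ventricles(self):
        V_lv = np.array([100.0, 30.0])
        V_rv = np.array([90.0, 30.0])
        assert stroke_volume(V_lv, V_rv) == pytest.approx(65.0)
        assert stroke_volume(V_lv, V_lv) == pytest.approx(70.0)

    def test_rv_underestimation_shifts_the_average(self):
        V_lv = np.array([100.0, 0.0])
        V_rv = 0.5 * V_lv
        assert stroke_volume(V_lv, V_rv) == pytest.approx(75.0)

    def test_gedv_sums_and_commutes(self):
        assert gedv(97.7, 93.3) == pytest.approx(191.0)
        assert gedv(0.0, 0.0) == 0.0
        assert gedv(12.0, 30.0) == gedv(30.0, 12.0)

    def test_end_diastolic_volume_of_fill_then_eject(self):
        fs, T = 200.0, 0.5
        n = int(T * fs)
        V = np.concatenate([np.linspace(80, 60, n // 3),
                            np.linspace(60, 100, n - n // 3)])
        assert end_diastolic_volume(V, fs, T, 0.01) == pytest.approx(100.0)
        assert end_diastolic_volume(np.full(n, 70.0), fs, T, 0.01) == 70.0

    def test_marker_outside_trace_rejected(self):
        with pytest.raises(ValueError):
            end_diastolic_volume(np.ones(100), 200.0, 0.5, 1.0)


class TestClosureFromPressures:
    def test_crossing_interpolated_between_samples(self):
        fs = 200.0
        P_v = np.linspace(0.0, 100.0, 100)       # rising ventricle
        P_up = np.full(100, 5.05)
        t = valve_closure_from_pressures(P_v, P_up, fs)
        crossing_idx = 5.05 / (100.0 / 99.0)
        assert t == pytest.approx(crossing_idx / fs, abs=1e-4)

    def test_closed_at_onset_returns_half_sample(self):
        t = valve_closure_from_pressures(np.linspace(10, 50, 50),
                                         np.full(50, 5.0), 200.0)
        assert t == pytest.approx(0.5 / 200.0)


class TestDriverEstimation:
    def test_normalisation_contract(self, truth_beat, default_params):
        d = estimate_driver(truth_beat["P_ao"], default_params.T, 200.0)
        vals = d.sample(512)
        assert vals.max() == pytest.approx(1.0, abs=1e-9)
        assert vals.min() >= 0.0

    def test_peak_time_recovered_from_simulated_beat(self, truth_beat,
                                                     default_params):
        d = estimate_driver(truth_beat["P_ao"], default_params.T, 200.0)
        true_peak = GaussianDriver.for_period(default_params.T).t_peak
        assert abs(d.peak_time - true_peak) < 0.1 * default_params.T

    def test_degenerate_trace_falls_back_to_parametric(self):
        d = estimate_driver(np.full(120, 80.0), 0.5, 200.0)
        assert d.fallback


class TestSetPoints:
    def test_contract_validation(self):
        kw = dict(GEDV=200.0, SV=30.0, MAP=90.0, MPAP=25.0, PP_ao=40.0,
                  PP_pa=30.0, dPao_max=900.0, dPpa_max=400.0, t_mt=0.01,
                  t_tc=0.02, T=0.5)
        ConvergenceSetPoints(**kw)
        with pytest.raises(ValueError):
            ConvergenceSetPoints(**{**kw, "SV": 250.0})   # SV > GEDV
        with pytest.raises(ValueError):
            ConvergenceSetPoints(**{**kw, "t_mt": 0.6})   # beyond the beat

    def test_round_trip_with_simulator_internals(self, truth_beat,
                                                 truth_setpoints):
        assert truth_setpoints.MAP == pytest.approx(
            float(np.mean(truth_beat["P_ao"])), rel=1e-3)
        assert truth_setpoints.GEDV == pytest.approx(
            float(truth_beat["V_lv"].max() + truth_beat["V_rv"].max()),
            rel=5e-3)

    def test_invariant_to_steady_beat_choice(self, default_params, truth_beat):
        rec = Engine(default_params).sample_beats(
            truth_beat.meta["state0"], 3, 200.0)
        s0 = extract_setpoints(rec, beat=0)
        s2 = extract_setpoints(rec, beat=2)
        for k in ("MAP", "MPAP", "PP_ao", "SV", "GEDV"):
            assert getattr(s0, k) == pytest.approx(getattr(s2, k), rel=1e-3)

    def test_invariant_to_time_shift(self, truth_beat):
        sp = extract_setpoints(truth_beat)
        shifted = WaveformSet(t=truth_beat.t + 4.2, f_s=truth_beat.f_s,
                              T=truth_beat.T, signals=truth_beat.signals,
                              beat_onsets=truth_beat.beat_onsets)
        sp2 = extract_setpoints(shifted)
        for k in ("MAP", "PP_ao", "SV", "t_mt"):
            assert getattr(sp, k) == pytest.approx(getattr(sp2, k), rel=1e-9)

    def test_invariant_to_sampling_rate(self, default_params, truth_beat):
        y0 = truth_beat.meta["state0"]
        lo = extract_setpoints(Engine(default_params).sample_beats(y0, 1, 100.0))
        hi = extract_setpoints(Engine(default_params).sample_beats(y0, 1, 1000.0))
        for k in ("MAP", "MPAP", "PP_ao", "PP_pa", "SV", "GEDV"):
            assert getattr(lo, k) == pytest.approx(getattr(hi, k), rel=5e-3)

    def test_json_round_trip(self, truth_setpoints, tmp_path):
        path = tmp_path / "sp.json"
        truth_setpoints.to_json(path)
        back = ConvergenceSetPoints.from_json(path)
        for k, v in truth_setpoints.to_dict().items():
            if isinstance(v, float):
                assert getattr(back, k, back.to_dict()[k]) == pytest.approx(v)
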