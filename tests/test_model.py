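"""Chamber mechanics, septum solver and the circulation integrator."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.optimize import brentq

from cvsid import CirculationParams, CVSState, simulate, steady_state_beat
from cvsid.driver import GaussianDriver
from cvsid.model import (Engine, compute_flows, compute_pressures,
                         derivatives, passive_pressure, solve_septum_volume,
                         ventricle_free_wall_pressure)
from cvsid.params import VentricleParams
from cvsid import _kernels as K


class TestFreeWallPressure:
    def test_linear_espvr_at_full_activation(self):
        vp = VentricleParams(E_es=2.0, V_d=23.0, P_0=0.0, lam=0.033)
        assert ventricle_free_wall_pressure(73.0, 1.0, vp) == pytest.approx(100.0)

    def test_zero_edpvr_scale_gives_zero_diastolic_pressure(self):
        vp = VentricleParams(E_es=2.0, V_d=23.0, P_0=0.0, lam=0.033)
        for V in (10.0, 100.0, 250.0):
            assert ventricle_free_wall_pressure(V, 0.0, vp) == 0.0

    def test_exponential_edpvr(self):
        vp = VentricleParams(E_es=2.0, V_d=23.0, P_0=1.0, lam=0.033, V_0=0.0)
        assert ventricle_free_wall_pressure(100.0, 0.0, vp) == pytest.approx(
            np.exp(3.3) - 1.0, rel=1e-9)
        assert ventricle_free_wall_pressure(100.0, 0.0, vp) == pytest.approx(
            26.11, abs=0.01)

    def test_preconditions(self):
        vp = VentricleParams(E_es=2.0, V_d=23.0, P_0=0.0, lam=0.033)
        with pytest.raises(ValueError):
            ventricle_free_wall_pressure(-1.0, 0.5, vp)
        with pytest.raises(ValueError):
            ventricle_free_wall_pressure(50.0, 1.5, vp)


class TestPassivePressure:
    @pytest.mark.parametrize("V,E,V_d,expected", [
        (40.0, 2.5, 0.0, 100.0),
        (17.0, 3.0, 17.0, 0.0),
        (10.0, 2.1, 0.0, 21.0),
    ])
    def test_linear_relation(self, V, E, V_d, expected):
        assert passive_pressure(V, E, V_d) == pytest.approx(expected)


class TestSeptum:
    def test_symmetric_ventricles_centre_the_septum(self, default_params):
        # with identical free walls and no septal volume offsets the free
        # wall pressure difference vanishes exactly at V_spt = 0
        p = default_params.replace(E_es_rvf=default_params.E_es_lvf,
                                   lambda_rvf=default_params.lambda_lvf,
                                   V_d_spt=0.0, V_0_spt=0.0)
        vs = solve_septum_volume(100.0, 100.0, 0.6, 0.6, p)
        assert abs(vs) < 1e-6
        resid = K.septum_residual(vs, 100.0, 100.0, 0.6, 0.6, p.to_array())
        assert abs(resid) < 1e-6

    def test_agrees_with_bisection_oracle(self, default_params, rng):
        pv = default_params.to_array()
        for _ in range(20):
            V_lv = rng.uniform(40, 220)
            V_rv = rng.uniform(40, 220)
            dL = rng.uniform(0, 1)
            dR = rng.uniform(0, 1)
            got = K.solve_septum(V_lv, V_rv, dL, dR, pv, 0.0)
            oracle = brentq(
                lambda v: K.septum_residual(v, V_lv, V_rv, dL, dR, pv),
                -200.0, 200.0, xtol=1e-10)
            assert got == pytest.approx(oracle, abs=1e-6)

    def test_monotone_in_left_ventricular_volume(self, default_params):
        pv = default_params.to_array()
        vols = np.linspace(60, 200, 15)
        vs = [K.solve_septum(v, 110.0, 0.7, 0.7, pv, 0.0) for v in vols]
        assert np.all(np.diff(vs) >= -1e-9)


class TestPressuresAndFlows:
    def test_pericardial_pressure_vanishes_at_reference_volume(self, default_params):
        s = CVSState(100.0, 40.0, 850.0, 100.0, 10.0, 400.0)
        pr = compute_pressures(s, 0.0, default_params)
        assert pr["P_pcd"] == pytest.approx(0.0, abs=1e-9)

    def test_pericardial_pressure_at_distension(self, default_params):
        s = CVSState(125.0, 40.0, 825.0, 125.0, 10.0, 375.0)
        pr = compute_pressures(s, 0.0, default_params)
        assert pr["P_pcd"] == pytest.approx(0.5003 * (np.exp(1.5) - 1.0),
                                            rel=1e-9)
        assert pr["P_pcd"] == pytest.approx(1.742, abs=1e-3)

    def test_thoracic_pressure_shifts_ventricular_pressures(self, default_params):
        s = CVSState(100.0, 40.0, 850.0, 100.0, 10.0, 400.0)
        base = compute_pressures(s, 0.0, default_params)
        shifted = compute_pressures(s, 0.0, default_params.replace(P_th=3.0))
        assert shifted["P_lv"] - base["P_lv"] == pytest.approx(3.0, abs=1e-9)
        assert shifted["P_ao"] == base["P_ao"]

    def test_valves_are_diodes(self, default_params):
        pr = {"P_lv": 50.0, "P_ao": 100.0, "P_vc": 5.0, "P_rv": 20.0,
              "P_pa": 25.0, "P_pu": 6.0}
        q = compute_flows(pr, default_params)
        assert q["Q_av"] == 0.0            # reverse aortic gradient blocked
        assert q["Q_mt"] == 0.0            # P_pu < P_lv
        assert q["Q_sys"] == pytest.approx((100.0 - 5.0) / 2.5)

    def test_ohmic_systemic_flow(self, default_params):
        pr = {"P_lv": 0.0, "P_ao": 100.0, "P_vc": 5.0, "P_rv": 0.0,
              "P_pa": 0.0, "P_pu": 0.0}
        assert compute_flows(pr, default_params)["Q_sys"] == pytest.approx(38.0)

    def test_equal_pressures_mean_no_flow(self, default_params):
        pr = {k: 42.0 for k in ("P_lv", "P_ao", "P_vc", "P_rv", "P_pa", "P_pu")}
        assert all(v == 0.0 for v in compute_flows(pr, default_params).values())


class TestDerivatives:
    def test_closed_loop_conserves_volume_pointwise(self, default_params, rng):
        for _ in range(10):
            s = CVSState(*(rng.uniform(20, 400, size=6)))
            dy = derivatives(s, rng.uniform(0, 0.5), default_params)
            assert sum(dy.values()) == pytest.approx(0.0, abs=1e-8)

    def test_submodel_mode_returns_reduced_state(self, default_params):
        s = CVSState(100.0, 40.0, 850.0, 100.0, 10.0, 400.0)
        dy = derivatives(s, 0.0, default_params, mode="systemic")
        assert set(dy) == {"V_lv", "V_ao"}
        dy = derivatives(s, 0.0, default_params, mode="pulmonary")
        assert set(dy) == {"V_rv", "V_pa"}


class TestSimulate:
    def test_single_beat_sample_count(self, default_params):
        w = simulate(default_params, n_beats=1, f_s=200.0)
        assert len(w.t) == round(default_params.T * 200.0)

    def test_volume_conservation_over_twenty_beats(self, default_params):
        w = simulate(default_params, n_beats=20)
        total = sum(w[k] for k in ("V_lv", "V_ao", "V_vc", "V_rv", "V_pa",
                                   "V_pu"))
        assert np.max(np.abs(total - total[0])) < 1e-3

    def test_valve_flows_nonnegative(self, truth_beat):
        for name in ("Q_mt", "Q_av", "Q_tc", "Q_pv"):
            assert np.min(truth_beat[name]) >= 0.0

    def test_tolerance_refinement_changes_little(self, default_params, truth_beat):
        y0 = truth_beat.meta["state0"]
        coarse = Engine(default_params, rtol=1e-7, atol=1e-7)
        fine = Engine(default_params, rtol=5e-8, atol=5e-8)
        b1 = coarse.sample_beats(y0, 1, 200.0)
        b2 = fine.sample_beats(y0, 1, 200.0)
        assert np.max(np.abs(b1["P_ao"] - b2["P_ao"])) < 0.1

    def test_invalid_arguments(self, default_params):
        with pytest.raises(ValueError):
            simulate(default_params, n_beats=0)
        with pytest.raises(ValueError):
            simulate(default_params, f_s=-1.0)


class TestSteadyState:
    def test_reached_from_default_initial_values(self, truth_beat):
        assert truth_beat.meta["converged"]
        assert truth_beat.meta["n_beats_to_converge"] <= 300

    def test_idempotent_at_the_fixed_point(self, default_params, truth_beat):
        eng = Engine(default_params)
        y1 = eng.integrate_beat(truth_beat.meta["state0"])
        assert np.max(np.abs(y1 - truth_beat.meta["state0"])) < 0.02

    def test_attractor_from_distinct_initial_states(self, default_params):
        w1 = steady_state_beat(default_params,
                               s0=CVSState(100, 40, 900, 100, 10, 350))
        w2 = steady_state_beat(default_params,
                               s0=CVSState(150, 30, 700, 150, 15, 455))
        for k in ("P_ao", "P_pa", "V_lv", "V_rv"):
            scale = np.max(np.abs(w2[k]))
            assert np.max(np.abs(w1[k] - w2[k])) / scale < 1e-3


class TestMonotoneSensitivities:
    """Steady-state responses to +/-5% parameter perturbations."""

    @pytest.fixture(scope="class")
    def baseline_outputs(self, default_params, truth_beat):
        return self._outputs(default_params, truth_beat.meta["state0"])

    @staticmethod
    def _outputs(p, y0):
        eng = Engine(p)
        y, _, ok = eng.steady_state(np.asarray(y0, dtype=float))
        assert ok
        b = eng.sample_beats(y, 1, 200.0)
        return {
            "MAP": float(np.mean(b["P_ao"])),
            "PP_ao": float(np.ptp(b["P_ao"])),
            "LVEDV": float(np.max(b["V_lv"])),
            "SV": float(0.5 * (np.ptp(b["V_lv"]) + np.ptp(b["V_rv"]))),
        }

    @pytest.mark.parametrize("param,output,direction", [
        ("R_sys", "MAP", +1),
        ("E_ao", "PP_ao", +1),
        ("E_es_lvf", "LVEDV", -1),
        ("R_mt", "SV", -1),
    ])
    def test_direction(self, default_params, truth_beat, baseline_outputs,
                       param, output, direction):
        p = default_params.replace(
            **{param: getattr(default_params, param) * 1.05})
        pert = self._outputs(p, truth_beat.meta["state0"])
        assert direction * (pert[output] - baseline_outputs[output]) > 0
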