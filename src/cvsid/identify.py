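"""Staged iterative proportional-gain identification of circulation models.

Each observable model output identifies one model parameter. Parameters
proportionally related to their output are updated with
``p_new = (measurement / model output) * p_old`` and inversely related ones
with the reciprocal ratio. The systemic and pulmonary circulation halves
are identified first as decoupled submodels between fixed boundary
pressures (population initial estimates), with the valve-closure times
identifying the venous source pressures; the halves are then joined
through the septum and pericardium and re-identified directly against the
closed-loop periodic steady state, where the global end-diastolic volume
identifies the venous compliance scale that releases the stored stressed
volume to the heart. Per-subject series are identified per timepoint, the
valve resistances averaged, and the remaining parameters re-identified
with the valves fixed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np

from .driver import DriverFunction, GaussianDriver
from .features import (ConvergenceSetPoints, FeatureConfig, _smooth,
                       end_diastolic_volume, max_ascending_gradient,
                       refined_amplitude, stroke_volume,
                       valve_closure_from_pressures, waveform_mean)
from .model import (CouplingForcing, CVSState, Engine, SimulationError,
                    WaveformSet)
from .params import (MODEL_CONSTANTS, PULMONARY_INITIAL, SYSTEMIC_INITIAL,
                     CirculationParams)

__all__ = [
    "PairingRule",
    "IdentificationConfig",
    "IdentifiedModel",
    "SubjectSeries",
    "InsensitivityError",
    "proportional_update",
    "relation_direction",
    "identify_submodel",
    "identify_sixchamber",
    "identify_timepoint",
    "identify_subject",
    "afterload_metric",
    "TimepointIdentification",
    "SubjectIdentification",
    "SYSTEMIC_PAIRS",
    "PULMONARY_PAIRS",
    "SIXCHAMBER_PAIRS",
]

log = logging.getLogger(__name__)

VALVE_PARAMS = ("R_mt", "R_av", "R_tc", "R_pv")


class InsensitivityError(RuntimeError):
    """An output does not respond to its paired parameter."""


@dataclass(frozen=True)
class PairingRule:
    """One measurement/parameter pair with its update direction."""

    output_name: str
    parameter_name: str
    relation: str = "auto"  # proportional | inverse | auto

    def __post_init__(self) -> None:
        if self.relation not in ("proportional", "inverse", "auto"):
            raise ValueError(f"unknown relation {self.relation!r}")


SYSTEMIC_PAIRS: tuple[PairingRule, ...] = (
    PairingRule("GEDV", "E_es_lvf", "auto"),
    PairingRule("SV", "R_mt", "auto"),
    PairingRule("MAP", "R_sys", "auto"),
    PairingRule("PP_ao", "E_ao", "auto"),
    PairingRule("dPao_max", "R_av", "auto"),
    PairingRule("t_mt", "P_pu", "auto"),
)

PULMONARY_PAIRS: tuple[PairingRule, ...] = (
    PairingRule("GEDV", "E_es_rvf", "auto"),
    PairingRule("SV", "R_tc", "auto"),
    PairingRule("MPAP", "R_pul", "auto"),
    PairingRule("PP_pa", "E_pa", "auto"),
    PairingRule("dPpa_max", "R_pv", "auto"),
    PairingRule("t_tc", "P_vc", "auto"),
)

SIXCHAMBER_PAIRS: tuple[PairingRule, ...] = (
    PairingRule("P_vc", "E_vc", "auto"),
    PairingRule("P_pu", "E_pu", "auto"),
)

#: Pairing table for the coupled re-identification sweep on the assembled
#: six-chamber model: the pressure/gradient/stroke-volume pairs of the
#: stage tables, iterated sequentially against the closed-loop steady
#: state. GEDV is handled inside ``identify_sixchamber``: in the closed
#: loop it identifies the common scale of the venous elastances, which
#: release the stored stressed volume toward the heart (the contractility
#: pair keeps its stage-identified, GEDV-matched values because the summed
#: end-diastolic volume and averaged stroke volume do not constrain the
#: left/right split any further). Both filling resistances match the
#: averaged stroke volume, which is the measured quantity; the individual
#: amplitudes differ only by septal shuttling.
CLOSED_PAIRS: tuple[PairingRule, ...] = (
    PairingRule("SV", "R_mt", "auto"),
    PairingRule("MAP", "R_sys", "auto"),
    PairingRule("PP_ao", "E_ao", "auto"),
    PairingRule("dPao_max", "R_av", "auto"),
    PairingRule("SV", "R_tc", "auto"),
    PairingRule("MPAP", "R_pul", "auto"),
    PairingRule("PP_pa", "E_pa", "auto"),
    PairingRule("dPpa_max", "R_pv", "auto"),
)

#: Update directions resolved by sensitivity analysis (relation_direction)
#: on the default parameter set; used as the cache seed for relation=auto.
PHYSIOLOGICAL_RELATIONS: dict[tuple[str, str], str] = {
    ("GEDV", "E_es_lvf"): "inverse",       # stronger LV empties further
    ("SV", "R_mt"): "inverse",             # filling resistance limits SV
    ("MAP", "R_sys"): "proportional",      # resistance raises mean pressure
    ("PP_ao", "E_ao"): "proportional",     # stiffer aorta, larger pulse
    ("dPao_max", "R_av"): "inverse",       # valve resistance slows upstroke
    ("t_mt", "P_pu"): "proportional",      # higher venous pressure closes later
    ("GEDV", "E_es_rvf"): "inverse",
    ("SV", "R_tc"): "inverse",
    ("MPAP", "R_pul"): "proportional",
    ("PP_pa", "E_pa"): "proportional",
    ("dPpa_max", "R_pv"): "inverse",
    ("t_tc", "P_vc"): "proportional",
    ("P_vc", "E_vc"): "proportional",
    ("P_pu", "E_pu"): "proportional",
    ("SV_lv", "R_mt"): "inverse",
    ("SV_rv", "R_tc"): "inverse",
    ("t_mt", "E_pu"): "proportional",
    ("t_tc", "E_vc"): "proportional",
    ("GEDV", "_venous_level"): "proportional",
}

_relation_cache: dict[tuple[str, str], str] = {}


@dataclass
class IdentificationConfig:
    """Tolerances, iteration caps and shared constants of the procedure."""

    inner_tol: float = 2e-3       # relative, per matched output
    outer_tol: float = 5e-3       # relative, for the whole-model GEDV and
                                  # max-gradient outputs in the coupled stage
    max_inner_iters: int = 100
    max_outer_iters: int = 90
    bootstrap_tol: float = 5e-3   # relative, for the decoupled bootstrap stages
    dead_space_V_d: float = 23.0  # mL, ventricular ESPVR dead space
    V_total: float = 1500.0       # mL, total stressed volume (population constant)
    E_vc_population: float = 0.005  # mmHg/mL, venous elastance ratio anchor
    E_pu_population: float = 0.016
    f_s: float = 200.0            # Hz, waveform sampling during identification
    ss_tol: float = 0.01          # mL, steady-state beat-onset criterion
    ss_max_beats: int = 300
    rtol: float = 1e-6            # identification-internal simulations need
    atol: float = 1e-6            # ~1e-4 relative output accuracy, not more
    damping: float = 0.5          # exponent applied when a residual grew
    ratio_clip: float = 3.0       # per-iteration bound on update ratios
    relation_overrides: dict = field(default_factory=dict)
    use_sensitivity_relations: bool = False  # resolve auto by fresh simulation
    feature: FeatureConfig = field(default_factory=FeatureConfig)

    def __post_init__(self) -> None:
        if not 0 < self.inner_tol < 1 or not 0 < self.outer_tol < 1:
            raise ValueError("tolerances must lie in (0, 1)")
        if self.max_inner_iters < 1 or self.max_outer_iters < 1:
            raise ValueError("iteration caps must be >= 1")


# ---------------------------------------------------------------------------
# elementary update rule
# ---------------------------------------------------------------------------

def proportional_update(p_old: float, measurement: float, model_output: float,
                        relation: str, exponent: float = 1.0,
                        ratio_clip: float = np.inf) -> float:
    """One multiplicative gain update of a parameter.

    ``relation='proportional'`` scales by measurement/model_output;
    ``'inverse'`` by the reciprocal. ``exponent`` < 1 damps the step.
    """
    if p_old <= 0 or measurement <= 0 or model_output <= 0:
        raise ValueError("proportional update requires positive inputs")
    if relation == "proportional":
        ratio = measurement / model_output
    elif relation == "inverse":
        ratio = model_output / measurement
    else:
        raise ValueError(f"unknown relation {relation!r}")
    factor = ratio ** exponent
    factor = min(max(factor, 1.0 / ratio_clip), ratio_clip)
    return p_old * factor


# ---------------------------------------------------------------------------
# model-output extraction (same feature definitions as the measured side)
# ---------------------------------------------------------------------------

def _av_closure_time(P_v: np.ndarray, P_src: np.ndarray, f_s: float,
                     fcfg: FeatureConfig) -> float:
    """Model-side valve closure, read with the same smoothing and crossing
    rule as the measured side."""
    return valve_closure_from_pressures(_smooth(P_v, fcfg, f_s),
                                        _smooth(P_src, fcfg, f_s), f_s)


def _submodel_outputs(beat: WaveformSet, stage: str, sp: ConvergenceSetPoints,
                      fcfg: FeatureConfig,
                      edv_other: float | None) -> dict[str, float]:
    T, f_s = beat.T, beat.f_s
    if stage == "systemic":
        P = _smooth(beat["P_ao"], fcfg, f_s)
        V = _smooth(beat["V_lv"], fcfg, f_s)
        edv = end_diastolic_volume(V, f_s, T, sp.t_mt)
        return {
            "GEDV": edv + (edv_other if edv_other is not None else edv),
            "EDV_own": edv,
            "SV": refined_amplitude(V),
            "MAP": waveform_mean(P, beat.t, period=T),
            "PP_ao": refined_amplitude(P),
            "dPao_max": max_ascending_gradient(P, f_s, fcfg.deriv_window),
            "t_mt": _av_closure_time(beat["P_lv"], beat["P_pu"], f_s, fcfg),
        }
    P = _smooth(beat["P_pa"], fcfg, f_s)
    V = _smooth(beat["V_rv"], fcfg, f_s)
    edv = end_diastolic_volume(V, f_s, T, sp.t_tc)
    return {
        "GEDV": edv + (edv_other if edv_other is not None else edv),
        "EDV_own": edv,
        "SV": refined_amplitude(V),
        "MPAP": waveform_mean(P, beat.t, period=T),
        "PP_pa": refined_amplitude(P),
        "dPpa_max": max_ascending_gradient(P, f_s, fcfg.deriv_window),
        "t_tc": _av_closure_time(beat["P_rv"], beat["P_vc"], f_s, fcfg),
    }


def _closed_outputs(beat: WaveformSet, sp: ConvergenceSetPoints,
                    fcfg: FeatureConfig) -> dict[str, float]:
    f_s, T = beat.f_s, beat.T
    P_ao = _smooth(beat["P_ao"], fcfg, f_s)
    P_pa = _smooth(beat["P_pa"], fcfg, f_s)
    V_lv = _smooth(beat["V_lv"], fcfg, f_s)
    V_rv = _smooth(beat["V_rv"], fcfg, f_s)
    lvedv = end_diastolic_volume(V_lv, f_s, T, sp.t_mt)
    rvedv = end_diastolic_volume(V_rv, f_s, T, sp.t_tc)
    return {
        "GEDV": lvedv + rvedv,
        "LVEDV": lvedv,
        "RVEDV": rvedv,
        "SV": stroke_volume(V_lv, V_rv),
        "SV_lv": refined_amplitude(V_lv),
        "SV_rv": refined_amplitude(V_rv),
        "MAP": waveform_mean(P_ao, beat.t, period=T),
        "MPAP": waveform_mean(P_pa, beat.t, period=T),
        "PP_ao": refined_amplitude(P_ao),
        "PP_pa": refined_amplitude(P_pa),
        "dPao_max": max_ascending_gradient(P_ao, f_s, fcfg.deriv_window),
        "dPpa_max": max_ascending_gradient(P_pa, f_s, fcfg.deriv_window),
        "t_mt": _av_closure_time(beat["P_lv"], beat["P_pu"], f_s, fcfg),
        "t_tc": _av_closure_time(beat["P_rv"], beat["P_vc"], f_s, fcfg),
        "P_vc": waveform_mean(beat["P_vc"], beat.t, period=T),
        "P_pu": waveform_mean(beat["P_pu"], beat.t, period=T),
    }


# ---------------------------------------------------------------------------
# relation resolution
# ---------------------------------------------------------------------------

def relation_direction(parameter_name: str, output_name: str,
                       p: CirculationParams, sp: ConvergenceSetPoints,
                       cfg: IdentificationConfig | None = None,
                       stage: str | None = None,
                       perturbation: float = 0.05) -> str:
    """Sign of the steady-state sensitivity of an output to its parameter.

    Perturbs the parameter by +``perturbation``, re-simulates to the
    periodic steady state, and classifies the pair as ``proportional`` if
    the output increased, ``inverse`` otherwise.
    """
    cfg = cfg or IdentificationConfig()
    if stage is None:
        stage = _stage_of_pair(output_name, parameter_name)
    vals = []
    for fac in (1.0, 1.0 + perturbation):
        pp = p.replace(**{parameter_name: getattr(p, parameter_name) * fac})
        eng = Engine(pp, mode=stage, rtol=cfg.rtol, atol=cfg.atol)
        y0 = _initial_state(pp, sp, stage)
        y, _, _ = eng.steady_state(y0, tol=cfg.ss_tol,
                                   max_beats=cfg.ss_max_beats)
        beat = eng.sample_beats(y, 1, cfg.f_s)
        if stage == "closed":
            outs = _closed_outputs(beat, sp, cfg.feature)
        else:
            outs = _submodel_outputs(beat, stage, sp, cfg.feature, None)
        vals.append(outs[output_name])
    base, pert = vals
    if abs(base) < 1e-12 or abs(pert - base) / max(abs(base), 1e-12) < 1e-6:
        raise InsensitivityError(
            f"output {output_name} insensitive to {parameter_name}")
    return "proportional" if pert > base else "inverse"


def _stage_of_pair(output_name: str, parameter_name: str) -> str:
    for rules, stage in ((SYSTEMIC_PAIRS, "systemic"),
                         (PULMONARY_PAIRS, "pulmonary"),
                         (SIXCHAMBER_PAIRS, "closed"),
                         (CLOSED_PAIRS, "closed")):
        for r in rules:
            if r.output_name == output_name and r.parameter_name == parameter_name:
                return stage
    raise ValueError(f"unknown pairing ({output_name}, {parameter_name})")


def _resolve_relation(rule: PairingRule, cfg: IdentificationConfig,
                      p: CirculationParams,
                      sp: ConvergenceSetPoints) -> str:
    key = (rule.output_name, rule.parameter_name)
    if key in cfg.relation_overrides:
        return cfg.relation_overrides[key]
    if rule.relation != "auto":
        return rule.relation
    if key in _relation_cache:
        return _relation_cache[key]
    if cfg.use_sensitivity_relations:
        rel = relation_direction(rule.parameter_name, rule.output_name, p, sp,
                                 cfg)
    else:
        rel = PHYSIOLOGICAL_RELATIONS[key]
    _relation_cache[key] = rel
    return rel


# ---------------------------------------------------------------------------
# stage identification
# ---------------------------------------------------------------------------

def _initial_state(p: CirculationParams, sp: ConvergenceSetPoints,
                   stage: str) -> np.ndarray:
    if stage == "systemic":
        return np.array([sp.GEDV / 2.0, sp.MAP / p.E_ao])
    if stage == "pulmonary":
        return np.array([sp.GEDV / 2.0, sp.MPAP / p.E_pa])
    V_lv = V_rv = sp.GEDV / 2.0
    V_ao = sp.MAP / p.E_ao
    V_pa = sp.MPAP / p.E_pa
    rest = p.V_total - (V_lv + V_rv + V_ao + V_pa)
    if rest <= 0:
        raise ValueError("V_total too small for the measured volumes")
    return np.array([V_lv, V_ao, 0.7 * rest, V_rv, V_pa, 0.3 * rest])


@dataclass
class StageResult:
    """Outcome of one submodel identification pass."""

    stage: str
    params: dict[str, float]
    residuals: dict[str, float]
    converged: bool
    n_iters: int
    beat: WaveformSet | None = None
    y_warm: np.ndarray | None = None
    outputs: dict[str, float] = field(default_factory=dict)
    residual_trace: list = field(default_factory=list)


def _blend(p_bad: CirculationParams, p_good: CirculationParams,
           names: Sequence[str]) -> CirculationParams:
    """Geometric mean of two parameter sets over the identified fields
    (backtracking step after a failed simulation)."""
    upd = {}
    for name in names:
        a, b = getattr(p_bad, name), getattr(p_good, name)
        if a > 0 and b > 0:
            upd[name] = float(np.sqrt(a * b))
    return p_bad.replace(**upd)


IDENTIFIED_PARAMS: tuple[str, ...] = (
    "E_es_lvf", "E_es_rvf", "R_mt", "R_tc", "R_sys", "R_pul",
    "E_ao", "E_pa", "R_av", "R_pv", "E_vc", "E_pu", "P_pu", "P_vc",
)


def identify_submodel(sp: ConvergenceSetPoints, stage: str,
                      driver: DriverFunction | None = None,
                      init: dict[str, float] | None = None,
                      cfg: IdentificationConfig | None = None,
                      forcing: CouplingForcing | None = None,
                      edv_other: float | None = None,
                      y_warm: np.ndarray | None = None,
                      fixed: dict[str, float] | None = None) -> StageResult:
    """Iterative proportional-gain identification of one circulation half.

    ``forcing`` carries the closed-loop coupling context (septal volume,
    pericardial pressure and venous pressure curves); without it the
    submodel is fully decoupled and its boundary pressures are constant.
    ``edv_other`` is the other ventricle's end-diastolic volume from the
    latest closed-loop beat; when absent the submodel's own EDV is doubled
    to form the model GEDV. ``fixed`` pins parameters (e.g. averaged valve
    resistances) — their pairs are reported but not updated or required to
    converge.
    """
    if stage not in ("systemic", "pulmonary"):
        raise ValueError(f"unknown stage {stage!r}")
    cfg = cfg or IdentificationConfig()
    sp.validate()
    fixed = dict(fixed or {})
    pairs = SYSTEMIC_PAIRS if stage == "systemic" else PULMONARY_PAIRS
    meas = {r.output_name: getattr(sp, r.output_name) for r in pairs}
    init_all = dict(SYSTEMIC_INITIAL if stage == "systemic" else PULMONARY_INITIAL)
    if init:
        init_all.update(init)
    init_all.update(fixed)

    p = CirculationParams(
        T=sp.T, V_total=cfg.V_total,
        V_d_lvf=cfg.dead_space_V_d, V_d_rvf=cfg.dead_space_V_d,
        **{k: v for k, v in init_all.items()})
    relations = {r.parameter_name: _resolve_relation(r, cfg, p, sp)
                 for r in pairs}

    y = np.asarray(y_warm, dtype=float) if y_warm is not None else \
        _initial_state(p, sp, stage)
    prev_res: dict[str, float] | None = None
    trace: list[dict[str, float]] = []
    converged = False
    beat = None
    # a closure time at the read-off resolution floor (valve already shut
    # at beat onset) carries no timing information: the source pressure
    # keeps its initial estimate instead of chasing the floor value
    degenerate = {r.output_name for r in pairs
                  if r.output_name in ("t_mt", "t_tc")
                  and meas[r.output_name] < 2.0 / cfg.f_s}
    active = [r for r in pairs if r.parameter_name not in fixed
              and r.output_name not in degenerate]
    # generous physiological bounds stop multiplicative runaways when a
    # target is momentarily unreachable
    bounds = {r.parameter_name:
              (getattr(p, r.parameter_name) / 50.0,
               getattr(p, r.parameter_name) * 50.0) for r in pairs}

    state = {"p_good": None, "y_good": None}

    def _simulate(pp: CirculationParams, yy: np.ndarray):
        """Steady state + sampled beat, backtracking on solver failure."""
        nonlocal p
        for _ in range(4):
            try:
                f = _shifted_forcing(forcing, pp, stage)
                eng = Engine(pp, driL=driver, driR=driver, mode=stage,
                             forcing=f, rtol=cfg.rtol, atol=cfg.atol)
                yy2, _, ss_ok = eng.steady_state(
                    np.asarray(yy, dtype=float), tol=cfg.ss_tol,
                    max_beats=cfg.ss_max_beats)
                b = eng.sample_beats(yy2, 1, cfg.f_s)
                o = _submodel_outputs(b, stage, sp, cfg.feature, edv_other)
                state["p_good"], state["y_good"] = pp, yy2.copy()
                p = pp
                return yy2, b, o, ss_ok
            except SimulationError:
                if state["p_good"] is None:
                    raise
                pp = _blend(pp, state["p_good"], IDENTIFIED_PARAMS)
                yy = state["y_good"]
        pp, yy = state["p_good"], state["y_good"]
        f = _shifted_forcing(forcing, pp, stage)
        eng = Engine(pp, driL=driver, driR=driver, mode=stage, forcing=f,
                     rtol=cfg.rtol, atol=cfg.atol)
        yy2, _, ss_ok = eng.steady_state(yy, tol=cfg.ss_tol,
                                         max_beats=cfg.ss_max_beats)
        b = eng.sample_beats(yy2, 1, cfg.f_s)
        o = _submodel_outputs(b, stage, sp, cfg.feature, edv_other)
        p = pp
        return yy2, b, o, ss_ok

    # one proportional-gain sweep updates each parameter in turn, with a
    # re-simulation between updates (sequential updates keep the strongly
    # coupled pairs, e.g. the venous source pressure, from oscillating);
    # a secant estimate of the local log-gain rescales the step for pairs
    # whose output responds weakly to its parameter
    hist: dict[str, tuple[float, float]] = {}
    for it in range(1, cfg.max_inner_iters + 1):
        for r in active:
            y, beat, outs, ss_ok = _simulate(p, y)
            # a degenerate beat (e.g. a valve that never opened) can zero an
            # output; a floored value turns into a maximal clipped step
            out = max(outs[r.output_name], 1e-9 * meas[r.output_name])
            p_old = getattr(p, r.parameter_name)
            r_now = abs(out - meas[r.output_name]) / abs(meas[r.output_name])
            if r_now < cfg.inner_tol:
                hist[r.parameter_name] = (np.log(p_old), np.log(out))
                continue
            # closure times respond to the source pressure with log-gain
            # above one, so their base step is damped
            is_time = r.output_name in ("t_mt", "t_tc")
            exponent = 0.5 if is_time else 1.0
            exp_hi = 1.0 if is_time else 5.0
            if r.parameter_name in hist:
                lp0, lo0 = hist[r.parameter_name]
                dlp = np.log(p_old) - lp0
                dlo = np.log(out) - lo0
                if abs(dlp) > 1e-9:
                    g = dlo / dlp
                    expected_sign = 1.0 if \
                        relations[r.parameter_name] == "proportional" else -1.0
                    if g * expected_sign > 1e-3:
                        exponent = min(max(1.0 / abs(g), 0.3), exp_hi)
            if r_now < 5 * cfg.inner_tol:
                exponent = min(exponent, 1.0)
            if prev_res is not None and \
                    r_now > prev_res[r.output_name] * (1 + 1e-12):
                exponent *= cfg.damping
            if prev_res is not None:
                prev_res[r.output_name] = r_now
            hist[r.parameter_name] = (np.log(p_old), np.log(out))
            new = proportional_update(
                p_old, meas[r.output_name], out,
                relations[r.parameter_name], exponent, cfg.ratio_clip)
            lo, hi = bounds[r.parameter_name]
            p = p.replace(**{r.parameter_name: min(max(new, lo), hi)})
        y, beat, outs, ss_ok = _simulate(p, y)
        res = {r.output_name:
               abs(outs[r.output_name] - meas[r.output_name])
               / abs(meas[r.output_name]) for r in pairs}
        trace.append(res)
        log.debug("%s stage sweep %d residuals %s", stage, it,
                  {k: f"{v:.2e}" for k, v in res.items()})
        if ss_ok and all(res[r.output_name] < cfg.inner_tol for r in active):
            converged = True
            break
        prev_res = dict(res)
    if degenerate:
        log.debug("%s stage: timing outputs at resolution floor skipped: %s",
                  stage, sorted(degenerate))
    result_params = {r.parameter_name: getattr(p, r.parameter_name)
                     for r in pairs}
    return StageResult(stage=stage, params=result_params, residuals=res,
                       converged=converged, n_iters=it, beat=beat, y_warm=y,
                       outputs=outs, residual_trace=trace)


def _shifted_forcing(forcing: CouplingForcing | None, p: CirculationParams,
                     stage: str) -> CouplingForcing | None:
    """Shift venous forcing curves so their means track the current source
    pressure parameter (the coupling context keeps its pulsatile shape)."""
    if forcing is None:
        return None
    src_target = p.P_pu if stage == "systemic" else p.P_vc
    snk_target = p.P_vc if stage == "systemic" else p.P_pu
    src = forcing.P_src - forcing.P_src.mean() + src_target
    snk = forcing.P_snk - forcing.P_snk.mean() + snk_target
    return CouplingForcing(forcing.V_spt, forcing.P_pcd, src, snk)


# ---------------------------------------------------------------------------
# six-chamber assembly and outer loop
# ---------------------------------------------------------------------------

@dataclass
class IdentifiedModel:
    """A converged subject-specific parameter set for one timepoint."""

    params: CirculationParams
    setpoints: ConvergenceSetPoints
    residuals: dict[str, float]
    converged: bool
    flags: list[str]
    n_outer: int
    inner_iters: dict[str, int]
    predicted: dict[str, float]
    label: str = ""
    residual_trace: list = field(default_factory=list)

    @property
    def max_residual(self) -> float:
        """Largest relative residual over the matched measurement outputs
        (the informational closure-time and venous entries excluded)."""
        skip = {"t_mt", "t_tc", "P_pu", "P_vc"}
        return max(v for k, v in self.residuals.items() if k not in skip)

    def simulate(self, n_beats: int = 1, f_s: float | None = None,
                 driL: DriverFunction | None = None,
                 driR: DriverFunction | None = None) -> WaveformSet:
        from .model import steady_state_beat

        return steady_state_beat(self.params, f_s=f_s or 200.0,
                                 driL=driL, driR=driR)


def _assemble(sysres: StageResult, pulres: StageResult,
              sp: ConvergenceSetPoints, cfg: IdentificationConfig,
              E_vc: float, E_pu: float) -> CirculationParams:
    kw = dict(MODEL_CONSTANTS)
    for name in ("L_mt", "L_av", "L_tc", "L_pv"):
        kw[name] = 0.0
    kw.update(sysres.params)
    kw.update(pulres.params)
    kw.update(T=sp.T, V_total=cfg.V_total, E_vc=E_vc, E_pu=E_pu,
              V_d_lvf=cfg.dead_space_V_d, V_d_rvf=cfg.dead_space_V_d)
    return CirculationParams(**kw)


def _predicted_from_beat(beat: WaveformSet, sp: ConvergenceSetPoints,
                         p: CirculationParams) -> dict[str, float]:
    E_a = afterload_metric(p.R_pv, p.R_pul, p.T)
    return {
        "LVEDV": end_diastolic_volume(beat["V_lv"], beat.f_s, beat.T, sp.t_mt),
        "RVEDV": end_diastolic_volume(beat["V_rv"], beat.f_s, beat.T, sp.t_tc),
        "P_lv_max": float(np.max(beat["P_lv"])),
        "P_rv_max": float(np.max(beat["P_rv"])),
        "E_a": E_a,
        "RVAC": p.E_es_rvf / E_a,
        "mean_P_vc": waveform_mean(beat["P_vc"], beat.t, period=beat.T),
        "mean_P_pu": waveform_mean(beat["P_pu"], beat.t, period=beat.T),
    }


def identify_sixchamber(sysres: StageResult | None, pulres: StageResult | None,
                        sp: ConvergenceSetPoints,
                        cfg: IdentificationConfig | None = None,
                        driL: DriverFunction | None = None,
                        driR: DriverFunction | None = None,
                        fixed: dict[str, float] | None = None,
                        label: str = "",
                        p0: CirculationParams | None = None) -> IdentifiedModel:
    """Join the identified halves and re-identify against the closed loop.

    The closed-loop model is assembled with septum and pericardium coupling
    and every measurement/parameter pair is re-identified with the same
    sequential proportional-gain sweep used in the stages (a fresh periodic
    steady state between updates, secant-rescaled steps for weakly
    responding pairs). In the closed loop the venous elastances take over
    the global end-diastolic volume: they set how much of the fixed total
    stressed volume the veins release to the heart, which is the strongest
    and only sign-safe lever on preload, while their ratio keeps the
    population value (the venous pressure levels themselves are fixed by
    the flow balance, so only the common compliance scale is identifiable).
    The ventricular end-systolic elastances keep their stage-identified
    values: with the stroke volume averaged over the two ventricles and
    only the summed end-diastolic volume measured, the contractility split
    is not further constrained by the closed loop.

    ``p0`` warm-starts the sweep from a previously identified parameter
    set (used by the valve-averaged re-identification pass), in which case
    the stage results may be omitted.
    """
    cfg = cfg or IdentificationConfig()
    fixed = dict(fixed or {})
    driL = driL or GaussianDriver.for_period(sp.T)
    driR = driR or driL
    if p0 is not None:
        p = p0.replace(T=sp.T, V_total=cfg.V_total,
                       V_d_lvf=cfg.dead_space_V_d,
                       V_d_rvf=cfg.dead_space_V_d, **fixed)
        alloc = _initial_state(p, sp, "closed")
    else:
        if sysres is None or pulres is None:
            raise ValueError("stage results required when p0 is not given")
        P_vc_t = pulres.params["P_vc"]
        # venous elastances: population ratio, level from the allocation
        E_vc0, E_pu0 = cfg.E_vc_population, cfg.E_pu_population
        p = _assemble(sysres, pulres, sp, cfg, E_vc=E_vc0, E_pu=E_pu0)
        alloc = _initial_state(p, sp, "closed")
        level = max((P_vc_t / alloc[2]) / E_vc0, 1e-6)
        p = _assemble(sysres, pulres, sp, cfg, E_vc=E_vc0 * level,
                      E_pu=E_pu0 * level)

    meas = {"GEDV": sp.GEDV, "SV": sp.SV, "MAP": sp.MAP, "MPAP": sp.MPAP,
            "PP_ao": sp.PP_ao, "PP_pa": sp.PP_pa, "dPao_max": sp.dPao_max,
            "dPpa_max": sp.dPpa_max}
    flags: list[str] = []
    inner_iters = {"systemic": sysres.n_iters if sysres else 0,
                   "pulmonary": pulres.n_iters if pulres else 0}
    trace: list[float] = []
    y = alloc
    # GEDV leads the sweep: the venous level governs overall feasibility
    sweep_plan: list[tuple[str, str]] = [("GEDV", "_venous_level")] +         [(r.output_name, r.parameter_name) for r in CLOSED_PAIRS
         if r.parameter_name not in fixed]
    if {"E_vc", "E_pu"} & set(fixed):
        sweep_plan = sweep_plan[1:]
    relations = {r.parameter_name: _resolve_relation(r, cfg, p, sp)
                 for r in CLOSED_PAIRS}
    relations["_venous_level"] = "proportional"

    state = {"p_good": None, "y_good": None}

    def _simulate(pp: CirculationParams, yy: np.ndarray):
        """Steady state + sampled beat; backtracks toward the last good
        parameter set if the solver fails on a pathological iterate."""
        nonlocal p
        for _ in range(4):
            try:
                eng = Engine(pp, driL=driL, driR=driR, mode="closed",
                             rtol=cfg.rtol, atol=cfg.atol)
                yy2, _, ss_ok = eng.steady_state(
                    np.asarray(yy, dtype=float), tol=cfg.ss_tol,
                    max_beats=cfg.ss_max_beats)
                b = eng.sample_beats(yy2, 1, cfg.f_s)
                state["p_good"], state["y_good"] = pp, yy2.copy()
                p = pp
                return yy2, b, _closed_outputs(b, sp, cfg.feature), ss_ok
            except SimulationError:
                if state["p_good"] is None:
                    raise
                pp = _blend(pp, state["p_good"], IDENTIFIED_PARAMS)
                yy = state["y_good"]
        flags.append("simulation failure; step retracted")
        pp, yy = state["p_good"], state["y_good"]
        eng = Engine(pp, driL=driL, driR=driR, mode="closed",
                     rtol=cfg.rtol, atol=cfg.atol)
        yy2, _, ss_ok = eng.steady_state(yy, tol=cfg.ss_tol,
                                         max_beats=cfg.ss_max_beats)
        b = eng.sample_beats(yy2, 1, cfg.f_s)
        p = pp
        return yy2, b, _closed_outputs(b, sp, cfg.feature), ss_ok

    def _get(pp: CirculationParams, name: str) -> float:
        return pp.E_pu if name == "_venous_level" else getattr(pp, name)

    def _put(pp: CirculationParams, name: str, value: float
             ) -> CirculationParams:
        if name == "_venous_level":
            factor = value / pp.E_pu
            return pp.replace(E_pu=value, E_vc=pp.E_vc * factor)
        return pp.replace(**{name: value})

    hist: dict[str, tuple[float, float]] = {}
    beat = None
    outs: dict[str, float] = {}
    res: dict[str, float] = {}
    ss_ok = True
    converged = False
    sweeps = 0
    best: dict | None = None
    par_of = {o: q for o, q in sweep_plan}
    # per-output tolerances: the mean/pulse pressures and stroke volume
    # carry the convergence contract; the summed end-diastolic volume and
    # the pressure gradients ride on the cross-talk of the global venous
    # volume lever and settle at the half-percent level
    tols = {k: cfg.inner_tol for k, _ in sweep_plan}
    for k in ("GEDV", "dPao_max", "dPpa_max"):
        if k in tols:
            tols[k] = max(cfg.inner_tol, cfg.outer_tol)
    # generous physiological bounds stop multiplicative runaways
    bounds = {q: (_get(p, q) / 50.0, _get(p, q) * 50.0)
              for _, q in sweep_plan}
    for sweeps in range(1, cfg.max_outer_iters + 1):
        # near the solution only the worst pair moves: full sweeps keep
        # re-perturbing already matched outputs and limit-cycle at the
        # few-tenths-of-a-percent level
        tail = bool(res) and \
            max(res[k] / tols[k] for k, _ in sweep_plan) < 5.0
        if tail:
            worst_out = max((k for k, _ in sweep_plan),
                            key=lambda k: res[k] / tols[k])
            plan = [(worst_out, par_of[worst_out])]
        else:
            plan = sweep_plan
        for out_name, par_name in plan:
            y, beat, outs, ss_ok = _simulate(p, y)
            out = max(outs[out_name], 1e-9 * meas[out_name])
            p_old = _get(p, par_name)
            r_now = abs(out - meas[out_name]) / abs(meas[out_name])
            if r_now < tols[out_name]:
                hist[par_name] = (np.log(p_old), np.log(out))
                continue
            # secant estimate of the local log-gain rescales the step for
            # weakly responding pairs (e.g. the valve resistances)
            exponent = 1.0
            if par_name in hist:
                lp0, lo0 = hist[par_name]
                dlp = np.log(p_old) - lp0
                dlo = np.log(out) - lo0
                if abs(dlp) > 1e-9:
                    g = dlo / dlp
                    expected = 1.0 if relations[par_name] == \
                        "proportional" else -1.0
                    if g * expected > 1e-3:
                        exponent = min(max(1.0 / abs(g), 0.3), 5.0)
            if r_now < 5 * cfg.inner_tol:
                # small, careful steps in the tail: large rescaled steps
                # perturb the other matched outputs more than they gain
                exponent = min(exponent, 1.0)
            if tail:
                # damped single-pair rounds let the residual cycle contract
                exponent *= cfg.damping
            hist[par_name] = (np.log(p_old), np.log(out))
            new = proportional_update(
                p_old, meas[out_name], out,
                relations[par_name], exponent, cfg.ratio_clip)
            lo, hi = bounds[par_name]
            p = _put(p, par_name, min(max(new, lo), hi))
        y, beat, outs, ss_ok = _simulate(p, y)
        res = {k: abs(outs[k] - v) / abs(v) for k, v in meas.items()}
        res["t_mt"] = abs(outs["t_mt"] - sp.t_mt) / sp.t_mt
        res["t_tc"] = abs(outs["t_tc"] - sp.t_tc) / sp.t_tc
        max_rel = max(res[k] / tols[k] for k, _ in sweep_plan)
        trace.append(max(res[k] for k, _ in sweep_plan))
        log.debug("closed sweep %d residuals %s", sweeps,
                  {k: f"{v:.2e}" for k, v in res.items()})
        if ss_ok and (best is None or max_rel < best["max_rel"]):
            best = {"p": p, "y": y.copy(), "beat": beat, "outs": dict(outs),
                    "res": dict(res), "max_rel": max_rel}
        if ss_ok and max_rel < 1.0:
            converged = True
            break
    # the sweep can cycle at the few-tenths-of-a-percent level once the
    # cross-talk of the venous volume lever balances the other pairs;
    # return the best iterate actually visited
    if best is not None:
        p, y, beat = best["p"], best["y"], best["beat"]
        outs, res = best["outs"], best["res"]
        converged = best["max_rel"] < 1.0
    if not ss_ok:
        flags.append("closed-loop steady state not reached")
    if not converged:
        flags.append("whole-model identification did not converge")
    # the identified venous source pressures are the coupled model's own
    # mean venous pressures
    p = p.replace(P_pu=float(np.mean(beat["P_pu"])),
                  P_vc=float(np.mean(beat["P_vc"])))
    final_res = {k: v for k, v in res.items()}
    predicted = _predicted_from_beat(beat, sp, p)
    return IdentifiedModel(params=p, setpoints=sp, residuals=final_res,
                           converged=converged, flags=flags, n_outer=sweeps,
                           inner_iters=inner_iters, predicted=predicted,
                           label=label or sp.label, residual_trace=trace)


def _valves_of(fixed: dict[str, float], stage: str) -> dict[str, float]:
    names = ("R_mt", "R_av") if stage == "systemic" else ("R_tc", "R_pv")
    return {k: v for k, v in fixed.items() if k in names}


def _pair_param(output_name: str) -> str:
    for rules in (SYSTEMIC_PAIRS, PULMONARY_PAIRS, SIXCHAMBER_PAIRS):
        for r in rules:
            if r.output_name == output_name:
                return r.parameter_name
    return output_name


def identify_timepoint(sp: ConvergenceSetPoints,
                       cfg: IdentificationConfig | None = None,
                       driL: DriverFunction | None = None,
                       driR: DriverFunction | None = None,
                       fixed_valves: dict[str, float] | None = None,
                       label: str = "",
                       init_params: CirculationParams | None = None
                       ) -> IdentifiedModel:
    """Full staged identification of one measurement set.

    ``init_params`` skips the decoupled bootstrap stages and warm-starts
    the coupled re-identification from an existing parameter set (used for
    the re-identification pass with averaged valve resistances).
    """
    cfg = cfg or IdentificationConfig()
    driL = driL or GaussianDriver.for_period(sp.T)
    driR = driR or driL
    fixed = dict(fixed_valves or {})
    if init_params is not None:
        return identify_sixchamber(None, None, sp, cfg, driL, driR,
                                   fixed=fixed, label=label or sp.label,
                                   p0=init_params)
    # the decoupled bootstrap stages only seed the coupled re-identification,
    # so they run at a looser tolerance
    bcfg = dc_replace(cfg, inner_tol=max(cfg.inner_tol, cfg.bootstrap_tol))
    sysres = identify_submodel(sp, "systemic", driver=driL, cfg=bcfg,
                               fixed=_valves_of(fixed, "systemic"))
    pulres = identify_submodel(sp, "pulmonary", driver=driR, cfg=bcfg,
                               fixed=_valves_of(fixed, "pulmonary"))
    return identify_sixchamber(sysres, pulres, sp, cfg, driL, driR,
                               fixed=fixed, label=label or sp.label)


# ---------------------------------------------------------------------------
# subject series: valve averaging and re-identification
# ---------------------------------------------------------------------------

@dataclass
class SubjectSeries:
    """Identified models at every timepoint of one subject.

    ``first_pass`` holds the per-timepoint identifications; ``models`` the
    re-identified models sharing the averaged valve resistances.
    """

    first_pass: list[IdentifiedModel]
    valve_resistances: dict[str, float]
    models: list[IdentifiedModel]
    labels: list[str]

    def trajectory(self, name: str) -> np.ndarray:
        """Identified values of one parameter across timepoints."""
        return np.array([getattr(m.params, name) for m in self.models])

    def to_dataframe(self):
        import pandas as pd

        rows = []
        for m in self.models:
            row = {"label": m.label, "converged": m.converged,
                   "max_residual": m.max_residual}
            row.update(m.params.to_dict())
            row.update({f"pred_{k}": v for k, v in m.predicted.items()})
            rows.append(row)
        return pd.DataFrame(rows)


def identify_subject(setpoint_series: Sequence[ConvergenceSetPoints],
                     cfg: IdentificationConfig | None = None,
                     drivers: Sequence[tuple] | None = None) -> SubjectSeries:
    """Identify a timepoint series, average valve resistances, re-identify.

    Timepoints that fail to converge are carried with flags and excluded
    from the valve averages.
    """
    if len(setpoint_series) < 1:
        raise ValueError("need at least one timepoint")
    cfg = cfg or IdentificationConfig()
    first = []
    for i, sp in enumerate(setpoint_series):
        dl, dr = (drivers[i] if drivers is not None else (None, None))
        label = sp.label or f"T{30 * i}"
        first.append(identify_timepoint(sp, cfg, dl, dr, label=label))
    usable = [m for m in first if m.converged]
    pool = usable if usable else first
    valve_avg = {name: float(np.mean([getattr(m.params, name) for m in pool]))
                 for name in VALVE_PARAMS}
    second = []
    for i, (sp, m1) in enumerate(zip(setpoint_series, first)):
        dl, dr = (drivers[i] if drivers is not None else (None, None))
        m2 = identify_timepoint(sp, cfg, dl, dr, fixed_valves=valve_avg,
                                label=m1.label, init_params=m1.params)
        m2.params = m2.params.replace(**valve_avg)
        second.append(m2)
    return SubjectSeries(first_pass=first, valve_resistances=valve_avg,
                         models=second, labels=[m.label for m in first])


def afterload_metric(R_pv: float, R_pul: float, T: float) -> float:
    """Pulmonary arterial elastance E_a = (R_pv + R_pul) / T (mmHg/mL)."""
    if T <= 0:
        raise ValueError("heart period must be positive")
    if R_pv < 0 or R_pul < 0:
        raise ValueError("resistances must be nonnegative")
    return (R_pv + R_pul) / T


# ---------------------------------------------------------------------------
# estimation-style front end
# ---------------------------------------------------------------------------

class TimepointIdentification:
    """Identification of one measurement set, statsmodels-style.

    Parameters
    ----------
    setpoints : ConvergenceSetPoints
        The minimal measurement record for one timepoint.
    config : IdentificationConfig, optional
    driver_left, driver_right : DriverFunction, optional
        Subject-specific activation curves; the population parametric
        driver for the measured period is used when omitted.
    """

    def __init__(self, setpoints: ConvergenceSetPoints,
                 config: IdentificationConfig | None = None,
                 driver_left: DriverFunction | None = None,
                 driver_right: DriverFunction | None = None):
        self.setpoints = setpoints
        self.config = config or IdentificationConfig()
        self.driver_left = driver_left
        self.driver_right = driver_right

    @classmethod
    def from_waveforms(cls, w: WaveformSet,
                       config: IdentificationConfig | None = None,
                       feature_config: FeatureConfig | None = None,
                       label: str = "") -> "TimepointIdentification":
        from .features import extract_setpoints

        config = config or IdentificationConfig()
        fcfg = feature_config or config.feature
        sp = extract_setpoints(w, fcfg, label=label)
        return cls(sp, config)

    def fit(self) -> "IdentificationResults":
        m = identify_timepoint(self.setpoints, self.config,
                               self.driver_left, self.driver_right)
        return IdentificationResults(self, m)


class IdentificationResults:
    """Converged parameter estimates, residual diagnostics and predictions."""

    def __init__(self, model: TimepointIdentification, fit: IdentifiedModel):
        self.model = model
        self._fit = fit
        self.params = fit.params
        self.residuals = fit.residuals
        self.converged = fit.converged
        self.flags = fit.flags
        self.predicted = fit.predicted

    @property
    def identified(self) -> IdentifiedModel:
        return self._fit

    def simulate(self, **kwargs) -> WaveformSet:
        return self._fit.simulate(**kwargs)

    def summary(self) -> str:
        sp = self._fit.setpoints
        lines = [
            "Subject-specific circulation model identification",
            "=" * 49,
            f"label: {self._fit.label or '-'}    converged: {self.converged}"
            f"    outer iterations: {self._fit.n_outer}",
            f"heart period T = {sp.T:.4f} s ({sp.heart_rate:.0f} bpm)",
            "",
            "Identified parameters",
            "-" * 49,
        ]
        for name in ("E_es_lvf", "E_es_rvf", "E_ao", "E_pa", "E_vc", "E_pu",
                     "R_mt", "R_av", "R_sys", "R_tc", "R_pv", "R_pul"):
            lines.append(f"  {name:<10} {getattr(self.params, name):>12.5g}")
        lines += ["", "Matched outputs (relative residuals)", "-" * 49]
        for k, v in self.residuals.items():
            lines.append(f"  {k:<10} {100 * v:>10.3f} %")
        lines += ["", "Predicted validation quantities", "-" * 49]
        for k in ("LVEDV", "RVEDV", "P_lv_max", "P_rv_max", "E_a", "RVAC"):
            lines.append(f"  {k:<10} {self.predicted[k]:>12.4g}")
        if self.flags:
            lines += ["", "flags: " + "; ".join(self.flags)]
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        beat = self.simulate()
        return beat.plot(ax=ax)


class SubjectIdentification:
    """Identification of a full timepoint series for one subject."""

    def __init__(self, setpoint_series: Sequence[ConvergenceSetPoints],
                 config: IdentificationConfig | None = None):
        self.setpoint_series = list(setpoint_series)
        self.config = config or IdentificationConfig()

    @classmethod
    def from_waveforms(cls, waveform_sets: Sequence[WaveformSet],
                       config: IdentificationConfig | None = None,
                       feature_config: FeatureConfig | None = None
                       ) -> "SubjectIdentification":
        from .features import extract_setpoints

        config = config or IdentificationConfig()
        fcfg = feature_config or config.feature
        sps = [extract_setpoints(w, fcfg, label=f"T{30 * i}")
               for i, w in enumerate(waveform_sets)]
        return cls(sps, config)

    def fit(self) -> "SubjectSeriesResults":
        series = identify_subject(self.setpoint_series, self.config)
        return SubjectSeriesResults(self, series)


class SubjectSeriesResults:
    """Series of identified models with shared averaged valve resistances."""

    def __init__(self, model: SubjectIdentification, series: SubjectSeries):
        self.model = model
        self.series = series
        self.models = series.models
        self.valve_resistances = series.valve_resistances

    def trajectory(self, name: str) -> np.ndarray:
        return self.series.trajectory(name)

    def to_dataframe(self):
        return self.series.to_dataframe()

    def summary(self) -> str:
        df = self.to_dataframe()
        lines = [
            "Subject series identification",
            "=" * 49,
            f"timepoints: {len(self.models)}   converged: "
            f"{sum(m.converged for m in self.models)}",
            "averaged valve resistances: " + ", ".join(
                f"{k}={v:.4g}" for k, v in self.valve_resistances.items()),
            "",
            df[["label", "converged", "max_residual", "R_sys", "R_pul",
                "E_es_lvf", "E_es_rvf"]].to_string(index=False),
        ]
        return "\n".join(lines)

    def plot_trajectories(self, names=("R_sys", "R_pul"), ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(len(self.models))
        for name in names:
            ax.plot(x, self.trajectory(name), marker="o", label=name)
        ax.set_xticks(x, [m.label for m in self.models])
        ax.set_ylabel("identified value")
        ax.legend()
        return ax
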