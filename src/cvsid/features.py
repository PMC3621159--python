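"""Beat-level feature extraction: waveforms -> convergence set points.

The identification needs only discrete features of one good heartbeat:
means, amplitudes and maximum ascending gradients of the arterial
pressures, stroke volume, global end-diastolic volume, and the AV-valve
closure times read off the normalised driver function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .driver import DriverFunction, GaussianDriver, SampledDriver
from .model import WaveformSet

__all__ = [
    "ConvergenceSetPoints",
    "FeatureConfig",
    "waveform_mean",
    "waveform_amplitude",
    "max_ascending_gradient",
    "stroke_volume",
    "gedv",
    "end_diastolic_volume",
    "estimate_driver",
    "valve_closure_time",
    "extract_setpoints",
]


@dataclass
class ConvergenceSetPoints:
    """The minimal measurement record driving model identification."""

    GEDV: float      # mL
    SV: float        # mL
    MAP: float       # mmHg
    MPAP: float      # mmHg
    PP_ao: float     # mmHg
    PP_pa: float     # mmHg
    dPao_max: float  # mmHg/s
    dPpa_max: float  # mmHg/s
    t_mt: float      # s, mitral closure relative to beat onset
    t_tc: float      # s, tricuspid closure relative to beat onset
    T: float         # s, beat period
    label: str = ""

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if not self.GEDV > self.SV > 0:
            raise ValueError("requires GEDV > SV > 0")
        if self.PP_ao <= 0 or self.PP_pa <= 0:
            raise ValueError("pulse pressures must be positive")
        if self.T <= 0:
            raise ValueError("beat period must be positive")
        for name in ("t_mt", "t_tc"):
            v = getattr(self, name)
            if not 0 <= v < self.T:
                raise ValueError(f"{name} must lie in [0, T)")

    @property
    def heart_rate(self) -> float:
        return 60.0 / self.T

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        d["heart_rate"] = self.heart_rate
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConvergenceSetPoints":
        d = dict(d)
        d.pop("heart_rate", None)
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "ConvergenceSetPoints":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class FeatureConfig:
    """Extraction settings.

    A Savitzky-Golay window of ``smooth_window_s`` seconds is applied to
    every trace before feature read-off (noise suppression; the same
    extractor is used on model output during identification so the
    definition is consistent on both sides, and a time-based window keeps
    the features sampling-rate invariant). ``deriv_window`` is the 5-point
    quadratic smoothing of the first derivative. ``delta`` is the
    activation-onset threshold defining AV-valve closure on the driver.
    """

    smooth_window_s: float = 0.075
    smooth_polyorder: int = 3
    deriv_window: int = 5
    delta: float = 0.05
    driver_source: str = "parametric"  # or "estimated"
    driver_grid: int = 512


def _smooth(x: np.ndarray, cfg: FeatureConfig, f_s: float) -> np.ndarray:
    w = int(round(cfg.smooth_window_s * f_s))
    w = min(w, len(x) - (1 - len(x) % 2))
    if w <= cfg.smooth_polyorder + 1:
        return x
    if w % 2 == 0:
        w -= 1
    return savgol_filter(x, w, cfg.smooth_polyorder, mode="wrap")


def waveform_mean(trace: np.ndarray, t: np.ndarray | None = None,
                  period: float | None = None) -> float:
    """Time-weighted (trapezoidal) mean over one beat.

    With ``period`` given, the wrap-around segment from the last sample
    back to the first closes the beat, so the mean covers exactly one
    period of the periodic waveform.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if trace.size == 1:
        return float(trace[0])
    if t is None:
        t = np.arange(trace.size, dtype=float)
    area = float(np.trapezoid(trace, t))
    span = float(t[-1] - t[0])
    if period is not None and period > span:
        area += 0.5 * (trace[-1] + trace[0]) * (period - span)
        span = period
    return area / span


def waveform_amplitude(trace: np.ndarray) -> float:
    """Max minus min over the beat (pulse pressure / stroke excursion)."""
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    return float(trace.max() - trace.min())


def max_ascending_gradient(trace: np.ndarray, f_s: float,
                           window: int = 5) -> float:
    """Maximum of the smoothed first derivative (mmHg/s).

    The derivative uses a quadratic Savitzky-Golay window (default 5
    points), i.e. smoothed central differences.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size < window:
        raise ValueError("trace shorter than the smoothing window")
    d = savgol_filter(trace, window, 2, deriv=1, delta=1.0 / f_s, mode="wrap")
    return float(d.max())


def _refined_extremum(x: np.ndarray, idx: int) -> float:
    """Parabolic sub-sample refinement of a sampled extremum (periodic)."""
    n = x.size
    if n < 3:
        return float(x[idx])
    a, b, c = x[(idx - 1) % n], x[idx], x[(idx + 1) % n]
    denom = a - 2.0 * b + c
    if abs(denom) < 1e-12:
        return float(b)
    delta = 0.5 * (a - c) / denom
    if not -1.0 <= delta <= 1.0:
        return float(b)
    return float(b - 0.25 * (a - c) * delta)


def refined_amplitude(trace: np.ndarray) -> float:
    """Max minus min with sub-sample refinement of both extremes.

    Keeps amplitudes invariant to the sampling rate where the plain
    sampled max/min would discretise the extremes.
    """
    x = np.asarray(trace, dtype=float)
    if x.size == 0:
        raise ValueError("empty trace")
    hi = _refined_extremum(x, int(np.argmax(x)))
    lo = _refined_extremum(x, int(np.argmin(x)))
    return hi - lo


def stroke_volume(V_lv: np.ndarray | None, V_rv: np.ndarray | None) -> float:
    """Average of the left and right ventricular volume amplitudes."""
    amps = [refined_amplitude(v) for v in (V_lv, V_rv) if v is not None]
    if not amps:
        raise ValueError("need at least one ventricular volume trace")
    return float(np.mean(amps))


def gedv(LVEDV: float, RVEDV: float) -> float:
    """Global end-diastolic volume: LVEDV + RVEDV."""
    if LVEDV < 0 or RVEDV < 0:
        raise ValueError("end-diastolic volumes must be nonnegative")
    return LVEDV + RVEDV


def end_diastolic_volume(V: np.ndarray, f_s: float, T: float,
                         onset_time: float) -> float:
    """Volume maximum in the half-beat preceding activation onset.

    ``onset_time`` is the activation onset (valve closure) relative to the
    beat start; the search window wraps around the beat boundary.
    """
    V = np.asarray(V, dtype=float)
    n = V.size
    i_on = int(round(onset_time * f_s))
    if not 0 <= i_on <= n:
        raise ValueError("onset marker outside the trace")
    half = int(round(0.5 * T * f_s))
    idx = (np.arange(i_on - half, i_on + 1) % n)
    return float(V[idx].max())


def valve_closure_time(d: DriverFunction, delta: float = 0.05,
                       grid: int = 4096) -> float:
    """Time at which the driver first exceeds ``delta`` of its maximum.

    Activation onset coincides with AV-valve closure. Linear interpolation
    between grid samples gives sub-sample resolution.
    """
    if not 0 < delta < 1:
        raise ValueError("delta must lie in (0, 1)")
    vals = d.sample(grid)
    thr = delta * vals.max()
    above = vals >= thr
    if not above.any():
        raise ValueError("driver never exceeds the threshold")
    i = int(np.argmax(above))
    dt = d.T / grid
    if i == 0:
        return 0.0
    # linear interpolation of the crossing inside [i-1, i]
    v0, v1 = vals[i - 1], vals[i]
    frac = (thr - v0) / (v1 - v0) if v1 > v0 else 0.0
    return float(((i - 1) + frac) * dt)


def valve_closure_from_pressures(P_v: np.ndarray, P_upstream: np.ndarray,
                                 f_s: float) -> float:
    """AV-valve closure time read from the pressure crossing.

    The inflow valve closes when the rising ventricular pressure first
    exceeds the upstream (venous) pressure after beat onset; the crossing
    is located by linear interpolation between samples. Returns half a
    sample interval when the valve is already closed at onset.
    """
    d = np.asarray(P_upstream, dtype=float) - np.asarray(P_v, dtype=float)
    n = d.size
    if n < 2:
        raise ValueError("need at least two samples")
    stop = max(2, int(0.6 * n))
    if d[0] <= 0:
        return 0.5 / f_s
    for i in range(1, stop):
        if d[i] <= 0:
            frac = d[i - 1] / (d[i - 1] - d[i])
            return float((i - 1 + frac) / f_s)
    return float((stop - 1) / f_s)


def estimate_driver(P_art: np.ndarray, T: float, f_s: float,
                    SV: float | None = None, GEDV: float | None = None,
                    cfg: FeatureConfig | None = None) -> DriverFunction:
    """Normalised time-varying elastance estimated from an arterial beat.

    During the ejection window (steepest upstroke to the dicrotic landmark)
    the activation follows the normalised arterial pressure; outside it the
    curve ramps up from and decays back to zero. Degenerate inputs fall
    back to the population parametric driver (flagged).
    """
    cfg = cfg or FeatureConfig()
    P = np.asarray(P_art, dtype=float)
    n = P.size
    if T <= 0:
        raise ValueError("beat period must be positive")
    if n < 8 or np.ptp(P) < 1e-9:
        return _fallback_driver(T)
    P = _smooth(P, cfg, f_s)
    dP = savgol_filter(P, min(cfg.deriv_window, n - (1 - n % 2)), 2, deriv=1,
                       delta=1.0 / f_s, mode="wrap")
    i_on = int(np.argmax(dP))          # steepest upstroke: ejection onset
    i_pk = int(np.argmax(P))           # systolic peak
    # dicrotic landmark: steepest fall after the peak
    tail = dP.copy()
    order = (np.arange(n) - i_pk) % n
    tail[order > n // 2] = np.inf      # only look half a beat past the peak
    tail[order == 0] = np.inf
    i_off = int(np.argmin(tail))
    if np.ptp(P) <= 0 or i_on == i_off:
        return _fallback_driver(T)
    base = P.min()
    span = P.max() - base
    # indices of the ejection window, wrapped
    length = (i_off - i_on) % n
    if length < 3 or length > 0.8 * n:
        return _fallback_driver(T)
    idx = (i_on + np.arange(length + 1)) % n
    shape = (P[idx] - base) / span
    shape = np.clip(shape, 0.0, None)
    g = cfg.driver_grid
    vals = np.zeros(g)
    tgrid = np.arange(g) / g * T
    t_on = i_on / f_s
    t_off = t_on + length / f_s
    # ejection segment
    seg_t = t_on + np.arange(length + 1) / f_s
    vals_idx = np.interp(tgrid, seg_t, shape, left=np.nan, right=np.nan)
    in_win = ~np.isnan(vals_idx)
    vals[in_win] = vals_idx[in_win]
    # cosine ramp up before ejection (isovolumetric contraction)
    rise = max(3, int(0.08 * g))
    for k in range(rise):
        tt = t_on - (rise - k) / g * T
        j = int(np.floor((tt % T) / T * g))
        vals[j] = max(vals[j], shape[0] * 0.5 * (1 + np.cos(np.pi * (rise - k) / rise)))
    # exponential decay after the dicrotic landmark (relaxation)
    tau = 0.08 * T
    decay_len = max(3, int(0.3 * g))
    for k in range(1, decay_len):
        tt = t_off + k / g * T
        j = int(np.floor((tt % T) / T * g))
        vals[j] = max(vals[j], shape[-1] * np.exp(-(k / g * T) / tau))
    m = vals.max()
    if m <= 0:
        return _fallback_driver(T)
    return SampledDriver(T=T, values=vals / m, estimated=True)


def _fallback_driver(T: float) -> DriverFunction:
    d = GaussianDriver.for_period(T)
    sd = SampledDriver(T=T, values=d.sample(512), estimated=True, fallback=True)
    return sd


def extract_setpoints(w: WaveformSet, cfg: FeatureConfig | None = None,
                      beat: int = -1, label: str = "") -> ConvergenceSetPoints:
    """Assemble the full set-point record from one selected beat.

    The last complete beat is used by default. Every trace is pre-smoothed
    with the configured Savitzky-Golay window before read-off.
    """
    cfg = cfg or FeatureConfig()
    if w.n_beats < 1:
        raise ValueError("waveform set contains no complete beat")
    b = w.beat(beat if beat >= 0 else w.n_beats + beat)
    T, f_s = w.T, w.f_s

    def sm(name: str) -> np.ndarray:
        return _smooth(b[name], cfg, f_s)

    P_ao, P_pa = sm("P_ao"), sm("P_pa")
    MAP = waveform_mean(P_ao, b.t, period=T)
    MPAP = waveform_mean(P_pa, b.t, period=T)
    PP_ao = refined_amplitude(P_ao)
    PP_pa = refined_amplitude(P_pa)
    dPao = max_ascending_gradient(P_ao, f_s, cfg.deriv_window)
    dPpa = max_ascending_gradient(P_pa, f_s, cfg.deriv_window)

    if cfg.driver_source == "estimated":
        driL = estimate_driver(b["P_ao"], T, f_s, cfg=cfg)
        driR = estimate_driver(b["P_pa"], T, f_s, cfg=cfg)
    elif cfg.driver_source == "parametric":
        driL = driR = GaussianDriver.for_period(T)
    else:
        raise ValueError(f"unknown driver_source {cfg.driver_source!r}")
    # valve closure: read the actual pressure crossing when ventricular and
    # venous traces were recorded; fall back to the activation-onset
    # threshold on the driver for arterial-only records
    if "P_lv" in b and "P_pu" in b:
        t_mt = valve_closure_from_pressures(sm("P_lv"), sm("P_pu"), f_s)
    else:
        t_mt = valve_closure_time(driL, cfg.delta)
    if "P_rv" in b and "P_vc" in b:
        t_tc = valve_closure_from_pressures(sm("P_rv"), sm("P_vc"), f_s)
    else:
        t_tc = valve_closure_time(driR, cfg.delta)

    V_lv = sm("V_lv") if "V_lv" in b else None
    V_rv = sm("V_rv") if "V_rv" in b else None
    if V_lv is None and V_rv is None:
        raise ValueError("need at least one ventricular volume trace")
    SV = stroke_volume(V_lv, V_rv)
    edvs = []
    if V_lv is not None:
        edvs.append(end_diastolic_volume(V_lv, f_s, T, t_mt))
    if V_rv is not None:
        edvs.append(end_diastolic_volume(V_rv, f_s, T, t_tc))
    GEDV = gedv(edvs[0], edvs[-1]) if len(edvs) == 2 else 2.0 * edvs[0]

    return ConvergenceSetPoints(
        GEDV=GEDV, SV=SV, MAP=MAP, MPAP=MPAP, PP_ao=PP_ao, PP_pa=PP_pa,
        dPao_max=dPao, dPpa_max=dPpa, t_mt=t_mt, t_tc=t_tc, T=T, label=label)
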