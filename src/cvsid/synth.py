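"""Virtual subjects with endotoxic-shock parameter trajectories.

The generator produces ground-truth circulation parameter sets (baselines
sampled around the standard initial estimates, then evolved along
phenomenological septic-shock trends: systemic resistance falls, pulmonary
resistance rises, heart rate climbs) and the corresponding "measured"
waveform records at 200 Hz with multiplicative sensor noise. It exists so
the identification pipeline and its validation statistics can be exercised
end to end with known truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np

from .model import Engine, SimulationError, WaveformSet, steady_state_beat
from .features import (ConvergenceSetPoints, FeatureConfig,
                       extract_setpoints)
from .params import CirculationParams

__all__ = [
    "SepsisTrajectoryConfig",
    "VirtualSubject",
    "SubjectDataset",
    "sample_baseline",
    "septic_trajectory",
    "generate_dataset",
    "write_dataset",
]

#: Parameters drawn per subject, anchored at the standard initial estimates.
SAMPLED_PARAMS: tuple[str, ...] = (
    "E_es_lvf", "R_mt", "R_sys", "E_ao", "R_av",
    "E_es_rvf", "R_tc", "R_pul", "E_pa", "R_pv",
)

#: Signals carried into the "measured" record (with noise when enabled).
MEASURED_SIGNALS: tuple[str, ...] = ("P_ao", "P_pa", "P_lv", "V_lv", "P_rv",
                                     "V_rv", "P_vc", "P_pu")


@dataclass
class SepsisTrajectoryConfig:
    """Shape of the induced septic-shock trends.

    The systemic resistance declines by ``r_sys_drop_fraction`` of baseline
    by the 120-minute timepoint (logistic in time between 30 and 120 min)
    and the pulmonary resistance rises by ``r_pul_rise_fraction``;
    contractilities stay constant. Responders relax back toward their
    baseline systemic resistance during the treatment phase.
    """

    n_timepoints: int = 9           # T0 ... T240 at 30-min spacing
    interval_min: float = 30.0
    r_sys_drop_fraction: float = 0.42
    r_pul_rise_fraction: float = 0.5
    responder: bool = False
    recovery_tau_min: float = 90.0  # responder relaxation time constant
    hr_rise_fraction: float = 0.15
    noise_sd: float = 0.03          # multiplicative, per sample and signal
    rv_underestimation: float = 1.0  # < 1 emulates conductance-catheter bias
    logistic_midpoint_min: float = 75.0
    logistic_rate_per_min: float = 0.08

    def __post_init__(self) -> None:
        for name in ("r_sys_drop_fraction", "r_pul_rise_fraction"):
            if not 0 <= getattr(self, name) < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.n_timepoints < 1:
            raise ValueError("need at least one timepoint")

    def times_min(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.interval_min

    def labels(self) -> list[str]:
        return [f"T{int(t)}" for t in self.times_min()]

    def _shape(self, tau: float) -> float:
        """Normalised logistic trend, 0 at T0, 1 at the 120-min mark."""
        k, t0 = self.logistic_rate_per_min, self.logistic_midpoint_min

        def s(t):
            return 1.0 / (1.0 + np.exp(-k * (t - t0)))

        val = (s(tau) - s(0.0)) / (s(120.0) - s(0.0))
        return float(min(max(val, 0.0), 1.0))


@dataclass
class VirtualSubject:
    """Ground-truth baseline parameters for one synthetic animal."""

    baseline: CirculationParams
    seed: int
    screen: dict = field(default_factory=dict)


@dataclass
class SubjectDataset:
    """Per-timepoint measured records plus the generating truth."""

    subject: VirtualSubject
    labels: list[str]
    waveforms: list[WaveformSet]
    setpoints: list[ConvergenceSetPoints]
    truth_params: list[CirculationParams]
    truth_outputs: list[dict]
    flags: list[str] = field(default_factory=list)


def sample_baseline(seed: int, max_tries: int = 50,
                    spread: float = 0.30,
                    hr_range: tuple[float, float] = (80.0, 160.0),
                    map_range: tuple[float, float] = (50.0, 130.0),
                    sv_range: tuple[float, float] = (20.0, 60.0)
                    ) -> VirtualSubject:
    """Draw a physiologically screened ground-truth baseline.

    Elastances and resistances are sampled uniformly within ``spread`` of
    the standard initial estimates; the heart rate uniformly in
    ``hr_range``. Venous elastances and the total stressed volume are
    population constants (the measurement set identifies only their common
    scale, so sampling them would make the virtual population
    unidentifiable by construction). Draws whose steady-state beat falls
    outside the mean-pressure or stroke-volume screens are rejected.
    """
    rng = np.random.default_rng(seed)
    defaults = CirculationParams()
    for attempt in range(max_tries):
        hr = rng.uniform(*hr_range)
        draw = {name: getattr(defaults, name)
                * (1.0 + rng.uniform(-spread, spread))
                for name in SAMPLED_PARAMS}
        p = defaults.replace(T=60.0 / hr, **draw)
        try:
            beat = steady_state_beat(p)
        except SimulationError:
            continue
        if not beat.meta["converged"]:
            continue
        MAP = float(np.mean(beat["P_ao"]))
        SV = float(0.5 * (np.ptp(beat["V_lv"]) + np.ptp(beat["V_rv"])))
        if map_range[0] <= MAP <= map_range[1] and \
                sv_range[0] <= SV <= sv_range[1]:
            return VirtualSubject(baseline=p, seed=seed,
                                  screen={"MAP": MAP, "SV": SV,
                                          "attempts": attempt + 1})
    raise RuntimeError(f"no physiological baseline found in {max_tries} draws "
                       f"for seed {seed}")


def septic_trajectory(subject: VirtualSubject,
                      cfg: SepsisTrajectoryConfig | None = None
                      ) -> list[CirculationParams]:
    """Ground-truth parameter sets along the induced-shock time course."""
    cfg = cfg or SepsisTrajectoryConfig()
    base = subject.baseline
    out = []
    for tau in cfg.times_min():
        s = cfg._shape(float(tau))
        drop = cfg.r_sys_drop_fraction * s
        if cfg.responder and tau > 120.0:
            drop *= float(np.exp(-(tau - 120.0) / cfg.recovery_tau_min))
        hr = base.heart_rate * (1.0 + cfg.hr_rise_fraction * s)
        out.append(base.replace(
            R_sys=base.R_sys * (1.0 - drop),
            R_pul=base.R_pul * (1.0 + cfg.r_pul_rise_fraction * s),
            T=60.0 / hr))
    return out


def _true_outputs(beat: WaveformSet, p: CirculationParams) -> dict:
    from .identify import afterload_metric

    E_a = afterload_metric(p.R_pv, p.R_pul, p.T)
    return {
        "LVEDV": float(beat["V_lv"].max()),
        "RVEDV": float(beat["V_rv"].max()),
        "P_lv_max": float(beat["P_lv"].max()),
        "P_rv_max": float(beat["P_rv"].max()),
        "MAP": float(np.mean(beat["P_ao"])),
        "MPAP": float(np.mean(beat["P_pa"])),
        "SV": float(0.5 * (np.ptp(beat["V_lv"]) + np.ptp(beat["V_rv"]))),
        "E_a": E_a,
        "RVAC": p.E_es_rvf / E_a,
    }


def generate_dataset(subject: VirtualSubject,
                     cfg: SepsisTrajectoryConfig | None = None,
                     f_s: float = 200.0, beats: int = 8,
                     noise: bool = True, seed: int | None = None,
                     feature_config: FeatureConfig | None = None
                     ) -> SubjectDataset:
    """Simulate, corrupt and feature-extract one subject's full record.

    Every timepoint is simulated to its periodic steady state; ``beats``
    consecutive beats are emitted at ``f_s`` with multiplicative Gaussian
    noise applied per sample and signal when ``noise`` is on. The right
    ventricular volume trace can additionally be shrunk about its mean to
    emulate conductance-catheter underestimation; the stored ground truth
    is never touched. Timepoints whose simulation fails to settle are
    flagged and omitted, like the unusable records of a real trial.
    """
    cfg = cfg or SepsisTrajectoryConfig()
    fcfg = feature_config or FeatureConfig()
    rng = np.random.default_rng(subject.seed if seed is None else seed)
    labels_all = cfg.labels()
    trajectory = septic_trajectory(subject, cfg)
    labels, waves, sps, truths, t_outs, flags = [], [], [], [], [], []
    for label, p in zip(labels_all, trajectory):
        try:
            ss = steady_state_beat(p)
        except SimulationError as exc:
            flags.append(f"{label}: simulation failed ({exc})")
            continue
        if not ss.meta["converged"]:
            flags.append(f"{label}: steady state not reached, record dropped")
            continue
        eng = Engine(p)
        record = eng.sample_beats(ss.meta["state0"], beats, f_s)
        signals = {k: record[k].copy() for k in MEASURED_SIGNALS}
        if cfg.rv_underestimation != 1.0:
            m = signals["V_rv"].mean()
            signals["V_rv"] = m + cfg.rv_underestimation * (signals["V_rv"] - m)
        if noise and cfg.noise_sd > 0:
            for k in signals:
                signals[k] = signals[k] * (
                    1.0 + cfg.noise_sd * rng.standard_normal(len(signals[k])))
        w = WaveformSet(t=record.t, f_s=f_s, T=p.T, signals=signals,
                        beat_onsets=record.beat_onsets,
                        meta={"label": label, "noise_sd":
                              cfg.noise_sd if noise else 0.0})
        labels.append(label)
        waves.append(w)
        sps.append(extract_setpoints(w, fcfg, label=label))
        truths.append(p)
        t_outs.append(_true_outputs(ss, p))
    return SubjectDataset(subject=subject, labels=labels, waveforms=waves,
                          setpoints=sps, truth_params=truths,
                          truth_outputs=t_outs, flags=flags)


def write_dataset(ds: SubjectDataset, out_dir: str | Path) -> None:
    """Write waveform CSVs, set-point JSONs and the ground-truth record."""
    from .io import write_waveforms

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth = {
        "seed": ds.subject.seed,
        "flags": ds.flags,
        "timepoints": {
            label: {"params": p.to_dict(), "outputs": outs}
            for label, p, outs in zip(ds.labels, ds.truth_params,
                                      ds.truth_outputs)
        },
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=1, sort_keys=True))
    for label, w, sp in zip(ds.labels, ds.waveforms, ds.setpoints):
        write_waveforms(w, out / f"waveforms_{label}.csv")
        sp.to_json(out / f"setpoints_{label}.json")
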