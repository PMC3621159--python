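"""File formats and run configuration.

Waveforms travel as flat CSV (comma separated, dot decimal, mandatory
header, time column ``t`` in seconds); structured records (set points,
identified models, ground truth) as JSON keyed by the standard parameter
symbols; run configuration as YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .features import FeatureConfig
from .identify import (IdentificationConfig, IdentifiedModel, SubjectSeries)
from .model import WaveformSet
from .params import CirculationParams
from .synth import SepsisTrajectoryConfig

__all__ = [
    "RunConfig",
    "read_waveforms",
    "write_waveforms",
    "write_identified",
    "read_identified",
    "config_hash",
]

REQUIRED_COLUMNS = ("t", "P_ao", "P_pa")


def write_waveforms(w: WaveformSet, path: str | Path) -> None:
    """Write a waveform set as CSV (deterministic float formatting)."""
    df = pd.DataFrame({"t": w.t, **{k: w.signals[k] for k in w.signals}})
    df.to_csv(path, index=False, float_format="%.10g")


def read_waveforms(path: str | Path, f_s: float | None = None,
                   T: float | None = None) -> WaveformSet:
    """Load a waveform CSV into a validated, uniformly sampled record.

    The time base must be uniform and strictly increasing; the sampling
    frequency is inferred from it. The beat period is taken from ``T`` or
    detected from the aortic pressure autocorrelation; beat onsets are
    placed at multiples of the period.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required columns: {missing}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) < 4:
        raise ValueError("waveform record too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValueError("time base must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("time base must be uniformly sampled")
    fs = f_s or 1.0 / dt[0]
    signals = {c: df[c].to_numpy(dtype=float) for c in df.columns if c != "t"}
    period = T if T is not None else _detect_period(signals["P_ao"], fs)
    n = int(round(period * fs))
    onsets = np.arange(0, len(t) - n + 1, n)
    missing_opt = [c for c in ("P_lv", "V_lv", "P_rv", "V_rv")
                   if c not in signals]
    return WaveformSet(t=t - t[0], f_s=fs, T=period, signals=signals,
                       beat_onsets=onsets,
                       meta={"source": str(path),
                             "absent_optional": missing_opt})


def _detect_period(trace: np.ndarray, f_s: float,
                   hr_range: tuple[float, float] = (30.0, 250.0)) -> float:
    """Beat period from the first autocorrelation peak in the heart-rate band."""
    x = trace - trace.mean()
    ac = np.correlate(x, x, mode="full")[len(x) - 1:]
    lo = max(2, int(f_s * 60.0 / hr_range[1]))
    hi = min(len(ac) - 1, int(f_s * 60.0 / hr_range[0]))
    if hi <= lo:
        raise ValueError("record too short to detect the beat period")
    lag = lo + int(np.argmax(ac[lo:hi]))
    return lag / f_s


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    f_s: float = 200.0
    seed: int = 1
    n_subjects: int = 1
    beats: int = 8
    noise: bool = True
    log_level: str = "INFO"
    identification: IdentificationConfig = field(
        default_factory=IdentificationConfig)
    trajectory: SepsisTrajectoryConfig = field(
        default_factory=SepsisTrajectoryConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        ident = d.pop("identification", {})
        traj = d.pop("trajectory", {})
        if set(ident) - {f.name for f in
                         dataclasses.fields(IdentificationConfig)}:
            raise ValueError("unknown identification configuration keys")
        if set(traj) - {f.name for f in
                        dataclasses.fields(SepsisTrajectoryConfig)}:
            raise ValueError("unknown trajectory configuration keys")
        feat = ident.pop("feature", {})
        icfg = IdentificationConfig(**ident)
        if feat:
            icfg.feature = FeatureConfig(**feat)
        return cls(identification=icfg,
                   trajectory=SepsisTrajectoryConfig(**traj), **d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


def config_hash(cfg: IdentificationConfig | RunConfig) -> str:
    """Stable digest of a configuration (changes when any setting does)."""
    d = cfg.to_dict() if isinstance(cfg, RunConfig) else dataclasses.asdict(cfg)
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _model_record(m: IdentifiedModel) -> dict:
    return {
        "label": m.label,
        "params": m.params.to_dict(),
        "residuals": m.residuals,
        "converged": m.converged,
        "flags": m.flags,
        "n_outer": m.n_outer,
        "inner_iters": m.inner_iters,
        "predicted": m.predicted,
    }


def write_identified(model: IdentifiedModel | SubjectSeries,
                     path: str | Path,
                     cfg: IdentificationConfig | None = None,
                     seed: int | None = None) -> None:
    """Serialise an identified model or subject series as JSON."""
    meta = {"config_hash": config_hash(cfg) if cfg else None, "seed": seed}
    if isinstance(model, SubjectSeries):
        doc = {
            "kind": "subject_series",
            "valve_resistances": model.valve_resistances,
            "first_pass": [_model_record(m) for m in model.first_pass],
            "models": [_model_record(m) for m in model.models],
            **meta,
        }
    else:
        doc = {"kind": "timepoint", **_model_record(model), **meta}
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_identified(path: str | Path) -> dict:
    """Load an identified-model JSON document (raw dictionary form)."""
    return json.loads(Path(path).read_text())
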