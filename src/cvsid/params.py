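"""Model parameters for the six-chamber lumped cardiovascular system.

The circulation is described by two actively elastic ventricles (linear
end-systolic and exponential end-diastolic pressure-volume relationships,
blended by a normalised activation), four passively elastic chambers
(aorta, vena cava, pulmonary artery, pulmonary vein), six resistive flow
paths, and a septum/pericardium coupling. Units are fixed package-wide:
pressure mmHg, volume mL, time s, elastance mmHg/mL, resistance mmHg*s/mL.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

__all__ = [
    "VentricleParams",
    "SeptumPericardiumParams",
    "CirculationParams",
    "MODEL_CONSTANTS",
    "SYSTEMIC_INITIAL",
    "PULMONARY_INITIAL",
]

#: Population constants of the model (held fixed during identification).
MODEL_CONSTANTS: dict[str, float] = {
    "P_0_lvf": 0.0,
    "lambda_lvf": 0.033,
    "V_d_lvf": 23.0,
    "V_0_lvf": 0.0,
    "P_0_rvf": 0.0,
    "lambda_rvf": 0.023,
    "V_d_rvf": 23.0,
    "V_0_rvf": 0.0,
    "V_d_spt": 2.0,
    "V_0_spt": 2.0,
    "lambda_spt": 0.435,
    "P_0_spt": 1.1101,
    "E_es_spt": 48.754,
    "P_0_pcd": 0.5003,
    "V_0_pcd": 200.0,
    "lambda_pcd": 0.03,
    "P_th": 0.0,
    "V_d_ao": 0.0,
    "V_d_vc": 0.0,
    "V_d_pa": 0.0,
    "V_d_pu": 0.0,
    "L_mt": 0.0,
    "L_av": 0.0,
    "L_tc": 0.0,
    "L_pv": 0.0,
}

#: Initial estimates for the systemic submodel identification stage.
SYSTEMIC_INITIAL: dict[str, float] = {
    "P_pu": 5.0,
    "R_mt": 0.05,
    "E_es_lvf": 2.0,
    "R_av": 0.04,
    "E_ao": 2.5,
    "R_sys": 2.5,
    "P_vc": 5.0,
}

#: Initial estimates for the pulmonary submodel identification stage.
PULMONARY_INITIAL: dict[str, float] = {
    "P_vc": 5.0,
    "R_tc": 0.04,
    "E_es_rvf": 0.8,
    "R_pv": 0.03,
    "E_pa": 2.1,
    "R_pul": 0.4,
    "P_pu": 5.0,
}


@dataclass(frozen=True)
class VentricleParams:
    """Free-wall pressure-volume relationship of one ventricle.

    ESPVR: P_es = E_es * (V - V_d);  EDPVR: P_ed = P_0 * (exp(lam*(V - V_0)) - 1).
    """

    E_es: float
    V_d: float
    P_0: float
    lam: float
    V_0: float = 0.0

    def __post_init__(self) -> None:
        if self.E_es <= 0:
            raise ValueError("E_es must be > 0")
        if self.lam < 0 or self.P_0 < 0 or self.V_d < 0:
            raise ValueError("lambda, P_0 and V_d must be nonnegative")


@dataclass(frozen=True)
class SeptumPericardiumParams:
    """Septal free-wall relationship, pericardial EDPVR and thoracic pressure."""

    E_es_spt: float
    V_d_spt: float
    P_0_spt: float
    lambda_spt: float
    V_0_spt: float
    P_0_pcd: float
    V_0_pcd: float
    lambda_pcd: float
    P_th: float

    def __post_init__(self) -> None:
        for name in ("E_es_spt", "P_0_spt", "lambda_spt", "P_0_pcd", "lambda_pcd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


# Order of the packed parameter vector consumed by the numerical kernels.
PARAM_FIELDS: tuple[str, ...] = (
    "E_es_lvf", "V_d_lvf", "P_0_lvf", "lambda_lvf", "V_0_lvf",
    "E_es_rvf", "V_d_rvf", "P_0_rvf", "lambda_rvf", "V_0_rvf",
    "E_es_spt", "V_d_spt", "P_0_spt", "lambda_spt", "V_0_spt",
    "P_0_pcd", "V_0_pcd", "lambda_pcd", "P_th",
    "E_ao", "V_d_ao", "E_vc", "V_d_vc", "E_pa", "V_d_pa", "E_pu", "V_d_pu",
    "R_mt", "R_av", "R_sys", "R_tc", "R_pv", "R_pul",
    "P_pu", "P_vc", "T",
)


@dataclass
class CirculationParams:
    """Full parameter set of the closed-loop model.

    ``P_pu``/``P_vc`` are the constant source pressures used when a
    circulation half is simulated as a stand-alone submodel; in closed-loop
    mode the venous pressures follow from ``E_pu``/``E_vc`` and the chamber
    volumes instead. ``T`` is the heart period and ``V_total`` the total
    stressed volume of the closed loop.
    """

    # left/right ventricle free walls
    E_es_lvf: float = 2.0
    V_d_lvf: float = 23.0
    P_0_lvf: float = 0.0
    lambda_lvf: float = 0.033
    V_0_lvf: float = 0.0
    E_es_rvf: float = 0.8
    V_d_rvf: float = 23.0
    P_0_rvf: float = 0.0
    lambda_rvf: float = 0.023
    V_0_rvf: float = 0.0
    # septum and pericardium
    E_es_spt: float = 48.754
    V_d_spt: float = 2.0
    P_0_spt: float = 1.1101
    lambda_spt: float = 0.435
    V_0_spt: float = 2.0
    P_0_pcd: float = 0.5003
    V_0_pcd: float = 200.0
    lambda_pcd: float = 0.03
    P_th: float = 0.0
    # passive chambers
    E_ao: float = 2.5
    V_d_ao: float = 0.0
    E_vc: float = 0.005
    V_d_vc: float = 0.0
    E_pa: float = 2.1
    V_d_pa: float = 0.0
    E_pu: float = 0.016
    V_d_pu: float = 0.0
    # resistances
    R_mt: float = 0.05
    R_av: float = 0.04
    R_sys: float = 2.5
    R_tc: float = 0.04
    R_pv: float = 0.03
    R_pul: float = 0.4
    # valve inertances (fixed at zero in this implementation)
    L_mt: float = 0.0
    L_av: float = 0.0
    L_tc: float = 0.0
    L_pv: float = 0.0
    # submodel source pressures
    P_pu: float = 5.0
    P_vc: float = 5.0
    # timing and volume
    T: float = 0.5
    V_total: float = 1500.0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name in ("R_mt", "R_av", "R_sys", "R_tc", "R_pv", "R_pul"):
            if getattr(self, name) <= 0:
                raise ValueError(f"resistance {name} must be > 0")
        for name in ("E_es_lvf", "E_es_rvf", "E_ao", "E_vc", "E_pa", "E_pu"):
            if getattr(self, name) <= 0:
                raise ValueError(f"elastance {name} must be > 0")
        for name in ("L_mt", "L_av", "L_tc", "L_pv"):
            if getattr(self, name) != 0.0:
                raise ValueError("valve inertances are fixed at zero")
        if self.T <= 0:
            raise ValueError("heart period T must be > 0")
        if self.V_total <= 0:
            raise ValueError("V_total must be > 0")

    # -- structured views -------------------------------------------------
    @property
    def left(self) -> VentricleParams:
        return VentricleParams(self.E_es_lvf, self.V_d_lvf, self.P_0_lvf,
                               self.lambda_lvf, self.V_0_lvf)

    @property
    def right(self) -> VentricleParams:
        return VentricleParams(self.E_es_rvf, self.V_d_rvf, self.P_0_rvf,
                               self.lambda_rvf, self.V_0_rvf)

    @property
    def septum_pericardium(self) -> SeptumPericardiumParams:
        return SeptumPericardiumParams(
            self.E_es_spt, self.V_d_spt, self.P_0_spt, self.lambda_spt,
            self.V_0_spt, self.P_0_pcd, self.V_0_pcd, self.lambda_pcd, self.P_th)

    @property
    def heart_rate(self) -> float:
        """Heart rate in beats per minute."""
        return 60.0 / self.T

    # -- serialisation ----------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        return {f.name: float(getattr(self, f.name)) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "CirculationParams":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**{k: float(v) for k, v in d.items()})

    def replace(self, **kwargs: float) -> "CirculationParams":
        return dataclasses.replace(self, **kwargs)

    def to_file(self, path: str | Path) -> None:
        path = Path(path)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=1, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "CirculationParams":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)

    @classmethod
    def defaults(cls, T: float = 0.5) -> "CirculationParams":
        """Table of model constants plus the submodel initial estimates."""
        return cls(T=T)

    def to_array(self) -> np.ndarray:
        """Pack into the flat vector layout used by the numerical kernels."""
        return np.array([getattr(self, name) for name in PARAM_FIELDS], dtype=np.float64)
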