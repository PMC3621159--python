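"""Cardiac driver functions (normalised time-varying elastance).

A driver maps time to an activation level in [0, 1] with period ``T`` equal
to one heartbeat. Activation 1 corresponds to end systole (the ESPVR),
activation 0 to full relaxation (the EDPVR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DriverFunction", "GaussianDriver", "SampledDriver", "driver_value"]

#: Default Gaussian width at the reference period (s^-2 at T = 0.75 s).
DEFAULT_W = 80.0
#: Reference period the default width is quoted at.
REFERENCE_PERIOD = 0.75
#: Peak activation time as a fraction of the period.
PEAK_FRACTION = 0.3


class DriverFunction:
    """Base class; subclasses implement ``_raw(tau)`` on one period."""

    T: float

    def __call__(self, t):
        if self.T <= 0 or not np.isfinite(self.T):
            raise ValueError("driver period must be positive and finite")
        tau = np.mod(t, self.T)
        out = self._raw(tau) / self._max
        if np.ndim(t) == 0:
            return float(out[0])
        return out

    def sample(self, n: int = 1024) -> np.ndarray:
        """Activation values on a uniform grid over [0, T)."""
        return np.asarray(self(np.arange(n) * (self.T / n)), dtype=np.float64)

    @property
    def peak_time(self) -> float:
        grid = np.linspace(0.0, self.T, 4096, endpoint=False)
        return float(grid[np.argmax(self(grid))])


@dataclass
class GaussianDriver(DriverFunction):
    """Periodised Gaussian activation pulse exp(-W*(t - t_peak)^2).

    The pulse is wrapped over neighbouring periods so the curve is periodic,
    and normalised so its maximum is exactly 1.
    """

    T: float
    t_peak: float | None = None
    W: float | None = None

    def __post_init__(self) -> None:
        if self.T <= 0 or not np.isfinite(self.T):
            raise ValueError("driver period must be positive and finite")
        if self.t_peak is None:
            self.t_peak = PEAK_FRACTION * self.T
        if self.W is None:
            # systolic width scales with the period
            self.W = DEFAULT_W * (REFERENCE_PERIOD / self.T) ** 2
        self._max = float(self._raw(np.array([self.t_peak]))[0])

    @classmethod
    def for_period(cls, T: float) -> "GaussianDriver":
        return cls(T=T)

    def _raw(self, tau):
        tau = np.atleast_1d(np.asarray(tau, dtype=np.float64))
        val = np.zeros_like(tau)
        for k in (-1, 0, 1):
            val += np.exp(-self.W * (tau - self.t_peak - k * self.T) ** 2)
        return val

    def threshold_time(self, delta: float = 0.05) -> float:
        """First time the activation exceeds ``delta`` (closed form).

        For the Gaussian pulse this is t_peak - sqrt(ln(1/delta)/W).
        """
        if not (0 < delta < 1):
            raise ValueError("delta must lie in (0, 1)")
        return self.t_peak - np.sqrt(np.log(1.0 / delta) / self.W)


@dataclass
class SampledDriver(DriverFunction):
    """Activation given by samples on a uniform grid over [0, T).

    Used for drivers estimated from arterial pressure waveforms.
    """

    T: float
    values: np.ndarray = field(default_factory=lambda: np.array([]))
    estimated: bool = False
    fallback: bool = False

    def __post_init__(self) -> None:
        if self.T <= 0 or not np.isfinite(self.T):
            raise ValueError("driver period must be positive and finite")
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size < 4:
            raise ValueError("sampled driver needs at least 4 samples")
        if np.any(self.values < 0):
            raise ValueError("sampled driver values must be nonnegative")
        self._max = float(self.values.max())
        if self._max <= 0:
            raise ValueError("sampled driver must attain a positive maximum")

    def _raw(self, tau):
        tau = np.atleast_1d(np.asarray(tau, dtype=np.float64))
        n = self.values.size
        pos = tau / self.T * n
        i0 = np.floor(pos).astype(np.int64) % n
        frac = pos - np.floor(pos)
        i1 = (i0 + 1) % n
        return self.values[i0] * (1 - frac) + self.values[i1] * frac


def driver_value(t, d: DriverFunction):
    """Evaluate a driver at time(s) ``t`` (periodic, normalised to max 1)."""
    if not np.all(np.isfinite(t)):
        raise ValueError("time must be finite")
    return d(t)
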