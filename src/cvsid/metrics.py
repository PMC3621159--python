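"""Agreement statistics for validating identified models.

Bland-Altman bias/precision, squared Pearson correlation and absolute
percentage-error percentiles, plus the right-ventricular-arterial coupling
ratio used as a derived hemodynamic index.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AgreementReport",
    "bland_altman",
    "r_squared",
    "percentage_error_stats",
    "rvac",
    "agreement_report",
]


@dataclass(frozen=True)
class AgreementReport:
    """Bias/precision, correlation and error-percentile summary."""

    bias: float
    precision: float       # 2 * SD of the differences
    r_squared: float
    error_median: float    # absolute percentage errors
    error_p5: float
    error_p95: float
    n: int

    def __post_init__(self) -> None:
        if self.precision < 0:
            raise ValueError("precision must be nonnegative")
        if not (np.isnan(self.r_squared)
                or 0 <= self.r_squared <= 1 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if not self.error_p5 <= self.error_median <= self.error_p95:
            raise ValueError("error percentiles out of order")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in
                ("bias", "precision", "r_squared", "error_median",
                 "error_p5", "error_p95", "n")}


def _paired(measured, modelled) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(measured, dtype=float)
    y = np.asarray(modelled, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("need two equal-length 1-d series")
    return x, y


def bland_altman(measured, modelled) -> tuple[float, float]:
    """Bias (mean of modelled - measured) and precision (2 * sample SD)."""
    x, y = _paired(measured, modelled)
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = y - x
    return float(d.mean()), float(2.0 * d.std(ddof=1))


def r_squared(x, y) -> float:
    """Squared Pearson correlation coefficient."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("need at least three pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate variance")
    r, _ = stats.pearsonr(x, y)
    return float(r * r)


def percentage_error_stats(measured, modelled) -> tuple[float, float, float]:
    """Median and 5th/95th percentiles of absolute percentage errors.

    Percentiles use linear interpolation between order statistics.
    """
    x, y = _paired(measured, modelled)
    if np.any(x == 0):
        raise ValueError("measured values must be nonzero")
    e = 100.0 * np.abs(y - x) / np.abs(x)
    p5, med, p95 = np.percentile(e, [5, 50, 95])
    return float(med), float(p5), float(p95)


def rvac(E_es_rvf: float, E_a: float) -> float:
    """Right ventricular-arterial coupling ratio E_es,rvf / E_a."""
    if E_a <= 0:
        raise ValueError("arterial elastance must be positive")
    return E_es_rvf / E_a


def agreement_report(measured, modelled) -> AgreementReport:
    """Full agreement summary for one validated quantity."""
    x, y = _paired(measured, modelled)
    bias, precision = bland_altman(x, y)
    med, p5, p95 = percentage_error_stats(x, y)
    r2 = r_squared(x, y) if len(x) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0 \
        else float("nan")
    return AgreementReport(bias=bias, precision=precision, r_squared=r2,
                           error_median=med, error_p5=p5, error_p95=p95,
                           n=len(x))
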