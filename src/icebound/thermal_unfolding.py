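"""CD thermal-denaturation curves: fraction unfolded and melting midpoint.

A melting trace is the ellipticity theta(T) at a fixed wavelength
(typically 220 nm) recorded while heating.  Assuming two-state behaviour,
the fraction of unfolded protein is

    f(T) = (theta_T - theta_low) / (theta_high - theta_low)

with theta_low / theta_high the ellipticities at the folded and unfolded
reference temperatures (20 and 60 deg C by default; thermostable variants
use a 70 deg C unfolded reference).  The trace is smoothed by an unweighted
mean over a symmetric +-0.4 deg C window, resampled to a 1.0 deg C grid,
and the denaturation midpoint Tm is read off as the temperature of the
first upward crossing of f = 0.5 (linear interpolation between grid
points).  No thermodynamic (van't Hoff) fit is attempted: the proteins
this targets denature irreversibly, so only the midpoint is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["MeltTrace", "UnfoldingCurve", "fraction_unfolded", "estimate_tm", "read_melt_trace"]

DEFAULT_T_LOW = 20.0  # deg C, folded baseline reference
DEFAULT_T_HIGH = 60.0  # deg C, unfolded reference (70.0 for thermostable variants)
SMOOTH_HALF_WIDTH = 0.4  # deg C, symmetric averaging window
RESAMPLE_STEP = 1.0  # deg C


@dataclass
class MeltTrace:
    """A temperature / ellipticity trace with baseline references."""

    temperature: np.ndarray  # deg C, strictly increasing
    ellipticity: np.ndarray  # CD units, signed
    t_low: float = DEFAULT_T_LOW
    t_high: float = DEFAULT_T_HIGH

    def __post_init__(self) -> None:
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.temperature.ndim != 1 or self.temperature.shape != self.ellipticity.shape:
            raise ValueError("temperature and ellipticity must be equal-length 1-D arrays")
        if np.any(np.diff(self.temperature) <= 0):
            raise ValueError("temperature grid must be strictly increasing")
        lo, hi = self.temperature[0], self.temperature[-1]
        eps = 1e-6 * max(1.0, hi - lo)  # tolerate float-accumulated grid ends
        if not (lo - eps <= self.t_low <= hi + eps and lo - eps <= self.t_high <= hi + eps):
            raise ValueError("reference temperatures must lie within the measured span")


@dataclass
class UnfoldingCurve:
    """Fraction-unfolded curve on a uniform 1.0 deg C grid."""

    temperature: np.ndarray
    fraction: np.ndarray
    t_low: float
    t_high: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"temperature_C": self.temperature, "fraction_unfolded": self.fraction}
        )


def read_melt_trace(
    path: str | Path,
    t_low: float = DEFAULT_T_LOW,
    t_high: float = DEFAULT_T_HIGH,
) -> MeltTrace:
    """Read a two-column (temperature, ellipticity) CSV/TSV trace."""
    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (temperature, ellipticity)")
    return MeltTrace(
        df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float), t_low, t_high
    )


def _smooth(temp: np.ndarray, y: np.ndarray, half_width: float) -> np.ndarray:
    """Unweighted mean over a symmetric window, truncated symmetrically at
    the trace ends so endpoint values stay unbiased."""
    out = np.empty_like(y)
    for i, t in enumerate(temp):
        hw = min(half_width, t - temp[0], temp[-1] - t)
        m = np.abs(temp - t) <= hw + 1e-12
        out[i] = y[m].mean()
    return out


def fraction_unfolded(
    trace: MeltTrace, smooth_half_width: float = SMOOTH_HALF_WIDTH
) -> UnfoldingCurve:
    """Normalize, smooth and resample a melting trace.

    The ellipticity is smoothed by an unweighted mean over all samples
    within ``+-smooth_half_width`` of each point, normalized by the
    (smoothed) baseline values at ``t_low`` / ``t_high``, and linearly
    resampled to a 1.0 deg C grid.  By construction f(t_low) = 0 and
    f(t_high) = 1.  The result is invariant to affine rescaling of the
    ellipticity units.
    """
    theta = _smooth(trace.temperature, trace.ellipticity, smooth_half_width)
    th_low = float(np.interp(trace.t_low, trace.temperature, theta))
    th_high = float(np.interp(trace.t_high, trace.temperature, theta))
    if abs(th_high - th_low) < 1e-12 * max(1.0, abs(th_low)):
        raise ValueError(
            "degenerate baselines: ellipticity at the folded and unfolded "
            "references is identical"
        )
    frac = (theta - th_low) / (th_high - th_low)
    t0 = np.ceil(trace.temperature[0] / RESAMPLE_STEP) * RESAMPLE_STEP
    t1 = np.floor(trace.temperature[-1] / RESAMPLE_STEP) * RESAMPLE_STEP
    grid = np.arange(t0, t1 + RESAMPLE_STEP / 2, RESAMPLE_STEP)
    f = np.interp(grid, trace.temperature, frac)
    return UnfoldingCurve(grid, f, trace.t_low, trace.t_high)


def estimate_tm(curve: UnfoldingCurve) -> float:
    """Midpoint temperature: first upward crossing of f = 0.5.

    Linear interpolation between the bracketing grid points.  Raises when
    the curve never crosses 0.5 from below within the grid.
    """
    f = curve.fraction
    t = curve.temperature
    for i in range(len(f) - 1):
        if f[i] < 0.5 <= f[i + 1]:
            w = (0.5 - f[i]) / (f[i + 1] - f[i])
            return float(t[i] + w * (t[i + 1] - t[i]))
    raise ValueError("no midpoint in range: curve never crosses 0.5 upward")
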