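"""Mass-photometry calibration and mass-distribution analysis.

Mass photometry measures the interferometric scattering contrast of
single particles landing on a coverslip; contrast is linear in
molecular mass.  The analysis has two steps:

1. contrast-to-mass (C2M) calibration against protein standards
   (NativeMark: 66, 146, 480 and 1048 kDa) by least squares, with a
   free intercept by default (switchable to through-origin);
2. a Gaussian kernel density estimate of the event-mass distribution
   with a *fixed* bandwidth (default 25 kDa) — no rule-of-thumb
   bandwidth selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal, stats

#: NativeMark protein-standard masses (kDa) used for C2M calibration.
NATIVEMARK_STANDARDS_KDA = (66.0, 146.0, 480.0, 1048.0)

DEFAULT_BANDWIDTH_KDA = 25.0


@dataclass(frozen=True)
class C2MCalibration:
    """Linear contrast-to-mass calibration: mass = slope·contrast + intercept."""

    contrasts: np.ndarray
    masses: np.ndarray          # kDa
    slope: float                # kDa per contrast unit
    intercept: float            # kDa
    residuals: np.ndarray       # kDa, mass - predicted

    def contrast_to_mass(self, contrast):
        return self.slope * np.asarray(contrast, dtype=float) + self.intercept

    def mass_to_contrast(self, mass_kda):
        return (np.asarray(mass_kda, dtype=float) - self.intercept) / self.slope


def fit_c2m(contrasts, masses, *, through_origin: bool = False) -> C2MCalibration:
    """Least-squares line mapping contrast to mass (kDa)."""
    contrasts = np.asarray(contrasts, dtype=float)
    masses = np.asarray(masses, dtype=float)
    if contrasts.size < 2:
        raise ValueError("need at least 2 calibration standards")
    if np.ptp(contrasts) == 0:
        raise ValueError("degenerate calibration: all contrasts equal")
    if through_origin:
        slope = float(np.sum(contrasts * masses) / np.sum(contrasts**2))
        intercept = 0.0
    else:
        res = stats.linregress(contrasts, masses)
        slope, intercept = float(res.slope), float(res.intercept)
    if slope == 0:
        raise ValueError("calibration slope is zero")
    residuals = masses - (slope * contrasts + intercept)
    return C2MCalibration(contrasts, masses, slope, intercept, residuals)


@dataclass
class MassDistribution:
    """Fixed-bandwidth Gaussian KDE of single-particle masses."""

    masses: np.ndarray      # kDa, one per landing event
    grid: np.ndarray        # kDa
    density: np.ndarray     # 1/kDa
    bandwidth: float        # kDa

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))

    def modes(self, min_prominence_frac: float = 0.05) -> np.ndarray:
        """Grid positions of local density maxima.

        Peaks with prominence below ``min_prominence_frac`` of the
        global maximum are ignored.
        """
        prominence = min_prominence_frac * float(np.max(self.density))
        peaks, _ = signal.find_peaks(self.density, prominence=prominence)
        return self.grid[peaks]

    def plot(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.density)
        ax.set_xlabel("mass (kDa)")
        ax.set_ylabel("density (1/kDa)")
        return ax

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mass_kDa": self.grid, "density": self.density})


def mass_kde(masses, bandwidth: float = DEFAULT_BANDWIDTH_KDA,
             grid: np.ndarray | None = None) -> MassDistribution:
    """Gaussian KDE with a fixed kernel SD in kDa.

    The kernel width is an absolute bandwidth, not the sample-SD-relative
    factor scipy's ``gaussian_kde`` uses, so the sum of kernels is formed
    directly.  The default grid spans [0, max mass + 4 bandwidths] at
    1 kDa resolution.
    """
    masses = np.asarray(masses, dtype=float)
    if masses.size == 0:
        raise ValueError("empty event list")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    if grid is None:
        grid = np.arange(0.0, float(np.max(masses)) + 4.0 * bandwidth + 1.0, 1.0)
    grid = np.asarray(grid, dtype=float)
    # (n_grid, n_events) kernel matrix; fine for typical event counts
    z = (grid[:, None] - masses[None, :]) / bandwidth
    density = np.exp(-0.5 * z**2).sum(axis=1) / (
        masses.size * bandwidth * math.sqrt(2.0 * math.pi)
    )
    return MassDistribution(masses, grid, density, float(bandwidth))


def read_events(path) -> np.ndarray:
    """Event contrasts from a CSV with a ``contrast`` column."""
    df = pd.read_csv(path)
    if "contrast" not in df.columns:
        raise ValueError(f"event table {path} needs a 'contrast' column")
    return df["contrast"].to_numpy(dtype=float)


def read_standards(path) -> tuple[np.ndarray, np.ndarray]:
    """(contrasts, masses_kDa) from a calibration-standard CSV."""
    df = pd.read_csv(path)
    missing = {"contrast", "mass_kDa"} - set(df.columns)
    if missing:
        raise ValueError(f"standards table {path} missing columns {sorted(missing)}")
    return df["contrast"].to_numpy(dtype=float), df["mass_kDa"].to_numpy(dtype=float)
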