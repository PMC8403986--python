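"""Radiometric kinase-assay analysis.

Workflow, mirroring how ³²P kinase time courses are quantified:

1. :func:`fit_standard_curve` converts background-corrected spot
   intensities of known ATP amounts into a signal-per-pmol slope
   (through the origin by default: zero radiolabel gives zero signal
   after background correction; switchable).
2. :func:`initial_rate` fits an ordinary least-squares line (free
   intercept) to product (pmol) versus time (min) and returns its slope.
3. :class:`MichaelisMenten` fits v0 = kcat·[E_T]·[S] / (K_M + [S]) to
   initial rates over a substrate titration by nonlinear least squares.
   By the paper-field convention [E_T] is an *amount* (pmol), so Vmax is
   in pmol/min and kcat = Vmax/[E_T] in min⁻¹.  If the titration never
   approaches saturation — the top of the curve is still essentially
   linear — the fit degrades gracefully to a linear-efficiency-only
   result ("n.d." for Vmax/KM/kcat), with kcat/K_M taken from the slope
   of the straight-line fit.
4. :func:`propagate_ratio_error` propagates standard errors into
   kcat/K_M via relative errors in quadrature:
   δz/z = sqrt((δx/x)² + (δy/y)²).

:func:`polyubiquitylated_fraction` is the lane-signal ratio used to
quantify poly-ubiquitylated β-catenin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: Spot amounts (pmol) of the two-fold ATP dilution series used for the
#: radiometric standard curve.
STANDARD_AMOUNTS_PMOL = (12.5, 6.25, 3.125, 1.563, 0.781, 0.390, 0.195)

#: Ratio v(Smax)/v(Smax/2) at or above which the titration is treated as
#: non-saturating (2.0 is exactly linear; 1.8 corresponds to Smax ≈ KM/4).
SATURATION_RATIO = 1.8


def enzyme_amount_pmol(volume_uL: float, concentration_nM: float) -> float:
    """Enzyme amount (pmol) from a reaction volume and molar concentration.

    E.g. 6 μL of a 150 nM kinase complex is 0.9 pmol.
    """
    return volume_uL * concentration_nM * 1e-3


@dataclass(frozen=True)
class StandardCurve:
    """Signal-vs-amount calibration line for radiometric spots."""

    amounts: np.ndarray      # pmol
    signals: np.ndarray      # linear-scale a.u.
    slope: float             # a.u. per pmol
    slope_se: float
    residual_rms: float
    through_origin: bool

    def to_pmol(self, signal):
        """Convert background-corrected signals (a.u.) to pmol."""
        return np.asarray(signal, dtype=float) / self.slope


def fit_standard_curve(amounts, signals, *, through_origin: bool = True) -> StandardCurve:
    """Least-squares calibration line; through the origin by default."""
    amounts = np.asarray(amounts, dtype=float)
    signals = np.asarray(signals, dtype=float)
    if amounts.size < 3:
        raise ValueError("need at least 3 standard spots")
    if np.any(amounts <= 0):
        raise ValueError("standard amounts must be > 0")
    if through_origin:
        sxx = float(np.sum(amounts**2))
        slope = float(np.sum(amounts * signals)) / sxx
        resid = signals - slope * amounts
        dof = max(amounts.size - 1, 1)
        slope_se = math.sqrt(float(np.sum(resid**2)) / dof / sxx)
    else:
        res = stats.linregress(amounts, signals)
        slope, slope_se = float(res.slope), float(res.stderr)
        resid = signals - (res.slope * amounts + res.intercept)
    if slope <= 0:
        raise ValueError("standard-curve slope is non-positive; signals inconsistent")
    rms = math.sqrt(float(np.mean(resid**2)))
    return StandardCurve(amounts, signals, slope, slope_se, rms, through_origin)


def initial_rate(timepoints, product) -> float:
    """Initial rate (pmol/min): OLS slope of product vs time, free intercept."""
    t = np.asarray(timepoints, dtype=float)
    p = np.asarray(product, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 timepoints")
    if np.ptp(t) == 0:
        raise ValueError("degenerate time axis (all timepoints equal)")
    return float(stats.linregress(t, p).slope)


@dataclass
class KineticsDataset:
    """One substrate titration: timepoints × substrate concentrations.

    ``signals[i, j]`` is the product signal (a.u., linear scale) for
    concentration ``concentrations[i]`` at time ``timepoints[j]``.
    """

    concentrations: np.ndarray   # μM, distinct and positive
    timepoints: np.ndarray       # min
    signals: np.ndarray          # (n_conc, n_time) a.u.
    et_pmol: float

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.timepoints = np.asarray(self.timepoints, dtype=float)
        self.signals = np.asarray(self.signals, dtype=float)
        if self.timepoints.size < 2:
            raise ValueError("need at least 2 timepoints per series")
        if np.any(self.concentrations <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if len(set(self.concentrations.tolist())) != self.concentrations.size:
            raise ValueError("substrate concentrations must be distinct")
        if self.signals.shape != (self.concentrations.size, self.timepoints.size):
            raise ValueError("signals must be (n_conc, n_time)")
        if self.et_pmol <= 0:
            raise ValueError("et_pmol must be > 0")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, c in enumerate(self.concentrations):
            for j, t in enumerate(self.timepoints):
                rows.append({"conc_uM": c, "time_min": t, "signal": self.signals[i, j]})
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, et_pmol: float) -> "KineticsDataset":
        concs = np.array(sorted(df["conc_uM"].unique()))
        times = np.array(sorted(df["time_min"].unique()))
        signals = np.empty((concs.size, times.size))
        for i, c in enumerate(concs):
            sub = df[df["conc_uM"] == c].set_index("time_min")["signal"]
            signals[i] = [sub.loc[t] for t in times]
        return cls(concs, times, signals, et_pmol)


def michaelis_menten_rate(S, vmax: float, km: float):
    """v0 = Vmax·[S]/(K_M + [S])."""
    S = np.asarray(S, dtype=float)
    return vmax * S / (km + S)


@dataclass(frozen=True)
class MichaelisMentenResults:
    """Fit results for one titration series.

    In ``linear-only`` mode (no saturation within the titration) Vmax,
    K_M and kcat are undetermined (None), matching the "n.d." convention;
    the catalytic efficiency comes from a straight-line fit instead.
    """

    mode: str                        # "saturating" | "linear-only"
    et_pmol: float
    efficiency: float                # kcat/KM, μM⁻¹ min⁻¹
    efficiency_se: float
    vmax: float | None = None        # pmol/min
    vmax_se: float | None = None
    km: float | None = None          # μM
    km_se: float | None = None
    kcat: float | None = None        # min⁻¹
    kcat_se: float | None = None
    n_points: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "mode": self.mode,
                    "Vmax_pmol_min": self.vmax,
                    "Vmax_se": self.vmax_se,
                    "KM_uM": self.km,
                    "KM_se": self.km_se,
                    "kcat_per_min": self.kcat,
                    "kcat_se": self.kcat_se,
                    "kcat_over_KM": self.efficiency,
                    "kcat_over_KM_se": self.efficiency_se,
                    "ET_pmol": self.et_pmol,
                    "n_points": self.n_points,
                }
            ]
        )

    def summary(self) -> str:
        def fmt(v, se):
            if v is None:
                return "n.d."
            return f"{v:.4g} ± {se:.2g}"

        lines = [
            "Michaelis-Menten fit" + (" (linear-only: no saturation)" if self.mode == "linear-only" else ""),
            "-" * 46,
            f"{'Vmax (pmol/min)':<24}{fmt(self.vmax, self.vmax_se)}",
            f"{'KM (uM)':<24}{fmt(self.km, self.km_se)}",
            f"{'kcat (1/min)':<24}{fmt(self.kcat, self.kcat_se)}",
            f"{'kcat/KM (1/uM/min)':<24}{fmt(self.efficiency, self.efficiency_se)}",
            f"{'[E_T] (pmol)':<24}{self.et_pmol:g}",
            f"{'n points':<24}{self.n_points}",
        ]
        return "\n".join(lines)

    def plot(self, concentrations=None, rates=None, ax=None):
        """Rate-vs-[S] plot with the fitted curve overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        if concentrations is not None and rates is not None:
            ax.plot(concentrations, rates, "o", label="initial rates")
            smax = float(np.max(concentrations))
        else:
            smax = (self.km or 1.0) * 10
        grid = np.linspace(0, smax, 200)
        if self.mode == "saturating":
            ax.plot(grid, michaelis_menten_rate(grid, self.vmax, self.km), "-", label="MM fit")
        else:
            ax.plot(grid, self.efficiency * self.et_pmol * grid, "-", label="linear fit")
        ax.set_xlabel("[S] (μM)")
        ax.set_ylabel("v₀ (pmol/min)")
        ax.legend()
        return ax


class MichaelisMenten:
    """Michaelis–Menten model for initial rates over a substrate titration.

    Parameters
    ----------
    rates : array
        Initial rates (pmol/min), one per substrate concentration.
    concentrations : array
        Substrate concentrations (μM).
    et_pmol : float
        Total enzyme amount [E_T] in pmol (amount, not concentration).
    saturation_ratio : float
        Linearity threshold on v(Smax)/v(Smax/2); at or above it the
        model falls back to linear-only mode.
    """

    def __init__(self, rates, concentrations, et_pmol: float,
                 saturation_ratio: float = SATURATION_RATIO):
        self.rates = np.asarray(rates, dtype=float)
        self.concentrations = np.asarray(concentrations, dtype=float)
        if self.rates.shape != self.concentrations.shape:
            raise ValueError("rates and concentrations must align")
        if self.concentrations.size < 4:
            raise ValueError("need at least 4 substrate concentrations")
        if np.any(self.concentrations <= 0):
            raise ValueError("substrate concentrations must be > 0")
        if et_pmol <= 0:
            raise ValueError("et_pmol must be > 0")
        self.et_pmol = float(et_pmol)
        self.saturation_ratio = float(saturation_ratio)

    def _is_saturating(self) -> bool:
        order = np.argsort(self.concentrations)
        s = self.concentrations[order]
        v = self.rates[order]
        smax = s[-1]
        v_top = float(v[-1])
        v_half = float(np.interp(smax / 2.0, s, v))
        if v_half <= 0:
            return True  # cannot judge linearity; attempt the full fit
        return v_top / v_half < self.saturation_ratio

    def fit(self) -> MichaelisMentenResults:
        s, v = self.concentrations, self.rates
        n = s.size
        if not self._is_saturating():
            res = stats.linregress(s, v)
            slope, slope_se = float(res.slope), float(res.stderr)
            return MichaelisMentenResults(
                mode="linear-only",
                et_pmol=self.et_pmol,
                efficiency=slope / self.et_pmol,
                efficiency_se=slope_se / self.et_pmol,
                n_points=n,
            )
        p0 = (float(np.max(v)) * 1.2, float(np.median(s)))
        try:
            popt, pcov = optimize.curve_fit(
                michaelis_menten_rate, s, v, p0=p0,
                bounds=([0.0, 0.0], [np.inf, np.inf]), maxfev=10000,
            )
        except RuntimeError as err:
            raise RuntimeError(f"Michaelis-Menten fit did not converge: {err}") from err
        vmax, km = (float(x) for x in popt)
        vmax_se, km_se = (float(x) for x in np.sqrt(np.diag(pcov)))
        kcat = vmax / self.et_pmol
        kcat_se = vmax_se / self.et_pmol
        eff, eff_se = propagate_ratio_error(kcat, kcat_se, km, km_se)
        return MichaelisMentenResults(
            mode="saturating",
            et_pmol=self.et_pmol,
            efficiency=eff,
            efficiency_se=eff_se,
            vmax=vmax,
            vmax_se=vmax_se,
            km=km,
            km_se=km_se,
            kcat=kcat,
            kcat_se=kcat_se,
            n_points=n,
        )


def fit_michaelis_menten(concentrations, rates, et_pmol: float, **kwargs) -> MichaelisMentenResults:
    """Functional wrapper around :class:`MichaelisMenten`."""
    return MichaelisMenten(rates, concentrations, et_pmol, **kwargs).fit()


def analyze_assay(dataset: KineticsDataset, standard_amounts, standard_signals,
                  **kwargs) -> MichaelisMentenResults:
    """Full pipeline: standard curve → pmol → initial rates → MM fit."""
    curve = fit_standard_curve(standard_amounts, standard_signals)
    rates = np.array(
        [initial_rate(dataset.timepoints, curve.to_pmol(row)) for row in dataset.signals]
    )
    return fit_michaelis_menten(dataset.concentrations, rates, dataset.et_pmol, **kwargs)


def propagate_ratio_error(x: float, dx: float, y: float, dy: float) -> tuple[float, float]:
    """Standard error of z = x/y from relative errors in quadrature.

    δz = z · sqrt((δx/x)² + (δy/y)²).
    """
    if x == 0 or y == 0:
        raise ValueError("x and y must be non-zero")
    if dx < 0 or dy < 0:
        raise ValueError("standard errors must be >= 0")
    z = x / y
    dz = abs(z) * math.sqrt((dx / x) ** 2 + (dy / y) ** 2)
    return z, dz


def polyubiquitylated_fraction(polyub_signal: float, total_signal: float) -> float:
    """Fraction of poly-ubiquitylated substrate in a lane: polyub / total."""
    if total_signal <= 0:
        raise ValueError("total_signal must be > 0")
    if polyub_signal < 0 or polyub_signal > total_signal:
        raise ValueError("polyub_signal must lie in [0, total_signal]")
    return polyub_signal / total_signal
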