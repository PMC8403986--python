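"""SEC-MALS slice analysis.

Size-exclusion chromatography with in-line multi-angle light scattering
(SEC-MALS) yields, per elution "slice", a differential refractive index
(dRI), an absorbance at 280 nm (A280) and a light-scattering signal.
This module converts those raw channels into per-slice mass
concentrations, absolute molar masses and molar extinction
coefficients, and summarizes an elution peak into the weight- and
number-average molar masses (Mw, Mn), the dispersity Đ = Mw/Mn, the
mean ± SD molar extinction coefficient and the peak molar
concentration — the measurement windows consumed by the stoichiometry
enumerator in :mod:`dcstoich.stoich`.

Physical relations
------------------
* concentration:      c = dRI / (dn/dc)                       [g/mL]
* molar mass:         M = LS / (K · c)                        [g/mol]
  (zero-angle, zero-virial light-scattering relation; the complex is
  treated as a point scatterer, so only the product K·c·M is observable
  and the instrument constant K must be shared between simulation and
  analysis)
* molar extinction:   ε = A280 / (l · c[g/L]) · M             [M^-1 cm^-1]
* averages over the peak window:
  Mw = Σ cᵢMᵢ / Σ cᵢ,   Mn = Σ cᵢ / Σ (cᵢ/Mᵢ),   Đ = Mw/Mn
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Refractive-index increment of protein solutions, mL/g.
DEFAULT_DN_DC = 0.185


@dataclass
class SliceSeries:
    """Per-slice SEC-MALS chromatogram record.

    Arrays must have equal length and strictly increasing volumes.
    ``true_c`` (g/mL) and ``true_M`` (g/mol) are optional ground-truth
    channels carried along by the synthetic-data generator.
    """

    volume: np.ndarray          # mL
    dRI: np.ndarray             # dimensionless
    A280: np.ndarray            # absorbance units
    scattering: np.ndarray | None = None   # detector units
    molar_mass: np.ndarray | None = None   # g/mol, if pre-computed
    peak_window: tuple[float, float] | None = None  # inclusive, mL
    true_c: np.ndarray | None = None
    true_M: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.volume = np.asarray(self.volume, dtype=float)
        n = self.volume.size
        if n == 0:
            raise ValueError("empty slice series")
        if np.any(np.diff(self.volume) <= 0):
            raise ValueError("volumes must be strictly increasing")
        for name in ("dRI", "A280", "scattering", "molar_mass", "true_c", "true_M"):
            arr = getattr(self, name)
            if arr is None:
                continue
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} has shape {arr.shape}, expected ({n},)")
            setattr(self, name, arr)
        if self.scattering is None and self.molar_mass is None:
            raise ValueError("need a scattering signal or pre-computed molar masses")
        if self.peak_window is None:
            self.peak_window = (float(self.volume[0]), float(self.volume[-1]))
        lo, hi = self.peak_window
        if lo > hi:
            raise ValueError("peak_window must be (low, high)")
        if lo < self.volume[0] or hi > self.volume[-1]:
            raise ValueError("peak_window outside recorded volume range")

    def window_mask(self) -> np.ndarray:
        lo, hi = self.peak_window
        return (self.volume >= lo) & (self.volume <= hi)

    def __len__(self) -> int:
        return self.volume.size


@dataclass(frozen=True)
class AnalysisConfig:
    """Instrument constants used to invert the raw channels."""

    dn_dc: float = DEFAULT_DN_DC        # mL/g
    optical_constant: float = 1e-5      # K; detector units per (g/mL · g/mol)
    path_length: float = 1.0            # cm
    c_floor: float = 1e-9               # g/mL; slices below are excluded

    def __post_init__(self) -> None:
        if self.dn_dc <= 0:
            raise ValueError("dn_dc must be > 0")
        if self.optical_constant <= 0:
            raise ValueError("optical_constant must be > 0")
        if self.path_length <= 0:
            raise ValueError("path_length must be > 0")
        if self.c_floor < 0:
            raise ValueError("c_floor must be >= 0")


@dataclass(frozen=True)
class MassSummary:
    """Peak-window summary of one SEC-MALS run."""

    mw: float               # g/mol
    mn: float               # g/mol
    dispersity: float       # Mw/Mn
    eps_mean: float         # M^-1 cm^-1
    eps_sd: float           # M^-1 cm^-1
    c_max_detector: float   # M (molar), maximum over slices
    n_slices: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "Mw_Da": self.mw,
                    "Mn_Da": self.mn,
                    "dispersity": self.dispersity,
                    "eps_mean": self.eps_mean,
                    "eps_sd": self.eps_sd,
                    "c_max_nM": self.c_max_detector * 1e9,
                    "n_slices": self.n_slices,
                }
            ]
        )


def slice_concentration(dRI, dn_dc: float = DEFAULT_DN_DC):
    """Mass concentration (g/mL) from the dRI channel: c = dRI / (dn/dc)."""
    if dn_dc <= 0:
        raise ValueError("dn_dc must be > 0")
    return np.asarray(dRI, dtype=float) / dn_dc


def slice_molar_mass(scattering, c_mass, optical_constant: float):
    """Molar mass (g/mol) per slice from the zero-angle relation LS = K·c·M.

    Slices with non-positive concentration cannot be inverted; they are
    returned as NaN (excluded) and logged.
    """
    if optical_constant <= 0:
        raise ValueError("optical_constant must be > 0")
    scattering = np.asarray(scattering, dtype=float)
    c_mass = np.asarray(c_mass, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        mass = scattering / (optical_constant * c_mass)
    bad = ~(c_mass > 0)
    if np.any(bad):
        logger.info("excluding %d slice(s) with non-positive concentration", int(np.sum(bad)))
        mass = np.where(bad, np.nan, mass)
    return mass


def average_molar_masses(c_mass, molar_mass) -> tuple[float, float, float]:
    """(Mw, Mn, Đ) over valid slices.

    Mw = Σ cᵢMᵢ / Σ cᵢ and Mn = Σ cᵢ / Σ (cᵢ/Mᵢ); both are invariant
    under uniform rescaling of the concentrations, and Mw >= Mn (hence
    Đ >= 1) by the Cauchy–Schwarz inequality.
    """
    c = np.asarray(c_mass, dtype=float)
    m = np.asarray(molar_mass, dtype=float)
    valid = (c > 0) & np.isfinite(m) & (m > 0)
    if not np.any(valid):
        raise ValueError("no valid slices in window")
    c, m = c[valid], m[valid]
    mw = float(np.sum(c * m) / np.sum(c))
    mn = float(np.sum(c) / np.sum(c / m))
    return mw, mn, mw / mn


def slice_molar_extinction(A280, c_mass_gL, molar_mass, path_length: float = 1.0):
    """Molar ε (M^-1 cm^-1) per slice via Beer–Lambert.

    ε(L g^-1 cm^-1) = A / (l · c) with c in g/L, converted to molar units
    by multiplying with the slice molar mass.
    """
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    A = np.asarray(A280, dtype=float)
    c = np.asarray(c_mass_gL, dtype=float)
    m = np.asarray(molar_mass, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = A / (path_length * c) * m
    return np.where(c > 0, eps, np.nan)


def analyze_slices(slices: SliceSeries, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Per-slice table over the peak window.

    Columns: ``volume_mL``, ``c_g_per_mL``, ``M_Da``, ``eps``,
    ``c_molar_M`` and ``valid`` (concentration above the floor and
    invertible).
    """
    mask = slices.window_mask()
    vol = slices.volume[mask]
    c = slice_concentration(slices.dRI[mask], config.dn_dc)
    if slices.molar_mass is not None:
        m = slices.molar_mass[mask]
    else:
        m = slice_molar_mass(slices.scattering[mask], c, config.optical_constant)
    valid = (c >= config.c_floor) & np.isfinite(m) & (m > 0)
    eps = slice_molar_extinction(slices.A280[mask], c * 1000.0, m, config.path_length)
    with np.errstate(divide="ignore", invalid="ignore"):
        c_molar = np.where(valid, c * 1000.0 / m, np.nan)
    return pd.DataFrame(
        {
            "volume_mL": vol,
            "c_g_per_mL": c,
            "M_Da": m,
            "eps": eps,
            "c_molar_M": c_molar,
            "valid": valid,
        }
    )


def summarize_run(slices: SliceSeries, config: AnalysisConfig = AnalysisConfig()) -> MassSummary:
    """Aggregate a run into a :class:`MassSummary` over its peak window.

    ε is reported as mean ± 1 SD across valid slices; confidence-interval
    multipliers (e.g. 1.96 for 95%) are applied downstream by the
    enumerator, not here.
    """
    table = analyze_slices(slices, config)
    ok = table[table["valid"]]
    if ok.empty:
        raise ValueError("no valid slices in peak window")
    mw, mn, disp = average_molar_masses(ok["c_g_per_mL"].to_numpy(), ok["M_Da"].to_numpy())
    eps = ok["eps"].to_numpy()
    return MassSummary(
        mw=mw,
        mn=mn,
        dispersity=disp,
        eps_mean=float(np.mean(eps)),
        eps_sd=float(np.std(eps)),  # population SD over slices
        c_max_detector=float(np.nanmax(ok["c_molar_M"].to_numpy())),
        n_slices=int(len(ok)),
    )


def estimate_input_concentration(A280_input: float, eps_mean: float, path_length: float = 1.0) -> float:
    """Molar concentration (M) of an input sample from its A280.

    c = A / (ε · l), using the peak-mean molar extinction coefficient.
    """
    if eps_mean <= 0:
        raise ValueError("eps_mean must be > 0")
    if path_length <= 0:
        raise ValueError("path_length must be > 0")
    return float(A280_input) / (eps_mean * path_length)


# ---------------------------------------------------------------------------
# I/O: CSV slice tables (columns volume_mL, dRI, A280, LS, optional truth)

def read_slice_table(path, peak_window: tuple[float, float] | None = None) -> SliceSeries:
    df = pd.read_csv(path)
    required = {"volume_mL", "dRI", "A280", "LS"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"slice table {path} missing columns {sorted(missing)}")
    return SliceSeries(
        volume=df["volume_mL"].to_numpy(),
        dRI=df["dRI"].to_numpy(),
        A280=df["A280"].to_numpy(),
        scattering=df["LS"].to_numpy(),
        peak_window=peak_window,
        true_c=df["true_c_g_per_mL"].to_numpy() if "true_c_g_per_mL" in df else None,
        true_M=df["true_M_Da"].to_numpy() if "true_M_Da" in df else None,
    )


def write_slice_table(slices: SliceSeries, path) -> None:
    data = {
        "volume_mL": slices.volume,
        "dRI": slices.dRI,
        "A280": slices.A280,
        "LS": slices.scattering,
    }
    if slices.true_c is not None:
        data["true_c_g_per_mL"] = slices.true_c
    if slices.true_M is not None:
        data["true_M_Da"] = slices.true_M
    pd.DataFrame(data).to_csv(path, index=False)
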