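"""Seeded synthetic-data generators with retained ground truth.

Emulates the statistical structure the analysis stages assume:

* SEC-MALS chromatograms: each species elutes as a Gaussian peak in
  volume; per slice, the detector channels are formed from the forward
  physical relations (dRI = c·dn/dc; A280 = Σ ε·c_molar·l;
  LS = K·Σ c·M) and perturbed by multiplicative Gaussian noise,
  independent per channel and slice (detector noise scales with signal).
* Mass photometry: event masses drawn from a categorical mixture plus
  Gaussian mass noise, converted to contrasts by inverting a known
  calibration line.
* Radiometric kinase assays: product(t) = v0·t in the initial-rate
  regime with v0 from the Michaelis–Menten equation, reported as spot
  signals through a known signal-per-pmol slope, together with the
  two-fold ATP-dilution standard-curve table.

Every generator takes a seed and is bit-reproducible; ground truth is
stored beside the observations so that downstream stages can be tested
for exact round-trip inversion at zero noise and for statistical
recovery under noise.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .components import ComponentSpec, Stoichiometry, validate_components
from .kinetics import STANDARD_AMOUNTS_PMOL, KineticsDataset, michaelis_menten_rate
from .secmals import DEFAULT_DN_DC, SliceSeries
from .stoich import complex_extinction, complex_mass


@dataclass(frozen=True)
class GeneratorConfig:
    """Instrument constants and noise level for the simulators."""

    dn_dc: float = DEFAULT_DN_DC     # mL/g
    optical_constant: float = 1e-5   # K: LS units per (g/mL · g/mol)
    path_length: float = 1.0         # cm
    noise_sd_rel: float = 0.02       # relative SD of multiplicative noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dn_dc <= 0 or self.optical_constant <= 0 or self.path_length <= 0:
            raise ValueError("dn_dc, optical_constant and path_length must be > 0")
        if self.noise_sd_rel < 0:
            raise ValueError("noise_sd_rel must be >= 0")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


@dataclass(frozen=True)
class SpeciesSpec:
    """One eluting species: a stoichiometry with a Gaussian elution profile."""

    stoichiometry: Stoichiometry
    peak_center: float        # mL
    peak_width: float         # mL, SD of the Gaussian profile
    total_mass_loaded: float  # g, integral of c over volume

    def __post_init__(self) -> None:
        if self.peak_width <= 0:
            raise ValueError("peak_width must be > 0")
        if self.total_mass_loaded < 0:
            raise ValueError("total_mass_loaded must be >= 0")


def _gaussian_profile(grid: np.ndarray, center: float, width: float) -> np.ndarray:
    return np.exp(-0.5 * ((grid - center) / width) ** 2) / (width * np.sqrt(2 * np.pi))


def simulate_chromatogram(
    species: Sequence[SpeciesSpec],
    grid,
    components: Sequence[ComponentSpec],
    config: GeneratorConfig = GeneratorConfig(),
    peak_window: tuple[float, float] | None = None,
) -> SliceSeries:
    """Synthetic SEC-MALS slice series with ground-truth c and M channels.

    Per slice i: c_i = Σ_s Gaussian contribution of species s (g/mL);
    dRI_i = c_i·dn/dc; A280_i = Σ_s ε_s·(c_{s,i}·1000/M_s)·l;
    LS_i = K·Σ_s c_{s,i}·M_s.  The true weight-average molar mass per
    slice is stored in ``true_M`` (NaN where c is zero).
    """
    if not species:
        raise ValueError("need at least one species")
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 2 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be 1-D and strictly increasing")
    comps = validate_components(components)

    c_total = np.zeros_like(grid)
    a280 = np.zeros_like(grid)
    ls = np.zeros_like(grid)
    cm_sum = np.zeros_like(grid)  # Σ c_s · M_s, for the true mass channel
    for sp in species:
        mass = complex_mass(sp.stoichiometry, comps)
        eps = complex_extinction(sp.stoichiometry, comps)
        c_s = sp.total_mass_loaded * _gaussian_profile(grid, sp.peak_center, sp.peak_width)
        c_total += c_s
        a280 += eps * (c_s * 1000.0 / mass) * config.path_length
        ls += config.optical_constant * c_s * mass
        cm_sum += c_s * mass

    with np.errstate(divide="ignore", invalid="ignore"):
        true_m = np.where(c_total > 0, cm_sum / c_total, np.nan)

    rng = np.random.default_rng(config.seed)
    sd = config.noise_sd_rel
    dri = config.dn_dc * c_total
    if sd > 0:
        dri = dri * (1.0 + sd * rng.standard_normal(grid.size))
        a280 = a280 * (1.0 + sd * rng.standard_normal(grid.size))
        ls = ls * (1.0 + sd * rng.standard_normal(grid.size))

    return SliceSeries(
        volume=grid,
        dRI=dri,
        A280=a280,
        scattering=ls,
        peak_window=peak_window,
        true_c=c_total,
        true_M=true_m,
    )


def simulate_mp_events(
    masses: Sequence[tuple[float, float]],
    n_events: int,
    noise_sd: float,
    calibration: tuple[float, float],
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic mass-photometry events.

    Parameters
    ----------
    masses : sequence of (mass_kDa, weight_fraction)
        Categorical species mixture; fractions must sum to 1.
    n_events : int
        Number of landing events.
    noise_sd : float
        Gaussian mass noise SD in kDa.
    calibration : (slope, intercept)
        The contrast-to-mass line mass = slope·contrast + intercept;
        events are emitted as contrasts by inverting it.
    seed : int

    Returns
    -------
    (contrasts, true_masses_kDa)
    """
    if n_events <= 0:
        raise ValueError("n_events must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    vals = np.array([m for m, _ in masses], dtype=float)
    weights = np.array([w for _, w in masses], dtype=float)
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError(f"weight fractions must sum to 1, got {weights.sum()}")
    slope, intercept = calibration
    if slope == 0:
        raise ValueError("calibration slope must be non-zero")
    rng = np.random.default_rng(seed)
    true = rng.choice(vals, size=n_events, p=weights)
    observed = true + noise_sd * rng.standard_normal(n_events) if noise_sd > 0 else true.copy()
    contrasts = (observed - intercept) / slope
    return contrasts, true


@dataclass
class SyntheticKinaseAssay:
    """A simulated titration plus its standard curve and ground truth."""

    dataset: KineticsDataset
    standard_amounts: np.ndarray   # pmol
    standard_signals: np.ndarray   # a.u.
    truth: dict


def simulate_kinase_assay(
    kcat: float,
    km: float,
    et_pmol: float,
    substrate_grid,
    timepoints=(0.5, 1.0, 2.0, 5.0),
    noise_sd_rel: float = 0.02,
    seed: int = 0,
    signal_per_pmol: float = 1000.0,
) -> SyntheticKinaseAssay:
    """Synthetic radiometric kinase titration.

    Product at time t is v0·t with v0 = kcat·[E_T]·[S]/(K_M+[S])
    (initial-rate regime; kcat in min⁻¹, K_M and [S] in μM, [E_T] in
    pmol, so v0 is in pmol/min).  Product amounts are reported as spot
    signals via ``signal_per_pmol`` with multiplicative Gaussian noise;
    a standard-curve spot table over the two-fold ATP dilution series
    (12.5 … 0.195 pmol) is emitted alongside with the same noise level.
    """
    if min(kcat, km, et_pmol) <= 0:
        raise ValueError("kcat, km and et_pmol must be > 0")
    if noise_sd_rel < 0:
        raise ValueError("noise_sd_rel must be >= 0")
    if signal_per_pmol <= 0:
        raise ValueError("signal_per_pmol must be > 0")
    s = np.asarray(substrate_grid, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if np.any(s <= 0):
        raise ValueError("substrate concentrations must be > 0")

    vmax = kcat * et_pmol
    v0 = michaelis_menten_rate(s, vmax, km)            # pmol/min per series
    product = v0[:, None] * t[None, :]                 # pmol
    signals = product * signal_per_pmol

    rng = np.random.default_rng(seed)
    if noise_sd_rel > 0:
        signals = signals * (1.0 + noise_sd_rel * rng.standard_normal(signals.shape))

    amounts = np.array(STANDARD_AMOUNTS_PMOL)
    sc_signals = amounts * signal_per_pmol
    if noise_sd_rel > 0:
        sc_signals = sc_signals * (1.0 + noise_sd_rel * rng.standard_normal(amounts.shape))

    dataset = KineticsDataset(s, t, signals, et_pmol)
    truth = {
        "kcat": kcat,
        "km": km,
        "et_pmol": et_pmol,
        "vmax": vmax,
        "v0": v0,
        "signal_per_pmol": signal_per_pmol,
    }
    return SyntheticKinaseAssay(dataset, amounts, sc_signals, truth)


# ---------------------------------------------------------------------------
# CSV writers (mirrored by readers in the consuming modules)

def write_events(contrasts: np.ndarray, path, true_masses: np.ndarray | None = None) -> None:
    data = {"contrast": contrasts}
    if true_masses is not None:
        data["true_mass_kDa"] = true_masses
    pd.DataFrame(data).to_csv(path, index=False)


def write_standards(contrasts: np.ndarray, masses_kda: np.ndarray, path) -> None:
    pd.DataFrame({"contrast": contrasts, "mass_kDa": masses_kda}).to_csv(path, index=False)


def write_timecourse(dataset: KineticsDataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def write_standard_curve(amounts: np.ndarray, signals: np.ndarray, path) -> None:
    pd.DataFrame({"amount_pmol": amounts, "signal": signals}).to_csv(path, index=False)


def read_standard_curve(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path)
    missing = {"amount_pmol", "signal"} - set(df.columns)
    if missing:
        raise ValueError(f"standard-curve table {path} missing columns {sorted(missing)}")
    return df["amount_pmol"].to_numpy(dtype=float), df["signal"].to_numpy(dtype=float)
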