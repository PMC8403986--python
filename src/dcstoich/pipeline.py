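"""End-to-end orchestration from a single YAML config.

Chains the stages with reproducible seeding and a provenance record:

* stoichiometry arm: simulate chromatogram → SEC-MALS summary →
  enumerate feasible stoichiometries → cross-variant pairing, run for
  both the wild-type and M3 AXIN1 variants;
* kinetics arm: simulate titration + standard curve → standard-curve
  conversion → initial rates → Michaelis–Menten fit;
* mass-photometry arm: simulate events + standards → C2M calibration →
  fixed-bandwidth KDE.

All intermediates are written as CSV under the output directory; a
``provenance.json`` records package and library versions, the seed and a
hash of the config so any stage can be re-run in isolation.  Outputs
carry no timestamps, so a fixed (config, seed) pair reproduces
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .components import Stoichiometry, default_components, read_components
from .kinetics import analyze_assay
from .massphot import fit_c2m, mass_kde
from .secmals import AnalysisConfig, summarize_run, write_slice_table
from .stoich import EnumerationConstraints, enumerate_stoichiometries, pair_wt_m3
from .synthetic import (
    GeneratorConfig,
    SpeciesSpec,
    simulate_chromatogram,
    simulate_kinase_assay,
    simulate_mp_events,
    write_events,
    write_standard_curve,
    write_standards,
    write_timecourse,
)

logger = logging.getLogger(__name__)

# per-arm seed offsets so stages draw independent streams from one run seed
_SEED_OFFSETS = {"wt": 1, "m3": 2, "kinetics": 3, "massphot": 4}
_SEED_MOD = 2**31 - 1


def _stage_seed(base: int, stage: str) -> int:
    return (int(base) + _SEED_OFFSETS[stage]) % _SEED_MOD


DEFAULT_CONFIG: dict = {
    "seed": 0,
    "components": None,  # path to a component CSV, or None for defaults
    "generator": {
        "dn_dc": 0.185,
        "optical_constant": 1e-5,
        "path_length": 1.0,
        "noise_sd_rel": 0.0,
    },
    "grid": {"start": 1.5, "stop": 4.0, "step": 0.005},
    "variants": {
        "wt": {
            "species": [
                {
                    "counts": {"APC": 1, "AXIN1": 3, "CK1a": 3, "GSK3b": 3, "bcat": 13},
                    "peak_center": 2.65,
                    "peak_width": 0.12,
                    "total_mass_loaded": 2.0e-5,
                }
            ],
            "peak_window": [2.3, 3.0],
        },
        "m3": {
            "species": [
                {
                    "counts": {"APC": 1, "AXIN1": 1, "CK1a": 1, "GSK3b": 1, "bcat": 2},
                    "peak_center": 2.85,
                    "peak_width": 0.12,
                    "total_mass_loaded": 2.0e-5,
                }
            ],
            "peak_window": [2.5, 3.2],
        },
    },
    "enumeration": {"ci_multiplier": 1.96, "bcat_lower_rule": "max", "mn_sd_rel": 0.02},
    "kinetics": {
        "kcat": 10.0,
        "km": 50.0,
        "et_pmol": 0.9,
        "substrate_grid": [200.0, 100.0, 50.0, 12.5, 6.25, 3.125, 1.56, 0.78],
        "timepoints": [0.5, 1.0, 2.0, 5.0],
        "noise_sd_rel": 0.02,
    },
    "massphot": {
        "mixture": [[660.0, 1.0]],
        "n_events": 3000,
        "noise_sd": 25.0,
        "calibration": [2000.0, 0.0],
        "bandwidth": 25.0,
    },
}


def load_config(path) -> dict:
    """Load a YAML run config, filling unspecified keys from the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = _deep_merge(DEFAULT_CONFIG, user)
    if not isinstance(cfg.get("seed"), int):
        raise ValueError("config 'seed' must be an integer")
    return cfg


def _deep_merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def _config_hash(config: dict) -> str:
    canonical = yaml.safe_dump(config, sort_keys=True)
    return hashlib.sha256(canonical.encode()).hexdigest()


def _load_components(config: dict):
    path = config.get("components")
    return read_components(path) if path else default_components()


def _setup_run_logging(outdir: Path) -> logging.Handler:
    """Attach a run-local log file (no timestamps: outputs stay reproducible)."""
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("dcstoich")
    root.setLevel(logging.INFO)
    root.addHandler(handler)
    return handler


def write_provenance(config: dict, outdir: Path) -> None:
    import pandas
    import scipy

    record = {
        "dcstoich_version": __version__,
        "numpy_version": np.__version__,
        "scipy_version": scipy.__version__,
        "pandas_version": pandas.__version__,
        "seed": config["seed"],
        "config_sha256": _config_hash(config),
        "config": config,
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(record, fh, indent=2, sort_keys=True)


def _simulate_variant(variant: str, config: dict, components) -> tuple:
    gcfg = GeneratorConfig(seed=_stage_seed(config["seed"], variant), **config["generator"])
    g = config["grid"]
    grid = np.arange(g["start"], g["stop"] + g["step"] / 2, g["step"])
    vcfg = config["variants"][variant]
    species = [
        SpeciesSpec(
            Stoichiometry(s["counts"]),
            peak_center=float(s["peak_center"]),
            peak_width=float(s["peak_width"]),
            total_mass_loaded=float(s["total_mass_loaded"]),
        )
        for s in vcfg["species"]
    ]
    slices = simulate_chromatogram(
        species, grid, components, gcfg, peak_window=tuple(vcfg["peak_window"])
    )
    return slices, gcfg


def run_stoichiometry_pipeline(config: dict, outdir) -> dict:
    """simulate → secmals → enumerate → pair for both AXIN1 variants."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    components = _load_components(config)
    ecfg = config["enumeration"]

    results: dict = {"summaries": {}, "feasible": {}}
    feasible_sets = {}
    for variant in ("wt", "m3"):
        logger.info("stage simulate[%s]", variant)
        try:
            slices, gcfg = _simulate_variant(variant, config, components)
            write_slice_table(slices, outdir / f"slices_{variant}.csv")
            logger.info("stage secmals[%s]", variant)
            acfg = AnalysisConfig(
                dn_dc=gcfg.dn_dc,
                optical_constant=gcfg.optical_constant,
                path_length=gcfg.path_length,
            )
            summary = summarize_run(slices, acfg)
            summary.to_frame().to_csv(outdir / f"summary_{variant}.csv", index=False)
            logger.info(
                "secmals[%s]: Mn=%.0f Da, eps=%.0f +/- %.0f",
                variant, summary.mn, summary.eps_mean, summary.eps_sd,
            )
            logger.info("stage enumerate[%s]", variant)
            constraints = EnumerationConstraints(
                mn_mean=summary.mn,
                mn_sd=ecfg["mn_sd_rel"] * summary.mn,
                eps_mean=summary.eps_mean,
                eps_sd=summary.eps_sd,
                ci_multiplier=ecfg["ci_multiplier"],
                variant=variant,
                bcat_lower_rule=ecfg["bcat_lower_rule"],
            )
            feasible = enumerate_stoichiometries(components, constraints)
            feasible.write_csv(outdir / f"feasible_{variant}.csv")
            results["summaries"][variant] = summary
            feasible_sets[variant] = feasible
        except Exception as err:  # annotate with the failing stage
            raise RuntimeError(f"stoichiometry pipeline failed for variant {variant!r}: {err}") from err

    logger.info("stage pair")
    wt, m3 = pair_wt_m3(feasible_sets["wt"], feasible_sets["m3"])
    wt.write_csv(outdir / "feasible_wt_paired.csv")
    m3.write_csv(outdir / "feasible_m3_paired.csv")
    results["feasible"] = {"wt": wt, "m3": m3}
    write_provenance(config, outdir)
    return results


def run_kinetics_pipeline(config: dict, outdir) -> dict:
    """simulate kinase assay → standard curve → rates → MM fit."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    k = config["kinetics"]
    assay = simulate_kinase_assay(
        kcat=k["kcat"],
        km=k["km"],
        et_pmol=k["et_pmol"],
        substrate_grid=k["substrate_grid"],
        timepoints=k["timepoints"],
        noise_sd_rel=k["noise_sd_rel"],
        seed=_stage_seed(config["seed"], "kinetics"),
    )
    write_timecourse(assay.dataset, outdir / "timecourse.csv")
    write_standard_curve(assay.standard_amounts, assay.standard_signals, outdir / "standard_curve.csv")
    fit = analyze_assay(assay.dataset, assay.standard_amounts, assay.standard_signals)
    fit.to_frame().to_csv(outdir / "kinetics_fit.csv", index=False)
    logger.info("kinetics fit:\n%s", fit.summary())
    write_provenance(config, outdir)
    return {"assay": assay, "fit": fit}


def run_massphot_pipeline(config: dict, outdir) -> dict:
    """simulate events → C2M calibration → fixed-bandwidth KDE."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    m = config["massphot"]
    slope, intercept = m["calibration"]
    seed = _stage_seed(config["seed"], "massphot")
    contrasts, true_masses = simulate_mp_events(
        [tuple(x) for x in m["mixture"]], m["n_events"], m["noise_sd"], (slope, intercept), seed=seed
    )
    write_events(contrasts, outdir / "events.csv", true_masses)
    # noiseless standards sit exactly on the generating line
    std_masses = np.array([66.0, 146.0, 480.0, 1048.0])
    std_contrasts = (std_masses - intercept) / slope
    write_standards(std_contrasts, std_masses, outdir / "mp_standards.csv")
    cal = fit_c2m(std_contrasts, std_masses)
    dist = mass_kde(cal.contrast_to_mass(contrasts), bandwidth=m["bandwidth"])
    dist.to_frame().to_csv(outdir / "mass_kde.csv", index=False)
    write_provenance(config, outdir)
    return {"calibration": cal, "distribution": dist}


def run_all(config: dict, outdir) -> dict:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(outdir)
    try:
        return {
            "stoichiometry": run_stoichiometry_pipeline(config, outdir),
            "kinetics": run_kinetics_pipeline(config, outdir),
            "massphot": run_massphot_pipeline(config, outdir),
        }
    finally:
        logging.getLogger("dcstoich").removeHandler(handler)
        handler.close()
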