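"""Constraint-based enumeration of destruction-complex stoichiometries.

Given a component table (masses and molar extinction coefficients of
APC, AXIN1, CK1α, GSK3β and β-catenin) and the measurement windows from
SEC-MALS (number-average molar mass Mn and mean molar ε, each with an
SD and a confidence-interval multiplier), this module enumerates every
integer copy-number vector whose complex mass and ε fall inside the
windows and which respects the biochemical binding-site constraints:

* at least one copy of every component (integral counts);
* AXIN1 polymerizes through its DIX domain, so the wild-type complex
  carries at least two AXIN1; the polymerization-deficient M3 mutant
  needs only one and can only be scaffold-attached, capping AXIN1 at
  three per APC (the three SAMP repeats);
* each AXIN1 carries one CK1α site and one GSK3β site; kinase occupancy
  is assumed to be at least 50% (ceiling for odd AXIN1 counts) and at
  most complete;
* each APC binds one to ten β-catenin molecules through its usable
  15R/20R repeats and at least one AXIN1;
* at least one β-catenin is bound per AXIN1 and per APC.  Because a
  single β-catenin can simultaneously engage an AXIN1 site and an APC
  repeat, the default lower bound is max(n_AXIN1, n_APC); the stricter
  additive reading is available via ``bcat_lower_rule="sum"``;
* each vacant kinase site on AXIN1 may instead hold one extra
  β-catenin, so the upper bound gains Σ(n_AXIN1 − n_kinase) over the
  kinase species.

A cross-variant coupling (:func:`pair_wt_m3`) encodes the observation
that at a given APC:AXIN1 count pair the wild-type complex carries at
least one more β-catenin than the M3 complex.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import pandas as pd

from .components import (
    ComponentSpec,
    Stoichiometry,
    components_by_role,
    half_occupancy_floor,
    validate_components,
)

VARIANTS = ("wt", "m3")
BCAT_LOWER_RULES = ("max", "sum")


@dataclass(frozen=True)
class SiteCapacities:
    """Binding-site capacities of the scaffolds."""

    bcat_per_apc: int = 10   # four 15R + six usable 20R repeats
    axin_per_apc: int = 3    # three SAMP repeats
    kinase_per_axin: int = 1
    bcat_per_axin: int = 1


@dataclass(frozen=True)
class EnumerationConstraints:
    """Measurement windows and variant-specific rules for enumeration.

    ``mn_mean ± ci_multiplier · mn_sd`` defines the admissible complex
    mass window; ``eps_mean ± ci_multiplier · eps_sd`` the ε window
    (``eps_mean=None`` leaves ε unconstrained).  ``variant`` is ``"wt"``
    (polymerizing AXIN1) or ``"m3"`` (polymerization-deficient).
    """

    mn_mean: float
    mn_sd: float
    eps_mean: float | None = None
    eps_sd: float = 0.0
    ci_multiplier: float = 1.96
    variant: str = "wt"
    bcat_lower_rule: str = "max"
    capacities: SiteCapacities = field(default_factory=SiteCapacities)

    def __post_init__(self) -> None:
        if self.mn_mean <= 0:
            raise ValueError("mn_mean must be > 0")
        if self.mn_sd < 0 or self.eps_sd < 0:
            raise ValueError("SDs must be >= 0")
        if self.eps_mean is not None and self.eps_mean <= 0:
            raise ValueError("eps_mean must be > 0 (or None)")
        if self.ci_multiplier <= 0:
            raise ValueError("ci_multiplier must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.bcat_lower_rule not in BCAT_LOWER_RULES:
            raise ValueError(f"bcat_lower_rule must be one of {BCAT_LOWER_RULES}")

    @property
    def mass_window(self) -> tuple[float, float]:
        half = self.ci_multiplier * self.mn_sd
        return (self.mn_mean - half, self.mn_mean + half)

    @property
    def eps_window(self) -> tuple[float, float] | None:
        if self.eps_mean is None:
            return None
        half = self.ci_multiplier * self.eps_sd
        return (self.eps_mean - half, self.eps_mean + half)


@dataclass(frozen=True)
class ConditionReport:
    """Per-condition pass/fail record for one candidate stoichiometry."""

    results: tuple[tuple[str, bool], ...]

    @property
    def passed(self) -> bool:
        return all(ok for _, ok in self.results)

    def as_dict(self) -> dict[str, bool]:
        return dict(self.results)

    def failed(self) -> list[str]:
        return [name for name, ok in self.results if not ok]


@dataclass
class FeasibleSet:
    """Stoichiometries passing every condition, sorted lexicographically."""

    stoichiometries: list[Stoichiometry]
    constraints: EnumerationConstraints
    components: list[ComponentSpec]
    reports: list[ConditionReport]

    def __len__(self) -> int:
        return len(self.stoichiometries)

    def to_frame(self) -> pd.DataFrame:
        order = _canonical_order(self.components)
        rows = []
        for s in self.stoichiometries:
            row = {f"n_{name}": s[name] for name in order}
            row["mass_Da"] = complex_mass(s, self.components)
            row["eps"] = complex_extinction(s, self.components)
            rows.append(row)
        cols = [f"n_{name}" for name in order] + ["mass_Da", "eps"]
        return pd.DataFrame(rows, columns=cols)

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _canonical_order(components: Sequence[ComponentSpec]) -> list[str]:
    """Scaffold-A, scaffold-B, kinases, substrate — the loop/sort order."""
    by_role = components_by_role(components)
    order: list[str] = []
    for role in ("scaffold_a", "scaffold_b", "kinase", "substrate"):
        order.extend(c.name for c in by_role[role])
    return order


def _role_names(components: Sequence[ComponentSpec]):
    by_role = components_by_role(components)
    if len(by_role["scaffold_a"]) != 1 or len(by_role["scaffold_b"]) != 1:
        raise ValueError("exactly one scaffold of each kind is required")
    if len(by_role["substrate"]) != 1:
        raise ValueError("exactly one substrate is required")
    if not by_role["kinase"]:
        raise ValueError("at least one kinase is required")
    return (
        by_role["scaffold_a"][0],
        by_role["scaffold_b"][0],
        by_role["kinase"],
        by_role["substrate"][0],
    )


def complex_mass(stoich: Stoichiometry, components: Sequence[ComponentSpec]) -> float:
    """Count-weighted sum of component molecular weights (g/mol)."""
    comps = {c.name: c for c in validate_components(components)}
    if stoich.total() == 0:
        raise ValueError("empty stoichiometry")
    total = 0.0
    for name, n in stoich.counts:
        if name not in comps:
            raise KeyError(f"unknown component {name!r}")
        total += n * comps[name].mass
    return total


def complex_extinction(stoich: Stoichiometry, components: Sequence[ComponentSpec]) -> float:
    """Count-weighted sum of component molar extinction coefficients."""
    comps = {c.name: c for c in validate_components(components)}
    if stoich.total() == 0:
        raise ValueError("empty stoichiometry")
    total = 0.0
    for name, n in stoich.counts:
        if name not in comps:
            raise KeyError(f"unknown component {name!r}")
        total += n * comps[name].eps
    return total


def check_conditions(
    stoich: Stoichiometry,
    constraints: EnumerationConstraints,
    components: Sequence[ComponentSpec],
) -> ConditionReport:
    """Evaluate every enumeration condition; always returns a report.

    Report keys: ``integral_counts``, ``one_of_each``, ``axin_minimum``,
    ``kinase_occupancy``, ``bcat_lower``, ``bcat_upper``,
    ``axin_per_apc``, ``mass_window``, ``eps_window``.
    """
    apc, axin, kinases, substrate = _role_names(components)
    caps = constraints.capacities
    counts = stoich.as_dict()

    n_apc = counts.get(apc.name, 0)
    n_axin = counts.get(axin.name, 0)
    n_sub = counts.get(substrate.name, 0)
    n_kin = {k.name: counts.get(k.name, 0) for k in kinases}

    results: list[tuple[str, bool]] = []
    # counts are validated integers >= 0 by construction
    results.append(("integral_counts", all(isinstance(n, int) for n in counts.values())))
    results.append(
        ("one_of_each", all(counts.get(c.name, 0) >= 1 for c in components))
    )
    axin_min = 2 if constraints.variant == "wt" else 1
    results.append(("axin_minimum", n_axin >= axin_min))
    results.append(
        (
            "kinase_occupancy",
            all(
                half_occupancy_floor(n_axin) <= nk <= caps.kinase_per_axin * n_axin
                for nk in n_kin.values()
            ),
        )
    )
    if constraints.bcat_lower_rule == "max":
        bcat_lo = max(n_axin, n_apc)
    else:
        bcat_lo = n_axin + n_apc
    results.append(("bcat_lower", n_sub >= bcat_lo))
    vacancies = sum(caps.kinase_per_axin * n_axin - nk for nk in n_kin.values())
    bcat_hi = caps.bcat_per_axin * n_axin + caps.bcat_per_apc * n_apc + vacancies
    results.append(("bcat_upper", n_sub <= bcat_hi))
    axin_ok = n_axin >= n_apc
    if constraints.variant == "m3":
        # non-polymerizing AXIN1 can only attach through APC's SAMP repeats
        axin_ok = axin_ok and n_axin <= caps.axin_per_apc * n_apc
    results.append(("axin_per_apc", axin_ok))

    mass = complex_mass(stoich, components) if stoich.total() else 0.0
    lo, hi = constraints.mass_window
    results.append(("mass_window", lo <= mass <= hi))
    eps_window = constraints.eps_window
    if eps_window is None:
        results.append(("eps_window", True))
    else:
        eps = complex_extinction(stoich, components)
        results.append(("eps_window", eps_window[0] <= eps <= eps_window[1]))

    return ConditionReport(tuple(results))


def enumerate_stoichiometries(
    components: Sequence[ComponentSpec],
    constraints: EnumerationConstraints,
) -> FeasibleSet:
    """Exhaustive enumeration of feasible stoichiometries.

    Visits, in lexicographic order over (scaffold A, scaffold B,
    kinases…, substrate), every count vector with n_X ≤
    floor(mass upper bound / mass_X), pruning branches whose partial
    mass already exceeds the window; each surviving candidate is passed
    through :func:`check_conditions`, which remains the single source of
    truth for feasibility.  An upper mass bound below the one-of-each
    minimum yields an empty set, not an error.
    """
    comps = validate_components(components)
    apc, axin, kinases, substrate = _role_names(comps)
    ordered = [apc, axin, *kinases, substrate]
    lo, hi = constraints.mass_window
    if hi <= 0:
        return FeasibleSet([], constraints, comps, [])

    bounds = [int(hi // c.mass) for c in ordered]
    if any(b < 1 for b in bounds):
        return FeasibleSet([], constraints, comps, [])
    # minimal mass of one copy of every component from index i onward
    tail_min = [0.0] * (len(ordered) + 1)
    for i in range(len(ordered) - 1, -1, -1):
        tail_min[i] = tail_min[i + 1] + ordered[i].mass

    found: list[tuple[Stoichiometry, ConditionReport]] = []

    def recurse(i: int, partial_mass: float, counts: dict[str, int]) -> None:
        if i == len(ordered):
            stoich = Stoichiometry(counts)
            report = check_conditions(stoich, constraints, comps)
            if report.passed:
                found.append((stoich, report))
            return
        comp = ordered[i]
        for n in range(1, bounds[i] + 1):
            mass = partial_mass + n * comp.mass
            if mass + tail_min[i + 1] > hi:
                break
            counts[comp.name] = n
            recurse(i + 1, mass, counts)
        counts.pop(comp.name, None)

    recurse(0, 0.0, {})
    # recursion already emits lexicographic order over the canonical axes
    return FeasibleSet(
        [s for s, _ in found], constraints, comps, [r for _, r in found]
    )


def pair_wt_m3(wt: FeasibleSet, m3: FeasibleSet) -> tuple[FeasibleSet, FeasibleSet]:
    """Apply the cross-variant β-catenin coupling.

    For every (n_APC, n_AXIN1) pair present in *both* feasible sets, M3
    entries whose β-catenin count exceeds (max wild-type β-catenin at
    that pair) − 1 are dropped: the wild-type complex must carry at
    least one more β-catenin, and the M3 complex may not exceed it.
    Entries whose count pair has no counterpart in the other set are
    retained unchanged.
    """
    if [c.name for c in wt.components] != [c.name for c in m3.components]:
        raise ValueError("feasible sets come from different component tables")
    apc, axin, _, substrate = _role_names(wt.components)

    def pair_key(s: Stoichiometry) -> tuple[int, int]:
        return (s[apc.name], s[axin.name])

    wt_max_bcat: dict[tuple[int, int], int] = {}
    for s in wt.stoichiometries:
        key = pair_key(s)
        wt_max_bcat[key] = max(wt_max_bcat.get(key, 0), s[substrate.name])

    kept_s, kept_r = [], []
    for s, r in zip(m3.stoichiometries, m3.reports):
        key = pair_key(s)
        if key in wt_max_bcat and s[substrate.name] > wt_max_bcat[key] - 1:
            continue
        kept_s.append(s)
        kept_r.append(r)
    m3_filtered = FeasibleSet(kept_s, m3.constraints, m3.components, kept_r)
    return wt, m3_filtered


def pair_frames(
    wt_df: pd.DataFrame,
    m3_df: pd.DataFrame,
    apc_col: str = "n_APC",
    axin_col: str = "n_AXIN1",
    bcat_col: str = "n_bcat",
) -> pd.DataFrame:
    """:func:`pair_wt_m3` on feasible-set CSV tables; returns the filtered M3 table."""
    wt_max = wt_df.groupby([apc_col, axin_col])[bcat_col].max()

    def keep(row) -> bool:
        key = (row[apc_col], row[axin_col])
        if key not in wt_max.index:
            return True
        return row[bcat_col] <= wt_max.loc[key] - 1

    return m3_df[m3_df.apply(keep, axis=1)].reset_index(drop=True)


def read_feasible_csv(path, components: Sequence[ComponentSpec], constraints: EnumerationConstraints) -> FeasibleSet:
    """Rebuild a :class:`FeasibleSet` from a CSV written by ``write_csv``."""
    comps = validate_components(components)
    df = pd.read_csv(path)
    order = _canonical_order(comps)
    stoichs = [
        Stoichiometry({name: int(row[f"n_{name}"]) for name in order})
        for _, row in df.iterrows()
    ]
    reports = [check_conditions(s, constraints, comps) for s in stoichs]
    return FeasibleSet(stoichs, constraints, comps, reports)
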