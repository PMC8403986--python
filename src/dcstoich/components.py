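"""Subunit definitions for destruction-complex (DC) stoichiometry analysis.

The Wnt-pathway destruction complex is assembled from two scaffolds —
APC (adenomatous polyposis coli) and AXIN1 — which co-recruit the kinases
CK1α and GSK3β together with their substrate β-catenin.  Every module in
this package describes a candidate complex as an integer copy-number
vector over such subunits; the complex's molecular weight and molar
extinction coefficient at 280 nm are the count-weighted sums of the
subunit values.

Roles drive the binding-site constraints used by :mod:`dcstoich.stoich`:

``scaffold_a``
    APC-like scaffold: carries a fixed number of substrate-binding
    repeats (ten usable 15R/20R repeats) and scaffold-B-binding SAMP
    repeats (three).
``scaffold_b``
    AXIN1-like scaffold: one kinase site per kinase species and one
    substrate site per copy; may self-polymerize (wild type) or not
    (the M3 point mutant).
``kinase``
    CK1α / GSK3β; occupancy is counted against scaffold-B sites.
``substrate``
    β-catenin.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

ROLES = ("scaffold_a", "scaffold_b", "kinase", "substrate")

#: Canonical column order used in component CSV files.
_CSV_COLUMNS = ("name", "mass_Da", "eps", "role")


@dataclass(frozen=True)
class ComponentSpec:
    """One complex subunit.

    Parameters
    ----------
    name : str
        Unique identifier, e.g. ``"APC"``.
    mass : float
        Molecular weight in g/mol (Da).
    eps : float
        Molar extinction coefficient at 280 nm in M^-1 cm^-1.
    role : str
        One of :data:`ROLES`.
    """

    name: str
    mass: float
    eps: float
    role: str

    def __post_init__(self) -> None:
        if self.mass <= 0:
            raise ValueError(f"component {self.name!r}: mass must be > 0")
        if self.eps < 0:
            raise ValueError(f"component {self.name!r}: eps must be >= 0")
        if self.role not in ROLES:
            raise ValueError(
                f"component {self.name!r}: role {self.role!r} not in {ROLES}"
            )


@dataclass(frozen=True)
class Stoichiometry:
    """Integer copy-number vector over components.

    ``counts`` maps component name -> non-negative integer.  Derived
    complex mass and extinction coefficient are computed against a
    component table via :func:`dcstoich.stoich.complex_mass` and
    :func:`dcstoich.stoich.complex_extinction`.
    """

    counts: tuple[tuple[str, int], ...]

    def __init__(self, counts: Mapping[str, int] | Iterable[tuple[str, int]]):
        items = tuple(sorted(dict(counts).items()))
        for name, n in items:
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise TypeError(f"count for {name!r} must be an integer, got {n!r}")
            if n < 0:
                raise ValueError(f"count for {name!r} must be >= 0, got {n}")
        object.__setattr__(self, "counts", items)

    def as_dict(self) -> dict[str, int]:
        return dict(self.counts)

    def __getitem__(self, name: str) -> int:
        return self.as_dict().get(name, 0)

    def total(self) -> int:
        return sum(n for _, n in self.counts)


def validate_components(components: Iterable[ComponentSpec]) -> list[ComponentSpec]:
    """Check name uniqueness and return the components as a list."""
    comps = list(components)
    names = [c.name for c in comps]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate component names in {names}")
    return comps


def components_by_role(
    components: Iterable[ComponentSpec],
) -> dict[str, list[ComponentSpec]]:
    out: dict[str, list[ComponentSpec]] = {r: [] for r in ROLES}
    for c in validate_components(components):
        out[c.role].append(c)
    return out


def extinction_coefficient_280nm(sequence: str, *, oxidized_cysteines: bool = False) -> int:
    """Predicted molar extinction coefficient at 280 nm from sequence.

    Uses the Gill–von Hippel composition method (as implemented by
    ProtParam): 5500 M^-1 cm^-1 per tryptophan, 1490 per tyrosine and,
    for the oxidized form, 125 per cystine (disulfide-bonded cysteine
    pair).

    Parameters
    ----------
    sequence : str
        One-letter amino-acid sequence.
    oxidized_cysteines : bool
        If True, assume all cysteines form cystines.
    """
    seq = sequence.upper()
    eps = 5500 * seq.count("W") + 1490 * seq.count("Y")
    if oxidized_cysteines:
        eps += 125 * (seq.count("C") // 2)
    return eps


def default_components() -> list[ComponentSpec]:
    """Default human destruction-complex component table.

    Masses are the predicted molecular weights of the five human
    proteins (APC 312 kDa, AXIN1 92 kDa, CK1α 39 kDa, GSK3β 47 kDa,
    β-catenin 85 kDa).  The ε values are *synthetic placeholders* set at
    typical protein absorptivities (A280 of a 1 g/L, 1 cm sample between
    0.8 and 1.1): sequence-derived values were not available offline.
    For real analyses compute ε from the canonical sequences with
    :func:`extinction_coefficient_280nm` and build your own table.
    """
    return [
        ComponentSpec("APC", 312_000.0, 280_000.0, "scaffold_a"),
        ComponentSpec("AXIN1", 92_000.0, 90_000.0, "scaffold_b"),
        ComponentSpec("CK1a", 39_000.0, 35_000.0, "kinase"),
        ComponentSpec("GSK3b", 47_000.0, 50_000.0, "kinase"),
        ComponentSpec("bcat", 85_000.0, 75_000.0, "substrate"),
    ]


def write_components(components: Iterable[ComponentSpec], path) -> None:
    comps = validate_components(components)
    df = pd.DataFrame(
        {
            "name": [c.name for c in comps],
            "mass_Da": [c.mass for c in comps],
            "eps": [c.eps for c in comps],
            "role": [c.role for c in comps],
        }
    )
    df.to_csv(path, index=False)


def read_components(path) -> list[ComponentSpec]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"component table {path} missing columns {sorted(missing)}")
    return validate_components(
        ComponentSpec(str(r["name"]), float(r["mass_Da"]), float(r["eps"]), str(r["role"]))
        for _, r in df.iterrows()
    )


def half_occupancy_floor(n_scaffold_b: int) -> int:
    """Minimum kinase count for >= 50% occupancy of scaffold-B sites.

    With integer molecules, "at least 50%" of an odd number of sites
    rounds up: ceil(n/2).
    """
    return math.ceil(n_scaffold_b / 2)
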