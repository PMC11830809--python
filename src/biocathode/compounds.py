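"""Compound registry: electron equivalents and COD per mole.

For an organic CxHyOz, full oxidation to CO2 and H2O releases
ne = 4x + y - 2z electrons per mole (each C goes to +IV, each H to +I,
each O claims -II). The COD equivalent follows as 8*ne g O2/mol, since
one mole of O2 accepts 4 electrons (32 g O2 per 4 mol e-).

Inorganic species carry registered half-reaction electron counts instead:
H2 -> 2H+ + 2e- (2), S2O3^2- + 5H2O -> 2SO4^2- + 10H+ + 8e- (8),
Fe3+ + e- -> Fe2+ (1).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Optional

import pandas as pd

from biocathode.constants import GRAMS_O2_PER_MOL_E

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Standard atomic weights (g/mol) for the elements occurring in the media
# and registry compounds.
ATOMIC_WEIGHTS = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "P": 30.974,
    "S": 32.06,
    "K": 39.098,
    "Fe": 55.845,
}


def parse_formula(formula: str) -> dict[str, int]:
    """Parse a Hill-style formula like ``C4H8O2`` into element counts."""
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula) or not counts:
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def electron_equivalents(formula: str) -> int:
    """Electrons per mole released by full oxidation of CxHyOz to CO2/H2O.

    Raises for elements outside {C, H, O} (e.g. N or S in organics): such
    species need an explicit electron count, not the combustion formula.
    """
    counts = parse_formula(formula)
    extra = set(counts) - {"C", "H", "O"}
    if extra:
        raise ValueError(
            f"formula {formula!r} contains {sorted(extra)}; "
            "provide an explicit ne for non-CHO species"
        )
    ne = 4 * counts.get("C", 0) + counts.get("H", 0) - 2 * counts.get("O", 0)
    if ne <= 0:
        raise ValueError(f"non-positive electron count for {formula!r}")
    return ne


def molar_mass(formula: str) -> float:
    """Molar mass in g/mol of a formula over the registered atomic weights.

    Handy for medium stoichiometry, e.g. sodium formate CHO2Na at
    1.36 g/L is 20 mM.
    """
    counts = parse_formula(formula)
    unknown = set(counts) - set(ATOMIC_WEIGHTS)
    if unknown:
        raise ValueError(f"no atomic weight registered for {sorted(unknown)}")
    return sum(ATOMIC_WEIGHTS[el] * n for el, n in counts.items())


def mass_to_mM(mass_g_per_L: float, formula: str) -> float:
    """Convert a medium recipe mass concentration (g/L) to mM."""
    if mass_g_per_L < 0:
        raise ValueError("mass must be >= 0")
    return mass_g_per_L / molar_mass(formula) * 1000.0


@dataclass(frozen=True)
class CompoundSpec:
    """One registry entry: name, composition or half-reaction tag, ne, COD."""

    name: str
    ne: int
    elements: Optional[Mapping[str, int]] = None
    half_reaction: Optional[str] = None
    role: str = "product"

    @property
    def cod_gO2_per_mol(self) -> float:
        return GRAMS_O2_PER_MOL_E * self.ne

    @classmethod
    def from_formula(cls, name: str, formula: str, role: str = "product") -> "CompoundSpec":
        return cls(
            name=name,
            ne=electron_equivalents(formula),
            elements=parse_formula(formula),
            role=role,
        )


def load_registry(path=None) -> dict[str, CompoundSpec]:
    """Load the compound registry from a TSV (default: the bundled table).

    Columns: name, formula (organics), half_reaction + ne_override
    (inorganics), role. An explicit ne_override always wins.
    """
    if path is None:
        source = resources.files("biocathode.data").joinpath("compounds.tsv")
        with resources.as_file(source) as p:
            table = pd.read_csv(p, sep="\t", dtype=str)
    else:
        table = pd.read_csv(path, sep="\t", dtype=str)
    registry: dict[str, CompoundSpec] = {}
    for row in table.itertuples(index=False):
        name = row.name.strip()
        formula = row.formula if isinstance(row.formula, str) and row.formula else None
        tag = (
            row.half_reaction
            if isinstance(row.half_reaction, str) and row.half_reaction
            else None
        )
        override = (
            int(row.ne_override)
            if isinstance(row.ne_override, str) and row.ne_override
            else None
        )
        role = row.role if isinstance(row.role, str) and row.role else "product"
        if override is not None:
            spec = CompoundSpec(
                name=name,
                ne=override,
                elements=parse_formula(formula) if formula else None,
                half_reaction=tag,
                role=role,
            )
        elif formula is not None:
            spec = CompoundSpec.from_formula(name, formula, role=role)
        else:
            raise ValueError(f"registry row {name!r} has neither formula nor ne")
        registry[name] = spec
    return registry


DEFAULT_REGISTRY = load_registry()

ORGANIC_ACIDS = tuple(
    name for name, spec in DEFAULT_REGISTRY.items() if spec.elements and spec.ne > 0
)
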