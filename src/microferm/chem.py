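"""Elemental-formula chemistry for fermentation balances.

Provides condensed-formula parsing, per-carbon molar mass, mean carbon
oxidation state under a fixed-oxidation-state convention, degree of
reduction per carbon, and the registry of fermentation products with
their carbon atoms and reducing equivalents (electrons released on
complete oxidation).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Mapping

from .constants import ATOMIC_WEIGHTS


class FormulaError(ValueError):
    """Malformed or chemically invalid elemental formula."""


class ConventionError(ValueError):
    """Oxidation-state convention cannot be applied to a formula."""


@dataclass(frozen=True)
class ElementalFormula:
    """An element -> stoichiometric coefficient map for one formula unit.

    Coefficients may be fractional (biomass formulas are normalized per
    carbon; nucleic-acid formulas per nucleotide).
    """

    coefficients: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        coeffs = dict(self.coefficients)
        for elem, c in coeffs.items():
            if elem not in ATOMIC_WEIGHTS:
                raise FormulaError(f"unknown element symbol {elem!r}")
            if not (c >= 0.0) or c != c or c == float("inf"):
                raise FormulaError(f"coefficient for {elem} must be finite and >= 0, got {c}")
        object.__setattr__(self, "coefficients", coeffs)

    @property
    def carbon(self) -> float:
        return self.coefficients.get("C", 0.0)

    def get(self, element: str) -> float:
        return self.coefficients.get(element, 0.0)

    def scaled(self, factor: float) -> "ElementalFormula":
        if factor <= 0:
            raise FormulaError("scale factor must be positive")
        return ElementalFormula(
            {e: c * factor for e, c in self.coefficients.items()}, label=self.label
        )

    def to_string(self) -> str:
        """Serialize in parse_formula-compatible condensed form."""
        parts = []
        order = sorted(self.coefficients, key=lambda e: (e != "C", e != "H", e))
        for elem in order:
            c = self.coefficients[elem]
            if c == 0:
                continue
            if c == 1:
                parts.append(elem)
            elif c == int(c):
                parts.append(f"{elem}{int(c)}")
            else:
                parts.append(f"{elem}{c:g}")
        return "".join(parts)


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?)?")


def parse_formula(text: str, label: str = "") -> ElementalFormula:
    """Parse a condensed elemental formula such as ``CH1.57N0.27O0.30S0.013``.

    Brackets, underscores, and a trailing polymer marker ``n`` are
    tolerated and stripped.  Repeated element symbols accumulate.

    Raises
    ------
    FormulaError
        On an unparseable token (with its offset) or unknown element.
    """
    # Strip polymer markers: "[...]_n", "(...)n", "..._n".  A bare trailing
    # "n" without underscore or bracket is ambiguous (Zn, Sn) and kept.
    cleaned = re.sub(r"(?:(?<=\])|(?<=\)))_?n_?$|_n_?$", "", text.strip())
    cleaned = re.sub(r"[\[\]()\s_]", "", cleaned)
    if not cleaned:
        raise FormulaError(f"empty formula string: {text!r}")

    coeffs: dict[str, float] = {}
    pos = 0
    while pos < len(cleaned):
        m = _TOKEN.match(cleaned, pos)
        if m is None or m.group(1) not in ATOMIC_WEIGHTS:
            raise FormulaError(f"malformed formula {text!r} at offset {pos} ({cleaned[pos:]!r})")
        elem = m.group(1)
        coeff = float(m.group(2)) if m.group(2) else 1.0
        coeffs[elem] = coeffs.get(elem, 0.0) + coeff
        pos = m.end()
    return ElementalFormula(coeffs, label=label or text)


@dataclass(frozen=True)
class OxidationConvention:
    """Fixed oxidation states used to solve for the mean carbon oxidation state.

    Carbon is never in the map: the charge balance is solved for it.
    Elements in ``ignored`` contribute nothing to the balance.
    """

    states: Mapping[str, float] = field(
        default_factory=lambda: {"H": +1.0, "O": -2.0, "N": -3.0, "S": -2.0, "P": +5.0}
    )
    ignored: frozenset[str] = frozenset({"K", "Mg", "Ca"})
    charge: float = 0.0
    name: str = "default"

    def __post_init__(self) -> None:
        if "C" in self.states:
            raise ConventionError("carbon must not carry a fixed oxidation state")
        object.__setattr__(self, "states", dict(self.states))
        object.__setattr__(self, "ignored", frozenset(self.ignored))


#: Convention for biomass and protein formulas: P is treated as part of the
#: redox-inert mineral fraction alongside K, Mg, Ca.
BIOMASS_CONVENTION = OxidationConvention(
    states={"H": +1.0, "O": -2.0, "N": -3.0, "S": -2.0},
    ignored=frozenset({"P", "K", "Mg", "Ca"}),
    name="biomass",
)

#: Convention for nucleic acids: phosphorus counted at +5, neutral unit.
NUCLEIC_ACID_CONVENTION = OxidationConvention(
    states={"H": +1.0, "O": -2.0, "N": -3.0, "S": -2.0, "P": +5.0},
    ignored=frozenset({"K", "Mg", "Ca"}),
    name="nucleic_acid",
)

CONVENTIONS: dict[str, OxidationConvention] = {
    "biomass": BIOMASS_CONVENTION,
    "nucleic_acid": NUCLEIC_ACID_CONVENTION,
}


def molar_mass(f: ElementalFormula) -> float:
    """Molar mass of one formula unit, g/mol."""
    return sum(ATOMIC_WEIGHTS[e] * c for e, c in f.coefficients.items())


def molar_mass_per_carbon(f: ElementalFormula) -> float:
    """Grams of formula per mole of carbon it contains.

    Invariant under rescaling all coefficients by a common factor.
    """
    if f.carbon <= 0:
        raise FormulaError(f"formula {f.label or f.to_string()!r} contains no carbon")
    return molar_mass(f) / f.carbon


def carbon_oxidation_state(
    f: ElementalFormula, conv: OxidationConvention = BIOMASS_CONVENTION
) -> float:
    """Mean oxidation state of carbon solving the charge balance.

    Every non-carbon, non-ignored element contributes coefficient times
    its fixed state; carbon absorbs the remainder so the unit carries
    the convention's net charge.
    """
    if f.carbon <= 0:
        raise FormulaError(f"formula {f.label or f.to_string()!r} contains no carbon")
    total = 0.0
    for elem, coeff in f.coefficients.items():
        if elem == "C" or elem in conv.ignored:
            continue
        if elem not in conv.states:
            raise ConventionError(
                f"element {elem} has no oxidation state in convention {conv.name!r} "
                "and is not ignored"
            )
        total += coeff * conv.states[elem]
    return (conv.charge - total) / f.carbon


def degree_of_reduction_per_carbon(
    f: ElementalFormula, conv: OxidationConvention = BIOMASS_CONVENTION
) -> float:
    """Electrons released per mole carbon on complete oxidation (gamma/C).

    Equals 4 minus the mean carbon oxidation state.
    """
    return 4.0 - carbon_oxidation_state(f, conv)


def reducing_equivalents_of(f: ElementalFormula) -> int:
    """Electrons obtained by complete oxidation of a neutral C/H/O compound.

    Computed as ``4c + h - 2o``.  Compounds containing other elements
    must use an explicit :class:`CompoundSpec` instead.
    """
    extra = set(f.coefficients) - {"C", "H", "O"}
    extra -= {e for e in extra if f.coefficients[e] == 0}
    if extra:
        raise FormulaError(
            f"reducing_equivalents_of supports C/H/O formulas only; found {sorted(extra)}"
        )
    val = 4 * f.get("C") + f.get("H") - 2 * f.get("O")
    if abs(val - round(val)) > 1e-9:
        raise FormulaError("non-integer electron count; check the formula")
    return int(round(val))


@dataclass(frozen=True)
class CompoundSpec:
    """A fermentation product with its carbon and electron bookkeeping."""

    name: str
    carbon_atoms: int
    reducing_equivalents: int
    formula: ElementalFormula | None = None

    def __post_init__(self) -> None:
        if self.carbon_atoms < 0 or self.reducing_equivalents < 0:
            raise ValueError("carbon atoms and reducing equivalents must be >= 0")
        if self.formula is not None:
            if abs(self.formula.carbon - self.carbon_atoms) > 1e-9:
                raise ValueError(
                    f"{self.name}: formula carbon {self.formula.carbon} != {self.carbon_atoms}"
                )
            gamma = reducing_equivalents_of(self.formula)
            if gamma != self.reducing_equivalents:
                raise ValueError(
                    f"{self.name}: formula gives {gamma} e-, registered "
                    f"{self.reducing_equivalents}"
                )

    @property
    def electrons_per_carbon(self) -> float:
        if self.carbon_atoms == 0:
            raise ZeroDivisionError(f"{self.name} has no carbon")
        return self.reducing_equivalents / self.carbon_atoms


def _spec(name: str, formula: str, c: int, e: int) -> CompoundSpec:
    return CompoundSpec(name, c, e, parse_formula(formula, label=name))


# Acid anions are represented by their undissociated neutral acids, which is
# what the per-compound electron counts are built from.
DEFAULT_REGISTRY: dict[str, CompoundSpec] = {
    s.name: s
    for s in (
        _spec("acetate", "C2H4O2", 2, 8),
        _spec("butyrate", "C4H8O2", 4, 20),
        _spec("CO2", "CO2", 1, 0),
        _spec("formate", "CH2O2", 1, 2),
        _spec("H2", "H2", 0, 2),
        _spec("methyl_butyrate", "C5H10O2", 5, 26),
        _spec("propionate", "C3H6O2", 3, 14),
        _spec("succinate", "C4H6O4", 4, 14),
        _spec("lactate", "C3H6O3", 3, 12),
        _spec("ethanol", "C2H6O", 2, 12),
    )
}
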