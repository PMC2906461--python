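"""Elemental formula arithmetic and electron-equivalent (degree of reduction)
bookkeeping.

The degree of reduction :math:`\\gamma` of a compound is the number of electron
equivalents released per mole on complete oxidation to CO2, H2O and NH3, under
a fixed valence convention (C=+4, H=+1, O=-2, N=-3 by default).  CO2, H2O and
NH3 are the zero-:math:`\\gamma` reference states.  Sulfur species deliberately
carry no :math:`\\gamma`; sulfate reduction is accounted for through an explicit
:class:`RedoxCouple` (8 e- per mole sulfate -> sulfide).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping

__all__ = [
    "ElementalFormula",
    "BiomassFormula",
    "RedoxCouple",
    "ReactionBalance",
    "FormulaError",
    "MissingValenceError",
    "DEFAULT_VALENCES",
    "ATOMIC_MASSES",
    "degree_of_reduction",
    "carbon_per_mol",
    "molar_mass",
    "check_reaction_balance",
    "SULFATE_TO_SULFIDE",
    "FUMARATE_TO_SUCCINATE",
]

#: Valence convention used for degree-of-reduction accounting.  Nitrogen at -3
#: makes NH3 a zero-reference state alongside CO2 and H2O.
DEFAULT_VALENCES: Mapping[str, int] = {"C": 4, "H": 1, "O": -2, "N": -3}

#: Standard atomic masses (g/mol) for the elements that occur in the compound
#: registry.  Kept as a compiled table; extend as needed.
ATOMIC_MASSES: Mapping[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.06,
    "Cl": 35.45,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
}

BALANCE_TOL = 1e-9


class FormulaError(ValueError):
    """Malformed or physically impossible elemental formula."""


class MissingValenceError(KeyError):
    """An element in a formula has no entry in the valence convention."""

    def __init__(self, element: str):
        super().__init__(element)
        self.element = element

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"no valence defined for element {self.element!r}"


_TOKEN = re.compile(r"([A-Z][a-z]?)(\d+(?:\.\d+)?)?")


@dataclass(frozen=True)
class ElementalFormula:
    """Immutable element -> count mapping with a text label.

    Counts are real-valued so that lumped biomass formulas such as
    ``C4H7O1.5N`` are representable.  Instances are hashable and usable as
    keys in reaction stoichiometry mappings.
    """

    composition: tuple[tuple[str, float], ...]
    name: str = ""

    def __init__(self, elements: Mapping[str, float], name: str = ""):
        items = []
        for symbol, count in elements.items():
            count = float(count)
            if count < 0:
                raise FormulaError(f"negative count for element {symbol!r}")
            if count > 0:
                items.append((symbol, count))
        if not items:
            raise FormulaError("formula must contain at least one element")
        object.__setattr__(self, "composition", tuple(sorted(items)))
        object.__setattr__(self, "name", name)

    @classmethod
    def parse(cls, text: str, name: str = "") -> "ElementalFormula":
        """Parse Hill-like notation with decimal subscripts, e.g. ``C4H7O1.5N``."""
        pos = 0
        elements: dict[str, float] = {}
        for match in _TOKEN.finditer(text):
            if match.start() != pos:
                raise FormulaError(f"cannot parse formula {text!r} at {text[pos:]!r}")
            symbol, count = match.group(1), match.group(2)
            elements[symbol] = elements.get(symbol, 0.0) + (float(count) if count else 1.0)
            pos = match.end()
        if pos != len(text) or not elements:
            raise FormulaError(f"cannot parse formula {text!r}")
        return cls(elements, name=name or text)

    def count(self, element: str) -> float:
        return dict(self.composition).get(element, 0.0)

    def items(self) -> Iterator[tuple[str, float]]:
        return iter(self.composition)

    @property
    def elements(self) -> dict[str, float]:
        return dict(self.composition)

    def formula_string(self) -> str:
        """Canonical element/count string in alphabetical element order."""
        return "".join(
            f"{sym}{count:g}" if count != 1 else sym for sym, count in self.composition
        )

    def __str__(self) -> str:
        return self.name or self.formula_string()


def degree_of_reduction(
    formula: ElementalFormula,
    valences: Mapping[str, int] = DEFAULT_VALENCES,
) -> float:
    """Electron equivalents per mole released on complete oxidation.

    Computes ``sum(count(e) * valence(e))``.  May be zero (CO2, H2O, NH3) or
    negative (O2 as an acceptor).  Raises :class:`MissingValenceError` for
    elements outside the convention (e.g. S), which must instead be handled
    through an explicit :class:`RedoxCouple`.
    """
    total = 0.0
    for symbol, count in formula.items():
        if symbol not in valences:
            raise MissingValenceError(symbol)
        total += count * valences[symbol]
    return total


def carbon_per_mol(formula: ElementalFormula) -> float:
    """Moles of carbon per mole of compound; 0 for carbon-free species."""
    return formula.count("C")


def molar_mass(formula: ElementalFormula) -> float:
    """Standard atomic-mass sum in g/mol."""
    total = 0.0
    for symbol, count in formula.items():
        try:
            total += count * ATOMIC_MASSES[symbol]
        except KeyError:
            raise FormulaError(f"unknown element symbol {symbol!r}") from None
    return total


@dataclass(frozen=True)
class BiomassFormula:
    """Lumped cell biomass: organic formula plus an ash/mineral mass override.

    Carbon accounting uses the organic formula (4 C/mol by default); mass
    accounting uses ``molar_mass_with_minerals`` (104 g/mol by default).  The
    default composition oxidizes with 17 electron equivalents per mole.
    """

    formula: ElementalFormula = field(
        default_factory=lambda: ElementalFormula.parse("C4H7O1.5N", name="biomass")
    )
    molar_mass_with_minerals: float = 104.0
    electron_equivalents_per_mol: float = 17.0
    #: volts per electron equivalent; the source literature quotes both ~-0.3
    #: and ~-0.37, so this is configurable and not used in any balance.
    energy_per_equivalent: float = -0.3

    def __post_init__(self):
        if self.molar_mass_with_minerals < molar_mass(self.formula):
            raise ValueError(
                "molar_mass_with_minerals must be >= molar mass of the organic formula"
            )
        if self.electron_equivalents_per_mol <= 0:
            raise ValueError("electron_equivalents_per_mol must be positive")

    @property
    def carbon_per_mol(self) -> float:
        return carbon_per_mol(self.formula)

    def millimolar_from_mg_per_l(self, biomass_mg_per_l: float) -> float:
        """Convert a dry-weight concentration (mg/L) to mM of formula units."""
        return biomass_mg_per_l / self.molar_mass_with_minerals


@dataclass(frozen=True)
class RedoxCouple:
    """A terminal-acceptor couple: electrons accepted per mole of acceptor."""

    name: str
    electrons_accepted_per_mol: float

    def __post_init__(self):
        if self.electrons_accepted_per_mol <= 0:
            raise ValueError("electrons_accepted_per_mol must be positive")


SULFATE_TO_SULFIDE = RedoxCouple("sulfate->sulfide", 8.0)
FUMARATE_TO_SUCCINATE = RedoxCouple("fumarate->succinate", 2.0)


@dataclass(frozen=True)
class ReactionBalance:
    """Net per-element and electron-equivalent sums for a signed reaction."""

    element_imbalance: Mapping[str, float]
    electron_imbalance: float

    def is_balanced(self, tol: float = BALANCE_TOL, *, elements=("C",)) -> bool:
        """Balanced in the tracked elements and in electron equivalents.

        H and O imbalances are ignored by default because water and protons
        are treated as implicit, consistent with degree-of-reduction
        bookkeeping.
        """
        if abs(self.electron_imbalance) > tol:
            return False
        return all(abs(self.element_imbalance.get(e, 0.0)) <= tol for e in elements)

    @property
    def carbon_imbalance(self) -> float:
        return self.element_imbalance.get("C", 0.0)


def check_reaction_balance(
    stoichiometry: Mapping[ElementalFormula, float],
    valences: Mapping[str, int] = DEFAULT_VALENCES,
    *,
    electron_overrides: Mapping[ElementalFormula, float] | None = None,
) -> ReactionBalance:
    """Net element and electron sums of a reaction with signed coefficients.

    Reactants carry negative coefficients, products positive.  Electron
    equivalents default to the degree of reduction; ``electron_overrides``
    supplies per-mole values for species outside the valence convention
    (sulfate 0, sulfide 8, the unresolved donor pool 1 per equivalent).
    """
    if not any(c < 0 for c in stoichiometry.values()) or not any(
        c > 0 for c in stoichiometry.values()
    ):
        raise ValueError("reaction needs at least one reactant and one product")
    electron_overrides = electron_overrides or {}
    element_net: dict[str, float] = {}
    electron_net = 0.0
    for formula, coeff in stoichiometry.items():
        for symbol, count in formula.items():
            element_net[symbol] = element_net.get(symbol, 0.0) + coeff * count
        if formula in electron_overrides:
            electron_net += coeff * electron_overrides[formula]
        else:
            electron_net += coeff * degree_of_reduction(formula, valences)
    return ReactionBalance(element_imbalance=element_net, electron_imbalance=electron_net)
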