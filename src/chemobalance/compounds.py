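"""Compound registry for the consortium balance.

Each entry carries an elemental formula, a role in the trophic network, and —
where the degree-of-reduction convention does not apply (sulfur species, the
unresolved electron-donor pool) — an explicit electron-equivalent value per
mole.  Organic acids are registered in their acid form; concentrations are
handled in mM throughout.

The registry round-trips through a plain CSV table (name, formula, role,
charge_note) so alternative registries can be supplied from disk.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from .stoichiometry import (
    DEFAULT_VALENCES,
    ElementalFormula,
    degree_of_reduction,
)

__all__ = [
    "Compound",
    "REGISTRY",
    "get",
    "gamma",
    "carbon",
    "ELECTRON_POOL",
    "load_registry",
    "dump_registry",
]


@dataclass(frozen=True)
class Compound:
    name: str
    formula: ElementalFormula | None
    role: str = "metabolite"
    charge_note: str = ""
    #: electron equivalents per mole when the valence convention does not
    #: apply (acceptors, reduced acceptor products, lumped donor pools).
    electron_equivalents: float | None = None
    #: excluded from carbon/electron balances (buffers, inert gases).
    balance_exempt: bool = False

    def degree_of_reduction(self, valences: Mapping[str, int] = DEFAULT_VALENCES) -> float:
        if self.electron_equivalents is not None:
            return self.electron_equivalents
        if self.formula is None or self.balance_exempt:
            return 0.0
        return degree_of_reduction(self.formula, valences)

    @property
    def carbon_per_mol(self) -> float:
        if self.balance_exempt or self.formula is None:
            return 0.0
        return self.formula.count("C")


def _c(name, formula, role, *, note="", eeq=None, exempt=False) -> Compound:
    f = ElementalFormula.parse(formula, name=name) if formula else None
    return Compound(name, f, role, note, electron_equivalents=eeq, balance_exempt=exempt)


#: Lumped, unresolved electron-donor pool (hydrogen / interspecies electron
#: transfer / ethanol), measured directly in electron equivalents (1 e-/unit).
ELECTRON_POOL = "electron_pool"

REGISTRY: dict[str, Compound] = {
    c.name: c
    for c in [
        _c("cellobiose", "C12H22O11", "substrate"),
        _c("glucose", "C6H12O6", "metabolite"),
        _c("acetate", "C2H4O2", "product", note="acid form"),
        _c("ethanol", "C2H6O", "product"),
        _c("lactate", "C3H6O3", "product", note="acid form"),
        _c("formate", "CH2O2", "product", note="acid form"),
        _c("fumarate", "C4H4O4", "acceptor", note="acid form"),
        _c("succinate", "C4H6O4", "product", note="acid form"),
        _c("malate", "C4H6O5", "product", note="acid form"),
        _c("H2", "H2", "product"),
        _c("CO2", "CO2", "gas"),
        _c("H2O", "H2O", "solvent"),
        _c("NH3", "NH3", "nitrogen source"),
        # Sulfur species sit outside the valence convention: sulfate is a pure
        # terminal acceptor (0 e- as input), sulfide its reduced product at
        # 8 e-/mol.
        _c("sulfate", "SO4", "acceptor", note="as Na2SO4; counted S-free of charge", eeq=0.0),
        _c("sulfide", "H2S", "product", note="reduced acceptor", eeq=8.0),
        _c("NaHCO3", "NaHCO3", "buffer", note="carbonate buffer, excluded from balances", exempt=True),
        _c("N2", "N2", "gas", note="sparge gas", exempt=True),
        Compound(ELECTRON_POOL, None, "internal transfer",
                 "unresolved donor pool in e- equivalents", electron_equivalents=1.0),
    ]
}


def get(name: str) -> Compound:
    try:
        return REGISTRY[name]
    except KeyError:
        raise KeyError(f"unknown compound {name!r}; register it first") from None


def gamma(name: str) -> float:
    """Electron equivalents per mole for balance accounting."""
    comp = get(name)
    return 0.0 if comp.balance_exempt else comp.degree_of_reduction()


def carbon(name: str) -> float:
    """Moles carbon per mole for balance accounting."""
    return get(name).carbon_per_mol


def dump_registry(path: str | Path, registry: Mapping[str, Compound] = REGISTRY) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["name", "formula", "role", "charge_note", "electron_equivalents", "balance_exempt"])
        for comp in registry.values():
            writer.writerow([
                comp.name,
                "" if comp.formula is None else comp.formula.formula_string(),
                comp.role,
                comp.charge_note,
                "" if comp.electron_equivalents is None else comp.electron_equivalents,
                int(comp.balance_exempt),
            ])


def load_registry(path: str | Path) -> dict[str, Compound]:
    registry: dict[str, Compound] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            formula = row["formula"].strip()
            eeq = row.get("electron_equivalents", "").strip()
            registry[row["name"]] = Compound(
                name=row["name"],
                formula=ElementalFormula.parse(formula, name=row["name"]) if formula else None,
                role=row.get("role", "metabolite"),
                charge_note=row.get("charge_note", ""),
                electron_equivalents=float(eeq) if eeq else None,
                balance_exempt=bool(int(row.get("balance_exempt", "0") or 0)),
            )
    return registry
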