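"""Trophic flux allocation and carbon/electron balance for the three-species
anaerobic community (cellulolytic fermenter, sulfate reducer, fumarate
reducer).

Community-level consumption and production are normalized to moles per mole
of cellobiose consumed, partitioned across the three species according to
their catabolic roles, and summarized as carbon recovery, electron recovery,
biomass partition, and the digestible-energy fraction of end products.

Electron bookkeeping follows the degree-of-reduction convention; sulfate
enters at 0 e-/mol and its reduced product sulfide at 8 e-/mol.  The donor
pool feeding sulfate reduction (hydrogen, direct interspecies electron
transfer, or ethanol cannot be distinguished from supernatant measurements)
is carried as a single electron-equivalent quantity with a configurable
H2:ethanol split and flagged as unresolved.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import compounds
from .compounds import ELECTRON_POOL
from .chemostat import BiomassCalibration, ChemostatState, ReactorConfig, od_to_biomass
from .stoichiometry import BiomassFormula, RedoxCouple, SULFATE_TO_SULFIDE, FUMARATE_TO_SUCCINATE

__all__ = [
    "FERMENTER",
    "SULFATE_REDUCER",
    "FUMARATE_REDUCER",
    "SpeciesRole",
    "AllocationSplits",
    "FluxTable",
    "SpeciesBalance",
    "ReportRow",
    "BalanceReport",
    "default_roles",
    "allocate_fluxes",
    "carbon_recovery",
    "electron_recovery",
    "digestible_energy_fraction",
    "partition_biomass",
    "build_report",
    "DEFAULT_DIGESTIBLE",
]

FERMENTER = "C. cellulolyticum"
SULFATE_REDUCER = "D. vulgaris"
FUMARATE_REDUCER = "G. sulfurreducens"

#: Readily digestible end products whose electron equivalents remain available
#: to further trophic levels.  Biomass and sulfide are always excluded.
#: Malate is included by default as a readily metabolized acid but can be
#: dropped via the ``digestible`` argument.
DEFAULT_DIGESTIBLE: frozenset[str] = frozenset(
    {"acetate", "succinate", "ethanol", "H2", "malate", ELECTRON_POOL}
)

#: Succinate concentration associated with fermenter inhibition; carried as
#: metadata for the simulator, not enforced in the balance.
SUCCINATE_INHIBITION_MM = 10.0


@dataclass(frozen=True)
class SpeciesRole:
    """Catabolic role of one community member."""

    species: str
    donors: tuple[str, ...]
    acceptor: RedoxCouple | None
    products: tuple[str, ...]
    carbon_source: str
    produces_co2: bool = True


def default_roles() -> dict[str, SpeciesRole]:
    return {
        FERMENTER: SpeciesRole(
            FERMENTER,
            donors=("cellobiose",),
            acceptor=None,
            products=("acetate", "CO2", "H2", "ethanol", ELECTRON_POOL),
            carbon_source="cellobiose",
        ),
        SULFATE_REDUCER: SpeciesRole(
            SULFATE_REDUCER,
            donors=(ELECTRON_POOL,),
            acceptor=SULFATE_TO_SULFIDE,
            products=("sulfide",),
            carbon_source="acetate",
            # incomplete TCA cycle: no CO2 release in this role
            produces_co2=False,
        ),
        FUMARATE_REDUCER: SpeciesRole(
            FUMARATE_REDUCER,
            donors=("acetate",),
            acceptor=FUMARATE_TO_SUCCINATE,
            products=("succinate", "malate", "CO2"),
            carbon_source="acetate",
        ),
    }


@dataclass(frozen=True)
class AllocationSplits:
    """Parameters for splitting community fluxes between species.

    The acetate draws cover acetate equivalents removed from the supernatant
    by the secondary trophic level (donor use plus biomass carbon); the
    unresolved donor pool for sulfate reduction is split H2:ethanol by
    ``pool_h2_fraction`` (1:1 by default; the pure-culture ratio that would
    pin it down is not available).
    """

    acetate_to_fumarate_reducer: float = 0.45
    acetate_oxidized_by_fumarate_reducer: float = 0.30
    acetate_to_sulfate_reducer: float = 0.25
    pool_h2_fraction: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.pool_h2_fraction <= 1.0:
            raise ValueError("pool_h2_fraction must be in [0, 1]")
        if self.acetate_oxidized_by_fumarate_reducer > self.acetate_to_fumarate_reducer:
            raise ValueError("oxidized acetate cannot exceed total acetate drawn")


@dataclass(frozen=True)
class FluxTable:
    """Per-species fluxes in mol per mol cellobiose consumed (negative =
    consumed).  Internal transfers (acetate draws, the donor pool) appear with
    opposite signs in producer and consumer so community totals reduce to the
    measured net fluxes."""

    species_fluxes: Mapping[str, Mapping[str, float]]
    basis_mM: float
    pool_h2_fraction: float = 0.5
    flags: tuple[str, ...] = ()

    def __post_init__(self):
        if self.basis_mM <= 0:
            raise ValueError("basis (cellobiose consumed, mM) must be positive")
        for species, fluxes in self.species_fluxes.items():
            if species != FERMENTER and fluxes.get("cellobiose", 0.0) != 0.0:
                raise ValueError("cellobiose may only be consumed by the fermenter")

    def community(self) -> dict[str, float]:
        totals: dict[str, float] = {}
        for fluxes in self.species_fluxes.values():
            for compound, value in fluxes.items():
                totals[compound] = totals.get(compound, 0.0) + value
        return totals

    def species(self, name: str) -> dict[str, float]:
        return dict(self.species_fluxes[name])

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.species_fluxes).fillna(0.0)
        frame["community"] = frame.sum(axis=1)
        frame.index.name = "compound"
        return frame


def allocate_fluxes(
    state: ChemostatState,
    config: ReactorConfig,
    roles: Mapping[str, SpeciesRole] | None = None,
    splits: AllocationSplits = AllocationSplits(),
) -> FluxTable:
    """Allocate steady-state community fluxes to species roles.

    Net per-compound fluxes are (residual - feed) / cellobiose consumed.
    Cellobiose and fermentation products go to the fermenter, sulfate/sulfide
    and the unresolved donor pool to the sulfate reducer, and the
    fumarate/succinate/malate pool plus its acetate draw to the fumarate
    reducer.  A warning (not an error) is raised when acceptor flux exceeds
    the apparent donor capacity, which the measured steady state does.
    """
    roles = roles or default_roles()
    feed = dict(config.feed_mM)
    residual = dict(state.residual_mM)
    basis = feed.get("cellobiose", 0.0) - residual.get("cellobiose", 0.0)
    if basis <= 0:
        raise ValueError("cellobiose consumption must be positive")

    names = set(feed) | set(residual)
    per_mol: dict[str, float] = {}
    for name in names:
        if compounds.get(name).balance_exempt:
            continue
        per_mol[name] = (residual.get(name, 0.0) - feed.get(name, 0.0)) / basis

    sulfate_reduced = -per_mol.get("sulfate", 0.0)
    sulfide_made = per_mol.get("sulfide", sulfate_reduced if sulfate_reduced > 0 else 0.0)
    pool_eeq = sulfate_reduced * SULFATE_TO_SULFIDE.electrons_accepted_per_mol

    geo_co2 = 2.0 * splits.acetate_oxidized_by_fumarate_reducer  # C2 -> 2 C1
    net_co2 = per_mol.get("CO2", 0.0)

    fermenter: dict[str, float] = {"cellobiose": per_mol["cellobiose"]}
    fermenter["acetate"] = (
        per_mol.get("acetate", 0.0)
        + splits.acetate_to_fumarate_reducer
        + splits.acetate_to_sulfate_reducer
    )
    if net_co2:
        fermenter["CO2"] = net_co2 - geo_co2
    if pool_eeq > 0:
        fermenter[ELECTRON_POOL] = pool_eeq

    sulfate_reducer: dict[str, float] = {}
    if sulfate_reduced > 0:
        sulfate_reducer["sulfate"] = -sulfate_reduced
        sulfate_reducer["sulfide"] = sulfide_made
        sulfate_reducer[ELECTRON_POOL] = -pool_eeq
        sulfate_reducer["acetate"] = -splits.acetate_to_sulfate_reducer

    fumarate_reducer: dict[str, float] = {
        "fumarate": per_mol.get("fumarate", 0.0),
        "succinate": per_mol.get("succinate", 0.0),
        "malate": per_mol.get("malate", 0.0),
        "acetate": -splits.acetate_to_fumarate_reducer,
        "CO2": geo_co2,
    }

    # Remaining measured compounds (ethanol, H2, lactate, ...) fall to the
    # primary fermenter.
    assigned = {"cellobiose", "acetate", "CO2", "sulfate", "sulfide", "fumarate",
                "succinate", "malate"}
    for name, value in per_mol.items():
        if name not in assigned and value != 0.0:
            fermenter[name] = fermenter.get(name, 0.0) + value

    flags: list[str] = []
    if pool_eeq > 0:
        flags.append("unresolved_electron_pool")
        # donor capacity check: electrons left after measured fermenter products
        surplus = -sum(
            v * compounds.gamma(c)
            for c, v in fermenter.items()
            if c != ELECTRON_POOL
        )
        if pool_eeq > surplus + 1e-9:
            flags.append("acceptor_flux_exceeds_donor_capacity")
            warnings.warn(
                "acceptor flux requires more electron equivalents than the "
                "fermenter's apparent donor surplus; electron recovery will "
                "exceed 100%",
                stacklevel=2,
            )

    return FluxTable(
        species_fluxes={
            FERMENTER: fermenter,
            SULFATE_REDUCER: sulfate_reducer,
            FUMARATE_REDUCER: fumarate_reducer,
        },
        basis_mM=basis,
        pool_h2_fraction=splits.pool_h2_fraction,
        flags=tuple(flags),
    )


def _biomass_mm(biomass: BiomassFormula, biomass_mg_per_l: float) -> float:
    return biomass.millimolar_from_mg_per_l(biomass_mg_per_l)


def carbon_recovery(
    fluxes: FluxTable,
    biomass: BiomassFormula = BiomassFormula(),
    biomass_mg_per_l: float = 0.0,
) -> float:
    """Percent of input carbon recovered in products plus biomass.

    Biomass carbon is counted on the organic formula (4 C/mol) at the
    mineral-inclusive molar mass (104 g/mol).
    """
    comm = fluxes.community()
    basis = fluxes.basis_mM
    carbon_in = sum(-v * compounds.carbon(c) for c, v in comm.items() if v < 0) * basis
    carbon_out = sum(v * compounds.carbon(c) for c, v in comm.items() if v > 0) * basis
    carbon_out += _biomass_mm(biomass, biomass_mg_per_l) * biomass.carbon_per_mol
    if carbon_in <= 0:
        raise ValueError("no carbon inputs in flux table")
    return 100.0 * carbon_out / carbon_in


def electron_recovery(
    fluxes: FluxTable,
    biomass: BiomassFormula = BiomassFormula(),
    biomass_mg_per_l: float = 0.0,
) -> float:
    """Percent of input electron equivalents recovered in products + biomass.

    Organics enter at their degree of reduction, sulfide at 8 e-/mol (reduced
    acceptor), sulfate at 0, biomass at 17 e-/mol.  Values above 100% are
    reported as computed; they indicate unaccounted donor pools.
    """
    comm = fluxes.community()
    basis = fluxes.basis_mM
    eeq_in = sum(-v * compounds.gamma(c) for c, v in comm.items() if v < 0) * basis
    eeq_out = sum(v * compounds.gamma(c) for c, v in comm.items() if v > 0) * basis
    eeq_out += _biomass_mm(biomass, biomass_mg_per_l) * biomass.electron_equivalents_per_mol
    if eeq_in <= 0:
        raise ValueError("no electron inputs in flux table")
    return 100.0 * eeq_out / eeq_in


def digestible_energy_fraction(
    fluxes: FluxTable,
    digestible: frozenset[str] | set[str] = DEFAULT_DIGESTIBLE,
    weights: Mapping[str, float] | None = None,
) -> float:
    """Percent of input electron equivalents remaining in digestible products.

    ``weights`` optionally scales each compound's equivalents by a per-couple
    energy weight (volts); with unit weights this is the pure
    electron-equivalent fraction.  Biomass and sulfide are never counted in
    the numerator.
    """
    weights = weights or {}
    comm = fluxes.community()

    def w(name: str) -> float:
        return weights.get(name, 1.0)

    denom = sum(-v * compounds.gamma(c) * w(c) for c, v in comm.items() if v < 0)
    if denom <= 0:
        raise ValueError("no weighted electron inputs in flux table")
    numer = sum(
        v * compounds.gamma(c) * w(c)
        for c, v in comm.items()
        if v > 0 and c in digestible and c != "sulfide"
    )
    return 100.0 * numer / denom


def partition_biomass(
    biomass_mg_per_l: float,
    cells_per_ml: Mapping[str, float],
    cell_mass_weights: Mapping[str, float] | None = None,
) -> dict[str, float]:
    """Allocate community biomass across species proportionally to cell counts
    (optionally weighted by relative per-cell mass); sums to the input."""
    if not cells_per_ml or all(v == 0 for v in cells_per_ml.values()):
        raise ValueError("need at least one species with a positive cell count")
    if any(v < 0 for v in cells_per_ml.values()):
        raise ValueError("cell counts must be non-negative")
    weights = cell_mass_weights or {}
    weighted = {sp: v * weights.get(sp, 1.0) for sp, v in cells_per_ml.items()}
    total = sum(weighted.values())
    return {sp: biomass_mg_per_l * v / total for sp, v in weighted.items()}


@dataclass(frozen=True)
class SpeciesBalance:
    """Raw numerators/denominators of one species' (or the community's)
    carbon and electron balance, in mM and meq per liter."""

    carbon_in: float
    carbon_out: float
    electron_in: float
    electron_out: float
    digestible_out: float

    @property
    def carbon_recovery_pct(self) -> float:
        return 100.0 * self.carbon_out / self.carbon_in if self.carbon_in else float("nan")

    @property
    def electron_recovery_pct(self) -> float:
        return 100.0 * self.electron_out / self.electron_in if self.electron_in else float("nan")

    @property
    def digestible_energy_pct(self) -> float:
        return 100.0 * self.digestible_out / self.electron_in if self.electron_in else float("nan")


def _species_balance(
    fluxes: Mapping[str, float],
    basis: float,
    biomass: BiomassFormula,
    biomass_mg_per_l: float,
    digestible: frozenset[str] | set[str],
    weights: Mapping[str, float] | None = None,
) -> SpeciesBalance:
    weights = weights or {}

    def w(name: str) -> float:
        return weights.get(name, 1.0)

    carbon_in = sum(-v * compounds.carbon(c) for c, v in fluxes.items() if v < 0) * basis
    carbon_out = sum(v * compounds.carbon(c) for c, v in fluxes.items() if v > 0) * basis
    eeq_in = sum(-v * compounds.gamma(c) * w(c) for c, v in fluxes.items() if v < 0) * basis
    eeq_out = sum(v * compounds.gamma(c) * w(c) for c, v in fluxes.items() if v > 0) * basis
    digest = (
        sum(
            v * compounds.gamma(c) * w(c)
            for c, v in fluxes.items()
            if v > 0 and c in digestible and c != "sulfide"
        )
        * basis
    )
    bm = _biomass_mm(biomass, biomass_mg_per_l)
    carbon_out += bm * biomass.carbon_per_mol
    eeq_out += bm * biomass.electron_equivalents_per_mol
    return SpeciesBalance(carbon_in, carbon_out, eeq_in, eeq_out, digest)


@dataclass(frozen=True)
class ReportRow:
    cell_count_1e8_per_ml: float
    biomass_mg_per_l: float
    carbon_recovery_pct: float
    electron_recovery_pct: float
    digestible_energy_pct: float


@dataclass(frozen=True)
class BalanceReport:
    """Community and per-species balance summary (the machine-readable twin of
    a five-column recovery table)."""

    community: ReportRow
    species: Mapping[str, ReportRow]
    basis_mM: float
    flags: tuple[str, ...] = ()
    balances: Mapping[str, SpeciesBalance] = field(default_factory=dict)

    def __post_init__(self):
        total = sum(r.biomass_mg_per_l for r in self.species.values())
        if abs(total - self.community.biomass_mg_per_l) > 1e-6 * max(1.0, total):
            raise ValueError("species biomass does not sum to community biomass")

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        rows = {"three species community": self.community, **self.species}
        frame = pd.DataFrame(
            {
                "cell_counts_1e8_per_ml": {k: r.cell_count_1e8_per_ml for k, r in rows.items()},
                "biomass_mg_per_L": {k: r.biomass_mg_per_l for k, r in rows.items()},
                "C_recovered_pct": {k: r.carbon_recovery_pct for k, r in rows.items()},
                "e_recovered_pct": {k: r.electron_recovery_pct for k, r in rows.items()},
                "digestible_energy_pct": {k: r.digestible_energy_pct for k, r in rows.items()},
            }
        )
        frame.index.name = "population"
        if rounded:
            frame = frame.round(
                {
                    "cell_counts_1e8_per_ml": 2,
                    "biomass_mg_per_L": 0,
                    "C_recovered_pct": 0,
                    "e_recovered_pct": 0,
                    "digestible_energy_pct": 0,
                }
            )
        return frame

    def to_csv(self, path: str | Path, rounded: bool = True) -> None:
        self.to_frame(rounded=rounded).to_csv(path)

    @staticmethod
    def read_csv(path: str | Path) -> pd.DataFrame:
        return pd.read_csv(path, index_col="population")


def build_report(
    state: ChemostatState,
    config: ReactorConfig,
    cells_per_ml: Mapping[str, float],
    *,
    roles: Mapping[str, SpeciesRole] | None = None,
    splits: AllocationSplits = AllocationSplits(),
    biomass: BiomassFormula = BiomassFormula(),
    calibration: BiomassCalibration = BiomassCalibration(),
    digestible: frozenset[str] | set[str] = DEFAULT_DIGESTIBLE,
    energy_weights: Mapping[str, float] | None = None,
    cell_mass_weights: Mapping[str, float] | None = None,
    biomass_mg_per_l: float | None = None,
) -> BalanceReport:
    """Full balance report: flux allocation, biomass partition and recoveries.

    ``biomass_mg_per_l`` defaults to OD600 x calibration.  Per-species rows
    use each species' own flux column plus its biomass share; internal
    transfers (acetate draws, donor pool) therefore appear as genuine inputs
    for the secondary species.
    """
    if biomass_mg_per_l is None:
        biomass_mg_per_l = od_to_biomass(state.od600, calibration)
    fluxes = allocate_fluxes(state, config, roles=roles, splits=splits)
    shares = partition_biomass(biomass_mg_per_l, cells_per_ml, cell_mass_weights)

    balances: dict[str, SpeciesBalance] = {}
    species_rows: dict[str, ReportRow] = {}
    for species, flux in fluxes.species_fluxes.items():
        bal = _species_balance(
            flux, fluxes.basis_mM, biomass, shares.get(species, 0.0), digestible, energy_weights
        )
        balances[species] = bal
        species_rows[species] = ReportRow(
            cell_count_1e8_per_ml=cells_per_ml.get(species, 0.0) / 1e8,
            biomass_mg_per_l=shares.get(species, 0.0),
            carbon_recovery_pct=bal.carbon_recovery_pct,
            electron_recovery_pct=bal.electron_recovery_pct,
            digestible_energy_pct=bal.digestible_energy_pct,
        )

    community = ReportRow(
        cell_count_1e8_per_ml=sum(cells_per_ml.values()) / 1e8,
        biomass_mg_per_l=biomass_mg_per_l,
        carbon_recovery_pct=carbon_recovery(fluxes, biomass, biomass_mg_per_l),
        electron_recovery_pct=electron_recovery(fluxes, biomass, biomass_mg_per_l),
        digestible_energy_pct=digestible_energy_fraction(fluxes, digestible, energy_weights),
    )
    return BalanceReport(
        community=community,
        species=species_rows,
        basis_mM=fluxes.basis_mM,
        flags=fluxes.flags,
        balances=balances,
    )
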