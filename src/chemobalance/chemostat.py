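"""Continuous-culture operating math.

Dilution rate, OD <-> dry-weight biomass <-> cell-count conversions,
steady-state consumption/production fluxes, and dissolved-gas bookkeeping
(Henry's law, with carbonate speciation for CO2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

__all__ = [
    "ReactorConfig",
    "ChemostatState",
    "BiomassCalibration",
    "GasSolubility",
    "dilution_rate",
    "od_to_biomass",
    "biomass_to_cell_density",
    "steady_state_flux",
    "dissolved_gas",
    "HENRY_CONSTANTS_30C",
    "DETECTION_LIMITS_MM",
]

DEFAULT_FEED_MM: Mapping[str, float] = {
    "cellobiose": 2.2,
    "fumarate": 4.9,
    "sulfate": 8.0,
    "NaHCO3": 5.0,
}

#: Henry solubility constants at 30 degC, mol L-1 atm-1 (standard-table values;
#: override via the ``constants`` argument of :func:`dissolved_gas`).
HENRY_CONSTANTS_30C: Mapping[str, float] = {
    "H2": 7.2e-4,
    "CO2": 2.96e-2,
    "H2S": 8.7e-2,
    "N2": 5.6e-4,
    "CH4": 1.2e-3,
}

#: van't Hoff temperature-dependence parameters d(ln kH)/d(1/T) in K.
_VANT_HOFF_K: Mapping[str, float] = {
    "H2": 500.0,
    "CO2": 2400.0,
    "H2S": 2100.0,
    "N2": 1300.0,
    "CH4": 1700.0,
}

#: Left-censoring limits for dissolved analytes (mM).
DETECTION_LIMITS_MM: Mapping[str, float] = {"H2": 3e-4}  # 0.3 uM

CARBONATE_PKA1_30C = 6.35


@dataclass(frozen=True)
class ReactorConfig:
    """Reactor geometry, flows and feed composition.

    The default working volume is the operating value (650 ml); the balance
    calculations in the companion model historically used 640 ml, available as
    ``ReactorConfig(working_volume_ml=640)``.
    """

    working_volume_ml: float = 650.0
    feed_flow_ml_per_min: float = 0.34
    headspace_gas_flow_ml_per_min: float = 49.0
    temperature_c: float = 30.0
    feed_mM: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_FEED_MM))

    def __post_init__(self):
        for name, value in [
            ("working_volume_ml", self.working_volume_ml),
            ("headspace_gas_flow_ml_per_min", self.headspace_gas_flow_ml_per_min),
            ("temperature_c", self.temperature_c),
        ]:
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.feed_flow_ml_per_min < 0:
            raise ValueError("feed_flow_ml_per_min must be non-negative")
        if any(v < 0 for v in self.feed_mM.values()):
            raise ValueError("feed concentrations must be non-negative")
        if dilution_rate(self) >= 1.0:
            raise ValueError("dilution rate >= 1 h^-1 fails the sanity bound")


@dataclass(frozen=True)
class ChemostatState:
    """Residual (vessel) concentrations and readings at one time point."""

    residual_mM: Mapping[str, float]
    od600: float = 0.0
    gas_headspace: Mapping[str, float] = field(default_factory=dict)
    pH: float = 7.1

    def __post_init__(self):
        if any(v < 0 for v in self.residual_mM.values()):
            raise ValueError("residual concentrations must be non-negative")
        if self.od600 < 0:
            raise ValueError("od600 must be non-negative")
        if not 6.5 <= self.pH <= 8.0:
            warnings.warn(
                f"pH {self.pH} outside the stable 6.5-8.0 band", stacklevel=2
            )


@dataclass(frozen=True)
class BiomassCalibration:
    """OD600 <-> dry weight <-> cell density calibration (fermenter-based)."""

    mg_dw_per_liter_per_od: float = 590.0
    cells_per_ml_at_reference: float = 1.3e9  # at OD600 = 1.0

    def __post_init__(self):
        if self.mg_dw_per_liter_per_od <= 0 or self.cells_per_ml_at_reference <= 0:
            raise ValueError("calibration constants must be positive")

    @property
    def mg_dw_per_cell(self) -> float:
        # mg dw per cell implied by the two reference readings (per liter).
        return self.mg_dw_per_liter_per_od / (self.cells_per_ml_at_reference * 1e3)


def dilution_rate(config: ReactorConfig) -> float:
    """Dilution rate D in h^-1 = feed flow (ml/min) * 60 / working volume (ml)."""
    if config.working_volume_ml <= 0:
        raise ValueError("working volume must be positive")
    return config.feed_flow_ml_per_min * 60.0 / config.working_volume_ml


def od_to_biomass(od600: float, calibration: BiomassCalibration = BiomassCalibration()) -> float:
    """Dry-weight biomass (mg/L) from OD600, assuming linearity."""
    if od600 < 0:
        raise ValueError("OD600 must be non-negative")
    return od600 * calibration.mg_dw_per_liter_per_od


def biomass_to_cell_density(
    biomass_mg_per_l: float, calibration: BiomassCalibration = BiomassCalibration()
) -> float:
    """Cell density (cells/ml) from dry-weight biomass by pure proportionality."""
    if biomass_mg_per_l < 0:
        raise ValueError("biomass must be non-negative")
    return biomass_mg_per_l * calibration.cells_per_ml_at_reference / calibration.mg_dw_per_liter_per_od


def steady_state_flux(
    config: ReactorConfig,
    state: ChemostatState,
    compound: str,
    *,
    consumption_positive: bool = False,
) -> float:
    """Volumetric steady-state flux of ``compound`` in mmol L-1 h-1.

    At steady state the net biological rate equals D * (residual - feed):
    negative for consumed compounds, positive for produced ones.  Set
    ``consumption_positive`` to flip the sign convention.
    """
    feed = config.feed_mM.get(compound, 0.0)
    residual = state.residual_mM.get(compound, 0.0)
    if compound not in config.feed_mM and compound not in state.residual_mM:
        raise KeyError(f"compound {compound!r} in neither feed nor residual table")
    flux = dilution_rate(config) * (residual - feed)
    return -flux if consumption_positive else flux


class GasSolubility(NamedTuple):
    """Dissolved concentration with left-censoring information."""

    millimolar: float
    censored: bool
    detection_limit_mM: float | None


def dissolved_gas(
    partial_pressure_atm: float,
    gas: str,
    temperature_c: float = 30.0,
    *,
    pH: float = 7.1,
    pka1: float = CARBONATE_PKA1_30C,
    constants: Mapping[str, float] | None = None,
    detection_limits: Mapping[str, float] = DETECTION_LIMITS_MM,
) -> GasSolubility:
    """Dissolved concentration (mM) of a gas at the given partial pressure.

    Plain Henry's law for most gases; for CO2 the chemically reactive total is
    returned, CO2(aq) * (1 + 10**(pH - pKa1)), covering the bicarbonate pool
    (carbonate is negligible below pH 8).  Concentrations below a configured
    detection limit are flagged as left-censored.
    """
    if partial_pressure_atm < 0:
        raise ValueError("partial pressure must be non-negative")
    table = dict(HENRY_CONSTANTS_30C)
    if constants:
        table.update(constants)
    if gas not in table:
        raise KeyError(f"no Henry constant for gas {gas!r}")
    kh = table[gas]
    if constants is None or gas not in constants:
        # constants table is referenced to 30 degC (303.15 K)
        dlnk = _VANT_HOFF_K.get(gas, 0.0)
        t_k = temperature_c + 273.15
        kh = kh * math.exp(dlnk * (1.0 / t_k - 1.0 / 303.15))
    aqueous_mM = kh * partial_pressure_atm * 1e3
    if gas == "CO2":
        aqueous_mM *= 1.0 + 10.0 ** (pH - pka1)
    limit = detection_limits.get(gas)
    censored = limit is not None and aqueous_mM < limit
    return GasSolubility(aqueous_mM, censored, limit)
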