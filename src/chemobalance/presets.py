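"""Reference operating point of the three-species chemostat.

These are the measured steady-state values used as the default worked example
throughout the package: feed 2.2 mM cellobiose / 4.9 mM fumarate / 8 mM
sulfate; residual acetate 5.93 mM; fumarate fully removed with 1.63 mol
succinate and 0.02 mol malate per mole cellobiose; 6.1 mM sulfate reduced to
sulfide; 3.3 mol CO2 produced per mole cellobiose; OD600 0.4.
"""

from __future__ import annotations

from typing import Mapping

from .chemostat import BiomassCalibration, ChemostatState, ReactorConfig
from .trophic import FERMENTER, FUMARATE_REDUCER, SULFATE_REDUCER

__all__ = [
    "reference_config",
    "reference_state",
    "reference_cell_counts",
    "REFERENCE_OD600",
    "REFERENCE_SULFATE_REDUCED_MM",
]

REFERENCE_OD600 = 0.4
REFERENCE_SULFATE_REDUCED_MM = 6.1

#: per-mole-cellobiose product stoichiometry observed at steady state
_PER_MOL = {"succinate": 1.63, "malate": 0.02, "CO2": 3.3}


def reference_config(working_volume_ml: float = 650.0) -> ReactorConfig:
    """Operating configuration (650 ml working volume, 0.34 ml/min feed)."""
    return ReactorConfig(working_volume_ml=working_volume_ml)


def reference_state(config: ReactorConfig | None = None) -> ChemostatState:
    """Measured steady-state residual concentrations."""
    config = config or reference_config()
    basis = config.feed_mM["cellobiose"]
    residual = {
        "cellobiose": 0.0,
        "acetate": 5.93,
        "fumarate": 0.0,
        "sulfate": config.feed_mM["sulfate"] - REFERENCE_SULFATE_REDUCED_MM,
        "sulfide": REFERENCE_SULFATE_REDUCED_MM,
        "succinate": _PER_MOL["succinate"] * basis,
        "malate": _PER_MOL["malate"] * basis,
        "CO2": _PER_MOL["CO2"] * basis,
    }
    return ChemostatState(residual_mM=residual, od600=REFERENCE_OD600, pH=7.1)


def reference_cell_counts() -> dict[str, float]:
    """qPCR-derived steady-state cell densities (cells/ml)."""
    return {FERMENTER: 4.6e8, SULFATE_REDUCER: 0.29e8, FUMARATE_REDUCER: 0.36e8}


def reference_biomass_mg_per_l(
    calibration: BiomassCalibration = BiomassCalibration(),
) -> float:
    return REFERENCE_OD600 * calibration.mg_dw_per_liter_per_od
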