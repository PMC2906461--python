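"""Synthetic chemostat data generator.

Simulates the three-species continuous culture as a deterministic ODE system
(Monod growth on limiting substrates, product inhibition, gas stripping) whose
per-species stoichiometries are exactly carbon- and electron-balanced — the
simulator refuses to run otherwise.  A separate observation layer adds seeded
measurement noise, detection-limit censoring, and converts biomass to qPCR
plate exports through a synthetic standard curve, so the full analysis
pipeline can be exercised without external data.

All dynamics beyond the steady state are illustrative: the kinetic constants
are calibrated so the default community settles near the reference operating
point (cellobiose exhausted, fumarate fully removed, residual sulfate left
over), not measured quantities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import compounds
from .chemostat import BiomassCalibration, ChemostatState, ReactorConfig, dilution_rate
from .qpcr import DEFAULT_ASSAYS, ExtractionProtocol, SpeciesAssay, StandardCurve
from .stoichiometry import BiomassFormula, check_reaction_balance
from .trophic import FERMENTER, FUMARATE_REDUCER, SULFATE_REDUCER

__all__ = [
    "SimSpecies",
    "NoiseModel",
    "Scenario",
    "UpsetEvent",
    "SimulationResult",
    "Observations",
    "default_community",
    "default_scenario",
    "simulate_chemostat",
    "simulate_scenario",
    "observe",
    "make_upset_scenario",
    "estimate_yields",
]

#: compounds integrated by the simulator, in state-vector order
SIM_COMPOUNDS: tuple[str, ...] = (
    "cellobiose", "acetate", "fumarate", "succinate", "sulfate", "sulfide", "H2", "CO2",
)

#: first-order gas-stripping rates at the default headspace flow, h^-1
DEFAULT_STRIPPING_PER_H: Mapping[str, float] = {"H2": 5.0, "CO2": 2.0, "sulfide": 0.5}

BALANCE_CHECK_TOL = 1e-6


@dataclass(frozen=True)
class SimSpecies:
    """One simulated population: Monod kinetics plus a balanced lumped
    growth reaction expressed per mole of biomass formed."""

    name: str
    mu_max_per_h: float
    ks_mM: Mapping[str, float]
    #: compound -> mol per mol biomass produced; negative = consumed.
    stoichiometry: Mapping[str, float]
    biomass: BiomassFormula = field(default_factory=BiomassFormula)
    #: compound -> (threshold_mM, hill exponent); growth x 1/(1+(S/K)^h)
    inhibition: Mapping[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self):
        if self.mu_max_per_h <= 0:
            raise ValueError("mu_max_per_h must be positive")
        for substrate in self.ks_mM:
            if self.stoichiometry.get(substrate, 0.0) >= 0:
                raise ValueError(f"{self.name}: Monod substrate {substrate!r} not consumed")

    def reaction_balance(self):
        """Carbon/electron balance of the lumped growth reaction."""
        stoich = {}
        overrides = {}
        for name, coeff in self.stoichiometry.items():
            comp = compounds.get(name)
            stoich[comp.formula] = stoich.get(comp.formula, 0.0) + coeff
            if comp.electron_equivalents is not None:
                overrides[comp.formula] = comp.electron_equivalents
        stoich[self.biomass.formula] = stoich.get(self.biomass.formula, 0.0) + 1.0
        overrides[self.biomass.formula] = self.biomass.electron_equivalents_per_mol
        return check_reaction_balance(stoich, electron_overrides=overrides)

    def validate(self) -> None:
        balance = self.reaction_balance()
        if not balance.is_balanced(BALANCE_CHECK_TOL):
            raise ValueError(
                f"{self.name}: growth reaction unbalanced "
                f"(C {balance.carbon_imbalance:+.3g}, "
                f"e- {balance.electron_imbalance:+.3g})"
            )

    def growth_rate(self, conc: Mapping[str, float]) -> float:
        mu = self.mu_max_per_h
        for substrate, ks in self.ks_mM.items():
            s = max(conc.get(substrate, 0.0), 0.0)
            mu *= s / (ks + s)
        for inhibitor, (threshold, hill) in self.inhibition.items():
            s = max(conc.get(inhibitor, 0.0), 0.0)
            mu /= 1.0 + (s / threshold) ** hill
        return mu


def _fermenter_stoich(acetate_per_cellobiose=1.8, biomass_per_cellobiose=0.88):
    """Balanced fermentation stoichiometry, normalized per mole biomass.

    CO2 and H2 close the carbon and electron balances for the chosen acetate
    and biomass yields.
    """
    p_ac, p_x = acetate_per_cellobiose, biomass_per_cellobiose
    p_co2 = 12.0 - 2.0 * p_ac - 4.0 * p_x
    p_h2 = (48.0 - 8.0 * p_ac - 17.0 * p_x) / 2.0
    if min(p_co2, p_h2) < 0:
        raise ValueError("infeasible fermentation yields")
    return {
        "cellobiose": -1.0 / p_x,
        "acetate": p_ac / p_x,
        "CO2": p_co2 / p_x,
        "H2": p_h2 / p_x,
    }


def _sulfate_reducer_stoich(sulfate_per_biomass=25.0):
    """Hydrogenotrophic sulfate reduction with acetate as carbon source."""
    s = sulfate_per_biomass
    return {
        "acetate": -2.0,
        "H2": -(1.0 + 8.0 * s) / 2.0,
        "sulfate": -s,
        "sulfide": s,
    }


def _fumarate_reducer_stoich(fumarate_per_biomass=30.0):
    """Acetate oxidation coupled to fumarate reduction."""
    f = fumarate_per_biomass
    a = (17.0 + 2.0 * f) / 8.0
    return {
        "acetate": -a,
        "fumarate": -f,
        "CO2": 2.0 * a - 4.0,
        "succinate": f,
    }


def default_community() -> tuple[SimSpecies, ...]:
    """Three-species preset calibrated to the reference operating point."""
    return (
        SimSpecies(
            FERMENTER,
            mu_max_per_h=0.25,
            ks_mM={"cellobiose": 0.05},
            stoichiometry=_fermenter_stoich(),
            inhibition={"succinate": (10.0, 6.0)},
        ),
        SimSpecies(
            SULFATE_REDUCER,
            mu_max_per_h=0.14,
            ks_mM={"H2": 0.001, "acetate": 0.02, "sulfate": 0.2},
            stoichiometry=_sulfate_reducer_stoich(),
        ),
        SimSpecies(
            FUMARATE_REDUCER,
            mu_max_per_h=0.20,
            ks_mM={"acetate": 0.02, "fumarate": 0.05},
            stoichiometry=_fumarate_reducer_stoich(),
        ),
    )


@dataclass(frozen=True)
class UpsetEvent:
    """A timed perturbation of the running culture."""

    kind: str  # "sporulation" | "high-fumarate"
    start_day: float
    end_day: float = math.inf
    fumarate_feed_mM: float = 8.0

    def active(self, t_h: float) -> bool:
        return self.start_day * 24.0 <= t_h < self.end_day * 24.0


@dataclass(frozen=True)
class Scenario:
    config: ReactorConfig
    species: tuple[SimSpecies, ...]
    inoculum_mg_per_l: Mapping[str, float]
    duration_days: float = 40.0
    events: tuple[UpsetEvent, ...] = ()


def default_scenario(
    config: ReactorConfig | None = None, duration_days: float = 40.0
) -> Scenario:
    return Scenario(
        config=config or ReactorConfig(),
        species=default_community(),
        inoculum_mg_per_l={FERMENTER: 20.0, SULFATE_REDUCER: 2.0, FUMARATE_REDUCER: 2.0},
        duration_days=duration_days,
    )


def make_upset_scenario(base: Scenario, trigger: str, *, start_day: float = 10.0,
                        duration_days: float = 3.0, fumarate_feed_mM: float = 8.0) -> Scenario:
    """Derive an upset scenario: ``sporulation`` silences the fermenter for a
    window; ``high-fumarate`` raises the fumarate feed (and with it succinate,
    engaging the fermenter's succinate inhibition)."""
    if trigger == "sporulation":
        event = UpsetEvent("sporulation", start_day, start_day + duration_days)
    elif trigger == "high-fumarate":
        event = UpsetEvent("high-fumarate", start_day, fumarate_feed_mM=fumarate_feed_mM)
    else:
        raise ValueError(f"unknown upset trigger {trigger!r}")
    return replace(base, events=base.events + (event,))


@dataclass(frozen=True)
class SimulationResult:
    """Deterministic trajectory plus conservation trackers."""

    frame: pd.DataFrame
    config: ReactorConfig
    species: tuple[SimSpecies, ...]
    calibration: BiomassCalibration
    stripping_per_h: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_STRIPPING_PER_H)
    )

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    def steady_state(self) -> pd.Series:
        return self.frame.iloc[-1]

    def to_state(self, extra_residual: Mapping[str, float] | None = None) -> ChemostatState:
        """Final row as a :class:`ChemostatState`.

        Volatile products mostly leave through the headspace rather than the
        liquid outflow; their entries are reported as the liquid-equivalent
        total production concentration S * (1 + k_strip/D), the quantity a
        combined liquid + off-gas measurement sees.
        """
        last = self.steady_state()
        d = dilution_rate(self.config)
        residual = {}
        for c in SIM_COMPOUNDS:
            value = max(float(last[c]), 0.0)
            strip = self.stripping_per_h.get(c, 0.0)
            if strip > 0:
                value *= 1.0 + strip / d
            residual[c] = value
        if extra_residual:
            residual.update(extra_residual)
        return ChemostatState(residual_mM=residual, od600=float(last["od600"]))

    def biomass_mg_per_l(self) -> dict[str, float]:
        last = self.steady_state()
        return {name: float(last[f"biomass_{name}"]) for name in self.species_names}

    def balance(self) -> pd.DataFrame:
        """Carbon/electron recovery (%) of the whole system along the
        trajectory: (medium + biomass + cumulative outflow + stripped gas)
        relative to (inoculum + initial medium + cumulative feed)."""
        frame = self.frame
        d = dilution_rate(self.config)
        t = frame["time_h"].to_numpy()
        carbon_now = np.zeros(len(frame))
        electron_now = np.zeros(len(frame))
        carbon_in = np.zeros(len(frame))
        electron_in = np.zeros(len(frame))
        for name in SIM_COMPOUNDS:
            c, g = compounds.carbon(name), compounds.gamma(name)
            held = (
                frame[name].to_numpy()
                + frame[f"outcum_{name}"].to_numpy()
                + frame.get(f"gascum_{name}", pd.Series(np.zeros(len(frame)))).to_numpy()
            )
            carbon_now += c * held
            electron_now += g * held
            feed = self.config.feed_mM.get(name, 0.0)
            supplied = frame[name].iloc[0] + d * t * feed
            carbon_in += c * supplied
            electron_in += g * supplied
        for sp in self.species:
            x = frame[f"x_{sp.name}"].to_numpy() + frame[f"outcum_x_{sp.name}"].to_numpy()
            carbon_now += sp.biomass.carbon_per_mol * x
            electron_now += sp.biomass.electron_equivalents_per_mol * x
            x0 = frame[f"x_{sp.name}"].iloc[0]
            carbon_in += sp.biomass.carbon_per_mol * x0
            electron_in += sp.biomass.electron_equivalents_per_mol * x0
        return pd.DataFrame(
            {
                "time_h": t,
                "carbon_recovery_pct": 100.0 * carbon_now / carbon_in,
                "electron_recovery_pct": 100.0 * electron_now / electron_in,
            }
        )


def simulate_chemostat(
    config: ReactorConfig,
    species: Sequence[SimSpecies],
    duration_days: float = 40.0,
    seed: int | None = None,
    *,
    inoculum_mg_per_l: Mapping[str, float] | None = None,
    initial_mM: Mapping[str, float] | None = None,
    events: Sequence[UpsetEvent] = (),
    calibration: BiomassCalibration = BiomassCalibration(),
    stripping_per_h: Mapping[str, float] = DEFAULT_STRIPPING_PER_H,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    n_points: int = 481,
) -> SimulationResult:
    """Integrate the chemostat ODEs and return the labelled trajectory.

    The solution is deterministic; ``seed`` is accepted for interface symmetry
    with :func:`observe` and ignored.  Every species' growth reaction must be
    carbon- and electron-balanced or the simulation refuses to run.
    """
    species = tuple(species)
    for sp in species:
        sp.validate()
    if inoculum_mg_per_l is None:
        inoculum_mg_per_l = {sp.name: 20.0 for sp in species}
    if not any(v > 0 for v in inoculum_mg_per_l.values()) and species:
        raise ValueError("inoculum must contain positive biomass")

    m, n = len(SIM_COMPOUNDS), len(species)
    d = dilution_rate(config)
    base_feed = np.array([config.feed_mM.get(c, 0.0) for c in SIM_COMPOUNDS])
    strip = np.array([stripping_per_h.get(c, 0.0) for c in SIM_COMPOUNDS])
    stoich = np.zeros((n, m))
    for i, sp in enumerate(species):
        for j, c in enumerate(SIM_COMPOUNDS):
            stoich[i, j] = sp.stoichiometry.get(c, 0.0)
    fum_idx = SIM_COMPOUNDS.index("fumarate")
    events = tuple(events)

    def feed_at(t_h: float) -> np.ndarray:
        feed = base_feed
        for ev in events:
            if ev.kind == "high-fumarate" and ev.active(t_h):
                feed = feed.copy()
                feed[fum_idx] = ev.fumarate_feed_mM
        return feed

    def mu_factor(name: str, t_h: float) -> float:
        for ev in events:
            if ev.kind == "sporulation" and ev.active(t_h) and name == FERMENTER:
                return 0.0
        return 1.0

    # state: [S(m), X(n), outcum_S(m), outcum_X(n), gascum(m)]
    def rhs(t, y):
        s = np.maximum(y[:m], 0.0)
        x = np.maximum(y[m : m + n], 0.0)
        conc = dict(zip(SIM_COMPOUNDS, s))
        rates = np.array(
            [sp.growth_rate(conc) * mu_factor(sp.name, t) * x[i] for i, sp in enumerate(species)]
        )
        ds = d * (feed_at(t) - s) + rates @ stoich - strip * s
        dx = rates - d * x
        return np.concatenate([ds, dx, d * s, d * x, strip * s])

    if initial_mM is None:
        s0 = base_feed  # vessel starts filled with fresh medium
    else:
        s0 = np.array([initial_mM.get(c, 0.0) for c in SIM_COMPOUNDS])
    y0 = np.concatenate(
        [
            s0,
            np.array(
                [inoculum_mg_per_l.get(sp.name, 0.0) / sp.biomass.molar_mass_with_minerals
                 for sp in species]
            ),
            np.zeros(m + n + m),
        ]
    )
    t_end = duration_days * 24.0
    t_eval = np.linspace(0.0, t_end, n_points)
    sol = solve_ivp(rhs, (0.0, t_end), y0, method="LSODA", rtol=rtol, atol=atol, t_eval=t_eval)
    if not sol.success:  # pragma: no cover - solver failure is exceptional
        raise RuntimeError(f"ODE solver failed: {sol.message}")

    data: dict[str, np.ndarray] = {"time_h": sol.t, "day": sol.t / 24.0}
    for j, c in enumerate(SIM_COMPOUNDS):
        data[c] = sol.y[j]
        data[f"outcum_{c}"] = sol.y[m + n + j]
        data[f"gascum_{c}"] = sol.y[2 * m + 2 * n + j]
    total_mg = np.zeros(len(sol.t))
    for i, sp in enumerate(species):
        x = sol.y[m + i]
        data[f"x_{sp.name}"] = x
        data[f"outcum_x_{sp.name}"] = sol.y[2 * m + n + i]
        data[f"biomass_{sp.name}"] = x * sp.biomass.molar_mass_with_minerals
        total_mg = total_mg + data[f"biomass_{sp.name}"]
    data["biomass_total_mg_per_l"] = total_mg
    data["od600"] = total_mg / calibration.mg_dw_per_liter_per_od
    return SimulationResult(
        frame=pd.DataFrame(data),
        config=config,
        species=species,
        calibration=calibration,
        stripping_per_h=dict(stripping_per_h),
    )


def simulate_scenario(scenario: Scenario, seed: int | None = None, **kwargs) -> SimulationResult:
    return simulate_chemostat(
        scenario.config,
        scenario.species,
        scenario.duration_days,
        seed,
        inoculum_mg_per_l=scenario.inoculum_mg_per_l,
        events=scenario.events,
        **kwargs,
    )


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise and censoring model for the observation layer."""

    concentration_sd_mM: float = 0.05
    od_sd: float = 0.01
    cq_sd: float = 0.1
    bio_rep_cv: float = 0.02
    detection_limits_mM: Mapping[str, float] = field(
        default_factory=lambda: {"H2": 3e-4}
    )

    def __post_init__(self):
        if min(self.concentration_sd_mM, self.od_sd, self.cq_sd, self.bio_rep_cv) < 0:
            raise ValueError("noise standard deviations must be non-negative")

    @classmethod
    def zero(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, detection_limits_mM={})


def _default_curves(species_names) -> dict[str, StandardCurve]:
    slope = -1.0 / math.log10(2.0)  # perfect doubling per cycle
    return {
        name: StandardCurve(slope=slope, intercept=37.0, copies_range=(1e2, 1e10))
        for name in species_names
    }


@dataclass(frozen=True)
class Observations:
    """Noisy observation tables in the CSV dialects the analysis consumes."""

    metabolites: pd.DataFrame  # day, compound, concentration_mM, censored
    od: pd.DataFrame  # day, od600
    plate: pd.DataFrame  # sample, day, species, cq, bio_rep, tech_rep
    curves: Mapping[str, StandardCurve]
    extraction: ExtractionProtocol


def observe(
    result: SimulationResult,
    noise: NoiseModel = NoiseModel(),
    seed: int | None = 0,
    *,
    sample_days: Sequence[float] | None = None,
    curves: Mapping[str, StandardCurve] | None = None,
    assays: Mapping[str, SpeciesAssay] = DEFAULT_ASSAYS,
    extraction: ExtractionProtocol = ExtractionProtocol(),
    n_bio_reps: int = 3,
    n_tech_reps: int = 3,
) -> Observations:
    """Sample the trajectory into metabolite, OD and qPCR plate tables.

    Deterministic for a fixed seed; with :meth:`NoiseModel.zero` the
    metabolite and OD tables reproduce the simulation exactly.  Values under a
    detection limit are reported at the limit and flagged left-censored.
    """
    rng = np.random.default_rng(seed)
    frame = result.frame
    if sample_days is None:
        sample_days = np.arange(0.0, float(frame["day"].iloc[-1]) + 1e-9, 1.0)
    sample_days = np.asarray(sample_days, dtype=float)
    t = frame["day"].to_numpy()

    def at_days(column: str) -> np.ndarray:
        return np.interp(sample_days, t, frame[column].to_numpy())

    met_rows = []
    for compound in SIM_COMPOUNDS:
        values = at_days(compound)
        noisy = values + rng.normal(0.0, noise.concentration_sd_mM, size=len(values))
        noisy = np.maximum(noisy, 0.0)
        limit = noise.detection_limits_mM.get(compound)
        for day, value in zip(sample_days, noisy):
            censored = limit is not None and value < limit
            met_rows.append(
                {
                    "day": day,
                    "compound": compound,
                    "concentration_mM": limit if censored else value,
                    "censored": censored,
                }
            )
    metabolites = pd.DataFrame(met_rows)

    od_values = at_days("od600") + rng.normal(0.0, noise.od_sd, size=len(sample_days))
    od = pd.DataFrame({"day": sample_days, "od600": np.maximum(od_values, 0.0)})

    curves = curves or _default_curves([sp.name for sp in result.species])
    plate_rows = []
    for name in result.species_names:
        assay = assays[name]
        cells = np.interp(
            sample_days, t, frame[f"biomass_{name}"].to_numpy()
        ) * result.calibration.cells_per_ml_at_reference / result.calibration.mg_dw_per_liter_per_od
        for k, day in enumerate(sample_days):
            for bio in range(1, n_bio_reps + 1):
                bio_cells = cells[k] * (
                    1.0 + rng.normal(0.0, noise.bio_rep_cv) if noise.bio_rep_cv else 1.0
                )
                copies_per_rxn = max(bio_cells, 1e-12) * assay.rrn_copies_per_genome * (
                    extraction.culture_ml_per_reaction
                )
                base_cq = curves[name].cq_from_copies(max(copies_per_rxn, 1e-12))
                for tech in range(1, n_tech_reps + 1):
                    plate_rows.append(
                        {
                            "sample": f"d{day:g}_{name}_b{bio}",
                            "day": day,
                            "species": name,
                            "cq": base_cq + rng.normal(0.0, noise.cq_sd),
                            "bio_rep": bio,
                            "tech_rep": tech,
                        }
                    )
    plate = pd.DataFrame(plate_rows)
    return Observations(metabolites=metabolites, od=od, plate=plate, curves=curves,
                        extraction=extraction)


def estimate_yields(observations: Observations, config: ReactorConfig,
                    *, window_days: float = 5.0) -> dict[str, float]:
    """Back out community yield coefficients from observed steady-state
    concentrations: products per mole cellobiose consumed and sulfate reduced."""
    met = observations.metabolites
    last_day = met["day"].max()
    window = met[met["day"] >= last_day - window_days]
    mean = window.groupby("compound")["concentration_mM"].mean()
    consumed_cb = config.feed_mM.get("cellobiose", 0.0) - mean.get("cellobiose", 0.0)
    if consumed_cb <= 0:
        raise ValueError("no cellobiose consumption in observation window")
    fed_fum = config.feed_mM.get("fumarate", 0.0)
    return {
        "acetate_per_cellobiose": mean.get("acetate", 0.0) / consumed_cb,
        "succinate_per_cellobiose": mean.get("succinate", 0.0) / consumed_cb,
        "co2_per_cellobiose": mean.get("CO2", 0.0) / consumed_cb,
        "fumarate_per_cellobiose": (fed_fum - mean.get("fumarate", 0.0)) / consumed_cb,
        "sulfate_reduced_mM": config.feed_mM.get("sulfate", 0.0) - mean.get("sulfate", 0.0),
    }
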