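import numpy as np
import pandas as pd
import pytest

from chemobalance.chemostat import ReactorConfig, dilution_rate
from chemobalance.qpcr import quantify_plate
from chemobalance.simulate import (
    NoiseModel,
    SimSpecies,
    UpsetEvent,
    default_community,
    default_scenario,
    estimate_yields,
    make_upset_scenario,
    observe,
    simulate_chemostat,
    simulate_scenario,
)
from chemobalance.trophic import FERMENTER


def _fermenter_only(mu_max):
    base = default_community()[0]
    return SimSpecies(
        name=base.name,
        mu_max_per_h=mu_max,
        ks_mM={"cellobiose": 1e-6},
        stoichiometry=base.stoichiometry,
    )


class TestSimulateChemostat:
    def test_default_preset_reaches_reference_like_steady_state(self, sim_result):
        last = sim_result.steady_state()
        assert last["cellobiose"] < 0.1  # virtually exhausted
        assert last["fumarate"] < 0.05  # complete removal
        assert last["sulfate"] > 1.0  # residual acceptor remains
        assert 0.3 < last["od600"] < 0.5

    def test_conservation_along_trajectory(self, sim_result):
        balance = sim_result.balance()
        assert np.allclose(balance["carbon_recovery_pct"], 100.0, atol=0.5)
        assert np.allclose(balance["electron_recovery_pct"], 100.0, atol=0.5)
        # solver tolerance is far tighter than the 0.5% contract
        assert abs(balance["carbon_recovery_pct"] - 100.0).max() < 1e-6

    def test_washout_below_dilution_rate(self):
        config = ReactorConfig()
        species = [_fermenter_only(mu_max=0.5 * dilution_rate(config))]
        result = simulate_chemostat(config, species, duration_days=60.0,
                                    inoculum_mg_per_l={FERMENTER: 50.0})
        last = result.steady_state()
        assert last[f"biomass_{FERMENTER}"] < 1.0  # washed out
        assert last["cellobiose"] == pytest.approx(config.feed_mM["cellobiose"], rel=0.05)

    def test_washout_bifurcation_at_mu_equals_d(self):
        config = ReactorConfig()
        d = dilution_rate(config)
        below = simulate_chemostat(
            config, [_fermenter_only(0.9 * d)], duration_days=100.0,
            inoculum_mg_per_l={FERMENTER: 50.0},
        ).steady_state()[f"biomass_{FERMENTER}"]
        above = simulate_chemostat(
            config, [_fermenter_only(3.0 * d)], duration_days=100.0,
            inoculum_mg_per_l={FERMENTER: 50.0},
        ).steady_state()[f"biomass_{FERMENTER}"]
        assert below < 5.0  # decaying toward washout
        assert above > 50.0  # persists above the inoculum

    def test_no_biomass_matches_closed_form(self):
        config = ReactorConfig()
        d = dilution_rate(config)
        result = simulate_chemostat(
            config, [], duration_days=5.0,
            inoculum_mg_per_l={}, initial_mM={"cellobiose": 0.0},
        )
        t = result.frame["time_h"].to_numpy()
        s_in = config.feed_mM["cellobiose"]
        expected = s_in + (0.0 - s_in) * np.exp(-d * t)
        assert np.allclose(result.frame["cellobiose"], expected, atol=1e-6)

    def test_unbalanced_reaction_refused(self):
        broken = SimSpecies(
            name="broken",
            mu_max_per_h=0.2,
            ks_mM={"cellobiose": 0.05},
            stoichiometry={"cellobiose": -1.0, "acetate": 1.0},
        )
        with pytest.raises(ValueError, match="unbalanced"):
            simulate_chemostat(ReactorConfig(), [broken], duration_days=1.0)

    def test_default_community_reactions_balanced(self):
        for sp in default_community():
            balance = sp.reaction_balance()
            assert balance.is_balanced(1e-9)

    def test_deterministic_trajectory(self):
        a = simulate_scenario(default_scenario(duration_days=5.0), seed=1)
        b = simulate_scenario(default_scenario(duration_days=5.0), seed=2)
        pd.testing.assert_frame_equal(a.frame, b.frame)  # ODE ignores seed


class TestObserve:
    def test_zero_noise_reproduces_simulation(self, sim_result):
        obs = observe(sim_result, NoiseModel.zero(), seed=0)
        met = obs.metabolites
        assert not met["censored"].any()
        day20 = met[(met["day"] == 20.0) & (met["compound"] == "acetate")]
        truth = np.interp(20.0, sim_result.frame["day"], sim_result.frame["acetate"])
        assert day20["concentration_mM"].iloc[0] == pytest.approx(truth, rel=1e-12)
        od20 = obs.od[obs.od["day"] == 20.0]["od600"].iloc[0]
        assert od20 == pytest.approx(
            np.interp(20.0, sim_result.frame["day"], sim_result.frame["od600"]), rel=1e-12
        )

    def test_detection_limit_censoring(self, sim_result):
        noise = NoiseModel(0.0, 0.0, 0.0, 0.0, detection_limits_mM={"H2": 1.0})
        obs = observe(sim_result, noise, seed=0)
        h2 = obs.metabolites[obs.metabolites["compound"] == "H2"]
        late = h2[h2["day"] > 20]
        assert late["censored"].all()
        assert (late["concentration_mM"] == 1.0).all()  # reported at the limit

    def test_fixed_seed_is_reproducible(self, sim_result):
        a = observe(sim_result, NoiseModel(), seed=11)
        b = observe(sim_result, NoiseModel(), seed=11)
        pd.testing.assert_frame_equal(a.metabolites, b.metabolites)
        pd.testing.assert_frame_equal(a.plate, b.plate)
        c = observe(sim_result, NoiseModel(), seed=12)
        assert not a.plate["cq"].equals(c.plate["cq"])

    def test_plate_quantifies_back_to_simulated_cells(self, sim_result):
        obs = observe(sim_result, NoiseModel.zero(), seed=0)
        cells = quantify_plate(obs.plate, obs.curves, extraction=obs.extraction)
        final = cells[cells["day"] == cells["day"].max()]
        frame = sim_result.frame
        cal = sim_result.calibration
        for _, row in final.iterrows():
            truth = (
                frame[f"biomass_{row['species']}"].iloc[-1]
                * cal.cells_per_ml_at_reference
                / cal.mg_dw_per_liter_per_od
            )
            assert row["cells_per_ml"] == pytest.approx(truth, rel=1e-6)

    def test_replicate_structure(self, sim_result):
        obs = observe(sim_result, NoiseModel(), seed=0, sample_days=[10.0])
        counts = obs.plate.groupby(["species", "bio_rep"]).size()
        assert (counts == 3).all()
        assert obs.plate.groupby("species")["bio_rep"].nunique().eq(3).all()


class TestUpsetScenarios:
    def test_unknown_trigger(self):
        with pytest.raises(ValueError, match="unknown"):
            make_upset_scenario(default_scenario(), "meteor strike")

    def test_no_trigger_identical(self):
        base = default_scenario(duration_days=10.0)
        a = simulate_scenario(base, seed=1)
        b = simulate_scenario(base, seed=1)
        pd.testing.assert_frame_equal(a.frame, b.frame)

    def test_sporulation_window_lets_cellobiose_rise(self):
        base = default_scenario(duration_days=25.0)
        upset = make_upset_scenario(base, "sporulation", start_day=15.0, duration_days=3.0)
        base_run = simulate_scenario(base, seed=1).frame
        upset_run = simulate_scenario(upset, seed=1).frame
        window = (upset_run["day"] >= 15.0) & (upset_run["day"] <= 18.5)
        assert upset_run.loc[window, "cellobiose"].max() > 1.5  # toward the 2.2 feed
        assert upset_run.loc[window, "cellobiose"].max() > 10 * base_run.loc[window, "cellobiose"].max()

    def test_high_fumarate_accumulates_succinate_and_inhibits(self):
        base = default_scenario(duration_days=40.0)
        upset = make_upset_scenario(base, "high-fumarate", start_day=10.0, fumarate_feed_mM=15.0)
        base_last = simulate_scenario(base, seed=1).steady_state()
        upset_last = simulate_scenario(upset, seed=1).steady_state()
        assert upset_last["succinate"] > base_last["succinate"]
        assert upset_last[f"biomass_{FERMENTER}"] < base_last[f"biomass_{FERMENTER}"]
        assert upset_last["cellobiose"] > base_last["cellobiose"]

    def test_inhibition_term_beats_dilution_rate(self):
        fermenter = default_community()[0]
        d = dilution_rate(ReactorConfig())
        healthy = fermenter.growth_rate({"cellobiose": 2.2, "succinate": 0.0})
        inhibited = fermenter.growth_rate({"cellobiose": 2.2, "succinate": 15.0})
        assert healthy > d
        assert inhibited < d

    def test_event_window(self):
        event = UpsetEvent("sporulation", start_day=2.0, end_day=3.0)
        assert event.active(2.5 * 24.0)
        assert not event.active(3.5 * 24.0)


class TestEstimateYields:
    def test_matches_generator_at_zero_noise(self, sim_result):
        obs = observe(sim_result, NoiseModel.zero(), seed=0)
        yields = estimate_yields(obs, sim_result.config)
        last = sim_result.steady_state()
        consumed = sim_result.config.feed_mM["cellobiose"] - last["cellobiose"]
        assert yields["acetate_per_cellobiose"] == pytest.approx(
            last["acetate"] / consumed, rel=0.02
        )
        assert yields["sulfate_reduced_mM"] == pytest.approx(
            sim_result.config.feed_mM["sulfate"] - last["sulfate"], rel=0.02
        )

    def test_noisy_recovery_within_10pct(self, sim_result):
        truth = estimate_yields(observe(sim_result, NoiseModel.zero(), seed=0), sim_result.config)
        keys = ("acetate_per_cellobiose", "succinate_per_cellobiose", "fumarate_per_cellobiose")
        rel_errors = []
        for seed in range(20):
            noisy = estimate_yields(
                observe(sim_result, NoiseModel(), seed=seed), sim_result.config
            )
            rel_errors.append(max(abs(noisy[k] / truth[k] - 1.0) for k in keys))
        assert max(rel_errors) < 0.10
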