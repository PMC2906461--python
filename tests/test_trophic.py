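import numpy as np
import pandas as pd
import pytest

from chemobalance.compounds import ELECTRON_POOL
from chemobalance.simulate import default_community
from chemobalance.stoichiometry import BiomassFormula
from chemobalance.trophic import (
    FERMENTER,
    FUMARATE_REDUCER,
    SULFATE_REDUCER,
    AllocationSplits,
    BalanceReport,
    FluxTable,
    allocate_fluxes,
    build_report,
    carbon_recovery,
    digestible_energy_fraction,
    electron_recovery,
    partition_biomass,
)

REFERENCE_BIOMASS = 236.0

# hand calculation (independent of the implementation):
#   inputs: 2.2 mM cellobiose * 48 e- + 4.9 mM fumarate * 12 e- = 164.4 meq
#   digestible products: acetate 5.93*8 + succinate 3.586*14 + malate 0.044*12
#                      = 47.44 + 50.204 + 0.528 = 98.172 meq
#   fraction = 98.172 / 164.4 = 59.72%
HAND_DIGESTIBLE_PCT = 59.72


def closed_flux_table():
    """Flux table constructed directly from the generator's exactly balanced
    reaction set; the oracle for conservation checks."""
    species = {sp.name: sp for sp in default_community()}
    extents = {FERMENTER: 0.88, SULFATE_REDUCER: 0.05, FUMARATE_REDUCER: 0.08}
    flux = {
        name: {c: coeff * e for c, coeff in species[name].stoichiometry.items()}
        for name, e in extents.items()
    }
    basis = 2.2
    biomass_mg = sum(extents.values()) * basis * 104.0
    return FluxTable(flux, basis_mM=basis), biomass_mg


class TestAllocateFluxes:
    def test_reference_yields(self, ref_fluxes):
        comm = ref_fluxes.community()
        assert round(comm["acetate"], 1) == 2.7
        assert round(-comm["fumarate"], 2) == 2.23
        assert comm["CO2"] == pytest.approx(3.3)
        assert comm["cellobiose"] == -1.0

    def test_geobacter_acetate_oxidation(self, ref_fluxes):
        geo = ref_fluxes.species(FUMARATE_REDUCER)
        # 0.3 mol acetate (C2) oxidized -> 0.6 mol CO2 (C1)
        assert geo["CO2"] == pytest.approx(0.6)
        assert geo["succinate"] == pytest.approx(1.63)
        assert geo["malate"] == pytest.approx(0.02)

    def test_electron_pool_carried_by_sulfate_reducer(self, ref_fluxes):
        pool = 8.0 * 6.1 / 2.2  # e- equivalents per mole cellobiose
        assert ref_fluxes.species(FERMENTER)[ELECTRON_POOL] == pytest.approx(pool)
        assert ref_fluxes.species(SULFATE_REDUCER)[ELECTRON_POOL] == pytest.approx(-pool)
        assert ref_fluxes.community()[ELECTRON_POOL] == pytest.approx(0.0, abs=1e-12)

    def test_overcommitted_acceptor_warns(self, ref_state, ref_config):
        with pytest.warns(UserWarning, match="donor"):
            fluxes = allocate_fluxes(ref_state, ref_config)
        assert "acceptor_flux_exceeds_donor_capacity" in fluxes.flags

    def test_requires_cellobiose_consumption(self, ref_config):
        from chemobalance.chemostat import ChemostatState

        state = ChemostatState(residual_mM={"cellobiose": 2.2})
        with pytest.raises(ValueError, match="cellobiose"):
            allocate_fluxes(state, ref_config)

    def test_community_totals_decompose(self, ref_fluxes):
        frame = ref_fluxes.to_frame()
        species_cols = [c for c in frame.columns if c != "community"]
        assert np.allclose(frame[species_cols].sum(axis=1), frame["community"])

    def test_cellobiose_only_fermenter(self):
        with pytest.raises(ValueError, match="fermenter"):
            FluxTable({SULFATE_REDUCER: {"cellobiose": -1.0}}, basis_mM=2.2)


class TestCarbonRecovery:
    def test_reference_is_93pct(self, ref_fluxes):
        pct = carbon_recovery(ref_fluxes, biomass_mg_per_l=REFERENCE_BIOMASS)
        assert round(pct) == 93

    def test_closed_system_is_exact(self):
        fluxes, biomass_mg = closed_flux_table()
        assert carbon_recovery(fluxes, biomass_mg_per_l=biomass_mg) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_linearity_in_products(self):
        full = FluxTable({FERMENTER: {"cellobiose": -1.0, "acetate": 3.0, "CO2": 6.0}}, 2.2)
        half = FluxTable({FERMENTER: {"cellobiose": -1.0, "acetate": 1.5, "CO2": 3.0}}, 2.2)
        assert carbon_recovery(full) == pytest.approx(2.0 * carbon_recovery(half))

    def test_monotone_in_added_product(self, ref_fluxes):
        base = carbon_recovery(ref_fluxes, biomass_mg_per_l=REFERENCE_BIOMASS)
        bumped = {
            sp: dict(fl) for sp, fl in ref_fluxes.species_fluxes.items()
        }
        bumped[FERMENTER]["ethanol"] = bumped[FERMENTER].get("ethanol", 0.0) + 0.05
        more = carbon_recovery(
            FluxTable(bumped, ref_fluxes.basis_mM), biomass_mg_per_l=REFERENCE_BIOMASS
        )
        assert more > base

    def test_no_carbon_input_errors(self):
        fluxes = FluxTable({FERMENTER: {"sulfate": -1.0, "sulfide": 1.0}}, 2.2)
        with pytest.raises(ValueError):
            carbon_recovery(fluxes)


class TestElectronRecovery:
    def test_reference_is_112pct(self, ref_fluxes):
        pct = electron_recovery(ref_fluxes, biomass_mg_per_l=REFERENCE_BIOMASS)
        # the printed intermediates round to 112; full-precision arithmetic
        # lands within one point of it
        assert pct == pytest.approx(112.0, abs=1.0)

    def test_closed_system_is_exact(self):
        fluxes, biomass_mg = closed_flux_table()
        assert electron_recovery(fluxes, biomass_mg_per_l=biomass_mg) == pytest.approx(
            100.0, abs=1e-9
        )

    def test_sulfide_counts_8_per_mol(self):
        with_s = FluxTable(
            {FERMENTER: {"cellobiose": -1.0, "acetate": 6.0},
             SULFATE_REDUCER: {"sulfate": -1.0, "sulfide": 1.0}}, 1.0
        )
        without = FluxTable({FERMENTER: {"cellobiose": -1.0, "acetate": 6.0}}, 1.0)
        diff = electron_recovery(with_s) - electron_recovery(without)
        assert diff == pytest.approx(100.0 * 8.0 / 48.0)


class TestDigestibleEnergy:
    def test_unit_weights_match_hand_calculation(self, ref_fluxes):
        pct = digestible_energy_fraction(ref_fluxes)
        assert pct == pytest.approx(HAND_DIGESTIBLE_PCT, abs=0.01)

    def test_empty_digestible_set(self, ref_fluxes):
        assert digestible_energy_fraction(ref_fluxes, digestible=set()) == 0.0

    def test_pass_through_is_100pct(self):
        fluxes = FluxTable({FERMENTER: {"cellobiose": -1.0, "acetate": 6.0}}, 1.0)
        assert digestible_energy_fraction(fluxes, digestible={"acetate"}) == pytest.approx(100.0)

    def test_relabeling_invariance(self):
        # acetate 6 mol * 8 e- == H2 24 mol * 2 e-
        a = FluxTable({FERMENTER: {"cellobiose": -1.0, "acetate": 6.0}}, 1.0)
        b = FluxTable({FERMENTER: {"cellobiose": -1.0, "H2": 24.0}}, 1.0)
        assert digestible_energy_fraction(a, {"acetate"}) == pytest.approx(
            digestible_energy_fraction(b, {"H2"})
        )

    def test_sulfide_never_digestible(self):
        fluxes = FluxTable(
            {FERMENTER: {"cellobiose": -1.0},
             SULFATE_REDUCER: {"sulfate": -3.0, "sulfide": 3.0}}, 1.0
        )
        assert digestible_energy_fraction(fluxes, digestible={"sulfide"}) == 0.0

    def test_energy_weights_change_result(self, ref_fluxes):
        unweighted = digestible_energy_fraction(ref_fluxes)
        weighted = digestible_energy_fraction(
            ref_fluxes, weights={"acetate": 0.5, "cellobiose": 1.0, "fumarate": 1.0}
        )
        assert weighted != pytest.approx(unweighted)


class TestPartitionBiomass:
    def test_reference_partition(self, ref_counts):
        shares = partition_biomass(REFERENCE_BIOMASS, ref_counts)
        assert shares[FERMENTER] == pytest.approx(236.0 * 4.6 / 5.25, abs=0.01)
        assert shares[SULFATE_REDUCER] == pytest.approx(13.04, abs=0.01)
        assert shares[FUMARATE_REDUCER] == pytest.approx(16.18, abs=0.01)
        assert sum(shares.values()) == pytest.approx(REFERENCE_BIOMASS, abs=1e-9)

    def test_single_species(self):
        assert partition_biomass(100.0, {"only": 5.0}) == {"only": 100.0}

    def test_equal_counts(self):
        shares = partition_biomass(99.0, {"a": 2.0, "b": 2.0, "c": 2.0})
        assert all(v == pytest.approx(33.0) for v in shares.values())

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            partition_biomass(100.0, {"a": 0.0})

    def test_mass_weights(self):
        shares = partition_biomass(30.0, {"a": 1.0, "b": 1.0}, {"a": 2.0})
        assert shares["a"] == pytest.approx(20.0)
        assert shares["b"] == pytest.approx(10.0)


class TestBuildReport:
    def test_reference_community_row(self, ref_state, ref_config, ref_counts):
        with pytest.warns(UserWarning):
            report = build_report(ref_state, ref_config, ref_counts)
        row = report.community
        assert row.cell_count_1e8_per_ml == pytest.approx(5.25)
        assert row.biomass_mg_per_l == pytest.approx(236.0)
        assert round(row.carbon_recovery_pct) == 93
        assert row.electron_recovery_pct == pytest.approx(112.0, abs=1.0)
        assert "unresolved_electron_pool" in report.flags

    def test_species_biomass_sums(self, ref_state, ref_config, ref_counts):
        with pytest.warns(UserWarning):
            report = build_report(ref_state, ref_config, ref_counts)
        total = sum(r.biomass_mg_per_l for r in report.species.values())
        assert total == pytest.approx(report.community.biomass_mg_per_l)

    def test_inconsistent_biomass_rejected(self):
        from chemobalance.trophic import ReportRow

        row = ReportRow(1.0, 100.0, 90.0, 90.0, 50.0)
        bad = ReportRow(1.0, 10.0, 90.0, 90.0, 50.0)
        with pytest.raises(ValueError):
            BalanceReport(community=row, species={"a": bad}, basis_mM=2.2)

    def test_csv_round_trip(self, ref_state, ref_config, ref_counts, tmp_path):
        with pytest.warns(UserWarning):
            report = build_report(ref_state, ref_config, ref_counts)
        path = tmp_path / "report.csv"
        report.to_csv(path)
        loaded = BalanceReport.read_csv(path)
        pd.testing.assert_frame_equal(loaded, report.to_frame(), check_dtype=False)

    def test_splits_validation(self):
        with pytest.raises(ValueError):
            AllocationSplits(acetate_to_fumarate_reducer=0.2,
                             acetate_oxidized_by_fumarate_reducer=0.3)
        with pytest.raises(ValueError):
            AllocationSplits(pool_h2_fraction=1.5)

    def test_rounding_matches_display_convention(self, ref_state, ref_config, ref_counts):
        with pytest.warns(UserWarning):
            report = build_report(ref_state, ref_config, ref_counts)
        frame = report.to_frame(rounded=True)
        assert frame.loc["three species community", "C_recovered_pct"] == 93
        raw = report.to_frame(rounded=False)
        assert raw.loc["three species community", "C_recovered_pct"] != 93
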