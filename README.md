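# chemobalance

Chemostat flux accounting, absolute qPCR quantification and carbon/electron
mass-balance modelling for a three-species anaerobic model community — a
cellulolytic fermenter (*Clostridium cellulolyticum*), a sulfate reducer
(*Desulfovibrio vulgaris*) and a fumarate reducer (*Geobacter
sulfurreducens*) grown in continuous culture on cellobiose.

The package turns raw observations (steady-state metabolite tables, qPCR
plate exports, OD600 readings) into a per-species trophic flux table and a
balance report: carbon recovery, electron recovery, biomass partition, and
the fraction of input energy left in digestible end products.  A synthetic
data generator simulates the chemostat (exactly mass- and electron-balanced
ODEs, Monod kinetics, product inhibition, gas stripping, upset scenarios) so
the entire pipeline runs and is tested without any external data.

## Modules

| module | contents |
| --- | --- |
| `chemobalance.stoichiometry` | elemental formulas, degree of reduction (electron equivalents), reaction balance checks, biomass formula (C4H7O1.5N, 104 g/mol with minerals, 17 e⁻/mol) |
| `chemobalance.compounds` | compound registry (formula, role, electron-accounting overrides for sulfur species), CSV round trip |
| `chemobalance.chemostat` | dilution rate, OD ↔ biomass ↔ cell density, steady-state fluxes, Henry's-law dissolved gases with CO2/bicarbonate speciation, detection-limit censoring |
| `chemobalance.qpcr` | DNA mass → copies, standard curves, extraction-volume scaling, 16S copy-number normalization to cells/ml, plate reduction, community composition |
| `chemobalance.trophic` | per-species flux allocation, carbon/electron recovery, digestible-energy fraction, biomass partition, balance report |
| `chemobalance.simulate` | the synthetic chemostat: balanced three-species ODE model, observation layer with noise/censoring/qPCR export, upset scenarios, yield estimation |
| `chemobalance.io` / `config` / `pipeline` / `cli` | CSV dialects, YAML configuration with schema validation, reproducible end-to-end runs, CLI |

## CLI

```bash
# balance report from a measured steady-state table
chemobalance balance --state steadystate.csv --out report.csv

# cells/ml from a qPCR plate + dilution-series standard curves
chemobalance quantify --plate plate.csv --curves curves.csv --out cells.csv

# synthetic chemostat run (timeseries + observation tables)
chemobalance simulate --days 40 --seed 1 --out-dir out/
chemobalance simulate --days 40 --seed 1 --upset sporulation --out-dir out/

# full simulate -> observe -> quantify -> balance pipeline
chemobalance report --seed 1 --out-dir out/
```

A packaged reference configuration (reactor geometry, feed, calibrations,
assays) lives at `src/chemobalance/data/reference_config.yaml`; pass any
YAML with the same sections via `--config` to override defaults.  Reruns
with the same seed produce byte-identical outputs.

## Conventions

- concentrations in mM, biomass in mg dry weight/L, cell densities in
  cells/ml, fluxes in mol per mol cellobiose consumed (negative = consumed)
- valences C=+4, H=+1, O=−2, N=−3; CO2/H2O/NH3 are zero-reference states;
  sulfate enters balances at 0 e⁻/mol and sulfide at 8 e⁻/mol (explicit
  redox couple rather than a sulfur valence)
- the donor pool feeding sulfate reduction (H2 / ethanol / direct electron
  transfer are indistinguishable in supernatant data) is carried as one
  electron-equivalent quantity and flagged as unresolved
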