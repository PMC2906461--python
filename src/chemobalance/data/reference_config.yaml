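# Reference configuration: default operating point of the three-species
# chemostat.  All values can be overridden; genome sizes are stated explicitly
# so this preset loads without provenance warnings.
reactor:
  working_volume_ml: 650.0
  feed_flow_ml_per_min: 0.34
  headspace_gas_flow_ml_per_min: 49.0
  temperature_c: 30.0
  feed_mM:
    cellobiose: 2.2
    fumarate: 4.9
    sulfate: 8.0
    NaHCO3: 5.0
calibration:
  mg_dw_per_liter_per_od: 590.0
  cells_per_ml_at_reference: 1300000000.0
assays:
  C. cellulolyticum:
    rrn_copies_per_genome: 8
    genome_size_bp: 4068724
  D. vulgaris:
    rrn_copies_per_genome: 5
    genome_size_bp: 3570858
  G. sulfurreducens:
    rrn_copies_per_genome: 2
    genome_size_bp: 3814128
splits:
  acetate_to_fumarate_reducer: 0.45
  acetate_oxidized_by_fumarate_reducer: 0.30
  acetate_to_sulfate_reducer: 0.25
  pool_h2_fraction: 0.5
noise:
  concentration_sd_mM: 0.05
  od_sd: 0.01
  cq_sd: 0.1
  bio_rep_cv: 0.02
  detection_limits_mM:
    H2: 0.0003
od600: 0.4
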