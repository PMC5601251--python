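# Example analysis configuration for `reproage analyze --config`.
# Exactly one of `input_path` / `simulation` must be present.

# input_path: my_breeding_records.csv
simulation: biennial_yearlong        # or a mapping of SimulationConfig fields,
                                     # or "annual+biennial_short+biennial_yearlong"
seed: 1
out_dir: reproage_out
log_level: INFO

min_age_count: 5                     # drop ages with < 5 observations
min_side: 25                         # support required on each side of a breakpoint
include_double_threshold: false      # also scan two-breakpoint age functions

# per species/sex overrides (keys "SPECIES/SEX")
cutoff_overrides:
  WA/F: 18                           # early/late split forced to 18
# threshold_grid:
#   GHA/M: [15, 16, 17, 18, 19, 20, 21, 22, 23, 24, 25, 26]

robustness_terms: []                 # any of: partner_change, years_since_last,
                                     # previous_outcome, years_since_last_x_previous_outcome
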