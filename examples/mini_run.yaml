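# Example run configuration: a reduced mineralized fibril.
#
#   minfibril build --config examples/mini_run.yaml --out mini.data
#
geometry:
  diameter_nm: 6.0
  periods: 2
  d_period: 670.0
  molecule_beads: null        # auto from the column-coverage fraction
  total_collagen_beads: null  # no exact-total calibration at this size
mineralization:
  target_wt: 25.0             # percent of total model mass
crosslink: null               # or e.g. {per_molecule: 2, search_radius: 18.0}
engine:
  temperature: 300.0
  timestep: 10.0
  damping: 1000.0
  equilibration_ns: 0.2
  pull_rate: 100.0            # m/s (scaled-down protocol)
analysis: {}
seed: 2025
output_dir: "."
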