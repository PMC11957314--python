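# A reduced screen for quick end-to-end runs (seconds, not minutes):
#   myoscreen all --config configs/small_screen.yaml --seed 42 --outdir out
# Structure matches the full default (plates, vehicle controls, dose series);
# only the sizes are down.
synthetic:
  n_compounds: 8
  n_mechanisms: 4
  n_features: 60
  baseline_cells_per_well: 60
  wells_per_condition_per_plate: 2
  n_plates: 2
  vehicle_wells_per_plate: 30
  emax_ladder: [0.6, 1.0]
  seed: 11

models:
  n_trees: 200
  seed: 42

clustering:
  linkage: average
  metric: pearson
  min_induction: 20.0

dose:
  alpha: 0.05
  decoupling_floor: 0.2
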