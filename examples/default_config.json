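{
  "n_cells": 300,
  "substrate_radius": 450.0,
  "cell_radius": 7.5,
  "growth_velocity": 30.0,
  "wiring_stop": 6,
  "total_steps": 18,
  "initial_tension": 1.0,
  "tension_increment": 1.0,
  "adhesion_per_cell": 14.0,
  "merge_distance": 15.0,
  "k0_min": 1,
  "k0_max": 50,
  "k0_mean": 8.0,
  "relax_step": 3.75,
  "relax_max_iter": 1000,
  "seed": 0
}
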