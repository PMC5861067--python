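{
  "feeding_canal": {
    "length_m": 1.56e-3,
    "diameter_m": 25e-6
  },
  "pharynx": {
    "length_m": 200e-6,
    "diameter_m": 25e-6
  },
  "esophagus": {
    "length_m": 100e-6,
    "diameter_m": 50e-6
  },
  "valve": {
    "constricted_length_m": 20e-6,
    "constricted_diameter_m": 5e-6,
    "esophageal_backflow_factor": 1e6
  },
  "cibarial": {
    "length_m": 232e-6,
    "h_min_m": 38e-6,
    "h_max_continuous_m": 50e-6,
    "h_max_burst_m": 63e-6
  },
  "pharyngeal": {
    "length_m": 326e-6,
    "h_min_m": 44e-6,
    "h_max_continuous_m": 50e-6,
    "h_max_burst_m": 256e-6
  },
  "fluid": {
    "density_kg_m3": 1100.0,
    "viscosity_pa_s": 3.0e-3,
    "surface_tension_n_m": 0.077
  },
  "boundaries": {
    "p_food_pa": 0.0,
    "p_gut_pa": 0.0,
    "p_hemo_pa": 0.0,
    "p_atm_pa": 0.0
  }
}
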