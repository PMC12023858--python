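# Synthetic demonstration scenario for `clonaltrace simulate`.
# All numbers are invented for demonstration; any field omitted here
# falls back to the bundled default scenario (see
# clonaltrace.synthetic_data.default_model).
seed: 0
dose_mg: 150.7
noise_cv: 0.10        # biological CV on tracer-derived atom% excess
biomass_cv: 0.10
n_replicates: 3
tracer:
  volume_ml: 10.0
  n_conc_mg_per_ml: 50.0
  atom_pct: 30.14
# Example pool overrides (mg N per kg, kg): make the early shoot smaller.
tn_conc:
  ES.shoot: 8000
biomass:
  ES.shoot: 0.25
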