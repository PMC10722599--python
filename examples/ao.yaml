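# Colloid-polymer depletion pipeline: quadrature mean forces -> pair model
seed: 11
pipeline:
  kind: ao
ao:
  q: 1.0
  eta_p_r: 0.5
sampling:
  n_distances: 250
  n_points: 120000
pool:
  preset: pair
  r_cut: 2.5
selection:
  delta_r2_min: 1.0e-4
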