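# Desk-scale ligand-nanoparticle pair scan -> two-body model (bad solvent)
seed: 7
pipeline:
  kind: np_pair
forcefield:
  s: 0.9
sampling:
  n_distances: 12
  r_min: 1.05
  r_max: 2.5
  n_steps: 6000
  n_equil: 2000
pool:
  preset: pair
  r_cut: 2.5
selection:
  delta_r2_min: 1.0e-4
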