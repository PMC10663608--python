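# Generative config for a synthetic three-channel vesicle table
ligand_concentrations: [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0, 10000.0]
vesicles_per_concentration: 250
K_L: 10.0          # nM
K_resp: 0.40
R_max: 0.95
E0: 0.12
receptor_log_mean: 5.0
receptor_log_sd: 0.5
cv_antibody: 0.2
cv_ligand: 0.0
ligand_gain: 1.5
seed: 1
three_channel: true
labels:
  receptor_variant: WT
  ligand: rho-mEGF
  py_site: Y1068
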