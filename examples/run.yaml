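# Full-pipeline config: two synthetic ligands sharing one receptor variant.
# Replace the simulate blocks with `inputs: [path1.csv, ...]` for real tables.
simulate:
  - labels: {ligand: EGF, py_site: Y1068}
    config: {ligand_concentrations: [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0],
             vesicles_per_concentration: 200, K_L: 10.0, K_resp: 0.40,
             R_max: 0.95, E0: 0.1, cv_antibody: 0.2, seed: 11}
  - labels: {ligand: EGF, py_site: Y1173}
    config: {ligand_concentrations: [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0],
             vesicles_per_concentration: 200, K_L: 10.0, K_resp: 0.86,
             R_max: 0.39, E0: 0.1, cv_antibody: 0.2, seed: 12}
  - labels: {ligand: epiregulin, py_site: Y1068}
    config: {ligand_concentrations: [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0],
             vesicles_per_concentration: 200, K_L: 50.0, K_resp: 0.55,
             R_max: 0.95, E0: 0.1, cv_antibody: 0.2, seed: 13}
  - labels: {ligand: epiregulin, py_site: Y1173}
    config: {ligand_concentrations: [0.0, 1.0, 3.0, 10.0, 30.0, 100.0, 1000.0],
             vesicles_per_concentration: 200, K_L: 50.0, K_resp: 0.45,
             R_max: 0.39, E0: 0.1, cv_antibody: 0.2, seed: 14}
reference_ligand: EGF
e0_mode: subtract
fit_target: vesicles
mc: {n_draws: 1000000, seed: 0}
out_dir: results
seed: 1
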