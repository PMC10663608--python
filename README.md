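# vesiclebias

Quantification of ligand- and mutation-induced signaling bias in receptor
phosphorylation from single-vesicle fluorescence dose-response data.

Each observation is one plasma-membrane-derived vesicle with a
receptor-channel fluorescence, a phospho-antibody-channel fluorescence and
(optionally) a ligand-channel fluorescence. The package implements the full
analysis chain on such tables:

- **`vesiclebias.synthetic`** — generative model for per-vesicle tables:
  Hill (slope 1) ligand binding, hyperbolic stimulus→response transducer,
  additive constitutive offset, log-normal receptor intensity,
  multiplicative per-vesicle noise.
- **`vesiclebias.dose_response`** — per-vesicle response ratios,
  constitutive-signal (zero-ligand) correction, fixed-slope Hill fitting
  (`E(L) = E_top·L/(L+EC50)`) over all single vesicles, per-concentration
  summaries, operational-model parameter maps
  (`E_top = τR_max/(τ+1)`, `EC50 = K_L/(τ+1)`), FRET bleed-through unmixing.
- **`vesiclebias.bias`** — bias plots (response A vs response B at matched
  concentrations), relative bias coefficients for ligand-vs-reference-ligand
  and mutant-vs-wild-type comparisons (log10, positive = response A
  preferred), absolute bias coefficients from transducer constants
  (`log10(K_resp,B/K_resp,A)`) and their additive chaining.
- **`vesiclebias.transducer`** — per-vesicle bound-fraction scaling from the
  ligand channel, hyperbolic transducer fit
  (`R = f·R_max/(f+K_resp)`), phosphorylation efficiency `1/(1+K_resp)`,
  stimulus-axis binning (width 0.1, bins with < 50 vesicles dropped).
- **`vesiclebias.stats`** — Monte-Carlo SE propagation (10⁶ Gaussian draws
  per parameter by default, domain violations rejected and counted),
  one-way ANOVA + Tukey HSD, two-tailed t-tests with Holm-Šidák step-down
  adjustment.
- **`vesiclebias.io` / `vesiclebias.cli`** — delimited vesicle-table format,
  validated run configuration (YAML/JSON), full pipeline with provenance.

## CLI

```sh
# synthetic three-channel table
vesiclebias simulate --config examples/gen.yaml --seed 1 --out table.csv

# Hill fits per (variant, ligand, phosphosite)
vesiclebias fit-dose table.csv --out fits.json

# transducer fit + binned curve for three-channel tables
vesiclebias transducer table.csv --out transducer.json

# full pipeline: Hill fits, bias plots, relative/absolute coefficients
vesiclebias report --config run.yaml --seed 1 --out results/

# ANOVA/Tukey or t-test/Holm-Šidák on computed coefficients
vesiclebias test coefficients.json --method anova --out tests.json
```

A `run.yaml` lists either `inputs:` (paths to vesicle tables) or `simulate:`
blocks (generative configs + condition labels), plus options such as
`e0_mode` (`subtract` | `fit` | a fixed value), `fit_target`
(`vesicles` | `means`), `reference_ligand`, `reference_variant`, and
`mc: {n_draws, seed}`. Unknown keys are rejected.

The vesicle-table format is delimited text (comma default, tab accepted)
with header columns `vesicle_id, experiment_id, receptor_variant, ligand,
ligand_conc_nM, py_site, receptor_fluor, antibody_fluor, ligand_fluor`
(the last may be empty).

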