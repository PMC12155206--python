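# neuropls

Multi-site brain–cognition latent-variable analysis for late-life
treatment-resistant depression cohorts.

Older adults with depression that persists through adequate antidepressant
trials carry a high risk of cognitive decline, and multi-center biomarker
studies of this population face two linked statistical problems: relating
high-dimensional brain measures (functional-connectivity edges, white-matter
tract integrity, gray-matter morphometry) to a battery of cognitive tests,
and predicting who will remit under treatment — all while removing
scanner/site artifacts and proving that findings survive a held-out site.
`neuropls` packages that analysis end to end, for imaging statisticians and
clinical-trial methodologists:

- **QC and preparation** — motion, surface-quality, and tract-quality
  filters with strict boundary semantics; mean imputation of sparse
  cognitive missingness; ICV-corrected, square-root-transformed
  white-matter-hyperintensity burden; leakage-free standardization.
- **Harmonization** — parametric empirical-Bayes location/scale site
  adjustment (the ComBat model) that removes site effects while protecting
  age, sex, and head-motion covariate effects; validated against the
  Bioconductor `sva::ComBat` reference.
- **PLS engine** — NIPALS partial least squares linking brain block X to
  cognition block Y: for standardized X and Y, each latent variable pairs
  directions *w*, *q* maximizing cov(Xw, Yq); significance by permutation of
  Y rows (p = (1 + #{null ≥ obs})/(n_perm + 1)); robust features by
  bootstrap ratio Z = loading mean / SE with |Z| > 3; latent-score/test
  correlations with Bonferroni correction; X→Y coefficients
  B = W(P′W)⁻¹Q′ for projecting held-out participants.
- **Generalizability** — leave-one-site-out evaluation: train on the other
  sites, predict the held-out site's cognition through the training B, and
  correlate predicted with observed composite cognition (first principal
  component of the training-significant tests).
- **Outcome prediction** — iterated nested cross-validated elastic-net
  logistic regression for remission, stability selection (features surviving
  regularization in >95% of iterations), confusion-matrix evaluation of the
  parsimonious model, and a PLS model of continuous depression-score change.
- **Synthetic cohorts** — a generator planting known latent factors, site
  effects, covariate slopes, and outcome signal, so every stage is validated
  by parameter recovery against ground truth.

See `docs/methods.md` for the models, defaults, and numerical decisions.

## Worked example

Generate a synthetic 4-site cohort and run the full pipeline from a config
file (`demo.yaml`):

```yaml
seed: 7
outdir: demo_run
generator:
  n_participants: 200
  n_sites: 4
  signal_strength: 0.12
  features_per_modality: {FC: 60, WM: 40, GM: 50}
pls: {n_perm: 200, n_boot: 200, max_components: 2, n_perm_select: 100}
loso: {modalities: [FC], n_components: 1}
prediction: {n_iter: 20, k_folds: 8}
```

```bash
neuropls run-all --config demo.yaml
```

(or from Python: `run_pipeline(PipelineConfig.from_yaml("demo.yaml"))`).
The run writes every intermediate table as CSV under `demo_run/`, a YAML
manifest, and `report.txt`, and prints:

```
[4] Brain-cognition PLS
  FC: n=199, 2 LV(s), 10.8% of cognition variance, permutation p=0.004975 (significant)
      robust features per LV (|Z|>3): [3, 6]
  ...

[5] Leave-one-site-out generalizability
  FC: mean held-out r=0.356 (site1: r=0.487, site2: r=-0.079, site3: r=0.589, site4: r=0.427)

[6] Remission prediction
  n=200 (72 remitters), 68 predictors
  mean held-out AUC: 0.779 (95% band 0.620-0.912)
  stable predictors (>95% of runs): ['thickness_45']
  parsimonious model: AUC=0.676, sens=0.31, spec=0.87 (TP=22, FP=17, TN=111, FN=50)
  MADRS-change PLS: 37.4% variance, permutation p=0.001996, held-out r=0.187
```

Reading the numbers: the FC block explains 10.8% of cognitive-battery
variance through two latent variables (planted: 12%; in-sample estimates at
n=199 carry optimism the report's debiased figure corrects), far beyond its
permutation null (p ≈ 0.005 is the smallest value 200 permutations can
resolve); a model trained on three sites predicts the fourth site's
composite cognition at r ≈ 0.36 on average; and the elastic net recovers
above-chance remission discrimination (held-out AUC 0.78) driven by the
planted gray-matter signal, with one cortical-thickness feature surviving
regularization in >95% of iterations. Exact values depend on the seed and
the scale in your configuration.

Individual stages are available as subcommands (`generate`, `prep`,
`harmonize`, `pls`, `loso`, `predict`), each reading and writing delimited
text.

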