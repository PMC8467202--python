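# progscape

Pan-cancer prognostic landscapes: compare gene-level and pathway-level
survival models across multi-omics cohorts.

Molecular profiles — gene expression (GE), copy-number variation (CNV),
binary somatic point mutations (SPM) — can predict cancer patient survival
in some cohorts and not others, and raw gene predictors behave differently
from pathway summaries of the same data. `progscape` is a pipeline for
mapping that landscape systematically: for every cohort × model
configuration it fits penalized Cox proportional-hazards models under
replicated nested cross-validation and reports three complementary
qualities:

* **prediction** — Harrell's concordance index C on held-out folds
  (0.5 chance, 1 perfect; C > 0.7 is the conventional "good model" bar);
* **stability** — Fleiss' κ over predictor selection, treating each trained
  model as a rater that labels every candidate variable selected or not
  (1 = identical selections across folds and replicates, ≤ 0 = chance);
* **parsimony** — average number of selected predictors.

The modelling core: continuous modalities can be collapsed to single-sample
pathway scores with a GSVA-style statistic (gene-wise kernel CDF, then a
weighted KS-like random walk over within-sample gene ranks); binary
mutation profiles are scored per pathway as the Haldane–Anscombe-corrected
log odds ratio of a 2×2 gene count table. Models are
L1-penalized Cox fits (coordinate descent on the Breslow partial
likelihood, λ chosen by inner 10-fold cross-validated deviance), or
group-lasso fits for multi-omics integration where one gene or pathway's
GE/CNV/SPM columns enter and leave the model as a unit. Gene prefilters
(pathway membership, cancer-gene list, training-fold univariable Cox
screen at p < 0.05) match common practice. A synthetic-cohort generator
with latent pathway activities, proportional-hazards survival and
calibrated censoring makes the whole pipeline testable end to end without
patient data.

## Worked example

```python
from progscape import (SimulationConfig, generate_cohort,
                       generate_pathway_collection, run_nested_cv,
                       ModelDescriptor, assemble_landscape)

config = SimulationConfig(n_samples=200, n_genes=120, pathway_sizes=(10,) * 10,
                          n_prognostic_pathways=3, effect_size=1.0,
                          censoring_rate_target=0.4, seed=42)
cohort = generate_cohort(config)
pathways = generate_pathway_collection(config)

cells = []
for level in ("pathway", "gene"):
    desc = ModelDescriptor(modalities=("GE",), level=level, penalty="lasso")
    res = run_nested_cv(cohort.bundle, desc, pathways, K=5, R=2, seed=7)
    cells.append(res)
    print(f"{desc.label}: CI = {res.mean_ci:.3f} +/- {res.se_ci:.3f}, "
          f"kappa = {res.kappa:.3f}, size = {res.avg_model_size:.1f}")

landscape = assemble_landscape(cells)
print(landscape.ci.round(3))
```

Output:

```
PLv-GE: CI = 0.747 +/- 0.011, kappa = 0.795, size = 4.8
GLv-GE: CI = 0.762 +/- 0.012, kappa = 0.697, size = 19.0
           PLv-GE  GLv-GE
synthetic   0.747   0.762
```

Three of this cohort's ten pathways drive the hazard. Both representations
predict held-out survival well (CI ≈ 0.75); the pathway-level model
(`PLv`) gets there with ~5 predictors selected far more consistently
across the 10 trained models (κ 0.80 vs 0.70) than the gene-level model's
~19 — the stability/parsimony trade-off the landscape is designed to
expose. scikit-learn users can reach the same machinery through
`CoxLassoCV`, `CoxGroupLassoCV`, `GSVAScorer`, `LogOddsScorer` and
`UnivariableCoxSelector`, which follow the fit/transform/predict
conventions and compose with pipelines.

## Command line

```bash
progscape simulate --outdir demo_data --seed 3          # write a synthetic cohort as TSV/GMT
progscape run --config config.yaml --outdir out         # full landscape run (see cli module docs)
progscape report --landscape out/landscape.tsv --outdir figs
```

`run` writes the landscape long table (the contract), per-cell JSON
results, model coefficient tables, heatmaps and a manifest; reruns with
the same config and seed are byte-identical.

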