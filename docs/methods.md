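# Methods

`progscape` evaluates how well different representations of tumor
multi-omics data predict patient survival. A model here is a combination of
(i) one or more omics modalities — gene expression (GE), gene-level copy
number (CNV), binary non-silent somatic point mutations (SPM), optionally
methylation, (ii) a predictor level — raw genes or single-sample pathway
scores, (iii) a penalty — lasso or group lasso — and (iv) optional gene
prefilters. Every cohort × model cell is scored on prediction, stability
and parsimony under replicated nested cross-validation, and the cells are
arranged into a landscape.

## Pathway scoring

**Continuous modalities (GSVA-style).** For gene *i* with values
*x_i1 … x_in* across samples, a Gaussian-kernel estimate of the gene's own
CDF is evaluated at each sample:

    z_ij = (1/n) Σ_k Φ((x_ij − x_ik) / h_i),   h_i = s_i / 4,

with *s_i* the gene's sample standard deviation (ddof = 1). This makes the
statistic invariant to positive affine transforms of each gene — genes with
different dynamic ranges land on a common (0, 1) scale. Zero-variance genes
get a constant 0.5 row and a warning rather than an error, because
degenerate columns are routine in binary-like or subsetted data.

Within each sample, genes are ranked by *z* (descending, stable tie-break
by gene order) and a weighted Kolmogorov–Smirnov-like walk is taken down
the ranked list: at a pathway member the walk rises by
|n/2 − rank|^τ normalized over members (τ = 1 by default), at a non-member
it falls by 1/(#non-members). The score is the maximal positive plus the
maximal negative deviation of the walk (`max_diff`; both capped at 0 from
the appropriate side), or the single largest-magnitude deviation
(`max_abs`). Defaults (bandwidth s/4, τ = 1, `max_diff`, minimum pathway
size 2) follow the reference single-sample enrichment method; all are
exposed in `EnrichmentConfig`. Pathways smaller than the minimum after
restriction to measured genes, or spanning the whole gene universe (the
down-step is undefined), are excluded with warnings.

**Binary mutations (log odds ratio).** Per pathway × sample, a 2×2 table
counts genes by pathway membership and mutation status over the *filtered*
gene universe (the same universe the models see, not the whole genome).
With 0.5 added to each cell (Haldane–Anscombe), the score is

    ln[ (a+0.5)(d+0.5) / ((b+0.5)(c+0.5)) ].

The correction keeps scores finite; note it makes a mutation-free sample's
score slightly positive (≈ 2.15 for a 10-of-100-gene pathway), not zero.

## Gene prefilters

* **Pathway membership** — restrict to genes occurring in at least one
  pathway, so gene- and pathway-level models draw on the same information.
* **Gene list** — optional restriction to a user-supplied cancer-gene list
  (COSMIC-style text file).
* **Univariable Cox** — keep predictors with Wald p < α (default 0.05) in a
  single-covariate Cox model (Breslow ties, Newton–Raphson with exact
  single-parameter information). No multiple-testing correction is applied;
  the raw threshold is the method's convention, and α is exposed. The
  screen is supervised, so inside cross-validation it is fit on the
  training fold only; non-converging (quasi-separated) and zero-variance
  predictors are treated as p = 1 and dropped.

## Penalized Cox models

Both penalties maximize the Breslow-ties partial likelihood minus a
penalty, by iteratively reweighted least squares: the likelihood is
expanded to second order in the linear predictor (exact gradient, diagonal
Hessian), giving a weighted least-squares working problem solved by
coordinate descent (lasso: soft-thresholding; group lasso: exact block
update via the eigendecomposition of the group's small Gram matrix and a
scalar secular-equation root). Predictors are standardized internally to
zero mean and unit variance; coefficients are reported on the original
scale. Group penalty weights are √(group size); a group is one gene or
pathway across modalities, so selection is all-in/all-out per entity.
Variables with penalty weight 0 (clinical stage indicators, one-hot with
first level dropped) are refit freely and never shrunk.

The λ grid has 100 log-spaced values from λ_max (the smallest λ with all
penalized coefficients exactly zero, computed from the null-model score)
down to λ_max·r, with r = 0.01 when n ≥ p and 0.05 otherwise. λ is chosen
by K-fold (default 10) event-stratified cross-validated held-out deviance
−2[ℓ_all(β̂_k) − ℓ_train(β̂_k)] (Verweij–van Houwelingen), by the `one_se`
rule by default (largest λ within one SE of the minimum; `min` is exposed
because either extraction is defensible).

Numerical choices: inner coordinate-descent tolerance 1e-7 on coefficient
change with an active-set strategy and KKT sweeps; outer IRLS tolerance
1e-6; CV fold fits use a looser 1e-4 / 8-outer-iteration budget since they
only trace the deviance curve, while the final model refits at full
tolerance. Samples whose IRLS curvature falls below 1e-5 get weight zero
(the working response would otherwise explode); fits whose coefficients
diverge (quasi-separation at tiny λ) are flagged non-converged rather than
iterated indefinitely; the path stops early once the selected set reaches
80% of the sample count, where the model is no longer identified —
subsequent λ entries inherit that solution. At convergence the KKT
conditions hold to ~1e-4 on the standardized scale (asserted in tests).

## Evaluation

Outer evaluation is an event-stratified 5-fold split, replicated R times
(R is not fixed by the method; the default is 10 and every result records
it). Per fold: unsupervised filters and enrichment are computed once on
the full cohort (the enrichment is sample-wise and never sees the outcome);
when the Cox screen is active, it runs on the training fold and enrichment
is recomputed for that fold's gene universe over all samples. The model is
fit on the training fold with inner 10-fold λ selection and predicts the
held-out fold. Three metrics summarize a cell:

* **Harrell's C** — comparable pairs are (i, j) with T_i < T_j and sample
  i's event observed (time-tied pairs excluded); tied risks count 1/2.
  The cell value is the unweighted mean over fold-level C's, with
  SE = SD/√(K·R). A fold with no comparable held-out pairs is flagged and
  excluded from the mean.
* **Fleiss κ** — each of the K·R trained models is a rater labelling every
  candidate variable selected/not-selected; κ is the standard
  chance-corrected agreement (κ = 1 when the chance-agreement term is 1,
  i.e. complete unanimity).
* **Average model size** — mean number of nonzero coefficients.

A fold that fails to converge or selects nothing is flagged; an
empty-selection fold still contributes its constant-risk C of 0.5. A cell
fails ("grey" in the landscape) only when all folds failed or no fold ever
selected a predictor. Cohorts in the landscape tables are ordered by mean
C, descending.

Multi-omics integration concatenates the per-modality predictor matrices
column-wise (variables suffixed `|GE`, `|CNV`, `|SPM`); standardization
inside the fitter brings the modalities to a common scale, and the shared
gene/pathway stem becomes the group label for the group lasso.

## Synthetic cohorts

The generator produces cohorts with exactly the structure the analysis
assumes, so every stage is testable without patient data. Latent pathway
activities a_Ps ~ N(0,1) drive everything: member-gene expression is
√ρ·a_Ps + √(1−ρ)·noise (so member genes share pairwise correlation ρ);
mutations are Bernoulli with logit(base rate) + a_Ps for member genes; the
true log-hazard is η_s = effect · Σ_{prognostic P} a_Ps. Copy number gets
the same block structure from an independent latent layer and therefore
carries no survival signal — it exercises the integration plumbing, not
recovery. Event times are Weibull with scale modulated by exp(η_s)
(proportional hazards); censoring is exponential with its rate calibrated
by bisection so the expected censored fraction matches the target. Genes
outside every pathway are pure noise, giving the membership filter
something to remove.

Defaults describe a mid-sized cohort: 300 samples, 50 pathways × 20 genes
plus 200 noise genes, ρ = 0.5, 5 prognostic pathways at unit effect,
Weibull scale 1095 days / shape 1.2 (≈3-year characteristic survival,
mildly increasing hazard), censoring target 0.5. Real cohorts span roughly
80–500 samples and death rates 0.02–0.75; the defaults sit mid-range.
What the generator does **not** emulate: library-size and batch effects,
CNV segmentation artifacts, mutation hotspots, non-proportional hazards,
informative censoring. Passing tests therefore demonstrate that the
pipeline recovers pathway-coherent proportional-hazards signal under clean
noise — not that any particular real cohort is predictable.

## Problem sizes used in the test suite

Tests scale the cohorts to what each property needs: recovery checks use
the full default geometry at n = 400 (20 replicates); the chance-level and
stability contrasts use compact cohorts (n = 150, 12 pathways of 6–8
genes) where the same qualitative behavior is visible; calibration
properties (censoring fraction, correlation structure) use n = 1000–2000.
These sizes are the package's choices and are stated in the tests.

## Known limitations

* Breslow tie handling only (no Efron), matching the reference Cox-path
  implementation; with heavily tied times coefficients shrink slightly.
* The log-OR mutation score uses the filtered gene universe; scores are
  not comparable across runs with different filters.
* Absolute Fleiss κ values depend on K·R and the fold seeds; only
  orderings across models are meaningful.
* The group-lasso λ grid is built from the group-level λ_max; very
  unbalanced group sizes with strong penalty-weight asymmetry are untested
  territory.
* No missing-value support: any NA input is an error by design.
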