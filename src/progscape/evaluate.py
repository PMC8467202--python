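"""Replicated nested cross-validation of prognostic models and assembly of
the cohort-by-model evaluation landscape.

For each cohort x model-descriptor cell: R replicates of an event-stratified
5-fold outer split; within every outer training fold a lasso- or
group-lasso-penalized Cox model is fit with its shrinkage chosen by an inner
10-fold CV; the fitted model predicts the held-out fold. Each cell is scored
on three axes:

* prediction — mean Harrell concordance index over the K x R held-out folds
  (SE = sample SD / sqrt(number of fold estimates));
* stability — Fleiss kappa over the K x R trained models, each model acting
  as a rater labelling every candidate variable selected / not-selected;
* parsimony — mean selected-set size.

Unsupervised steps (pathway-membership and gene-list filters, single-sample
enrichment) run once on the full cohort. When the supervised univariable-Cox
gene screen is active it runs on the training fold only, and enrichment is
recomputed for that fold's gene universe (enrichment itself never sees the
outcome, so held-out samples can be scored jointly without leakage).

A fold whose fit fails or selects nothing keeps a flag; a cell fails
("grey" in the landscape) only when every fold failed or every fold
selected zero predictors.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .enrichment import (EnrichmentConfig, gsva_enrichment, log_odds_enrichment)
from .filtering import (restrict_to_gene_list, restrict_to_pathway_genes,
                        univariable_cox_filter)
from .io import CohortBundle, OmicsMatrix, PathwayCollection, SurvivalTable
from .metrics import (average_model_size, fleiss_kappa, harrell_c,
                      selection_agreement_table)
from .penalized_cox import (FittedPenalizedCox, PredictorMatrix,
                            fit_group_lasso_cox, fit_lasso_cox,
                            predict_linear_risk)

logger = logging.getLogger(__name__)

__all__ = [
    "ModelDescriptor",
    "FoldAssignment",
    "EvaluationResult",
    "LandscapeResult",
    "integrate_modalities",
    "run_nested_cv",
    "assemble_landscape",
]


@dataclass(frozen=True)
class ModelDescriptor:
    """One model configuration: which omics, at which level, which penalty,
    which prefilters."""

    modalities: tuple[str, ...] = ("GE",)
    level: str = "gene"  # or "pathway"
    penalty: str = "lasso"  # or "group_lasso"
    cox_filter: bool = False
    gene_list: frozenset | None = None
    alpha: float = 0.05
    stage_adjust: bool = False

    def __post_init__(self) -> None:
        if self.level not in ("gene", "pathway"):
            raise ValueError(f"unknown level {self.level!r}")
        if self.penalty not in ("lasso", "group_lasso"):
            raise ValueError(f"unknown penalty {self.penalty!r}")
        if not self.modalities:
            raise ValueError("at least one modality is required")

    @property
    def label(self) -> str:
        lvl = "PLv" if self.level == "pathway" else "GLv"
        parts = [lvl, "+".join(self.modalities)]
        if self.penalty == "group_lasso":
            parts.append("grp")
        if self.gene_list is not None:
            parts.append("COSMIC")
        if self.cox_filter:
            parts.append("Cox")
        if self.stage_adjust:
            parts.append("stage")
        return "-".join(parts)


@dataclass(frozen=True)
class FoldAssignment:
    """Outer-fold labels for one replicate (event-stratified K-fold)."""

    replicate: int
    labels: np.ndarray  # per-sample fold id in 0..K-1
    seed: int

    @property
    def n_folds(self) -> int:
        return int(self.labels.max()) + 1


@dataclass
class EvaluationResult:
    """Aggregated nested-CV scores for one cohort x descriptor cell."""

    cohort: str
    descriptor: ModelDescriptor
    fold_cis: list[float | None]
    selected_sets: list[tuple[str, ...]]
    universe: tuple[str, ...]
    flags: list[str]
    seed: int
    n_replicates: int
    n_outer_folds: int

    @property
    def n_models(self) -> int:
        return len(self.selected_sets)

    @property
    def mean_ci(self) -> float:
        vals = [c for c in self.fold_cis if c is not None]
        return float(np.mean(vals)) if vals else float("nan")

    @property
    def se_ci(self) -> float:
        vals = [c for c in self.fold_cis if c is not None]
        if len(vals) < 2:
            return float("nan")
        return float(np.std(vals, ddof=1) / np.sqrt(len(vals)))

    @property
    def kappa(self) -> float:
        if len(self.selected_sets) < 2 or not self.universe:
            return float("nan")
        table = selection_agreement_table(self.selected_sets, self.universe)
        return fleiss_kappa(table)

    @property
    def avg_model_size(self) -> float:
        if not self.selected_sets:
            return float("nan")
        return average_model_size(self.selected_sets)

    @property
    def failed(self) -> bool:
        """Grey-cell semantics: every fold failed, or no fold ever selected
        a predictor."""
        if not self.selected_sets:
            return True
        return all(len(s) == 0 for s in self.selected_sets)


# ---------------------------------------------------------------------------
# predictor assembly
# ---------------------------------------------------------------------------


def integrate_modalities(matrices: Sequence[PredictorMatrix | pd.DataFrame]) -> PredictorMatrix:
    """Column-concatenate per-modality predictor matrices sharing one sample
    list. Variable names are expected to carry a ``|modality`` suffix; group
    labels are set to the shared gene/pathway stem so a downstream group
    lasso can treat one entity's modalities as a unit."""
    frames = [m.values if isinstance(m, PredictorMatrix) else m for m in matrices]
    if not frames:
        raise ValueError("no predictor matrices given")
    ref = list(frames[0].index)
    for f in frames[1:]:
        if list(f.index) != ref:
            raise ValueError("predictor matrices have mismatched sample lists")
    merged = pd.concat(frames, axis=1)
    groups = pd.Series([c.split("|")[0] for c in merged.columns],
                       index=merged.columns)
    return PredictorMatrix(merged, group_labels=groups)


def _modality_frame(matrix: OmicsMatrix, level: str,
                    pathways: PathwayCollection,
                    config: EnrichmentConfig) -> pd.DataFrame:
    """Samples x variables frame for one modality at the requested level,
    variables suffixed with the modality tag."""
    if level == "gene":
        frame = matrix.values.T.copy()
    else:
        if matrix.value_kind == "binary":
            scores = log_odds_enrichment(matrix, pathways)
        else:
            scores = gsva_enrichment(matrix, pathways, config)
        frame = scores.values.T.copy()
    frame.columns = [f"{c}|{matrix.modality}" for c in frame.columns]
    return frame


def _stage_columns(stage: pd.Series) -> pd.DataFrame:
    dummies = pd.get_dummies(stage, prefix="STAGE", drop_first=True).astype(float)
    dummies.columns = [f"{c}|clin" for c in dummies.columns]
    return dummies


def _prepare_cell_inputs(bundle: CohortBundle, descriptor: ModelDescriptor,
                         pathways: PathwayCollection,
                         config: EnrichmentConfig):
    """Apply the unsupervised filters; return per-modality gene matrices and,
    when the supervised screen is off, the precomputed predictor frames."""
    gene_mats: dict[str, OmicsMatrix] = {}
    for tag in descriptor.modalities:
        if tag not in bundle.omics:
            raise ValueError(f"cohort {bundle.name!r} has no {tag} matrix")
        m, _ = restrict_to_pathway_genes(bundle.omics[tag], pathways)
        if descriptor.gene_list is not None:
            m, _ = restrict_to_gene_list(m, descriptor.gene_list)
        gene_mats[tag] = m
    frames = None
    if not descriptor.cox_filter:
        frames = [_modality_frame(gene_mats[tag], descriptor.level, pathways,
                                  config)
                  for tag in descriptor.modalities]
    return gene_mats, frames


def _fold_assignments(survival: SurvivalTable, K: int, R: int,
                      seed: int) -> list[FoldAssignment]:
    ev = survival.event
    out = []
    for rep in range(R):
        rep_seed = int(np.random.SeedSequence([seed, rep]).generate_state(1)[0]
                       % (2**31))
        labels = None
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=K, shuffle=True,
                                  random_state=(rep_seed + attempt) % (2**31))
            lab = np.empty(len(ev), dtype=int)
            ok = True
            for k, (tr, te) in enumerate(skf.split(np.zeros(len(ev)), ev)):
                lab[te] = k
                if ev[tr].sum() < 2:
                    ok = False
            if ok:
                labels = lab
                break
        if labels is None:
            raise ValueError("could not build outer folds with >=2 training "
                             "events (too few events)")
        out.append(FoldAssignment(rep, labels, rep_seed))
    return out


def _fit_one_fold(train_frame: pd.DataFrame, surv_train: SurvivalTable,
                  descriptor: ModelDescriptor, inner_folds: int,
                  lambda_rule: str, n_lambda: int,
                  inner_seed: int,
                  penalty_weights: pd.Series | None) -> FittedPenalizedCox:
    if descriptor.penalty == "group_lasso":
        pm = integrate_modalities([train_frame])
        if penalty_weights is not None:
            pm.penalty_weights = penalty_weights.loc[pm.values.columns]
        return fit_group_lasso_cox(pm, surv_train, n_folds=inner_folds,
                                   rule=lambda_rule, seed=inner_seed,
                                   n_lambda=n_lambda)
    return fit_lasso_cox(train_frame, surv_train, n_folds=inner_folds,
                         rule=lambda_rule, seed=inner_seed, n_lambda=n_lambda,
                         penalty_weights=penalty_weights)


def run_nested_cv(
    bundle: CohortBundle,
    descriptor: ModelDescriptor,
    pathways: PathwayCollection,
    K: int = 5,
    R: int = 10,
    inner_folds: int = 10,
    lambda_rule: str = "one_se",
    n_lambda: int = 100,
    seed: int = 0,
    enrichment_config: EnrichmentConfig | None = None,
) -> EvaluationResult:
    """Evaluate one cohort x descriptor cell by replicated nested CV."""
    config = enrichment_config or EnrichmentConfig()
    surv = bundle.survival
    samples = np.asarray(bundle.samples, dtype=object)
    gene_mats, frames = _prepare_cell_inputs(bundle, descriptor, pathways,
                                             config)
    stage_frame = None
    if descriptor.stage_adjust:
        if bundle.stage is None:
            raise ValueError("stage adjustment requested but the cohort has "
                             "no stage labels")
        stage_frame = _stage_columns(bundle.stage)

    assignments = _fold_assignments(surv, K, R, seed)
    fold_cis: list[float | None] = []
    selected_sets: list[tuple[str, ...]] = []
    flags: list[str] = []
    universe: set[str] = set()
    if frames is not None:
        for f in frames:
            universe.update(f.columns)

    for fa in assignments:
        for k in range(fa.n_folds):
            te_mask = fa.labels == k
            tr_idx = samples[~te_mask]
            te_idx = samples[te_mask]
            inner_seed = int(np.random.SeedSequence(
                [seed, fa.replicate, k]).generate_state(1)[0] % (2**31))
            tag = f"rep{fa.replicate}/fold{k}"
            try:
                if frames is not None:
                    fold_frames = frames
                else:
                    fold_frames = []
                    for mtag in descriptor.modalities:
                        m = gene_mats[mtag]
                        m_tr = m.subset_samples(list(tr_idx))
                        m_f, _ = univariable_cox_filter(
                            m_tr, surv.subset(list(tr_idx)), descriptor.alpha)
                        m_all = m.subset_genes(m_f.genes)
                        fold_frames.append(_modality_frame(
                            m_all, descriptor.level, pathways, config))
                    for f in fold_frames:
                        universe.update(f.columns)
                pm = integrate_modalities(fold_frames)
                full = pm.values
                penalty_weights = None
                if stage_frame is not None:
                    full = pd.concat([full, stage_frame], axis=1)
                    penalty_weights = pd.Series(
                        [0.0 if c.endswith("|clin") else 1.0
                         for c in full.columns], index=full.columns)
                train = full.loc[list(tr_idx)]
                test = full.loc[list(te_idx)]
                fit = _fit_one_fold(train, surv.subset(list(tr_idx)),
                                    descriptor, inner_folds, lambda_rule,
                                    n_lambda, inner_seed, penalty_weights)
                risk = predict_linear_risk(fit, test)
                ci = harrell_c(risk.to_numpy(), surv.subset(list(te_idx)))
                sel = tuple(v for v in fit.selected if not v.endswith("|clin"))
                selected_sets.append(sel)
                if not sel:
                    # constant risk still has a defined (all-ties) CI of 0.5;
                    # keep it, but flag the fold for the grey-cell rule
                    flags.append(f"{tag}: empty selection")
                if ci is None:
                    flags.append(f"{tag}: no comparable pairs in test fold")
                    fold_cis.append(None)
                else:
                    fold_cis.append(float(ci))
            except Exception as exc:  # noqa: BLE001 - fold-level failure flag
                logger.warning("%s %s %s failed: %s", bundle.name,
                               descriptor.label, tag, exc)
                flags.append(f"{tag}: {exc}")
                fold_cis.append(None)

    return EvaluationResult(bundle.name, descriptor, fold_cis, selected_sets,
                            tuple(sorted(universe)), flags, seed, R, K)


# ---------------------------------------------------------------------------
# landscape
# ---------------------------------------------------------------------------


@dataclass
class LandscapeResult:
    """Aligned cohort x model tables of the three metrics (+ SE and failure
    flags). Rows are ordered by mean concordance descending, so strong
    cohorts sit at the top."""

    ci: pd.DataFrame
    ci_se: pd.DataFrame
    kappa: pd.DataFrame
    size: pd.DataFrame
    failed: pd.DataFrame
    cells: dict[tuple[str, str], EvaluationResult] = field(repr=False,
                                                           default_factory=dict)

    def to_long(self) -> pd.DataFrame:
        rows = []
        for cohort in self.ci.index:
            for model in self.ci.columns:
                res = self.cells.get((cohort, model))
                for metric, table in (("ci", self.ci), ("kappa", self.kappa),
                                      ("size", self.size)):
                    rows.append({
                        "cohort": cohort,
                        "model": model,
                        "metric": metric,
                        "value": table.loc[cohort, model],
                        "se": (self.ci_se.loc[cohort, model]
                               if metric == "ci" else np.nan),
                        "failed": bool(self.failed.loc[cohort, model]),
                        "n_models": res.n_models if res is not None else 0,
                    })
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_long().to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def assemble_landscape(cells: Sequence[EvaluationResult]) -> LandscapeResult:
    """Arrange per-cell results into the three metric tables."""
    if not cells:
        raise ValueError("at least one evaluated cell is required")
    seen = set()
    models: list[str] = []
    cohorts: list[str] = []
    for res in cells:
        key = (res.cohort, res.descriptor.label)
        if key in seen:
            raise ValueError(f"duplicate landscape cell {key}")
        seen.add(key)
        if res.descriptor.label not in models:
            models.append(res.descriptor.label)
        if res.cohort not in cohorts:
            cohorts.append(res.cohort)

    def table(getter, dtype=float):
        t = pd.DataFrame(np.nan, index=cohorts, columns=models)
        for res in cells:
            t.loc[res.cohort, res.descriptor.label] = getter(res)
        return t

    ci = table(lambda r: np.nan if r.failed else r.mean_ci)
    ci_se = table(lambda r: np.nan if r.failed else r.se_ci)
    kappa = table(lambda r: np.nan if r.failed else r.kappa)
    size = table(lambda r: np.nan if r.failed else r.avg_model_size)
    failed = table(lambda r: float(r.failed)).astype(bool)
    order = ci.mean(axis=1, skipna=True).sort_values(ascending=False,
                                                     kind="stable")
    idx = list(order.index)
    return LandscapeResult(ci.loc[idx], ci_se.loc[idx], kappa.loc[idx],
                           size.loc[idx], failed.loc[idx],
                           {(r.cohort, r.descriptor.label): r for r in cells})
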