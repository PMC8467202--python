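"""Gene prefiltering ahead of model fitting.

Three rules, composable in order:

* pathway membership — keep only genes appearing in at least one pathway of
  the collection (makes gene- and pathway-level models comparable);
* gene list — keep only genes on a user-supplied cancer-gene list
  (COSMIC-style, one symbol per line);
* univariable Cox — keep only predictors whose single-covariate Cox
  proportional-hazards Wald p-value is below ``alpha`` (default 0.05).

The first two are unsupervised and may be applied to the full cohort; the
Cox rule uses the outcome and must be fit on training samples only — the
caller is responsible for passing the training fold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

from ._cox_core import univariable_cox_scan
from .io import OmicsMatrix, PathwayCollection, SurvivalTable
from .penalized_cox import as_survival

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "restrict_to_pathway_genes",
    "restrict_to_gene_list",
    "univariable_cox_filter",
    "UnivariableCoxSelector",
]


@dataclass
class FilterReport:
    """Audit record of one filtering step."""

    rule: str  # {"pathway_membership", "gene_list", "univariable_cox"}
    genes_in: int
    genes_out: int
    retained: tuple[str, ...]
    p_values: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.genes_out != len(self.retained):
            raise ValueError("genes_out must equal the number of retained genes")


def restrict_to_pathway_genes(
    matrix: OmicsMatrix, pathways: PathwayCollection
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep genes in the union of the collection's member sets (order
    preserved); errors if nothing is retained."""
    union = pathways.gene_union()
    retained = tuple(g for g in matrix.genes if g in union)
    if not retained:
        raise ValueError("no matrix gene appears in any pathway")
    out = matrix.subset_genes(retained)
    report = FilterReport("pathway_membership", len(matrix.genes),
                          len(retained), retained)
    logger.info("pathway filter: %d -> %d genes", report.genes_in, report.genes_out)
    return out, report


def restrict_to_gene_list(
    matrix: OmicsMatrix, gene_list
) -> tuple[OmicsMatrix, FilterReport]:
    """Keep genes on a plain gene list (COSMIC-style); order preserved."""
    wanted = set(gene_list)
    retained = tuple(g for g in matrix.genes if g in wanted)
    if not retained:
        raise ValueError("no matrix gene appears on the gene list")
    out = matrix.subset_genes(retained)
    report = FilterReport("gene_list", len(matrix.genes), len(retained), retained)
    logger.info("gene-list filter: %d -> %d genes", report.genes_in, report.genes_out)
    return out, report


def univariable_cox_filter(
    predictors, survival: SurvivalTable, alpha: float = 0.05
):
    """Keep predictors with univariable Cox Wald p < alpha.

    ``predictors`` may be an OmicsMatrix / PathwayScoreMatrix (features as
    rows) or a samples-by-features DataFrame. Zero-variance and
    non-converging predictors are excluded (treated as p = 1). Returns the
    filtered object (same type) and a FilterReport carrying per-feature
    p-values. No multiple-testing correction is applied: the raw threshold
    is the method's published convention.
    """
    surv = as_survival(survival)
    if isinstance(predictors, OmicsMatrix):
        frame = predictors.values.T  # samples x features
    elif hasattr(predictors, "values") and hasattr(predictors, "pathways"):
        frame = predictors.values.T  # PathwayScoreMatrix
    else:
        frame = predictors if isinstance(predictors, pd.DataFrame) \
            else pd.DataFrame(predictors)
    if list(frame.index) != surv.samples and frame.shape[0] != len(surv.data):
        raise ValueError("predictors and survival have different samples")
    X = frame.to_numpy(dtype=float)
    _, _, pvals, ok = univariable_cox_scan(X, surv.time, surv.event)
    n_bad = int((~ok).sum())
    if n_bad:
        logger.info("univariable Cox: %d predictor(s) non-converged or "
                    "degenerate, excluded", n_bad)
    keep = pvals < alpha
    retained = tuple(np.asarray(frame.columns, dtype=object)[keep])
    pv = pd.Series(pvals, index=frame.columns, name="p_value")
    report = FilterReport("univariable_cox", frame.shape[1], len(retained),
                          retained, pv)
    if isinstance(predictors, OmicsMatrix):
        if not retained:
            raise ValueError("univariable Cox filter retained no genes")
        return predictors.subset_genes(retained), report
    if hasattr(predictors, "pathways"):
        from .enrichment import PathwayScoreMatrix

        if not retained:
            raise ValueError("univariable Cox filter retained no pathways")
        return (PathwayScoreMatrix(predictors.values.loc[list(retained)],
                                   predictors.provenance, predictors.modality),
                report)
    return frame.loc[:, list(retained)], report


class UnivariableCoxSelector(SelectorMixin, BaseEstimator):
    """scikit-learn feature selector: keep features whose univariable Cox
    Wald p-value on the training data is below ``alpha``.

    X is samples-by-features; y is anything :func:`as_survival` accepts.
    Fitted attributes: ``p_values_``, ``support_``.
    """

    def __init__(self, alpha: float = 0.05):
        self.alpha = alpha

    def fit(self, X, y):
        surv = as_survival(y)
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(np.asarray(X, float))
        if df.shape[0] != len(surv.data):
            raise ValueError("X rows and survival records differ in length")
        _, _, pvals, _ = univariable_cox_scan(df.to_numpy(dtype=float),
                                              surv.time, surv.event)
        self.p_values_ = pvals
        self.support_ = pvals < self.alpha
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        return self

    def _get_support_mask(self):
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "support_")
        return self.support_
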