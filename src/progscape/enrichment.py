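"""Single-sample pathway scoring: turn gene-by-sample matrices into
pathway-by-sample score matrices.

Continuous modalities (expression, copy number, methylation) are scored by
a GSVA-style statistic: each gene's profile is first mapped through a
Gaussian-kernel estimate of its own cumulative distribution (bandwidth
s_i / kernel_bandwidth_factor), which brings genes with different dynamic
ranges to a common (0, 1) scale; genes are then ranked within each sample
and a weighted Kolmogorov-Smirnov-like random walk over the ranked list
yields one enrichment score per (pathway, sample).

The binary mutation modality is scored per (pathway, sample) as the log
odds ratio of a 2x2 gene count table (mutated x in-pathway) over the
filtered gene universe, with 0.5 added to every cell (Haldane-Anscombe
correction) so the score is always finite. Note the correction makes the
score of a mutation-free sample slightly positive, not zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr
from sklearn.base import BaseEstimator, TransformerMixin

from .io import OmicsMatrix, PathwayCollection

try:  # numba fast path for the O(genes * n^2) kernel CDF
    import math

    from numba import njit

    @njit(cache=False)
    def _kcdf_kernel(X, h, Z):  # pragma: no cover - numerically identical
        g, n = X.shape
        inv = 1.0 / n
        sqrt2 = 1.4142135623730951
        for i in range(g):
            hi = h[i]
            for j in range(n):
                s = 0.0
                xj = X[i, j]
                for k in range(n):
                    s += 0.5 * (1.0 + math.erf((xj - X[i, k]) / (hi * sqrt2)))
                Z[i, j] = s * inv

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

__all__ = [
    "EnrichmentConfig",
    "PathwayScoreMatrix",
    "kernel_cdf_transform",
    "gsva_enrichment",
    "log_odds_enrichment",
    "GSVAScorer",
    "LogOddsScorer",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Tunables of the GSVA-style statistic (defaults match the reference
    single-sample enrichment method: Gaussian kernel with bandwidth s/4,
    rank weight exponent tau=1, signed max-deviation-difference score)."""

    kernel_bandwidth_factor: float = 4.0
    tau: float = 1.0
    statistic_mode: str = "max_diff"  # or "max_abs"
    min_pathway_size: int = 2

    def __post_init__(self) -> None:
        if self.kernel_bandwidth_factor <= 0:
            raise ValueError("kernel_bandwidth_factor must be positive")
        if self.tau < 0:
            raise ValueError("tau must be nonnegative")
        if self.statistic_mode not in ("max_diff", "max_abs"):
            raise ValueError(f"unknown statistic mode {self.statistic_mode!r}")
        if self.min_pathway_size < 1:
            raise ValueError("min_pathway_size must be >= 1")


@dataclass
class PathwayScoreMatrix:
    """Pathway-by-sample score grid with provenance."""

    values: pd.DataFrame  # pathways x samples
    provenance: str  # {"gsva", "log_odds"}
    modality: str

    @property
    def pathways(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path) -> None:
        df = self.values.copy()
        df.index.name = "pathway"
        df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# kernel CDF
# ---------------------------------------------------------------------------


def kernel_cdf_transform(matrix, config: EnrichmentConfig | None = None) -> pd.DataFrame:
    """Gene-wise Gaussian-kernel CDF estimate, evaluated at each sample.

    z_ij = (1/n) sum_k Phi((x_ij - x_ik) / h_i), h_i = s_i / factor with s_i
    the gene's sample standard deviation (ddof=1). Zero-variance genes are
    mapped to a constant 0.5 row with a warning. Output lies in (0, 1) and
    is invariant to positive affine transforms of each gene's values.
    """
    config = config or EnrichmentConfig()
    df = matrix.values if isinstance(matrix, OmicsMatrix) else matrix
    X = df.to_numpy(dtype=float)
    g, n = X.shape
    if n < 2:
        raise ValueError("kernel CDF needs at least 2 samples")
    s = X.std(axis=1, ddof=1)
    flat = s == 0.0
    if flat.any():
        warnings.warn(f"{int(flat.sum())} zero-variance gene(s) set to constant 0.5",
                      stacklevel=2)
    h = np.where(flat, 1.0, s / config.kernel_bandwidth_factor)
    Z = np.empty_like(X)
    if _HAVE_NUMBA:
        _kcdf_kernel(np.ascontiguousarray(X), h, Z)
    else:
        # chunk the (genes, n, n) pairwise-difference tensor to bound memory
        chunk = max(1, int(2**24 // max(n * n, 1)))
        for lo in range(0, g, chunk):
            hi = min(lo + chunk, g)
            diff = (X[lo:hi, :, None] - X[lo:hi, None, :]) / h[lo:hi, None, None]
            Z[lo:hi] = ndtr(diff).mean(axis=2)
    Z[flat] = 0.5
    return pd.DataFrame(Z, index=df.index, columns=df.columns)


# ---------------------------------------------------------------------------
# random walk
# ---------------------------------------------------------------------------


def _walk_scores(Z: np.ndarray, member: np.ndarray, tau: float, mode: str) -> np.ndarray:
    """Enrichment score per sample for one pathway.

    Z: (genes, samples) kernel-CDF values; member: boolean gene mask.
    Per sample: rank genes by Z descending (rank 1 = highest), form the
    symmetric rank statistic r = |n_genes/2 - rank|, then walk the ranked
    list stepping up |r|^tau (normalized over members) at member genes and
    down 1/(#non-members) otherwise. Score combines the maximal positive
    and negative deviations of the walk.
    """
    g, n = Z.shape
    n_mem = int(member.sum())
    if n_mem == 0 or n_mem == g:
        raise ValueError("pathway must be a proper nonempty subset of the universe")
    order = np.argsort(-Z, axis=0, kind="stable")  # walk order per sample
    ranks = np.empty_like(order)
    cols = np.arange(n)
    ranks[order, cols] = np.arange(1, g + 1)[:, None]
    r = np.abs(g / 2.0 - ranks) ** tau  # (genes, samples)
    member_in_order = member[order]  # (genes, samples)
    r_in_order = np.take_along_axis(r, order, axis=0)
    up = np.where(member_in_order, r_in_order, 0.0)
    denom_up = up.sum(axis=0)
    denom_up[denom_up == 0.0] = 1.0  # tau=0-safe; members all weight 0
    steps = np.where(member_in_order, up / denom_up, -1.0 / (g - n_mem))
    walk = np.cumsum(steps, axis=0)
    pos = np.maximum(walk.max(axis=0), 0.0)
    neg = np.minimum(walk.min(axis=0), 0.0)
    if mode == "max_diff":
        return pos + neg
    return np.where(pos > -neg, pos, neg)


def gsva_enrichment(
    matrix: OmicsMatrix,
    pathways: PathwayCollection,
    config: EnrichmentConfig | None = None,
) -> PathwayScoreMatrix:
    """GSVA-style enrichment of a continuous gene-by-sample matrix.

    Pathways are restricted to genes present in the matrix; pathways smaller
    than ``min_pathway_size`` or equal to the whole gene universe are
    excluded with a warning (the down-step is undefined for the latter).
    """
    config = config or EnrichmentConfig()
    Z = kernel_cdf_transform(matrix, config).to_numpy()
    genes = matrix.genes
    gene_pos = {g: i for i, g in enumerate(genes)}
    restricted = pathways.restrict_to(genes)
    rows, names = [], []
    for name in restricted.names:
        members = restricted[name]
        if len(members) < config.min_pathway_size:
            warnings.warn(f"pathway {name!r} below min size after gene "
                          "restriction; excluded", stacklevel=2)
            continue
        if len(members) >= len(genes):
            warnings.warn(f"pathway {name!r} spans the whole gene universe; "
                          "excluded", stacklevel=2)
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[[gene_pos[g] for g in members]] = True
        rows.append(_walk_scores(Z, mask, config.tau, config.statistic_mode))
        names.append(name)
    if not rows:
        raise ValueError("no pathway passed the size filters")
    values = pd.DataFrame(np.vstack(rows), index=pd.Index(names, name="pathway"),
                          columns=matrix.samples)
    return PathwayScoreMatrix(values, "gsva", matrix.modality)


def log_odds_enrichment(
    matrix: OmicsMatrix, pathways: PathwayCollection
) -> PathwayScoreMatrix:
    """Haldane-Anscombe-corrected log odds ratio pathway scores for a binary
    mutation matrix: per (pathway, sample),
    ln(((a+0.5)(d+0.5)) / ((b+0.5)(c+0.5))) over the 2x2 table of gene
    counts (in/out of pathway x mutated/not) on the matrix's gene universe."""
    if matrix.value_kind != "binary":
        raise ValueError("log-odds enrichment requires a binary matrix")
    genes = matrix.genes
    n_genes = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}
    restricted = pathways.restrict_to(genes)
    if not restricted.names:
        raise ValueError("no pathway overlaps the gene universe")
    M = np.zeros((len(restricted.names), n_genes))
    for pi, name in enumerate(restricted.names):
        M[pi, [gene_pos[g] for g in restricted[name]]] = 1.0
    X = matrix.values.to_numpy(dtype=float)  # genes x samples
    a = M @ X
    size = M.sum(axis=1, keepdims=True)
    mutated = X.sum(axis=0, keepdims=True)
    b = size - a
    c = mutated - a
    d = n_genes - size - c
    score = np.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    values = pd.DataFrame(score, index=pd.Index(restricted.names, name="pathway"),
                          columns=matrix.samples)
    return PathwayScoreMatrix(values, "log_odds", matrix.modality)


# ---------------------------------------------------------------------------
# scikit-learn transformers (X oriented samples x genes)
# ---------------------------------------------------------------------------


class GSVAScorer(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`gsva_enrichment` for samples-by-genes
    frames; stateless apart from parameter validation (the statistic is
    unsupervised and sample-wise)."""

    def __init__(self, gene_sets=None, kernel_bandwidth_factor=4.0, tau=1.0,
                 statistic_mode="max_diff", min_pathway_size=2,
                 modality="GE"):
        self.gene_sets = gene_sets
        self.kernel_bandwidth_factor = kernel_bandwidth_factor
        self.tau = tau
        self.statistic_mode = statistic_mode
        self.min_pathway_size = min_pathway_size
        self.modality = modality

    def _collection(self) -> PathwayCollection:
        if isinstance(self.gene_sets, PathwayCollection):
            return self.gene_sets
        if isinstance(self.gene_sets, dict):
            return PathwayCollection(list(self.gene_sets),
                                     {k: tuple(v) for k, v in self.gene_sets.items()})
        raise ValueError("gene_sets must be a PathwayCollection or a dict")

    def _config(self) -> EnrichmentConfig:
        return EnrichmentConfig(self.kernel_bandwidth_factor, self.tau,
                                self.statistic_mode, self.min_pathway_size)

    def fit(self, X, y=None):
        self._config()
        self._collection()
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        om = OmicsMatrix(df.T, self.modality, "continuous")
        return gsva_enrichment(om, self._collection(), self._config()).values.T

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)


class LogOddsScorer(BaseEstimator, TransformerMixin):
    """Transformer wrapping :func:`log_odds_enrichment` for samples-by-genes
    binary frames."""

    def __init__(self, gene_sets=None, modality="SPM"):
        self.gene_sets = gene_sets
        self.modality = modality

    def fit(self, X, y=None):
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        return self

    def transform(self, X) -> pd.DataFrame:
        df = X if isinstance(X, pd.DataFrame) else pd.DataFrame(X)
        gs = self.gene_sets
        if isinstance(gs, dict):
            gs = PathwayCollection(list(gs), {k: tuple(v) for k, v in gs.items()})
        om = OmicsMatrix(df.T, self.modality, "binary")
        return log_odds_enrichment(om, gs).values.T

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
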