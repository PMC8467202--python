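"""Penalized Cox proportional-hazards estimation.

Two penalties are provided, both solved by iteratively reweighted least
squares (a quadratic expansion of the Breslow partial likelihood around the
current linear predictor) with coordinate descent on the working problem:

* **Lasso** (L1): per-variable soft-thresholding along a decreasing
  log-spaced lambda grid starting at lambda_max (the smallest lambda at
  which every penalized coefficient is exactly zero), with warm starts.
* **Group lasso**: block soft-thresholding on the Euclidean norm of each
  group's coefficients with the conventional sqrt(group size) weight, so a
  group (e.g. one gene's GE/CNV/SPM columns) is selected or dropped as a
  unit.

Predictors are standardized internally to zero mean / unit variance;
coefficients are reported on the original scale. The shrinkage value is
chosen by K-fold cross-validated held-out partial-likelihood deviance
(Verweij-van Houwelingen form), using either the deviance-minimizing lambda
(``min``) or the largest lambda within one standard error of it
(``one_se``, the default). Variables with penalty weight 0 (e.g. clinical
stage indicators) are always refit freely and never shrunk.

The scikit-learn estimators :class:`CoxLassoCV` and :class:`CoxGroupLassoCV`
are the primary interface; :func:`fit_lasso_cox_path`,
:func:`cv_select_lambda`, :func:`fit_lasso_cox` and
:func:`fit_group_lasso_cox` are thin wrappers around the same solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from ._cox_core import SurvivalOrder, breslow_grad_hess, breslow_loglik
from .io import SurvivalTable

__all__ = [
    "PredictorMatrix",
    "FittedPenalizedCox",
    "LambdaPath",
    "CoxLassoCV",
    "CoxGroupLassoCV",
    "cox_partial_loglik",
    "fit_lasso_cox_path",
    "cv_select_lambda",
    "fit_lasso_cox",
    "fit_group_lasso_cox",
    "predict_linear_risk",
    "kkt_max_violation",
]

# IRLS weight floor: samples with (near-)zero curvature get weight 0 rather
# than an exploding working response g/h
_W_EPS = 1e-5

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PredictorMatrix:
    """Samples-by-variables design matrix with optional group labels and
    per-variable penalty weights (0 = never shrunk)."""

    values: pd.DataFrame  # samples x variables
    group_labels: pd.Series | None = None  # index = variables
    penalty_weights: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate variable names")
        if self.values.index.has_duplicates:
            raise ValueError("duplicate sample identifiers")
        if self.group_labels is not None:
            missing = set(self.values.columns) - set(self.group_labels.index)
            if missing:
                raise ValueError(f"variables without group label: {sorted(missing)[:5]}")
            self.group_labels = self.group_labels.loc[self.values.columns]
        if self.penalty_weights is not None:
            self.penalty_weights = self.penalty_weights.loc[self.values.columns]

    @property
    def variables(self) -> list[str]:
        return list(self.values.columns)

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    def subset_samples(self, samples: Sequence[str]) -> "PredictorMatrix":
        return PredictorMatrix(self.values.loc[list(samples)], self.group_labels,
                               self.penalty_weights)


@dataclass
class FittedPenalizedCox:
    """One trained penalized Cox model (coefficients on the original scale)."""

    beta: pd.Series
    lambda_: float
    penalty_kind: str  # {"lasso", "group_lasso"}
    center: pd.Series
    scale: pd.Series
    lambda_rule: str = "one_se"
    seed: int | None = None
    converged: bool = True

    @property
    def selected(self) -> tuple[str, ...]:
        return tuple(self.beta.index[self.beta.to_numpy() != 0.0])

    @property
    def model_size(self) -> int:
        return len(self.selected)

    def to_table(self, path: str | Path) -> None:
        """Serialize as a plain-text coefficient table with a metadata header."""
        with open(path, "w") as fh:
            fh.write(f"# penalty_kind\t{self.penalty_kind}\n")
            fh.write(f"# lambda\t{self.lambda_:.10g}\n")
            fh.write(f"# lambda_rule\t{self.lambda_rule}\n")
            fh.write(f"# seed\t{'' if self.seed is None else self.seed}\n")
            fh.write("variable\tcoefficient\tcenter\tscale\n")
            for v in self.beta.index:
                fh.write(f"{v}\t{self.beta[v]:.10g}\t{self.center[v]:.10g}"
                         f"\t{self.scale[v]:.10g}\n")

    @classmethod
    def from_table(cls, path: str | Path) -> "FittedPenalizedCox":
        meta: dict[str, str] = {}
        rows = []
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, val = line[1:].strip().partition("\t")
                    meta[key.strip()] = val.strip()
                elif line.strip() and not line.startswith("variable\t"):
                    rows.append(line.rstrip("\n").split("\t"))
        beta = pd.Series({r[0]: float(r[1]) for r in rows})
        center = pd.Series({r[0]: float(r[2]) for r in rows})
        scale = pd.Series({r[0]: float(r[3]) for r in rows})
        seed = int(meta["seed"]) if meta.get("seed") else None
        return cls(beta, float(meta["lambda"]), meta["penalty_kind"], center, scale,
                   meta.get("lambda_rule", "one_se"), seed)


@dataclass
class LambdaPath:
    """A decreasing lambda grid with per-lambda coefficients (original scale)
    and, once CV has been run, held-out deviance summaries."""

    lambdas: np.ndarray
    betas: pd.DataFrame  # n_lambda x n_variables
    converged: np.ndarray
    lambda_max: float
    cv_deviance_mean: np.ndarray | None = None
    cv_deviance_se: np.ndarray | None = None
    center: pd.Series | None = None
    scale: pd.Series | None = None
    penalty_kind: str = "lasso"
    group_labels: pd.Series | None = field(default=None, repr=False)
    penalty_weights: pd.Series | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# input coercion
# ---------------------------------------------------------------------------


def as_survival(y) -> SurvivalTable:
    """Coerce y to a SurvivalTable: accepts SurvivalTable, a structured array
    with (event, time) fields, or an (n, 2) array / DataFrame of time, event."""
    if isinstance(y, SurvivalTable):
        return y
    if isinstance(y, np.ndarray) and y.dtype.names:
        names = set(y.dtype.names)
        tkey = "time" if "time" in names else sorted(names - {"event"})[0]
        ekey = "event" if "event" in names else sorted(names - {tkey})[0]
        df = pd.DataFrame({"time": y[tkey].astype(float),
                           "event": y[ekey].astype(float)})
        df.index = [f"s{i}" for i in range(len(df))]
        return SurvivalTable(df)
    if isinstance(y, pd.DataFrame):
        return SurvivalTable(y[["time", "event"]].astype(float))
    arr = np.asarray(y, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("y must be (time, event) pairs or a SurvivalTable")
    df = pd.DataFrame(arr, columns=["time", "event"])
    df.index = [f"s{i}" for i in range(len(df))]
    return SurvivalTable(df)


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, PredictorMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    arr = np.asarray(X, dtype=float)
    return pd.DataFrame(arr, columns=[f"x{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# solver internals (standardized X, sorted by time)
# ---------------------------------------------------------------------------


@njit(cache=False)
def _cd_passes(X, w, r, beta, xwx, thr, active, tol, max_pass):  # pragma: no cover
    n = X.shape[0]
    maxd = 0.0
    for _ in range(max_pass):
        maxd = 0.0
        for a in range(active.shape[0]):
            j = active[a]
            if xwx[j] <= 1e-12:
                continue
            u = 0.0
            for i in range(n):
                u += w[i] * X[i, j] * r[i]
            u = u / n + xwx[j] * beta[j]
            if thr[j] > 0.0:
                if u > thr[j]:
                    new = (u - thr[j]) / xwx[j]
                elif u < -thr[j]:
                    new = (u + thr[j]) / xwx[j]
                else:
                    new = 0.0
            else:
                new = u / xwx[j]
            d = new - beta[j]
            if d != 0.0:
                for i in range(n):
                    r[i] -= X[i, j] * d
                beta[j] = new
            ad = abs(d)
            if ad > maxd:
                maxd = ad
        if maxd < tol:
            break
    return maxd


def _cd_passes_py(X, w, r, beta, xwx, thr, active, tol, max_pass):
    n = X.shape[0]
    maxd = 0.0
    for _ in range(max_pass):
        maxd = 0.0
        for j in active:
            if xwx[j] <= 1e-12:
                continue
            u = (w * X[:, j]) @ r / n + xwx[j] * beta[j]
            if thr[j] > 0.0:
                new = np.sign(u) * max(abs(u) - thr[j], 0.0) / xwx[j]
            else:
                new = u / xwx[j]
            d = new - beta[j]
            if d != 0.0:
                r -= X[:, j] * d
                beta[j] = new
            maxd = max(maxd, abs(d))
        if maxd < tol:
            break
    return maxd


_cd = _cd_passes if _HAVE_NUMBA else _cd_passes_py


def _irls_lasso_at_lambda(X, so, beta, lam, pen_w, tol, max_passes,
                          ever_active, max_outer=30):
    """Solve one lambda of the L1 path; beta modified in place (standardized
    scale). Returns True on convergence."""
    n, p = X.shape
    otol = max(tol * 100, 1e-6)  # outer quadratic-approximation loop
    inner_passes = int(min(max_passes, 200))
    for _ in range(max_outer):
        beta_old = beta.copy()
        eta = X @ beta
        _, g, h = breslow_grad_hess(eta, so)
        w = np.where(h > _W_EPS, h, 0.0)
        r = np.where(w > 0.0, g / np.maximum(w, _W_EPS), 0.0)
        xwx = (w @ (X * X)) / n
        thr = lam * pen_w
        # active-set CD with full KKT sweeps to admit violators
        for _sweep in range(100):
            active = np.flatnonzero(ever_active | (beta != 0.0) | (pen_w == 0.0))
            _cd(X, w, r, beta, xwx, thr, active, tol, inner_passes)
            u = (w * r) @ X / n + xwx * beta
            viol = (beta == 0.0) & (pen_w > 0.0) & (np.abs(u) > thr + 1e-12)
            if not viol.any():
                break
            ever_active |= viol
        ever_active |= beta != 0.0
        if not np.all(np.isfinite(beta)) or \
                np.max(np.abs(beta), initial=0.0) > 1e5:
            return False  # diverging (quasi-separated) fit: flag, don't spin
        if np.max(np.abs(beta - beta_old), initial=0.0) < otol:
            return True
    return False


def _lambda_grid(lambda_max, n_lambda, ratio):
    return np.exp(np.linspace(np.log(lambda_max), np.log(lambda_max * ratio), n_lambda))


def _null_eta(X, so, pen_w, tol, max_passes):
    """Linear predictor with only unpenalized variables fit (zeros if none)."""
    beta = np.zeros(X.shape[1])
    free = np.flatnonzero(pen_w == 0.0)
    if free.size:
        for _ in range(50):
            beta_old = beta.copy()
            eta = X @ beta
            _, g, h = breslow_grad_hess(eta, so)
            w = np.where(h > _W_EPS, h, 0.0)
            r = np.where(w > 0.0, g / np.maximum(w, _W_EPS), 0.0)
            xwx = (w @ (X * X)) / X.shape[0]
            _cd(X, w, r, beta, xwx, np.zeros_like(beta), free, tol,
                int(min(max_passes, 1000)))
            if np.max(np.abs(beta - beta_old), initial=0.0) < max(tol, 1e-9):
                break
    return beta


def _fit_lasso_path_std(X, so, pen_w, n_lambda, ratio, tol, max_passes,
                        lambdas=None, max_outer=30):
    """Core L1 path solver on standardized, time-sorted X."""
    n, p = X.shape
    beta = _null_eta(X, so, pen_w, tol, max_passes)
    eta = X @ beta
    _, g, _ = breslow_grad_hess(eta, so)
    score = np.abs(g @ X) / n
    pen_mask = pen_w > 0.0
    lambda_max = float(np.max(score[pen_mask] / pen_w[pen_mask])) if pen_mask.any() else 1.0
    lambda_max = max(lambda_max, 1e-10)
    if lambdas is None:
        lambdas = _lambda_grid(lambda_max, n_lambda, ratio)
    betas = np.zeros((len(lambdas), p))
    conv = np.zeros(len(lambdas), dtype=bool)
    ever_active = np.zeros(p, dtype=bool)
    # saturation guard: once the model grows close to n the fit is no longer
    # identified and the remaining (smaller) lambdas inherit this solution
    df_max = max(3, int(0.8 * n))
    for li, lam in enumerate(lambdas):
        conv[li] = _irls_lasso_at_lambda(X, so, beta, lam, pen_w, tol,
                                         max_passes, ever_active,
                                         max_outer=max_outer)
        betas[li] = beta
        if int((beta != 0.0).sum()) >= df_max:
            betas[li + 1:] = beta
            conv[li + 1:] = conv[li]
            break
    return np.asarray(lambdas), betas, conv, lambda_max


# ---- group lasso ----------------------------------------------------------


def _group_solution(eig, Q, b, lam_g, out):
    """Solve min 0.5 x'Ax - b.x + lam_g ||x|| for one group exactly given
    A = Q diag(eig) Q'; scalar fixed-point root on the solution norm."""
    nb = float(np.linalg.norm(b))
    if nb <= lam_g + 1e-15:
        out[:] = 0.0
        return
    c = Q.T @ b
    # the solution norm nu solves the secular equation
    # m(nu) = sum_k c_k^2 / (eig_k nu + lam_g)^2 = 1, m decreasing convex,
    # m(0) = ||b||^2/lam_g^2 > 1; Newton from 0 converges monotonically
    ck2 = [float(v) * float(v) for v in c]
    ev = [float(v) for v in eig]
    nu = 0.0
    for _ in range(100):
        m = 0.0
        mp = 0.0
        for k in range(len(ck2)):
            den = ev[k] * nu + lam_g
            q = ck2[k] / (den * den)
            m += q
            mp -= 2.0 * q * ev[k] / den
        diff = m - 1.0
        if abs(diff) < 1e-11 or mp == 0.0:
            break
        nu = nu - diff / mp
    out[:] = Q @ (c * nu / (eig * nu + lam_g))


def _irls_group_at_lambda(X, so, beta, lam, group_idx, group_mult, free_idx,
                          tol, ever_active, max_outer=50):
    """One lambda of the group-lasso path. group_idx: list of index arrays;
    group_mult: per-group penalty multiplier (sqrt group size);
    ever_active: persistent boolean per-group active mask (warm started)."""
    n = X.shape[0]
    n_grp = len(group_idx)
    otol = max(tol * 100, 1e-6)
    gtol = max(tol * 10, 1e-8)
    for _ in range(max_outer):
        beta_old = beta.copy()
        eta = X @ beta
        _, g, h = breslow_grad_hess(eta, so)
        w = np.where(h > _W_EPS, h, 0.0)
        r = np.where(w > 0.0, g / np.maximum(w, _W_EPS), 0.0)
        if free_idx.size:
            xwx = (w @ (X * X)) / n
            _cd(X, w, r, beta, xwx, np.zeros(X.shape[1]), free_idx, tol, 1000)
        # per-outer precomputation: A_g and its eigendecomposition are fixed
        sw = np.sqrt(w)
        Xw = X * sw[:, None]
        As, eigs, Qs = [], [], []
        for idx in group_idx:
            A = (Xw[:, idx].T @ Xw[:, idx]) / n
            ev, Q = np.linalg.eigh(A)
            As.append(A)
            eigs.append(np.maximum(ev, 1e-10))
            Qs.append(Q)
        for _sweep in range(50):
            for _pass in range(1000):
                maxd = 0.0
                for gi in np.flatnonzero(ever_active):
                    idx = group_idx[gi]
                    Xg = X[:, idx]
                    bg = beta[idx]
                    b = (w * r) @ Xg / n + As[gi] @ bg
                    new = np.empty_like(bg)
                    _group_solution(eigs[gi], Qs[gi], b, lam * group_mult[gi],
                                    new)
                    d = new - bg
                    if np.any(d != 0.0):
                        r -= Xg @ d
                        beta[idx] = new
                        md = float(np.max(np.abs(d)))
                        if md > maxd:
                            maxd = md
                if maxd < gtol:
                    break
            # KKT sweep over inactive groups: activate violators
            u = (w * r) @ X / n
            changed = False
            for gi in np.flatnonzero(~ever_active):
                idx = group_idx[gi]
                if np.linalg.norm(u[idx] + As[gi] @ beta[idx]) > \
                        lam * group_mult[gi] + 1e-12:
                    ever_active[gi] = True
                    changed = True
            if not changed:
                break
        for gi in range(n_grp):
            if np.any(beta[group_idx[gi]] != 0.0):
                ever_active[gi] = True
        if not np.all(np.isfinite(beta)) or \
                np.max(np.abs(beta), initial=0.0) > 1e5:
            return False
        if np.max(np.abs(beta - beta_old), initial=0.0) < otol:
            return True
    return False


def _fit_group_path_std(X, so, groups, pen_w, n_lambda, ratio, tol,
                        lambdas=None):
    n, p = X.shape
    codes, _ = pd.factorize(groups)
    free_idx = np.flatnonzero(pen_w == 0.0)
    group_idx = [np.flatnonzero((codes == k) & (pen_w > 0.0))
                 for k in range(codes.max() + 1)]
    group_idx = [ix for ix in group_idx if ix.size]
    group_mult = np.array([np.sqrt(ix.size) for ix in group_idx])
    beta = _null_eta(X, so, pen_w, tol, 1000)
    eta = X @ beta
    _, g, _ = breslow_grad_hess(eta, so)
    norms = np.array([np.linalg.norm(g @ X[:, ix]) / n for ix in group_idx])
    lambda_max = float(np.max(norms / group_mult)) if len(group_idx) else 1.0
    lambda_max = max(lambda_max, 1e-10)
    if lambdas is None:
        lambdas = _lambda_grid(lambda_max, n_lambda, ratio)
    betas = np.zeros((len(lambdas), p))
    conv = np.zeros(len(lambdas), dtype=bool)
    ever_active = np.zeros(len(group_idx), dtype=bool)
    df_max = max(3, int(0.8 * n))
    for li, lam in enumerate(lambdas):
        conv[li] = _irls_group_at_lambda(X, so, beta, lam, group_idx,
                                         group_mult, free_idx, tol,
                                         ever_active)
        # enforce the all-in/all-out structure exactly in the reported set
        for ix in group_idx:
            if np.linalg.norm(beta[ix]) == 0.0:
                beta[ix] = 0.0
        betas[li] = beta
        if int((beta != 0.0).sum()) >= df_max:
            betas[li + 1:] = beta
            conv[li + 1:] = conv[li]
            break
    return np.asarray(lambdas), betas, conv, lambda_max


# ---------------------------------------------------------------------------
# standardization + path on user-facing frames
# ---------------------------------------------------------------------------


def _standardize(df: pd.DataFrame):
    arr = df.to_numpy(dtype=float)
    center = arr.mean(axis=0)
    scale = arr.std(axis=0)  # population sd, matching glmnet
    keep = scale > 0.0
    if not keep.all():
        dropped = list(df.columns[~keep])
        warnings.warn(f"dropping {len(dropped)} zero-variance variable(s): "
                      f"{dropped[:5]}", stacklevel=3)
    Xs = (arr[:, keep] - center[keep]) / scale[keep]
    return Xs, center, scale, keep


def _prepare(X, survival: SurvivalTable, penalty_weights=None):
    df = _as_frame(X)
    if isinstance(X, PredictorMatrix) and penalty_weights is None and \
            X.penalty_weights is not None:
        penalty_weights = X.penalty_weights
    surv = as_survival(survival)
    if df.shape[0] != len(surv.data):
        raise ValueError("predictor rows and survival records differ in length")
    if surv.n_events < 2:
        raise ValueError("at least 2 observed events are required")
    Xs, center, scale, keep = _standardize(df)
    so = SurvivalOrder.from_arrays(surv.time, surv.event)
    Xs = Xs[so.order]
    if penalty_weights is None:
        pen_w = np.ones(int(keep.sum()))
    else:
        pen_w = pd.Series(penalty_weights).loc[df.columns].to_numpy(dtype=float)[keep]
    return df, surv, Xs, so, center, scale, keep, pen_w


def _auto_ratio(n, p):
    return 0.01 if n >= p else 0.05


def _betas_to_original(betas_std, keep, scale, columns, lambdas):
    full = np.zeros((betas_std.shape[0], len(columns)))
    full[:, np.flatnonzero(keep)] = betas_std / scale[keep]
    return pd.DataFrame(full, columns=columns,
                        index=pd.Index(lambdas, name="lambda"))


def fit_lasso_cox_path(
    X,
    survival: SurvivalTable,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    penalty_weights=None,
    tol: float = 1e-7,
    max_passes: int = 100_000,
) -> LambdaPath:
    """Fit the full L1-penalized Cox coefficient path.

    The grid is log-spaced over [lambda_max * ratio, lambda_max] with
    ``ratio`` defaulting to 0.01 when n >= p and 0.05 otherwise.
    """
    df, surv, Xs, so, center, scale, keep, pen_w = _prepare(X, survival,
                                                            penalty_weights)
    ratio = lambda_min_ratio if lambda_min_ratio is not None else \
        _auto_ratio(*df.shape)
    lambdas, betas, conv, lam_max = _fit_lasso_path_std(
        Xs, so, pen_w, n_lambda, ratio, tol, max_passes)
    if not conv.all():
        warnings.warn(f"{int((~conv).sum())} lambda value(s) flagged "
                      "non-converged", stacklevel=2)
    return LambdaPath(lambdas, _betas_to_original(betas, keep, scale,
                                                  df.columns, lambdas),
                      conv, lam_max,
                      center=pd.Series(center, index=df.columns),
                      scale=pd.Series(scale, index=df.columns),
                      penalty_kind="lasso",
                      penalty_weights=None if penalty_weights is None
                      else pd.Series(penalty_weights))


def _event_stratified_folds(surv: SurvivalTable, n_folds: int, seed):
    """Event-stratified K-fold split; refolds (new seed) until every training
    part holds >= 2 events, up to 10 attempts."""
    ev = surv.event
    n = len(ev)
    n_folds = min(n_folds, n)
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True,
                              random_state=None if seed is None
                              else (int(seed) + attempt) % (2**31))
        try:
            folds = list(skf.split(np.zeros(n), ev))
        except ValueError:
            continue
        if all(ev[tr].sum() >= 2 for tr, _ in folds):
            return folds
    raise ValueError("could not build folds with >=2 training events each")


def _cv_deviance(X_df, surv, lambdas, n_folds, seed, fitter):
    """Held-out deviance dev_k(lam) = -2 [ll_all(beta_k) - ll_train(beta_k)]."""
    folds = _event_stratified_folds(surv, n_folds, seed)
    so_all = SurvivalOrder.from_arrays(surv.time, surv.event)
    X_all = X_df.to_numpy(dtype=float)
    devs = np.zeros((len(folds), len(lambdas)))
    for k, (tr, _te) in enumerate(folds):
        tr_df = X_df.iloc[tr]
        tr_surv = surv.subset([surv.samples[i] for i in tr])
        betas = fitter(tr_df, tr_surv, lambdas)  # (L, p) original scale
        so_tr = SurvivalOrder.from_arrays(tr_surv.time, tr_surv.event)
        X_tr = tr_df.to_numpy(dtype=float)
        eta_all = X_all @ betas.T  # (n, L)
        eta_tr = X_tr @ betas.T
        for li in range(len(lambdas)):
            ll_all = breslow_loglik(eta_all[so_all.order, li], so_all)
            ll_tr = breslow_loglik(eta_tr[so_tr.order, li], so_tr)
            devs[k, li] = -2.0 * (ll_all - ll_tr)
    mean = devs.mean(axis=0)
    se = devs.std(axis=0, ddof=1) / np.sqrt(len(folds))
    return mean, se


def _pick_lambda(lambdas, mean, se, rule):
    imin = int(np.argmin(mean))
    if rule == "min":
        return float(lambdas[imin]), imin
    if rule != "one_se":
        raise ValueError(f"unknown lambda rule {rule!r}")
    cutoff = mean[imin] + se[imin]
    ok = np.flatnonzero(mean <= cutoff)
    i = int(ok[0])  # lambdas decrease along the path: first qualifying = largest
    return float(lambdas[i]), i


def cv_select_lambda(
    X,
    survival: SurvivalTable,
    path: LambdaPath,
    n_folds: int = 10,
    rule: str = "one_se",
    seed: int | None = None,
    tol: float = 1e-7,
    max_passes: int = 100_000,
) -> float:
    """Choose the shrinkage value by K-fold cross-validated deviance over
    ``path.lambdas``; fills the path's cv fields in place."""
    df = _as_frame(X)
    surv = as_survival(survival)
    pw = None if path.penalty_weights is None else path.penalty_weights
    # fold fits only trace the deviance curve; a looser tolerance than the
    # final fit's is ample there
    cv_tol = max(tol, 1e-4)

    if path.penalty_kind == "lasso":
        def fitter(tr_df, tr_surv, lambdas):
            _, _, Xs, so, _, scale, keep, pen_w = _prepare(tr_df, tr_surv, pw)
            _, betas, _, _ = _fit_lasso_path_std(Xs, so, pen_w, len(lambdas),
                                                 0.01, cv_tol, max_passes,
                                                 lambdas=lambdas, max_outer=8)
            return _betas_to_original(betas, keep, scale, tr_df.columns,
                                      lambdas).to_numpy()
    else:
        groups = path.group_labels

        def fitter(tr_df, tr_surv, lambdas):
            _, _, Xs, so, _, scale, keep, pen_w = _prepare(tr_df, tr_surv, pw)
            grp = groups.loc[tr_df.columns].to_numpy()[keep]
            _, betas, _, _ = _fit_group_path_std(Xs, so, grp, pen_w,
                                                 len(lambdas), 0.01, cv_tol,
                                                 lambdas=lambdas)
            return _betas_to_original(betas, keep, scale, tr_df.columns,
                                      lambdas).to_numpy()

    mean, se = _cv_deviance(df, surv, path.lambdas, n_folds, seed, fitter)
    path.cv_deviance_mean = mean
    path.cv_deviance_se = se
    lam, _ = _pick_lambda(path.lambdas, mean, se, rule)
    return lam


def fit_lasso_cox(
    X,
    survival: SurvivalTable,
    n_folds: int = 10,
    rule: str = "one_se",
    seed: int | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    penalty_weights=None,
    tol: float = 1e-7,
) -> FittedPenalizedCox:
    """Lasso-Cox with CV-selected shrinkage (path + cv_select_lambda)."""
    path = fit_lasso_cox_path(X, survival, n_lambda, lambda_min_ratio,
                              penalty_weights, tol)
    lam = cv_select_lambda(X, survival, path, n_folds, rule, seed, tol)
    i = int(np.argmin(np.abs(path.lambdas - lam)))
    beta = path.betas.iloc[i]
    return FittedPenalizedCox(beta.copy(), lam, "lasso", path.center,
                              path.scale, rule, seed,
                              bool(path.converged[i]))


def fit_group_lasso_cox(
    X: PredictorMatrix,
    survival: SurvivalTable,
    n_folds: int = 10,
    rule: str = "one_se",
    seed: int | None = None,
    n_lambda: int = 100,
    lambda_min_ratio: float | None = None,
    tol: float = 1e-7,
) -> FittedPenalizedCox:
    """Group-lasso Cox (groups selected or dropped as units) with
    CV-selected shrinkage; group penalty weight = sqrt(group size)."""
    if not isinstance(X, PredictorMatrix) or X.group_labels is None:
        raise ValueError("group lasso requires a PredictorMatrix with group_labels")
    df, surv, Xs, so, center, scale, keep, pen_w = _prepare(X, survival)
    ratio = lambda_min_ratio if lambda_min_ratio is not None else \
        _auto_ratio(*df.shape)
    grp = X.group_labels.loc[df.columns].to_numpy()[keep]
    lambdas, betas, conv, lam_max = _fit_group_path_std(
        Xs, so, grp, pen_w, n_lambda, ratio, tol)
    path = LambdaPath(lambdas, _betas_to_original(betas, keep, scale,
                                                  df.columns, lambdas),
                      conv, lam_max,
                      center=pd.Series(center, index=df.columns),
                      scale=pd.Series(scale, index=df.columns),
                      penalty_kind="group_lasso",
                      group_labels=X.group_labels)
    lam = cv_select_lambda(df, surv, path, n_folds, rule, seed, tol)
    i = int(np.argmin(np.abs(path.lambdas - lam)))
    return FittedPenalizedCox(path.betas.iloc[i].copy(), lam, "group_lasso",
                              path.center, path.scale, rule, seed,
                              bool(conv[i]))


# ---------------------------------------------------------------------------
# prediction, likelihood, KKT
# ---------------------------------------------------------------------------


def cox_partial_loglik(eta, survival: SurvivalTable) -> float:
    """Breslow-ties Cox partial log-likelihood of a linear predictor."""
    surv = as_survival(survival)
    eta = np.asarray(eta, dtype=float)
    if eta.shape[0] != len(surv.data):
        raise ValueError("eta length does not match survival records")
    if surv.n_events == 0:
        warnings.warn("all records censored: partial log-likelihood is 0",
                      stacklevel=2)
        return 0.0
    so = SurvivalOrder.from_arrays(surv.time, surv.event)
    return breslow_loglik(eta[so.order], so)


def predict_linear_risk(model: FittedPenalizedCox, X_new) -> pd.Series:
    """Linear risk eta = X beta on the original predictor scale (higher eta
    means higher hazard). X_new must contain every model variable."""
    df = _as_frame(X_new)
    missing = [v for v in model.beta.index if v not in df.columns]
    if missing:
        raise ValueError(f"X_new is missing model variable(s): {missing[:5]}")
    eta = df[list(model.beta.index)].to_numpy(dtype=float) @ model.beta.to_numpy()
    return pd.Series(eta, index=df.index, name="linear_risk")


def kkt_max_violation(X, survival: SurvivalTable, model: FittedPenalizedCox,
                      penalty_weights=None) -> float:
    """Maximum KKT violation of a lasso fit at its lambda, on the
    standardized scale: for zero coefficients |score_v| - lambda * w_v, for
    nonzero |score_v - lambda * w_v * sign(beta_v)|. Near 0 at convergence."""
    df = _as_frame(X)
    surv = as_survival(survival)
    n = len(df)
    arr = df.to_numpy(dtype=float)
    center = model.center.loc[df.columns].to_numpy()
    scale = model.scale.loc[df.columns].to_numpy()
    keep = scale > 0
    Xs = (arr[:, keep] - center[keep]) / scale[keep]
    beta_std = (model.beta.loc[df.columns].to_numpy() * scale)[keep]
    so = SurvivalOrder.from_arrays(surv.time, surv.event)
    eta = Xs @ beta_std
    _, g, _ = breslow_grad_hess(eta[so.order], so)
    score = (g @ Xs[so.order]) / n
    if penalty_weights is None:
        pw = np.ones(keep.sum())
    else:
        pw = pd.Series(penalty_weights).loc[df.columns].to_numpy(dtype=float)[keep]
    lam = model.lambda_
    viol_zero = np.abs(score) - lam * pw
    viol_nz = np.abs(score - lam * pw * np.sign(beta_std))
    out = np.where(beta_std == 0.0, viol_zero, viol_nz)
    return float(np.max(out, initial=0.0))


# ---------------------------------------------------------------------------
# scikit-learn estimators
# ---------------------------------------------------------------------------


class CoxLassoCV(BaseEstimator):
    """L1-penalized Cox proportional hazards with CV-chosen shrinkage.

    Parameters
    ----------
    n_lambda : int
        Length of the log-spaced shrinkage grid.
    lambda_min_ratio : float or None
        Smallest grid value as a fraction of lambda_max; ``None`` picks
        0.01 (n >= p) or 0.05 (n < p).
    cv : int
        Inner folds for shrinkage selection (event-stratified).
    lambda_rule : {"one_se", "min"}
        ``one_se`` takes the largest lambda within one SE of the deviance
        minimum; ``min`` takes the minimizer.
    random_state : int or None
        Seed for the inner folds.

    Attributes
    ----------
    coef_ : ndarray, original-scale coefficients.
    lambda_ : chosen shrinkage value; lambda_max_ : top of the grid.
    lambdas_, coef_path_, cv_deviance_, cv_deviance_se_ : the full path.
    selected_ : names (or indices) of variables with nonzero coefficients.
    """

    _penalty_kind = "lasso"

    def __init__(self, n_lambda=100, lambda_min_ratio=None, cv=10,
                 lambda_rule="one_se", tol=1e-7, max_passes=100_000,
                 random_state=None):
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.cv = cv
        self.lambda_rule = lambda_rule
        self.tol = tol
        self.max_passes = max_passes
        self.random_state = random_state

    def _fit_path(self, X, y, penalty_weights):
        return fit_lasso_cox_path(X, y, self.n_lambda, self.lambda_min_ratio,
                                  penalty_weights, self.tol, self.max_passes)

    def fit(self, X, y, penalty_weights=None):
        df = _as_frame(X)
        surv = as_survival(y)
        path = self._fit_path(X if isinstance(X, PredictorMatrix) else df,
                              surv, penalty_weights)
        lam = cv_select_lambda(df, surv, path, self.cv, self.lambda_rule,
                               self.random_state, self.tol, self.max_passes)
        i = int(np.argmin(np.abs(path.lambdas - lam)))
        self.feature_names_in_ = np.asarray(df.columns, dtype=object)
        self.n_features_in_ = df.shape[1]
        self.path_ = path
        self.lambdas_ = path.lambdas
        self.coef_path_ = path.betas.to_numpy()
        self.cv_deviance_ = path.cv_deviance_mean
        self.cv_deviance_se_ = path.cv_deviance_se
        self.lambda_ = lam
        self.lambda_max_ = path.lambda_max
        self.coef_ = path.betas.iloc[i].to_numpy()
        self.selected_ = tuple(df.columns[self.coef_ != 0.0])
        self.fitted_ = FittedPenalizedCox(
            path.betas.iloc[i].copy(), lam, self._penalty_kind, path.center,
            path.scale, self.lambda_rule, self.random_state,
            bool(path.converged[i]))
        return self

    def predict(self, X):
        """Linear risk score (higher = higher hazard)."""
        check_is_fitted(self, "coef_")
        df = _as_frame(X)
        return predict_linear_risk(self.fitted_, df).to_numpy()

    def score(self, X, y):
        """Harrell's concordance index on (X, y)."""
        from .metrics import harrell_c

        c = harrell_c(self.predict(X), as_survival(y))
        return float("nan") if c is None else c


class CoxGroupLassoCV(CoxLassoCV):
    """Group-lasso Cox: variables sharing a group label (e.g. one gene's
    GE/CNV/SPM columns) are selected or dropped together.

    ``groups`` maps each feature to its group key; if None, a
    PredictorMatrix's own group_labels are used.
    """

    _penalty_kind = "group_lasso"

    def __init__(self, groups=None, n_lambda=100, lambda_min_ratio=None,
                 cv=10, lambda_rule="one_se", tol=1e-7, max_passes=100_000,
                 random_state=None):
        super().__init__(n_lambda, lambda_min_ratio, cv, lambda_rule, tol,
                         max_passes, random_state)
        self.groups = groups

    def _fit_path(self, X, y, penalty_weights):
        df = _as_frame(X)
        if self.groups is not None:
            labels = pd.Series(list(self.groups), index=df.columns)
        elif isinstance(X, PredictorMatrix) and X.group_labels is not None:
            labels = X.group_labels
        else:
            raise ValueError("groups must be provided for the group lasso")
        pm = PredictorMatrix(df, group_labels=labels,
                             penalty_weights=None if penalty_weights is None
                             else pd.Series(penalty_weights, index=df.columns))
        _, surv, Xs, so, center, scale, keep, pen_w = _prepare(pm, y)
        ratio = self.lambda_min_ratio if self.lambda_min_ratio is not None \
            else _auto_ratio(*df.shape)
        grp = labels.loc[df.columns].to_numpy()[keep]
        lambdas, betas, conv, lam_max = _fit_group_path_std(
            Xs, so, grp, pen_w, self.n_lambda, ratio, self.tol)
        return LambdaPath(lambdas,
                          _betas_to_original(betas, keep, scale, df.columns,
                                             lambdas),
                          conv, lam_max,
                          center=pd.Series(center, index=df.columns),
                          scale=pd.Series(scale, index=df.columns),
                          penalty_kind="group_lasso", group_labels=labels)
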