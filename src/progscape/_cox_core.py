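"""Breslow partial-likelihood primitives shared by the penalized fitters and
the univariable screen.

All functions work on arrays pre-sorted by time; `SurvivalOrder` caches the
sort and the tied-time grouping so repeated likelihood evaluations (IRLS,
coordinate-descent paths, per-gene Newton scans) stay O(n) each.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

_ETA_CLIP = 250.0  # guards exp overflow; partial likelihood is shift-invariant


@dataclass(frozen=True)
class SurvivalOrder:
    """Sort order and tied-time grouping for one survival dataset."""

    order: np.ndarray          # indices sorting time ascending (stable)
    time: np.ndarray           # sorted times
    event: np.ndarray          # sorted event indicators (float 0/1)
    first_idx: np.ndarray      # first sorted index of each unique time
    inverse: np.ndarray        # unique-time id per sorted sample
    d_u: np.ndarray            # events per unique time

    @classmethod
    def from_arrays(cls, time: np.ndarray, event: np.ndarray) -> "SurvivalOrder":
        time = np.asarray(time, dtype=float)
        event = np.asarray(event, dtype=float)
        order = np.argsort(time, kind="stable")
        ts, es = time[order], event[order]
        _, first_idx, inverse = np.unique(ts, return_index=True, return_inverse=True)
        d_u = np.bincount(inverse, weights=es)
        return cls(order, ts, es, first_idx, inverse, d_u)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())


def _center_clip(eta: np.ndarray) -> np.ndarray:
    eta = eta - eta.mean()
    return np.clip(eta, -_ETA_CLIP, _ETA_CLIP)


def breslow_loglik(eta_sorted: np.ndarray, so: SurvivalOrder) -> float:
    """Breslow-ties Cox partial log-likelihood for sorted linear predictors."""
    eta = _center_clip(eta_sorted)
    ee = np.exp(eta)
    # risk-set sum at each unique time = reverse cumsum taken at first tied index
    rs = np.cumsum(ee[::-1])[::-1]
    s_u = rs[so.first_idx]
    has_d = so.d_u > 0
    ll = float(eta @ so.event - np.sum(so.d_u[has_d] * np.log(s_u[has_d])))
    return ll


def breslow_grad_hess(
    eta_sorted: np.ndarray, so: SurvivalOrder
) -> tuple[float, np.ndarray, np.ndarray]:
    """Log-likelihood, gradient and diagonal Hessian approximation wrt eta.

    The gradient is exact; the Hessian is the diagonal used by glmnet-style
    IRLS: h_i = e^{eta_i} A_i - e^{2 eta_i} B_i with A, B the Breslow
    cumulative d/S and d/S^2 sums (always >= 0).
    """
    eta = _center_clip(eta_sorted)
    ee = np.exp(eta)
    rs = np.cumsum(ee[::-1])[::-1]
    s_u = rs[so.first_idx]
    has_d = so.d_u > 0
    ll = float(eta @ so.event - np.sum(so.d_u[has_d] * np.log(s_u[has_d])))
    inc1 = np.where(has_d, so.d_u / s_u, 0.0)
    inc2 = np.where(has_d, so.d_u / s_u**2, 0.0)
    a = np.cumsum(inc1)[so.inverse]
    b = np.cumsum(inc2)[so.inverse]
    grad = so.event - ee * a
    hess = np.maximum(ee * a - ee**2 * b, 0.0)
    return ll, grad, hess


def cox_loglik_unsorted(eta: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    so = SurvivalOrder.from_arrays(time, event)
    return breslow_loglik(np.asarray(eta, float)[so.order], so)


# ---------------------------------------------------------------------------
# vectorised univariable Newton scan
# ---------------------------------------------------------------------------


def univariable_cox_scan(
    X: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 40,
    tol: float = 1e-8,
    beta_cap: float = 100.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Fit one single-covariate Cox model per column of ``X`` (Breslow ties).

    Runs Newton-Raphson on every column simultaneously via column-wise
    reverse cumulative sums; exact (not diagonal) single-parameter Hessian.

    Returns ``(beta, se, p, converged)``. Non-converged or diverging columns
    (|beta| > beta_cap) and zero-variance columns get p = 1 and
    converged = False, so callers can drop them.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    so = SurvivalOrder.from_arrays(time, event)
    Xs = X[so.order]
    has_d = so.d_u > 0
    d = so.d_u[has_d]
    first = so.first_idx[has_d]

    sd = Xs.std(axis=0)
    active = sd > 0
    beta = np.zeros(p)
    info = np.full(p, np.nan)
    converged = np.zeros(p, dtype=bool)
    ev = so.event

    work = np.flatnonzero(active)
    for _ in range(max_iter):
        if work.size == 0:
            break
        Xw = Xs[:, work]
        eta = Xw * beta[work]
        eta -= eta.mean(axis=0)
        np.clip(eta, -_ETA_CLIP, _ETA_CLIP, out=eta)
        ee = np.exp(eta)
        xee = Xw * ee
        x2ee = Xw * xee
        s0 = np.cumsum(ee[::-1], axis=0)[::-1][first]
        s1 = np.cumsum(xee[::-1], axis=0)[::-1][first]
        s2 = np.cumsum(x2ee[::-1], axis=0)[::-1][first]
        mean1 = s1 / s0
        score = ev @ Xw - d @ mean1
        fisher = d @ (s2 / s0 - mean1**2)
        fisher = np.maximum(fisher, 1e-12)
        step = score / fisher
        np.clip(step, -5.0, 5.0, out=step)  # damp early overshoot
        beta[work] += step
        info[work] = fisher
        done = (np.abs(step) < tol) | (np.abs(beta[work]) > beta_cap)
        converged[work[(np.abs(step) < tol) & (np.abs(beta[work]) <= beta_cap)]] = True
        work = work[~done]

    se = np.where(info > 0, 1.0 / np.sqrt(info), np.nan)
    ok = converged & active & np.isfinite(se)
    z = np.zeros(p)
    z[ok] = beta[ok] / se[ok]
    pval = np.ones(p)
    pval[ok] = 2.0 * norm.sf(np.abs(z[ok]))
    return beta, se, pval, ok
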