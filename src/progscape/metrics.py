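"""Model-evaluation metrics: prediction, stability, parsimony.

* :func:`harrell_c` — Harrell's concordance index; 0.5 is random ordering,
  1 is perfect. A pair (i, j) is comparable iff T_i < T_j and sample i's
  event was observed (pairs tied on time are not comparable); tied predicted
  risks count 1/2.
* :func:`fleiss_kappa` — chance-corrected multi-rater agreement. Here each
  trained model is a rater assigning each candidate variable to
  selected / not-selected, so kappa measures feature-selection stability
  across cross-validation fits: 1 = identical selections, <= 0 = agreement
  no better than chance.
* :func:`average_model_size` — mean number of predictors with nonzero
  coefficients across the trained models.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import SurvivalTable
from .penalized_cox import as_survival

__all__ = ["harrell_c", "AgreementTable", "fleiss_kappa",
           "selection_agreement_table", "average_model_size"]


def harrell_c(risk, survival: SurvivalTable | np.ndarray) -> float | None:
    """Harrell's concordance index of a risk score against censored survival.

    Returns ``None`` when no comparable pair exists (e.g. all samples
    censored), rather than a fake 0.5.
    """
    surv = as_survival(survival)
    risk = np.asarray(risk, dtype=float)
    t = surv.time
    e = surv.event
    if risk.shape[0] != t.shape[0]:
        raise ValueError("risk vector length does not match survival records")
    comparable = (t[:, None] < t[None, :]) & (e[:, None] == 1)
    n_comp = int(comparable.sum())
    if n_comp == 0:
        return None
    greater = risk[:, None] > risk[None, :]
    tied = risk[:, None] == risk[None, :]
    n_conc = int((comparable & greater).sum())
    n_tied = int((comparable & tied).sum())
    return (n_conc + 0.5 * n_tied) / n_comp


@dataclass
class AgreementTable:
    """Subject-by-category rating counts for Fleiss kappa.

    ``counts`` has one row per subject (candidate variable) and one column
    per category (selected / not-selected); every row sums to the number of
    raters (trained models).
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.counts.to_numpy()
        if arr.ndim != 2 or arr.shape[0] < 1 or arr.shape[1] < 2:
            raise ValueError("agreement table needs >=1 subject and >=2 categories")
        sums = arr.sum(axis=1)
        if not np.all(sums == sums[0]):
            raise ValueError("every subject must be rated by the same number of raters")

    @property
    def n_raters(self) -> int:
        return int(self.counts.to_numpy()[0].sum())


def selection_agreement_table(
    selected_sets: Sequence[Iterable[str]], universe: Sequence[str]
) -> AgreementTable:
    """Build the models-as-raters agreement table: one subject per candidate
    variable in ``universe``, categories (selected, not_selected)."""
    universe = list(universe)
    n = len(selected_sets)
    sel = np.zeros(len(universe), dtype=int)
    pos = {v: i for i, v in enumerate(universe)}
    for s in selected_sets:
        for v in s:
            if v in pos:
                sel[pos[v]] += 1
    counts = pd.DataFrame({"selected": sel, "not_selected": n - sel},
                          index=pd.Index(universe, name="variable"))
    return AgreementTable(counts)


def fleiss_kappa(table: AgreementTable | pd.DataFrame | np.ndarray) -> float:
    """Fleiss' kappa for an N-subject x C-category rating-count table.

    With n raters: p_j = sum_i n_ij / (N n); P_i = (sum_j n_ij^2 - n) /
    (n (n - 1)); kappa = (mean P_i - sum p_j^2) / (1 - sum p_j^2). When all
    raters are unanimous on a single category for every subject the
    chance-agreement term is 1 and kappa is defined as 1.
    """
    if isinstance(table, AgreementTable):
        arr = table.counts.to_numpy(dtype=float)
    else:
        arr = np.asarray(table, dtype=float)
    n = arr[0].sum()
    if n < 2:
        raise ValueError("Fleiss kappa needs at least 2 raters")
    N = arr.shape[0]
    p_j = arr.sum(axis=0) / (N * n)
    p_bar = float(np.mean((np.sum(arr**2, axis=1) - n) / (n * (n - 1.0))))
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        return 1.0
    return (p_bar - p_e) / (1.0 - p_e)


def average_model_size(selected_sets: Sequence[Iterable[str]]) -> float:
    """Arithmetic mean selected-set size over the trained models."""
    if len(selected_sets) == 0:
        raise ValueError("at least one fitted model is required")
    return float(np.mean([len(set(s)) for s in selected_sets]))
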