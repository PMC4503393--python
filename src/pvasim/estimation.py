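"""Parameterizing "estimated" PVA models from an observed census window.

Two model types are estimated from the same window:

* **scalar** — ``M - 1`` whole-population growth rates
  ``lambda_t = n_{t+1} / n_t`` from the observed totals; never censored.
* **matrix** — an age-structured model with one class fewer than the
  truth: the terminal estimated class is a composite of the last two true
  age classes.  Cohort-ratio survival estimates exceeding one are
  biologically impossible and are censored (excluded from the resampling
  pools but counted); fecundity and scalar growth-rate estimates are
  never censored.

Censoring of high survival ratios is the mechanism that biases matrix
projections toward steeper declines when measurement error is large.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_history import LifeHistorySpec
from .observation import ObservedWindow

__all__ = ["ScalarEstimate", "MatrixEstimate", "estimate_scalar", "estimate_matrix"]


@dataclass
class ScalarEstimate:
    """Resampling pool for a count-based (scalar) PVA."""

    lambda_pool: np.ndarray  # (M - 1,)
    initial_total: float

    @property
    def m(self) -> int:
        return len(self.lambda_pool) + 1


@dataclass
class MatrixEstimate:
    """Resampling pools for an age-structured (matrix) PVA.

    ``survival_pools[i]`` holds the retained estimates for the transition
    out of estimated class ``i+1`` (1-based); the last pool is the
    composite-class self-loop.  ``censored_values[i]`` keeps the
    discarded (> 1) estimates so downstream code can audit or, in the
    rare case of a fully censored pool, fall back on them.
    """

    n_est_classes: int
    survival_pools: list[np.ndarray]
    fecundity_pool: np.ndarray
    censored_counts: np.ndarray  # (n_est_classes,)
    censored_values: list[np.ndarray]
    initial_vector: np.ndarray  # (n_est_classes,)

    @property
    def censored_fraction(self) -> float:
        total = self.censored_counts.sum() + sum(len(p) for p in self.survival_pools)
        return float(self.censored_counts.sum() / total) if total else 0.0


def estimate_scalar(window: ObservedWindow) -> ScalarEstimate:
    """Scalar growth-rate pool from the observed totals.

    ``pool[t] = total_{t+1} / total_t``; the ratios are used as-is with
    no truncation, and the projection starts from the final observed
    total.
    """
    totals = window.totals
    if np.any(totals <= 0):
        raise ValueError("observed total population is zero in some census year")
    return ScalarEstimate(
        lambda_pool=totals[1:] / totals[:-1],
        initial_total=float(totals[-1]),
    )


def estimate_matrix(
    window: ObservedWindow,
    spec: LifeHistorySpec,
    fecundity_denominator: str = "total",
) -> MatrixEstimate:
    """Cohort-ratio vital-rate pools for the estimated matrix model.

    For each of the ``M - 1`` year pairs ``t -> t+1`` (observed classes
    ``n_{i,t}``, true class count ``K``):

    * transition survival of class ``i``: ``n_{i+1,t+1} / n_{i,t}`` for
      ``i = 1 .. K-2``;
    * composite-class survival: ``n_{K,t+1} / (n_{K-1,t} + n_{K,t})``;
    * fecundity: ``n_{1,t+1}`` divided by the total observed population
      at ``t`` (``fecundity_denominator="total"``, the default, which
      treats the estimated composite class as pooling true classes K-1
      and K) or by the sum of classes ``1 .. K-1`` only
      (``"exclude_terminal"``).

    Survival ratios above one, and ratios with a zero denominator, are
    censored: excluded from the pools and tallied per class.  The initial
    vector for projection is the final observed census aggregated onto
    the estimated classes (classes ``1 .. K-2`` one-to-one; composite =
    class ``K-1`` + class ``K``).
    """
    if fecundity_denominator not in ("total", "exclude_terminal"):
        raise ValueError(f"unknown fecundity_denominator {fecundity_denominator!r}")
    a = window.abundances
    k = spec.n_classes
    if a.shape[1] != k:
        raise ValueError(
            f"window has {a.shape[1]} observed classes, life history has {k}"
        )
    n_est = k - 1

    survival_pools: list[np.ndarray] = []
    censored_values: list[np.ndarray] = []
    censored_counts = np.zeros(n_est, dtype=int)

    def split(num: np.ndarray, den: np.ndarray, idx: int) -> None:
        valid_den = den > 0
        ratios = np.divide(num, den, out=np.full_like(num, np.inf), where=valid_den)
        keep = valid_den & (ratios <= 1.0)
        survival_pools.append(ratios[keep])
        censored_values.append(ratios[valid_den & (ratios > 1.0)])
        censored_counts[idx] = len(num) - keep.sum()

    for i in range(k - 2):  # transitions of true classes 1..K-2
        split(a[1:, i + 1], a[:-1, i], i)
    split(a[1:, k - 1], a[:-1, k - 2] + a[:-1, k - 1], n_est - 1)

    if fecundity_denominator == "total":
        denom = a[:-1].sum(axis=1)
    else:
        denom = a[:-1, : k - 1].sum(axis=1)
    if np.any(denom <= 0):
        raise ValueError("observed population is zero in some census year")
    fecundity_pool = a[1:, 0] / denom

    initial_vector = np.concatenate([a[-1, : k - 2], [a[-1, k - 2] + a[-1, k - 1]]])
    return MatrixEstimate(
        n_est_classes=n_est,
        survival_pools=survival_pools,
        fecundity_pool=fecundity_pool,
        censored_counts=censored_counts,
        censored_values=censored_values,
        initial_vector=initial_vector,
    )
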