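"""Resampling projection of estimated PVA models.

Estimated models are projected ten years ahead (the IUCN Red List
criterion A.3 horizon for these short-generation life histories) by
drawing each vital rate independently, with replacement, from its
estimated pool at every time step of every trajectory.  No distribution
is fitted to the pools.  Percent decline is signed: negative values are
growth, 100 is total extinction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .estimation import MatrixEstimate, ScalarEstimate
from .true_simulation import _as_rng

__all__ = [
    "ProjectionResult",
    "EmptyPoolError",
    "project_scalar",
    "project_matrix",
    "median_percent_decline",
]

DEFAULT_HORIZON = 10
DEFAULT_N_TRAJ = 1000


class EmptyPoolError(RuntimeError):
    """A vital-rate pool has no usable values to resample from."""


@dataclass
class ProjectionResult:
    declines: np.ndarray  # (n_traj,) signed percent declines
    model_type: str  # "scalar" | "matrix"
    horizon: int
    #: estimated survival classes whose pool was fully censored and restored
    #: from capped censored values (matrix model only)
    fallback_classes: tuple[int, ...] = field(default=())

    @property
    def n_traj(self) -> int:
        return len(self.declines)

    @property
    def median_decline(self) -> float:
        return float(np.median(self.declines))


def median_percent_decline(result: ProjectionResult) -> float:
    """Sample median of the projected declines (midpoint for even counts)."""
    return result.median_decline


def project_scalar(
    est: ScalarEstimate,
    horizon: int = DEFAULT_HORIZON,
    n_traj: int = DEFAULT_N_TRAJ,
    rng: np.random.Generator | int | None = None,
) -> ProjectionResult:
    """Project a scalar model: ``N_{t+1} = lambda* N_t`` with ``lambda*``
    resampled from the pool each year."""
    pool = np.asarray(est.lambda_pool, dtype=float)
    if pool.size == 0:
        raise EmptyPoolError("scalar growth-rate pool is empty")
    rng = _as_rng(rng)
    draws = pool[rng.integers(0, pool.size, size=(n_traj, horizon))]
    growth = draws.prod(axis=1)
    return ProjectionResult(
        declines=100.0 * (1.0 - growth), model_type="scalar", horizon=horizon
    )


def _projection_pools(
    est: MatrixEstimate, empty_pool_fallback: str
) -> tuple[list[np.ndarray], tuple[int, ...]]:
    if empty_pool_fallback not in ("cap", "error"):
        raise ValueError(f"unknown empty_pool_fallback {empty_pool_fallback!r}")
    pools: list[np.ndarray] = []
    fallbacks: list[int] = []
    for i, pool in enumerate(est.survival_pools):
        if pool.size == 0:
            restored = np.minimum(est.censored_values[i], 1.0)
            if empty_pool_fallback == "error" or restored.size == 0:
                raise EmptyPoolError(
                    f"survival pool for estimated class {i + 1} is empty after censoring"
                )
            pools.append(restored)
            fallbacks.append(i + 1)
        else:
            pools.append(pool)
    return pools, tuple(fallbacks)


def project_matrix(
    est: MatrixEstimate,
    horizon: int = DEFAULT_HORIZON,
    n_traj: int = DEFAULT_N_TRAJ,
    rng: np.random.Generator | int | None = None,
    empty_pool_fallback: str = "cap",
) -> ProjectionResult:
    """Project a matrix model by resampling each rate pool independently.

    Every year of every trajectory draws one value per survival pool and
    one fecundity, assembles the estimated-class Leslie matrix (single
    shared fecundity across the top row, composite self-loop from the
    composite pool), and advances the age vector.

    If every estimate in some survival pool was censored, the fallback
    (``"cap"``, the default) restores that pool's censored values capped
    at 1.0 and records the class in ``fallback_classes``; with
    ``"error"`` the condition raises :class:`EmptyPoolError`.
    """
    if est.fecundity_pool.size == 0:
        raise EmptyPoolError("fecundity pool is empty")
    n0 = float(est.initial_vector.sum())
    if n0 <= 0:
        raise ValueError("initial observed population is not positive")
    pools, fallbacks = _projection_pools(est, empty_pool_fallback)
    rng = _as_rng(rng)
    k = est.n_est_classes
    v = np.tile(np.asarray(est.initial_vector, dtype=float), (n_traj, 1))
    for _ in range(horizon):
        s = np.empty((n_traj, k))
        for i, pool in enumerate(pools):
            s[:, i] = pool[rng.integers(0, pool.size, size=n_traj)]
        fpool = est.fecundity_pool
        f = fpool[rng.integers(0, fpool.size, size=n_traj)]
        new = np.empty_like(v)
        new[:, 0] = f * v.sum(axis=1)
        if k > 2:
            new[:, 1 : k - 1] = s[:, : k - 2] * v[:, : k - 2]
        new[:, k - 1] = s[:, k - 2] * v[:, k - 2] + s[:, k - 1] * v[:, k - 1]
        v = new
    declines = 100.0 * (1.0 - v.sum(axis=1) / n0)
    return ProjectionResult(
        declines=declines,
        model_type="matrix",
        horizon=horizon,
        fallback_classes=fallbacks,
    )
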