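"""Stochastic "truth" model: age-structured trajectories under process error.

Each simulated year draws a fresh set of uncorrelated vital rates —
survivals from moment-matched beta distributions on [0, 1], the shared
fecundity from a stretched beta on [0, 1000] — and projects the
age-abundance vector one step, ``n_{t+1} = A_t n_t``.  Process error is
parameterized as a coefficient of variation applied to every vital-rate
mean.  Populations start at the stable age distribution with a large
initial size so that demographic stochasticity is negligible and is not
modeled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_history import (
    LifeHistorySpec,
    back_calculate_fecundity,
    build_leslie,
    stable_age_distribution,
)

__all__ = [
    "InfeasibleVarianceError",
    "beta_from_moments",
    "stretched_beta_from_moments",
    "AnnualMatrixSampler",
    "draw_annual_matrix",
    "TrueTrajectory",
    "simulate_true_series",
    "true_percent_decline",
    "stochastic_growth_rate",
]

DEFAULT_YEARS = 60
DEFAULT_N0 = 1e9
FECUNDITY_UPPER = 1000.0


class InfeasibleVarianceError(ValueError):
    """Requested variance exceeds what a beta on the interval can carry."""


def beta_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters of the beta on [0, 1] with the given mean and sd.

    Moment matching gives ``alpha = mu * nu`` and ``beta = (1 - mu) * nu``
    with ``nu = mu (1 - mu) / sd^2 - 1``; it requires
    ``sd^2 < mu (1 - mu)``.
    """
    if not 0.0 < mean < 1.0:
        raise ValueError(f"mean must lie strictly inside (0, 1), got {mean}")
    if sd < 0:
        raise ValueError("sd must be nonnegative")
    var = sd * sd
    bound = mean * (1.0 - mean)
    if var >= bound:
        raise InfeasibleVarianceError(
            f"variance {var:.6g} is not below the beta feasibility bound "
            f"mu*(1-mu) = {bound:.6g} for mean {mean}"
        )
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def stretched_beta_from_moments(
    mean: float, sd: float, lower: float = 0.0, upper: float = FECUNDITY_UPPER
) -> tuple[float, float, float, float]:
    """Shapes + bounds of a beta linearly rescaled to [lower, upper].

    Moment matching is affine-invariant: the standard-beta moments are the
    rescaled ``(mean - lower) / (upper - lower)`` and ``sd / (upper - lower)``.
    """
    if not lower < mean < upper:
        raise ValueError(f"mean {mean} must lie strictly inside ({lower}, {upper})")
    width = upper - lower
    a, b = beta_from_moments((mean - lower) / width, sd / width)
    return a, b, lower, upper


class AnnualMatrixSampler:
    """Draws one projection matrix per year at a fixed process-error CV.

    Per draw, each survival (ascending age class, composite self-loop
    last) and then the single shared fecundity are sampled independently;
    the per-rate standard deviation is ``pe_cv`` times the rate's mean.
    ``pe_cv = 0`` is a point mass: the mean matrix is returned unchanged.
    """

    def __init__(self, spec: LifeHistorySpec, fecundity: float, pe_cv: float):
        if pe_cv < 0:
            raise ValueError("pe_cv must be nonnegative")
        self.spec = spec
        self.fecundity = float(fecundity)
        self.pe_cv = float(pe_cv)
        self.mean_matrix = build_leslie(spec, fecundity)
        if pe_cv > 0:
            means = np.asarray(spec.survival)
            shapes = [beta_from_moments(m, pe_cv * m) for m in means]
            self._s_alpha = np.array([a for a, _ in shapes])
            self._s_beta = np.array([b for _, b in shapes])
            self._f_shapes = stretched_beta_from_moments(fecundity, pe_cv * fecundity)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        if self.pe_cv == 0:
            return self.mean_matrix.copy()
        s = rng.beta(self._s_alpha, self._s_beta)
        fa, fb, lo, up = self._f_shapes
        f = lo + (up - lo) * rng.beta(fa, fb)
        k = self.spec.n_classes
        a = np.zeros((k, k))
        for j in self.spec.reproductive_classes:
            a[0, j - 1] = f
        a[np.arange(1, k), np.arange(0, k - 1)] = s[:-1]
        a[k - 1, k - 1] = s[-1]
        return a


def draw_annual_matrix(
    spec: LifeHistorySpec, fecundity: float, pe_cv: float, rng: np.random.Generator
) -> np.ndarray:
    """One random annual Leslie matrix (see :class:`AnnualMatrixSampler`)."""
    return AnnualMatrixSampler(spec, fecundity, pe_cv).draw(rng)


@dataclass
class TrueTrajectory:
    """A simulated "true" age-by-time abundance array.

    ``abundances[t]`` is the age vector in year ``t`` (year 0 is the
    stable-age initial condition); rows run 0..years inclusive.
    """

    abundances: np.ndarray  # (years + 1, n_classes)
    lambda_target: float
    pe_cv: float
    spec: LifeHistorySpec
    fecundity: float

    @property
    def totals(self) -> np.ndarray:
        return self.abundances.sum(axis=1)

    @property
    def n_years(self) -> int:
        return self.abundances.shape[0] - 1


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def simulate_true_series(
    spec: LifeHistorySpec,
    target_lambda: float,
    pe_cv: float,
    years: int = DEFAULT_YEARS,
    n0: float = DEFAULT_N0,
    rng: np.random.Generator | int | None = None,
    fecundity: float | None = None,
) -> TrueTrajectory:
    """Simulate a "true" trajectory of ``years`` annual transitions.

    The initial vector is the stable age distribution of the mean matrix
    scaled to ``n0`` individuals; every subsequent year applies a freshly
    drawn annual matrix.
    """
    if years < 2:
        raise ValueError("need at least 2 years")
    rng = _as_rng(rng)
    if fecundity is None:
        fecundity = back_calculate_fecundity(spec, target_lambda)
    sampler = AnnualMatrixSampler(spec, fecundity, pe_cv)
    n = stable_age_distribution(sampler.mean_matrix) * n0
    out = np.empty((years + 1, spec.n_classes))
    out[0] = n
    for t in range(years):
        n = sampler.draw(rng) @ n
        out[t + 1] = n
    return TrueTrajectory(
        abundances=out,
        lambda_target=float(target_lambda),
        pe_cv=float(pe_cv),
        spec=spec,
        fecundity=float(fecundity),
    )


def true_percent_decline(
    traj: TrueTrajectory, from_year: int = 50, to_year: int = 60
) -> float:
    """Signed percent decline of the total population between two years.

    ``100 * (N_from - N_to) / N_from``; negative values denote growth.
    """
    totals = traj.totals
    if to_year > traj.n_years:
        raise ValueError(f"to_year {to_year} beyond simulated horizon {traj.n_years}")
    n_from = totals[from_year]
    if n_from <= 0:
        raise ValueError("total population at from_year is not positive")
    return 100.0 * (n_from - totals[to_year]) / n_from


def stochastic_growth_rate(
    traj: TrueTrajectory, from_year: int = 50, to_year: int = 60
) -> float:
    """Geometric-mean annual growth rate over the window."""
    totals = traj.totals
    if to_year > traj.n_years:
        raise ValueError(f"to_year {to_year} beyond simulated horizon {traj.n_years}")
    n_from, n_to = totals[from_year], totals[to_year]
    if n_from <= 0 or n_to <= 0:
        raise ValueError("totals must be positive over the window")
    return float((n_to / n_from) ** (1.0 / (to_year - from_year)))
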