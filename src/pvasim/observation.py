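"""Observation process: measurement error and census windows.

"Observed" censuses are the true age-specific abundances perturbed by
independent normal measurement error whose standard deviation is a
coefficient of variation times the true abundance, truncated below at
zero.  Totals are never perturbed separately — the observed total is the
sum of the observed age classes.  Estimators see only the last ``M``
years of the 50-year observed history.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .true_simulation import TrueTrajectory, _as_rng

__all__ = ["ObservedSeries", "ObservedWindow", "apply_measurement_error", "extract_window"]

#: measurement-error CVs used in the study
ME_CV_GRID = (0.0, 0.1, 0.3)
#: census-window lengths used in the study
M_GRID = (5, 10, 15, 20, 30, 40, 50)
#: years of "history" available to the estimators (the rest is projection)
HISTORY_YEARS = 50


@dataclass
class ObservedSeries:
    """Full-length measurement-error-corrupted age series (rows = years 0..T)."""

    abundances: np.ndarray
    me_cv: float
    truth: TrueTrajectory

    @property
    def totals(self) -> np.ndarray:
        return self.abundances.sum(axis=1)


@dataclass
class ObservedWindow:
    """The last ``M`` years of the observed history, as seen by estimators.

    ``abundances[0]`` is year ``start_year``; ``abundances[-1]`` is year
    ``end_year`` (inclusive, 1-based years of the simulation).
    """

    abundances: np.ndarray  # (M, n_classes)
    me_cv: float
    start_year: int
    end_year: int
    truth: TrueTrajectory

    @property
    def m(self) -> int:
        return self.abundances.shape[0]

    @property
    def totals(self) -> np.ndarray:
        return self.abundances.sum(axis=1)


def apply_measurement_error(
    traj: TrueTrajectory, me_cv: float, rng: np.random.Generator | int | None = None
) -> ObservedSeries:
    """Corrupt every age-year abundance with normal measurement error.

    Each entry is drawn ``Normal(n_true, me_cv * n_true)`` independently
    and clamped at zero.  ``me_cv = 0`` returns the true series unchanged.
    """
    if me_cv < 0:
        raise ValueError("me_cv must be nonnegative")
    if me_cv == 0:
        obs = traj.abundances.copy()
    else:
        rng = _as_rng(rng)
        true = traj.abundances
        obs = np.maximum(rng.normal(loc=true, scale=me_cv * true), 0.0)
    return ObservedSeries(abundances=obs, me_cv=float(me_cv), truth=traj)


def extract_window(series: ObservedSeries, m: int) -> ObservedWindow:
    """The last ``m`` of the first :data:`HISTORY_YEARS` observed years.

    Returns years ``50 - m + 1 .. 50`` inclusive (1-based years, i.e.
    ending at the last pre-projection census).
    """
    if m < 2:
        raise ValueError("window length must be at least 2")
    if m > HISTORY_YEARS:
        raise ValueError(f"window length {m} exceeds the {HISTORY_YEARS}-year history")
    if series.abundances.shape[0] <= HISTORY_YEARS:
        raise ValueError("observed series shorter than the required history")
    start = HISTORY_YEARS - m + 1
    return ObservedWindow(
        abundances=series.abundances[start : HISTORY_YEARS + 1].copy(),
        me_cv=series.me_cv,
        start_year=start,
        end_year=HISTORY_YEARS,
        truth=series.truth,
    )
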