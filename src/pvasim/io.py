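"""Plain-text I/O: census tables, trajectory exports, and test fixtures.

All tabular data are CSV; run metadata travel in ``#``-prefixed header
comments so files round-trip through the census reader.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .life_history import LifeHistorySpec, back_calculate_fecundity, get_preset
from .observation import ObservedSeries, ObservedWindow
from .true_simulation import TrueTrajectory, simulate_true_series

__all__ = [
    "write_trajectory_csv",
    "write_window_csv",
    "read_census_table",
    "make_fixture",
]


def _age_columns(n: int) -> list[str]:
    return [f"age_{i}" for i in range(1, n + 1)]


def _write_table(
    path, years: np.ndarray, abundances: np.ndarray, meta: dict
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(abundances, columns=_age_columns(abundances.shape[1]))
    df.insert(0, "year", years)
    df["total"] = abundances.sum(axis=1)
    tmp = path.with_suffix(path.suffix + ".tmp")
    with open(tmp, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key} = {value}\n")
        df.to_csv(fh, index=False)
    tmp.replace(path)  # atomic on POSIX
    return path


def write_trajectory_csv(traj: TrueTrajectory, path, seed=None) -> Path:
    """Export a true trajectory: one row per year, columns = age classes
    + total, metadata in comment headers."""
    meta = {
        "life_history": traj.spec.name,
        "lambda": traj.lambda_target,
        "pe_cv": traj.pe_cv,
        "fecundity": traj.fecundity,
    }
    if seed is not None:
        meta["seed"] = seed
    years = np.arange(traj.abundances.shape[0])
    return _write_table(path, years, traj.abundances, meta)


def write_window_csv(obj: ObservedSeries | ObservedWindow, path, seed=None) -> Path:
    """Export an observed series or window with its me_cv in the metadata."""
    meta = {"me_cv": obj.me_cv}
    if seed is not None:
        meta["seed"] = seed
    if isinstance(obj, ObservedWindow):
        years = np.arange(obj.start_year, obj.end_year + 1)
    else:
        years = np.arange(obj.abundances.shape[0])
    return _write_table(path, years, obj.abundances, meta)


def read_census_table(path) -> pd.DataFrame:
    """Read an age-structured census table.

    Expected layout: a header row, first column the census year, the
    remaining columns age-class counts; ``#`` lines are ignored.  Years
    must be contiguous and counts nonnegative.  A trailing ``total``
    column (as written by the exporters) is validated against the row
    sums and dropped.
    """
    path = Path(path)
    try:
        # round_trip parsing so exported trajectories re-read bit-identically
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed census table ({exc})") from exc
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a year column plus at least one age class")
    year_col = df.columns[0]
    years = df[year_col].to_numpy()
    if not np.array_equal(years, years.astype(int)):
        raise ValueError(f"{path}: year column must be integer")
    years = years.astype(int)
    if len(years) > 1 and not np.array_equal(np.diff(years), np.ones(len(years) - 1)):
        raise ValueError(f"{path}: census years must be contiguous and increasing")
    counts = df.drop(columns=[year_col])
    if "total" in counts.columns:
        totals = counts.pop("total").to_numpy(dtype=float)
        if not np.allclose(totals, counts.sum(axis=1), rtol=1e-9, atol=1e-6):
            raise ValueError(f"{path}: total column does not match the row sums")
    arr = counts.to_numpy(dtype=float)
    if np.any(np.isnan(arr)):
        raise ValueError(f"{path}: missing counts (ragged rows?)")
    if np.any(arr < 0):
        raise ValueError(f"{path}: negative counts are not valid censuses")
    out = pd.DataFrame(arr, columns=list(counts.columns))
    out.index = pd.Index(years, name=year_col)
    return out


def make_fixture(kind: str, params: dict | None = None, seed: int = 0):
    """Small deterministic inputs with hand-verifiable expected outputs.

    Kinds:

    * ``"deterministic-truth"`` — zero-process-error trajectory whose
      totals follow ``n0 * lambda**t`` exactly.
    * ``"toy-window"`` — a 3-class, 3-year observed window with
      hand-computable cohort-ratio estimates (one survival ratio > 1 to
      exercise censoring).
    * ``"enumerable-pools"`` — tiny resampling pools for brute-force
      enumeration of the projection distribution.
    """
    params = dict(params or {})
    if kind == "deterministic-truth":
        spec: LifeHistorySpec = params.pop("spec", None) or get_preset(
            params.pop("life_history", "hypothetical")
        )
        lam = params.pop("lam", 0.9)
        return simulate_true_series(spec, lam, pe_cv=0.0, rng=seed, **params)
    if kind == "toy-window":
        from .observation import ObservedWindow

        # year x class abundances chosen so every ratio is a short decimal;
        # the class-2 cohort "grows" 80 -> 90 in year pair 2 (ratio > 1),
        # exercising survival censoring.
        abundances = np.array(
            [
                [100.0, 50.0, 25.0],
                [80.0, 40.0, 30.0],
                [64.0, 90.0, 28.0],
            ]
        )
        return ObservedWindow(
            abundances=abundances, me_cv=0.0, start_year=48, end_year=50, truth=None
        )
    if kind == "enumerable-pools":
        from .estimation import ScalarEstimate

        return ScalarEstimate(
            lambda_pool=np.array(params.pop("pool", (0.8, 1.2)), dtype=float),
            initial_total=float(params.pop("initial_total", 100.0)),
        )
    raise ValueError(f"unknown fixture kind {kind!r}")
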