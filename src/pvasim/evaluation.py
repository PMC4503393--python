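"""Scenario grid, replication, and precision/bias summaries.

A *scenario* is one combination of life history, asymptotic growth rate
``lambda``, process-error CV, measurement-error CV, and census-window
length ``M``.  The full factorial per life history is 4 growth rates x 4
process-error levels x 3 measurement-error levels x 7 window lengths =
336 scenarios.  Each scenario is replicated: every replicate simulates a
fresh "true" series, observes and windows it, estimates both model
types, projects both, and records the difference

    diff = true percent decline  -  median estimated percent decline

over the shared 10-year horizon.  Per scenario and model, *precision* is
the inverse of the interquartile-range width of the diffs and *bias* is
their median displacement from zero.

Random streams are derived from named seed sequences keyed on the master
seed, life history, scenario coordinates, replicate index and stage, so
the same replicate index reuses the same true series and observed series
across window lengths (windows are nested, as in a real monitoring
program) while projections remain independent.
"""

from __future__ import annotations

import itertools
import zlib
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .estimation import estimate_matrix, estimate_scalar
from .life_history import LifeHistorySpec, back_calculate_fecundity, get_preset
from .observation import HISTORY_YEARS, M_GRID, ME_CV_GRID, apply_measurement_error, extract_window
from .projection import DEFAULT_HORIZON, project_matrix, project_scalar
from .true_simulation import DEFAULT_N0, DEFAULT_YEARS, simulate_true_series

__all__ = [
    "LAMBDA_GRID",
    "ScenarioConfig",
    "ScenarioResult",
    "run_replicate",
    "run_scenario",
    "run_grid",
    "iqr_reduction",
    "cross_life_history_iqr_ratio",
    "boxplot_summary",
]

LAMBDA_GRID = (0.9, 0.95, 1.0, 1.025)

_LH_CODES = {"hypothetical": 1, "t_lamproides": 2}


def _lh_code(name: str) -> int:
    return _LH_CODES.get(name, 1000 + zlib.crc32(name.encode()) % 2**20)


@dataclass(frozen=True)
class ScenarioConfig:
    """One cell of the simulation experiment."""

    life_history: str = "hypothetical"
    lam: float = 1.0
    pe_cv: float = 0.0
    me_cv: float = 0.0
    m: int = 10
    n_true_reps: int = 1000
    n_traj: int = 1000
    seed: int = 0
    horizon: int = DEFAULT_HORIZON
    fecundity_denominator: str = "total"
    empty_pool_fallback: str = "cap"

    def spec(self) -> LifeHistorySpec:
        return get_preset(self.life_history)

    def validate(self) -> "ScenarioConfig":
        spec = self.spec()
        if self.pe_cv not in spec.pe_cv_grid:
            raise ValueError(
                f"pe_cv {self.pe_cv} not in the {self.life_history} grid "
                f"{spec.pe_cv_grid}"
            )
        if self.me_cv < 0:
            raise ValueError("me_cv must be nonnegative")
        if not 2 <= self.m <= HISTORY_YEARS:
            raise ValueError(f"window length m must lie in [2, {HISTORY_YEARS}]")
        if self.n_true_reps < 1 or self.n_traj < 1:
            raise ValueError("replication counts must be positive")
        return self

    def _stage_seed(self, rep: int, stage: int) -> np.random.SeedSequence:
        return np.random.SeedSequence(
            [
                self.seed,
                _lh_code(self.life_history),
                int(round(self.lam * 10_000)),
                int(round(self.pe_cv * 1_000)),
                int(round(self.me_cv * 1_000)),
                rep,
                stage,
            ]
        )


# stage keys for the named substreams; projection streams also key on m
_STAGE_TRUTH = 1
_STAGE_MEASURE = 2
_STAGE_SCALAR = 3
_STAGE_MATRIX = 4


def run_replicate(
    config: ScenarioConfig, rep: int, fecundity: float | None = None
) -> dict:
    """Run one full truth -> observe -> estimate -> project replicate."""
    spec = config.spec()
    if fecundity is None:
        fecundity = back_calculate_fecundity(spec, config.lam)
    truth_rng = np.random.default_rng(config._stage_seed(rep, _STAGE_TRUTH))
    traj = simulate_true_series(
        spec, config.lam, config.pe_cv, years=DEFAULT_YEARS, n0=DEFAULT_N0,
        rng=truth_rng, fecundity=fecundity,
    )
    meas_rng = np.random.default_rng(config._stage_seed(rep, _STAGE_MEASURE))
    observed = apply_measurement_error(traj, config.me_cv, rng=meas_rng)
    window = extract_window(observed, config.m)

    scalar_est = estimate_scalar(window)
    matrix_est = estimate_matrix(
        window, spec, fecundity_denominator=config.fecundity_denominator
    )

    scalar_rng = np.random.default_rng(
        config._stage_seed(rep, _STAGE_SCALAR * 1_000 + config.m)
    )
    matrix_rng = np.random.default_rng(
        config._stage_seed(rep, _STAGE_MATRIX * 1_000 + config.m)
    )
    scalar_proj = project_scalar(
        scalar_est, horizon=config.horizon, n_traj=config.n_traj, rng=scalar_rng
    )
    matrix_proj = project_matrix(
        matrix_est, horizon=config.horizon, n_traj=config.n_traj, rng=matrix_rng,
        empty_pool_fallback=config.empty_pool_fallback,
    )

    start = HISTORY_YEARS
    from .true_simulation import true_percent_decline

    true_decline = true_percent_decline(traj, start, start + config.horizon)
    scalar_median = scalar_proj.median_decline
    matrix_median = matrix_proj.median_decline
    return {
        "rep": rep,
        "true_decline": true_decline,
        "scalar_median": scalar_median,
        "matrix_median": matrix_median,
        "scalar_diff": true_decline - scalar_median,
        "matrix_diff": true_decline - matrix_median,
        "censored_fraction": matrix_est.censored_fraction,
        "n_censored": int(matrix_est.censored_counts.sum()),
        "n_fallback_classes": len(matrix_proj.fallback_classes),
    }


@dataclass
class ScenarioResult:
    """Per-replicate records plus per-model precision/bias summaries."""

    config: ScenarioConfig
    records: pd.DataFrame
    summaries: dict[str, dict[str, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.summaries:
            for model in ("scalar", "matrix"):
                diffs = self.records[f"{model}_diff"].to_numpy()
                q25, q50, q75 = np.percentile(diffs, [25, 50, 75])
                width = q75 - q25
                self.summaries[model] = {
                    "bias": float(q50),
                    "q25": float(q25),
                    "q75": float(q75),
                    "iqr_width": float(width),
                    "precision": float(1.0 / width) if width > 0 else float("nan"),
                    "mean_censored_fraction": float(
                        self.records["censored_fraction"].mean()
                    )
                    if model == "matrix"
                    else 0.0,
                    "fallback_events": int(self.records["n_fallback_classes"].sum())
                    if model == "matrix"
                    else 0,
                }

    def iqr_width(self, model: str) -> float:
        return self.summaries[model]["iqr_width"]


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Replicate one scenario ``n_true_reps`` times and summarize."""
    config.validate()
    spec = config.spec()
    fecundity = back_calculate_fecundity(spec, config.lam)
    records = pd.DataFrame(
        [run_replicate(config, rep, fecundity) for rep in range(config.n_true_reps)]
    )
    return ScenarioResult(config=config, records=records)


def _scenario_rows(result: ScenarioResult) -> list[dict]:
    c = result.config
    rows = []
    for model in ("scalar", "matrix"):
        s = result.summaries[model]
        rows.append(
            {
                "life_history": c.life_history,
                "lambda": c.lam,
                "pe_cv": c.pe_cv,
                "me_cv": c.me_cv,
                "m": c.m,
                "model": model,
                "n_true_reps": c.n_true_reps,
                "n_traj": c.n_traj,
                **s,
            }
        )
    return rows


def run_grid(
    life_history: str = "hypothetical",
    lambdas: Iterable[float] = LAMBDA_GRID,
    pe_cvs: Iterable[float] | None = None,
    me_cvs: Iterable[float] = ME_CV_GRID,
    ms: Iterable[int] = M_GRID,
    n_true_reps: int = 1000,
    n_traj: int = 1000,
    seed: int = 0,
    progress: bool = False,
    **kwargs,
) -> pd.DataFrame:
    """Run a (partial) scenario grid and return the long summary table.

    The default grids give the full factorial: 336 scenarios per life
    history, two rows each (one per model type).
    """
    spec = get_preset(life_history)
    if pe_cvs is None:
        pe_cvs = spec.pe_cv_grid
    combos = list(itertools.product(lambdas, pe_cvs, me_cvs, ms))
    rows: list[dict] = []
    iterator = combos
    if progress:
        try:
            from tqdm import tqdm

            iterator = tqdm(combos, desc=f"grid[{life_history}]")
        except ImportError:
            pass
    for lam, pe, me, m in iterator:
        config = ScenarioConfig(
            life_history=life_history, lam=lam, pe_cv=pe, me_cv=me, m=m,
            n_true_reps=n_true_reps, n_traj=n_traj, seed=seed, **kwargs,
        )
        rows.extend(_scenario_rows(run_scenario(config)))
    return pd.DataFrame(rows)


_SCENARIO_KEYS = ("life_history", "lambda", "pe_cv", "me_cv", "m")


def _lookup_iqr(summary: pd.DataFrame, scenario: dict, model: str) -> float:
    mask = summary["model"] == model
    for key, value in scenario.items():
        if key not in summary.columns:
            raise KeyError(f"unknown scenario key {key!r}")
        mask &= summary[key] == value
    hit = summary[mask]
    if len(hit) != 1:
        raise ValueError(
            f"scenario {scenario} / model {model!r} matched {len(hit)} rows"
        )
    return float(hit["iqr_width"].iloc[0])


def iqr_reduction(
    summary: pd.DataFrame, scenario_a: dict, scenario_b: dict, model: str
) -> float:
    """Percent reduction in IQR width from scenario ``a`` to scenario ``b``:
    ``100 * (iqr_a - iqr_b) / iqr_a``."""
    iqr_a = _lookup_iqr(summary, scenario_a, model)
    iqr_b = _lookup_iqr(summary, scenario_b, model)
    if iqr_a == 0:
        raise ValueError("reference scenario has zero IQR width")
    return 100.0 * (iqr_a - iqr_b) / iqr_a


def cross_life_history_iqr_ratio(
    summary_a: pd.DataFrame, summary_b: pd.DataFrame, scenario: dict, model: str
) -> float:
    """Percent by which life history ``b``'s IQR is smaller than ``a``'s at
    the same scenario coordinates: ``100 * (iqr_a - iqr_b) / iqr_a``."""
    scen = {k: v for k, v in scenario.items() if k != "life_history"}
    iqr_a = _lookup_iqr(summary_a, scen, model)
    iqr_b = _lookup_iqr(summary_b, scen, model)
    if iqr_a == 0:
        raise ValueError("reference life history has zero IQR width")
    return 100.0 * (iqr_a - iqr_b) / iqr_a


def boxplot_summary(
    records: pd.DataFrame,
    out_dir,
    value_col: str | None = None,
    file_format: str = "png",
) -> list:
    """Faceted box plots of decline differences, one figure per
    (model, lambda, me_cv), panels over window length M, boxes over pe_cv.

    ``records`` is a long per-replicate table with columns
    ``life_history, lambda, pe_cv, me_cv, m, model`` and per-model diff
    columns (``scalar_diff`` / ``matrix_diff``) or a single ``diff``
    column named by ``value_col``.  Returns the written file paths.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    models = (
        sorted(records["model"].unique()) if "model" in records.columns else ["scalar", "matrix"]
    )
    for model in models:
        sub = records[records["model"] == model] if "model" in records.columns else records
        col = value_col or (f"{model}_diff" if f"{model}_diff" in sub.columns else "diff")
        for lam in sorted(sub["lambda"].unique()):
            for me in sorted(sub["me_cv"].unique()):
                panel = sub[(sub["lambda"] == lam) & (sub["me_cv"] == me)]
                if panel.empty:
                    continue
                ms = sorted(panel["m"].unique())
                pes = sorted(panel["pe_cv"].unique())
                fig, axes = plt.subplots(
                    1, len(ms), figsize=(2.4 * len(ms) + 1, 3.2), sharey=True,
                    squeeze=False,
                )
                for ax, m in zip(axes[0], ms):
                    cell = panel[panel["m"] == m]
                    data = [cell[cell["pe_cv"] == pe][col].to_numpy() for pe in pes]
                    ax.boxplot(data, tick_labels=[str(pe) for pe in pes], whis=(5, 95))
                    ax.axhline(0.0, color="0.6", lw=0.8, ls="--")
                    ax.set_title(f"M={m}", fontsize=9)
                    ax.set_xlabel("PE CV", fontsize=8)
                axes[0][0].set_ylabel("true − estimated decline (%)", fontsize=8)
                fig.suptitle(
                    f"{model} model, λ={lam}, ME CV={me}", fontsize=10
                )
                fig.tight_layout()
                path = out_dir / f"diff_{model}_lam{lam}_me{me}.{file_format}"
                fig.savefig(path, dpi=120)
                plt.close(fig)
                written.append(path)
    return written
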