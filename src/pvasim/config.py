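"""Run configuration: YAML parsing, defaults, and feasibility validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .evaluation import LAMBDA_GRID
from .life_history import get_preset
from .observation import HISTORY_YEARS, M_GRID, ME_CV_GRID
from .true_simulation import beta_from_moments, InfeasibleVarianceError

__all__ = ["RunConfig", "validate_config", "load_config"]

_KNOWN_KEYS = {
    "life_history",
    "lambdas",
    "pe_cvs",
    "me_cvs",
    "ms",
    "n_true_reps",
    "n_traj",
    "seed",
    "out_dir",
    "fecundity_denominator",
    "empty_pool_fallback",
}


@dataclass
class RunConfig:
    """A validated grid (or single-scenario) run description.

    Unspecified grids default to the full study design: growth rates
    {0.9, 0.95, 1.0, 1.025}, the life history's process-error CV grid,
    measurement-error CVs {0, 0.1, 0.3}, and window lengths
    {5, 10, 15, 20, 30, 40, 50} — 336 scenarios per life history.
    """

    life_history: str = "hypothetical"
    lambdas: tuple[float, ...] = LAMBDA_GRID
    pe_cvs: tuple[float, ...] = field(default=None)  # type: ignore[assignment]
    me_cvs: tuple[float, ...] = ME_CV_GRID
    ms: tuple[int, ...] = M_GRID
    n_true_reps: int = 1000
    n_traj: int = 1000
    seed: int = 0
    out_dir: Path = Path("pvasim_out")
    fecundity_denominator: str = "total"
    empty_pool_fallback: str = "cap"

    @property
    def n_scenarios(self) -> int:
        return len(self.lambdas) * len(self.pe_cvs) * len(self.me_cvs) * len(self.ms)


def validate_config(raw: dict) -> RunConfig:
    """Fill defaults and reject infeasible or unknown settings.

    Process-error CVs are checked against the beta feasibility bound
    ``(cv * mu)^2 < mu (1 - mu)`` for every survival mean of the life
    history — this is what caps the snail grid at 0.45.
    """
    unknown = set(raw) - _KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: raw[k] for k in raw})
    spec = get_preset(cfg.life_history)  # raises on unknown preset
    if cfg.pe_cvs is None:
        cfg.pe_cvs = spec.pe_cv_grid
    cfg.lambdas = tuple(float(x) for x in cfg.lambdas)
    cfg.pe_cvs = tuple(float(x) for x in cfg.pe_cvs)
    cfg.me_cvs = tuple(float(x) for x in cfg.me_cvs)
    cfg.ms = tuple(int(x) for x in cfg.ms)
    cfg.out_dir = Path(cfg.out_dir)

    if any(lam <= 0 for lam in cfg.lambdas):
        raise ValueError("growth rates must be positive")
    for me in cfg.me_cvs:
        if me < 0:
            raise ValueError(f"me_cv {me} is negative")
    for m in cfg.ms:
        if not 2 <= m <= HISTORY_YEARS:
            raise ValueError(f"window length {m} outside [2, {HISTORY_YEARS}]")
    for pe in cfg.pe_cvs:
        if pe < 0:
            raise ValueError(f"pe_cv {pe} is negative")
        if pe == 0:
            continue
        for mu in spec.survival:
            try:
                beta_from_moments(mu, pe * mu)
            except InfeasibleVarianceError as exc:
                raise ValueError(
                    f"pe_cv {pe} infeasible for {cfg.life_history} survival "
                    f"mean {mu}: {exc}"
                ) from exc
    if cfg.n_true_reps < 1 or cfg.n_traj < 1:
        raise ValueError("replication counts must be positive")
    if cfg.fecundity_denominator not in ("total", "exclude_terminal"):
        raise ValueError(f"unknown fecundity_denominator {cfg.fecundity_denominator!r}")
    if cfg.empty_pool_fallback not in ("cap", "error"):
        raise ValueError(f"unknown empty_pool_fallback {cfg.empty_pool_fallback!r}")
    return cfg


def load_config(path) -> RunConfig:
    """Load and validate a YAML run-configuration file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a key-value mapping")
    return validate_config(raw)
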