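"""Monte Carlo study of estimator accuracy under partition-volume variation.

Each simulated chip draws per-partition volumes from a normal distribution
truncated at zero (negative draws are rejected and redrawn), allocates
molecules by a volume-proportional Poisson process (a partition of volume v
is occupied with probability 1 - exp(-C v)), and feeds the resulting
negative fraction to each estimator.  Repeating over many iterations per
(concentration, cv) cell yields the inaccuracy and precision metrics used
to compare the models.

Metric definitions (estimates x_1..x_k, true concentration c):

inaccuracy
    |mean(x) - c| / c.
precision_ci95
    the worse of the two relative deviations of the empirical 2.5% and
    97.5% quantiles from c (both endpoint deviations are also reported).
precision_inner90
    max |x - c| / c over the estimates lying between the empirical 5% and
    95% quantiles (outliers beyond the inner 90% are trimmed).

Lower is better for all three.  Quantiles use linear interpolation of the
order statistics.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import InvalidInputError, PoissonPlusError
from .estimators import (
    MODEL_NAMES,
    PL_PER_UL,
    PartitionCounts,
    VolumeModel,
    estimate,
    observed_p_negative,
)

__all__ = [
    "SimConfig",
    "SimStudyResult",
    "sample_volumes",
    "simulate_chip",
    "inaccuracy",
    "precision_ci95",
    "precision_inner90",
    "run_study",
    "load_sim_config",
]

#: minimum number of estimates for a meaningful empirical quantile
MIN_ESTIMATES_FOR_PRECISION = 20


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulation study.

    ``concentrations`` are true concentrations in copies/uL; ``cv_levels``
    are volume coefficients of variation (SD as a fraction of the mean
    partition volume).  Defaults mirror the reference study design: 20000
    partitions of mean volume 755 pL, 10000 iterations per cell, cv levels
    10/20/30%.
    """

    concentrations: tuple[float, ...]
    v0: float = 755.0
    cv_levels: tuple[float, ...] = (0.1, 0.2, 0.3)
    n_partitions: int = 20000
    n_iterations: int = 10000
    models: tuple[str, ...] = MODEL_NAMES
    seed: int = 0
    use_sample_moments: bool = False
    keep_estimates: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "concentrations", tuple(float(c) for c in self.concentrations))
        object.__setattr__(self, "cv_levels", tuple(float(v) for v in self.cv_levels))
        object.__setattr__(self, "models", tuple(self.models))
        if not self.concentrations:
            raise InvalidInputError("at least one concentration is required")
        if any(c < 0 for c in self.concentrations):
            raise InvalidInputError("concentrations must be non-negative")
        if not self.v0 > 0:
            raise InvalidInputError("v0 must be positive")
        if any(cv < 0 for cv in self.cv_levels):
            raise InvalidInputError("cv levels must be non-negative")
        if self.n_partitions < 1 or self.n_iterations < 1:
            raise InvalidInputError("n_partitions and n_iterations must be >= 1")
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise InvalidInputError(f"unknown models: {sorted(unknown)}")


@dataclass
class SimStudyResult:
    """Tidy per-cell metrics plus (optionally) the raw per-iteration estimates."""

    table: pd.DataFrame
    config: SimConfig
    estimates: dict[tuple[float, float, str], np.ndarray] = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


def sample_volumes(
    n: int, v0: float, cv: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``n`` partition volumes ~ Normal(v0, cv*v0) truncated at zero.

    Truncation is by rejection: non-positive draws are redrawn, so the
    realised distribution is the zero-truncated normal.
    """
    if n < 1:
        raise InvalidInputError(f"n must be >= 1, got {n}")
    if not v0 > 0:
        raise InvalidInputError(f"v0 must be positive, got {v0}")
    if cv < 0:
        raise InvalidInputError(f"cv must be non-negative, got {cv}")
    if cv == 0.0:
        return np.full(n, v0, dtype=float)
    acceptance = stats.norm.sf(0.0, loc=v0, scale=cv * v0)
    if acceptance < 0.01:
        raise InvalidInputError(
            f"rejection sampling acceptance {acceptance:.2g} < 1%: "
            "degenerate volume regime"
        )
    out = rng.normal(v0, cv * v0, size=n)
    bad = out <= 0.0
    while bad.any():
        out[bad] = rng.normal(v0, cv * v0, size=int(bad.sum()))
        bad = out <= 0.0
    return out


def simulate_chip(
    c_true: float, volumes: np.ndarray, rng: np.random.Generator
) -> PartitionCounts:
    """Simulate one chip read-out at true concentration ``c_true`` (copies/uL).

    Partition i receives Poisson(C * v_i) molecules with C in copies/pL, so
    it is negative with probability exp(-C * v_i); occupancy is thresholded
    at zero to produce the counts.
    """
    if c_true < 0:
        raise InvalidInputError(f"c_true must be non-negative, got {c_true}")
    volumes = np.asarray(volumes, dtype=float)
    c_per_pl = c_true / PL_PER_UL
    occupancy = rng.poisson(c_per_pl * volumes)
    n_total = volumes.size
    n_negative = int(np.count_nonzero(occupancy == 0))
    return PartitionCounts(n_total=n_total, n_negative=n_negative)


def _as_estimates(estimates) -> np.ndarray:
    arr = np.asarray(estimates, dtype=float)
    if arr.size == 0:
        raise InvalidInputError("empty estimate vector")
    return arr


def inaccuracy(estimates, c_true: float) -> float:
    """Relative deviation of the mean estimate from the true concentration."""
    arr = _as_estimates(estimates)
    if not c_true > 0:
        raise InvalidInputError("c_true must be positive")
    return abs(float(arr.mean()) - c_true) / c_true


def _check_precision_inputs(arr: np.ndarray, c_true: float) -> None:
    if arr.size < MIN_ESTIMATES_FOR_PRECISION:
        raise InvalidInputError(
            f"need >= {MIN_ESTIMATES_FOR_PRECISION} estimates, got {arr.size}"
        )
    if not c_true > 0:
        raise InvalidInputError("c_true must be positive")


def precision_ci95(estimates, c_true: float) -> float:
    """Worse relative deviation of the empirical 95% interval endpoints."""
    lo, hi = ci95_endpoint_deviations(estimates, c_true)
    return max(lo, hi)


def ci95_endpoint_deviations(estimates, c_true: float) -> tuple[float, float]:
    """Relative deviations of the 2.5% and 97.5% quantiles from c_true."""
    arr = _as_estimates(estimates)
    _check_precision_inputs(arr, c_true)
    q_lo, q_hi = np.quantile(arr, [0.025, 0.975])
    return abs(q_lo - c_true) / c_true, abs(q_hi - c_true) / c_true


def precision_inner90(estimates, c_true: float) -> float:
    """Max relative deviation from c_true within the inner 90% of estimates."""
    arr = _as_estimates(estimates)
    _check_precision_inputs(arr, c_true)
    q5, q95 = np.quantile(arr, [0.05, 0.95])
    inner = arr[(arr >= q5) & (arr <= q95)]
    return float(np.max(np.abs(inner - c_true)) / c_true)


def _cell_metrics(values: np.ndarray, c_true: float) -> dict[str, float]:
    out: dict[str, float] = {}
    out["mean_estimate"] = float(values.mean()) if values.size else np.nan
    out["inaccuracy"] = inaccuracy(values, c_true) if values.size else np.nan
    if values.size >= MIN_ESTIMATES_FOR_PRECISION:
        lo, hi = ci95_endpoint_deviations(values, c_true)
        out["ci95_low_dev"] = lo
        out["ci95_high_dev"] = hi
        out["precision_ci95"] = max(lo, hi)
        out["precision_inner90"] = precision_inner90(values, c_true)
    else:
        out["ci95_low_dev"] = np.nan
        out["ci95_high_dev"] = np.nan
        out["precision_ci95"] = np.nan
        out["precision_inner90"] = np.nan
    return out


def run_study(config: SimConfig) -> SimStudyResult:
    """Run the full grid: concentrations x cv levels x models.

    Deterministic given ``config.seed``: each (concentration, cv) cell gets
    an independent child stream spawned from the seed, so adding or
    reordering models does not perturb the draws.  Iterations on which an
    estimator fails (saturated chip, or p_neg below the closed-form
    validity limit) are counted per model and excluded from the metrics.
    """
    cells = list(itertools.product(config.concentrations, config.cv_levels))
    streams = np.random.SeedSequence(config.seed).spawn(len(cells))
    rows = []
    estimates: dict[tuple[float, float, str], np.ndarray] = {}
    for (conc, cv), stream in zip(cells, streams):
        rng = np.random.default_rng(stream)
        values: dict[str, list[float]] = {m: [] for m in config.models}
        failures: dict[str, int] = {m: 0 for m in config.models}
        vol_nominal = VolumeModel(v0=config.v0, sigma=cv * config.v0)
        for _ in range(config.n_iterations):
            vols = sample_volumes(config.n_partitions, config.v0, cv, rng)
            counts = simulate_chip(conc, vols, rng)
            p_neg = observed_p_negative(counts)
            if config.use_sample_moments:
                vol = VolumeModel(
                    v0=float(vols.mean()), sigma=float(vols.std(ddof=1)) if vols.size > 1 else 0.0
                )
            else:
                vol = vol_nominal
            for model in config.models:
                try:
                    est = estimate(model, p_neg, vol)
                except PoissonPlusError:
                    failures[model] += 1
                    continue
                values[model].append(est.copies_per_microliter)
        for model in config.models:
            arr = np.asarray(values[model], dtype=float)
            if config.keep_estimates:
                estimates[(conc, cv, model)] = arr
            row = {
                "concentration": conc,
                "cv": cv,
                "model": model,
                "n_iterations": config.n_iterations,
                "n_valid": arr.size,
                "n_failed": failures[model],
            }
            if conc > 0 and arr.size:
                row.update(_cell_metrics(arr, conc))
            else:
                row.update(
                    mean_estimate=float(arr.mean()) if arr.size else np.nan,
                    inaccuracy=np.nan,
                    ci95_low_dev=np.nan,
                    ci95_high_dev=np.nan,
                    precision_ci95=np.nan,
                    precision_inner90=np.nan,
                )
            rows.append(row)
    table = pd.DataFrame(rows)
    return SimStudyResult(table=table, config=config, estimates=estimates)


def load_sim_config(path: str | Path) -> SimConfig:
    """Read a study configuration from a YAML (or JSON) mapping."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    known = set(SimConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return SimConfig(**raw)
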