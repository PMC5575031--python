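"""Synthetic chip generator.

Produces chip well tables with the statistical structure the estimators
assume, so calibration and quantification can be exercised end to end with
no instrument data:

* per-well volume ~ Normal(v_mean, cv_volume * v_mean) truncated at zero;
* occupancy ~ Poisson(C * v), call ``pos`` if occupancy > 0 else ``neg``;
* a random fraction of wells relabelled ``undet`` (unfilled/unqualified);
* ROX fluorescence linear in volume plus Gaussian noise whose SD is a
  fraction of the mean ROX level.

The default array is 64 x 313 (20032 wells), close to the 20000-partition
scale of chip-based digital PCR arrays, and the default proxy line and mean
volume match the calibration worked through in :mod:`poissonplus.calibration`.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .estimators import PL_PER_UL
from .simulation import sample_volumes

__all__ = ["GeneratorConfig", "generate_chip", "write_truth_json", "load_generator_config"]


@dataclass(frozen=True)
class GeneratorConfig:
    n_rows: int = 64
    n_cols: int = 313
    v_mean: float = 755.0
    cv_volume: float = 0.08
    concentration: float = 1000.0  # copies/uL
    rox_slope: float = 4454.4  # fluorescence units per pL
    rox_intercept: float = -541.0
    rox_noise_cv: float = 0.01
    undetermined_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise InvalidInputError("array dimensions must be >= 1")
        if not self.v_mean > 0:
            raise InvalidInputError("v_mean must be positive")
        if self.cv_volume < 0 or self.rox_noise_cv < 0:
            raise InvalidInputError("cv parameters must be non-negative")
        if self.concentration < 0:
            raise InvalidInputError("concentration must be non-negative")
        if not 0.0 <= self.undetermined_rate < 1.0:
            raise InvalidInputError("undetermined_rate must be in [0, 1)")

    @property
    def n_wells(self) -> int:
        return self.n_rows * self.n_cols


def generate_chip(config: GeneratorConfig) -> tuple[pd.DataFrame, dict]:
    """Generate one chip table plus a ground-truth sidecar dict.

    Returns ``(table, truth)`` where ``table`` follows the chip CSV schema
    (row, col, rox, call) and ``truth`` records the generating parameters
    together with the realised volume mean/CV and negative fraction, for
    use in assertions.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_wells
    rows, cols = np.divmod(np.arange(n), config.n_cols)

    volumes = sample_volumes(n, config.v_mean, config.cv_volume, rng)
    c_per_pl = config.concentration / PL_PER_UL
    occupancy = rng.poisson(c_per_pl * volumes)
    call = np.where(occupancy > 0, "pos", "neg").astype(object)

    if config.undetermined_rate > 0:
        undet = rng.random(n) < config.undetermined_rate
        call[undet] = "undet"

    mean_rox = config.rox_slope * config.v_mean + config.rox_intercept
    rox = config.rox_slope * volumes + config.rox_intercept
    if config.rox_noise_cv > 0:
        rox = rox + rng.normal(0.0, config.rox_noise_cv * abs(mean_rox), size=n)

    table = pd.DataFrame(
        {"row": rows, "col": cols, "rox": rox, "call": call}
    )
    qualified = call != "undet"
    truth = {
        **asdict(config),
        "n_wells": n,
        "realized_volume_mean": float(volumes.mean()),
        "realized_volume_cv": float(volumes.std(ddof=1) / volumes.mean()) if n > 1 else 0.0,
        "fraction_negative": float(
            np.count_nonzero(call[qualified] == "neg") / max(qualified.sum(), 1)
        ),
    }
    return table, truth


def write_truth_json(truth: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")


def load_generator_config(path: str | Path) -> GeneratorConfig:
    """Read a generator configuration from a YAML (or JSON) mapping."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise InvalidInputError(f"config file {path} must contain a mapping")
    known = set(GeneratorConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
    return GeneratorConfig(**raw)
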