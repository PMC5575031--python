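"""Per-chip volume-variation calibration from ROX fluorescence.

The ROX passive-reference dye is carried in the master mix, so each well's
ROX reading scales with the volume of mix the well actually received.  The
coefficient of variation (CV) of ROX across a clean population of wells is
therefore a proxy for the CV of the effective load volume — the quantity
the Poisson-Plus estimators need.

If average ROX is linear in average fill volume, R = s*v + b, then
mean and SD propagate as mean(R) = s*mean(v) + b and std(R) = s*std(v), so

    CV_R / CV_v = s*v_mean / (s*v_mean + b)

For the reference fit R = 4454.4*v - 541 evaluated at v_mean = 755 pL the
factor is 1.0002: ROX CV can stand in for volume CV essentially unchanged,
which is the package default (dividing by the factor is optional).

Population selection follows the rule: use wells in the central region of
the array (edges suffer evaporation and related artefacts); among them use
the negatives if more than ``min_negatives`` are available, otherwise the
positives.  Undetermined wells never enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .chip import qualified_counts, validate_chip_table
from .errors import CalibrationError, InvalidInputError, PoissonPlusError
from .estimators import (
    ConcentrationEstimate,
    VolumeModel,
    estimate,
)

__all__ = [
    "LinearProxyFit",
    "ChipCvEstimate",
    "fit_linear_proxy",
    "cv_proxy_factor",
    "select_population",
    "estimate_chip_cv",
    "quantify_chip",
    "DEFAULT_V_MEAN",
    "DEFAULT_REGION_MARGIN",
    "DEFAULT_MIN_NEGATIVES",
]

#: mean through-hole fill volume fixed by manufacturing specification, pL
DEFAULT_V_MEAN = 755.0
#: fraction of rows/columns excluded at each array edge
DEFAULT_REGION_MARGIN = 0.15
#: negatives required in the central region before they are preferred
DEFAULT_MIN_NEGATIVES = 50


@dataclass(frozen=True)
class LinearProxyFit:
    """OLS fit of mean ROX on mean fill volume across chips."""

    slope: float  # fluorescence units per picoliter
    intercept: float  # fluorescence units
    r: float  # correlation coefficient of the fitted points

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise CalibrationError(
                f"proxy slope must be positive (ROX increases with volume), "
                f"got {self.slope}"
            )

    def predict(self, v: float) -> float:
        return self.slope * v + self.intercept


@dataclass(frozen=True)
class ChipCvEstimate:
    """Per-chip volume-CV estimate derived from ROX statistics."""

    cv_rox: float
    cv_volume: float
    population_used: str  # "negatives" or "positives"
    n_wells_used: int
    region: str
    scaling_factor: float = 1.0
    v_mean: float = DEFAULT_V_MEAN

    @property
    def sigma(self) -> float:
        """Spread parameter handed to the estimators, pL."""
        return self.scaling_factor * self.cv_volume * self.v_mean

    def to_volume_model(self) -> VolumeModel:
        return VolumeModel(v0=self.v_mean, sigma=self.sigma)


def fit_linear_proxy(mean_volumes, mean_rox) -> LinearProxyFit:
    """Fit R = slope*v + intercept by ordinary least squares over chips."""
    v = np.asarray(mean_volumes, dtype=float)
    r = np.asarray(mean_rox, dtype=float)
    if v.shape != r.shape or v.ndim != 1:
        raise InvalidInputError("mean_volumes and mean_rox must be equal-length 1-d")
    if v.size < 2:
        raise InvalidInputError("need at least two chips to fit the proxy line")
    if np.any(v <= 0):
        raise InvalidInputError("mean volumes must be positive")
    if np.ptp(v) == 0:
        raise CalibrationError("degenerate fit: all mean volumes identical")
    res = stats.linregress(v, r)
    return LinearProxyFit(
        slope=float(res.slope), intercept=float(res.intercept), r=float(res.rvalue)
    )


def cv_proxy_factor(fit: LinearProxyFit, v_mean: float) -> float:
    """Multiplier CV_R / CV_v implied by the linear proxy at ``v_mean``.

    Equals ``slope*v_mean / (slope*v_mean + intercept)``; errors if the
    predicted mean fluorescence is non-positive.
    """
    if not v_mean > 0:
        raise InvalidInputError(f"v_mean must be positive, got {v_mean}")
    predicted = fit.predict(v_mean)
    if predicted <= 0:
        raise CalibrationError(
            f"predicted mean fluorescence {predicted:.4g} <= 0 at v_mean={v_mean}"
        )
    return fit.slope * v_mean / predicted


def _central_mask(df: pd.DataFrame, region_margin: float) -> pd.Series:
    n_rows = int(df["row"].max()) + 1
    n_cols = int(df["col"].max()) + 1
    r_lo = math.ceil(region_margin * n_rows)
    c_lo = math.ceil(region_margin * n_cols)
    r_hi = n_rows - r_lo
    c_hi = n_cols - c_lo
    if r_lo >= r_hi or c_lo >= c_hi:
        raise CalibrationError(
            f"region margin {region_margin} leaves no central wells on a "
            f"{n_rows}x{n_cols} array"
        )
    return (
        (df["row"] >= r_lo)
        & (df["row"] < r_hi)
        & (df["col"] >= c_lo)
        & (df["col"] < c_hi)
    )


def select_population(
    chip: pd.DataFrame,
    region_margin: float = DEFAULT_REGION_MARGIN,
    min_negatives: int = DEFAULT_MIN_NEGATIVES,
) -> tuple[pd.DataFrame, str]:
    """Pick the ROX reference population: central negatives, else positives.

    Wells strictly inside an outer margin of ``region_margin`` of the array
    extent are candidates; among them, the negatives are used if there are
    more than ``min_negatives`` of them, otherwise the positives.
    Undetermined wells are excluded throughout.
    """
    chip = validate_chip_table(chip)
    if not 0.0 <= region_margin < 0.5:
        raise InvalidInputError("region_margin must be in [0, 0.5)")
    central = chip[_central_mask(chip, region_margin)]
    negatives = central[central["call"] == "neg"]
    positives = central[central["call"] == "pos"]
    if len(negatives) > min_negatives:
        return negatives, "negatives"
    if len(positives) > 0:
        return positives, "positives"
    raise CalibrationError(
        "no usable population in the central region "
        f"({len(negatives)} negatives, {len(positives)} positives)"
    )


def estimate_chip_cv(
    chip: pd.DataFrame,
    fit: LinearProxyFit | None = None,
    v_mean: float = DEFAULT_V_MEAN,
    scaling_factor: float = 1.0,
    region_margin: float = DEFAULT_REGION_MARGIN,
    min_negatives: int = DEFAULT_MIN_NEGATIVES,
) -> ChipCvEstimate:
    """Estimate the volume CV of one chip from its ROX readings.

    ``cv_rox`` is SD/mean of ROX over the selected population.  When a
    proxy ``fit`` is supplied, ``cv_volume = cv_rox / cv_proxy_factor``;
    otherwise the factor is taken as 1 (adequate whenever the proxy
    intercept is small relative to the mean fluorescence).
    ``scaling_factor`` multiplies the CV on the way to sigma, allowing
    non-volumetric variation sources to be folded in (e.g. a factor of 2).
    """
    if not scaling_factor > 0:
        raise InvalidInputError(f"scaling_factor must be positive, got {scaling_factor}")
    population, label = select_population(chip, region_margin, min_negatives)
    rox = population["rox"].to_numpy(dtype=float)
    mean_rox = rox.mean()
    if mean_rox <= 0:
        raise CalibrationError(f"mean ROX of selected population is {mean_rox:.4g} <= 0")
    sd_rox = rox.std(ddof=1) if rox.size > 1 else 0.0
    cv_rox = sd_rox / mean_rox
    cv_volume = cv_rox / cv_proxy_factor(fit, v_mean) if fit is not None else cv_rox
    return ChipCvEstimate(
        cv_rox=float(cv_rox),
        cv_volume=float(cv_volume),
        population_used=label,
        n_wells_used=int(rox.size),
        region=f"central (margin {region_margin:g})",
        scaling_factor=scaling_factor,
        v_mean=v_mean,
    )


def quantify_chip(
    chip: pd.DataFrame,
    v_mean: float = DEFAULT_V_MEAN,
    cv: float | str = "auto",
    model: str = "poisson_plus",
    fit: LinearProxyFit | None = None,
    scaling_factor: float = 1.0,
    region_margin: float = DEFAULT_REGION_MARGIN,
    min_negatives: int = DEFAULT_MIN_NEGATIVES,
) -> ConcentrationEstimate:
    """Quantify one chip: count negatives, pick a CV, run the estimator.

    ``cv="auto"`` estimates the volume CV per chip from ROX (the default
    production behaviour); a float fixes the CV directly (the scaling
    factor then still applies).  Returns a :class:`ConcentrationEstimate`
    whose ``copies_per_microliter`` is the headline number.
    """
    chip = validate_chip_table(chip)
    n_total, n_negative = qualified_counts(chip)
    p_neg = n_negative / n_total
    if isinstance(cv, str):
        if cv != "auto":
            raise InvalidInputError(f"cv must be a number or 'auto', got {cv!r}")
        cv_value = estimate_chip_cv(
            chip,
            fit=fit,
            v_mean=v_mean,
            scaling_factor=scaling_factor,
            region_margin=region_margin,
            min_negatives=min_negatives,
        ).cv_volume
    else:
        if cv < 0:
            raise InvalidInputError(f"cv must be non-negative, got {cv}")
        cv_value = float(cv)
    vol = VolumeModel(v0=v_mean, sigma=scaling_factor * cv_value * v_mean)
    try:
        return estimate(model, p_neg, vol)
    except PoissonPlusError as exc:
        raise type(exc)(
            f"{exc} [chip: {n_total} qualified wells, {n_negative} negative, "
            f"cv={cv_value:.4g}, model={model}]"
        ) from exc
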