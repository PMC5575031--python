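"""Concentration estimators for digital PCR under partition-volume variability.

Digital PCR estimates a nucleic-acid concentration from the fraction of
partitions that record no target molecule.  The standard Poisson estimator
assumes every partition holds the same volume; when the effective load
volume varies from partition to partition the standard estimator is biased
low, increasingly so at high concentration.  This module implements three
estimators of the concentration ``C`` (copies per unit volume) from the
observed negative fraction ``p_neg``:

``poisson``
    Constant volume ``v0``:  ``C = -ln(p_neg) / v0``.

``poisson_plus_approx``
    Volumes normally distributed with mean ``v0`` and SD ``sigma``;
    marginalising the per-partition Poisson zero-class over the normal
    density gives ``P(neg) = exp(sigma^2 C^2 / 2 - C v0)`` and the
    closed-form inverse ``C = (v0 - sqrt(v0^2 + 2 sigma^2 ln p_neg)) /
    sigma^2`` (the root that reduces to the Poisson form as sigma -> 0).
    Real solutions require ``p_neg >= exp(-(v0/sigma)^2 / 2)``.

``poisson_plus``
    Volumes follow a normal distribution truncated at zero, the physically
    consistent model.  The forward map is

    ``P(neg) = erfc(-(v0/sigma - C sigma)/sqrt(2)) / erfc(-(v0/sigma)/sqrt(2))
    * exp(-C v0 + sigma^2 C^2 / 2)``

    and ``C`` is recovered by bracketed root finding.

Volumes are picoliters throughout; concentrations are stored per picoliter
and reported as copies per microliter (1 uL = 1e6 pL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, special, stats

from .errors import (
    BelowValidityLimitError,
    InvalidInputError,
    NumericalError,
    SaturatedChipError,
)

__all__ = [
    "VolumeModel",
    "PartitionCounts",
    "ConcentrationEstimate",
    "observed_p_negative",
    "estimate_poisson",
    "validity_limit_p_neg",
    "estimate_poisson_plus_approx",
    "p_negative_forward",
    "estimate_poisson_plus",
    "estimate",
    "to_copies_per_microliter",
    "volume_model_from_moments",
    "binomial_resampling_ci",
    "MODEL_NAMES",
]

PL_PER_UL = 1.0e6

#: sigma/v0 below this routes through the constant-volume formula; the
#: closed-form inverse is 0/0-indeterminate at sigma = 0.
SIGMA_SWITCH = 1e-8

#: cv above which normal/truncated-normal parameters stop tracking the
#: sample moments closely; flagged, not fatal.
CV_WARN_DEFAULT = 0.5

MODEL_NAMES = ("poisson", "poisson_plus_approx", "poisson_plus")

_SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class VolumeModel:
    """Effective-load volume distribution parameters.

    Parameters
    ----------
    v0 : float
        Mean-volume parameter in picoliters.  Must be positive.
    sigma : float
        Spread parameter (SD) in picoliters.  Must be non-negative.
    cv_warn_threshold : float
        cv = sigma/v0 above this marks the regime where identifying the
        distribution parameters with the sample moments degrades.
    """

    v0: float
    sigma: float
    cv_warn_threshold: float = CV_WARN_DEFAULT

    def __post_init__(self) -> None:
        if not (self.v0 > 0 and math.isfinite(self.v0)):
            raise InvalidInputError(f"v0 must be positive and finite, got {self.v0}")
        if not (self.sigma >= 0 and math.isfinite(self.sigma)):
            raise InvalidInputError(
                f"sigma must be non-negative and finite, got {self.sigma}"
            )

    @property
    def cv(self) -> float:
        return self.sigma / self.v0

    @property
    def cv_exceeds_threshold(self) -> bool:
        return self.cv > self.cv_warn_threshold


@dataclass(frozen=True)
class PartitionCounts:
    """Total and negative partition counts on one chip."""

    n_total: int
    n_negative: int

    def __post_init__(self) -> None:
        if self.n_total < 1:
            raise InvalidInputError(f"n_total must be >= 1, got {self.n_total}")
        if not 0 <= self.n_negative <= self.n_total:
            raise InvalidInputError(
                f"n_negative must be in [0, n_total], got {self.n_negative}"
            )

    @property
    def n_positive(self) -> int:
        return self.n_total - self.n_negative


@dataclass(frozen=True)
class ConcentrationEstimate:
    """A concentration estimate with its provenance.

    ``c_per_volume`` is copies per picoliter; ``lambda_mean`` is copies per
    mean partition (``c_per_volume * v0``); ``copies_per_microliter`` is the
    reporting unit (``c_per_volume * 1e6``).
    """

    c_per_volume: float
    lambda_mean: float
    model: str
    at_validity_limit: bool = False
    notes: str = ""

    def __post_init__(self) -> None:
        if self.c_per_volume < 0:
            raise InvalidInputError("c_per_volume must be non-negative")
        if self.model not in MODEL_NAMES:
            raise InvalidInputError(f"unknown model {self.model!r}")

    @property
    def copies_per_microliter(self) -> float:
        return self.c_per_volume * PL_PER_UL


def observed_p_negative(counts: PartitionCounts) -> float:
    """Observed fraction of negative partitions, ``n_negative / n_total``."""
    return counts.n_negative / counts.n_total


def _check_p_neg(p_neg: float) -> None:
    if not (0.0 <= p_neg <= 1.0) or not math.isfinite(p_neg):
        raise InvalidInputError(f"p_neg must lie in [0, 1], got {p_neg}")
    if p_neg == 0.0:
        raise SaturatedChipError(
            "all partitions positive (p_neg = 0): no finite concentration estimate"
        )


def estimate_poisson(p_neg: float, v0: float) -> ConcentrationEstimate:
    """Standard Poisson estimator, ``C = -ln(p_neg)/v0``, constant volume."""
    _check_p_neg(p_neg)
    if not v0 > 0:
        raise InvalidInputError(f"v0 must be positive, got {v0}")
    c = -math.log(p_neg) / v0
    return ConcentrationEstimate(c_per_volume=c, lambda_mean=c * v0, model="poisson")


def validity_limit_p_neg(vol: VolumeModel) -> float:
    """Smallest p_neg for which the closed-form inverse has a real solution.

    Equals ``exp(-0.5 * (v0/sigma)^2)``; zero when sigma = 0 (no constraint).
    """
    if vol.sigma == 0.0:
        return 0.0
    return math.exp(-0.5 * (vol.v0 / vol.sigma) ** 2)


def estimate_poisson_plus_approx(
    p_neg: float, vol: VolumeModel
) -> ConcentrationEstimate:
    """Closed-form estimator under the (untruncated) normal volume model.

    Solves ``p_neg = exp(sigma^2 C^2/2 - C v0)`` for the root that reduces
    to the Poisson estimate as sigma -> 0.  Raises
    :class:`BelowValidityLimitError` when ``p_neg`` falls below
    :func:`validity_limit_p_neg` (negative discriminant).
    """
    _check_p_neg(p_neg)
    v0, sigma = vol.v0, vol.sigma
    if sigma / v0 < SIGMA_SWITCH:
        c = -math.log(p_neg) / v0
        return ConcentrationEstimate(
            c_per_volume=c,
            lambda_mean=c * v0,
            model="poisson_plus_approx",
            notes="sigma ~ 0: constant-volume formula used",
        )
    disc = v0 * v0 + 2.0 * sigma * sigma * math.log(p_neg)
    tol = 1e-12 * v0 * v0
    if disc < -tol:
        raise BelowValidityLimitError(
            f"p_neg={p_neg:.6g} below validity limit "
            f"{validity_limit_p_neg(vol):.6g} (cv={vol.cv:.3g}): "
            "closed-form solution would be imaginary"
        )
    if disc < tol:
        c = v0 / (sigma * sigma)
        return ConcentrationEstimate(
            c_per_volume=c,
            lambda_mean=c * v0,
            model="poisson_plus_approx",
            at_validity_limit=True,
            notes="discriminant ~ 0: boundary solution C = v0/sigma^2",
        )
    c = (v0 - math.sqrt(disc)) / (sigma * sigma)
    return ConcentrationEstimate(
        c_per_volume=c, lambda_mean=c * v0, model="poisson_plus_approx"
    )


def p_negative_forward(c, vol: VolumeModel):
    """P(neg) for concentration ``c`` under the truncated-normal volume model.

    ``c`` is copies per picoliter; scalar or array.  The truncated-normal
    marginal is

    ``erfc(-(v0/s - c s)/sqrt(2)) / erfc(-(v0/s)/sqrt(2))
    * exp(-c v0 + s^2 c^2 / 2)``.

    With ``a = v0/sigma`` and ``t = (c sigma - a)/sqrt(2)`` the exponent is
    identically ``t^2 - a^2/2``, so for ``t > 0`` the product is evaluated
    as ``erfcx(t) * exp(-a^2/2)`` (``erfcx(t) = exp(t^2) erfc(t)``), which
    cannot overflow for large ``c``; for ``t <= 0`` the exponent is
    non-positive and the direct form is safe.
    """
    scalar = np.ndim(c) == 0
    c_arr = np.atleast_1d(np.asarray(c, dtype=float))
    if np.any(c_arr < 0) or not np.all(np.isfinite(c_arr)):
        raise InvalidInputError("c must be non-negative and finite")
    v0, sigma = vol.v0, vol.sigma

    if sigma / v0 < SIGMA_SWITCH:
        out = np.exp(-c_arr * v0)
        return float(out[0]) if scalar else out

    a = v0 / sigma
    t = (c_arr * sigma - a) / _SQRT2
    denom = special.erfc(-a / _SQRT2)
    out = np.empty_like(c_arr)
    lo = t <= 0.0
    out[lo] = (
        special.erfc(t[lo])
        * np.exp(-c_arr[lo] * v0 + 0.5 * (sigma * c_arr[lo]) ** 2)
        / denom
    )
    hi = ~lo
    if np.any(hi):
        out[hi] = special.erfcx(t[hi]) * math.exp(-0.5 * a * a) / denom
    return float(out[0]) if scalar else out


def estimate_poisson_plus(p_neg: float, vol: VolumeModel) -> ConcentrationEstimate:
    """Full truncated-normal estimator: numerically inverts the forward map.

    The forward map is strictly decreasing in ``c``, so the root is unique;
    it is bracketed on ``[0, c_hi]`` with ``c_hi`` starting at 10x the
    Poisson estimate and doubled until the bracket is valid, then solved
    with Brent's method to relative tolerance 1e-12.
    """
    _check_p_neg(p_neg)
    v0, sigma = vol.v0, vol.sigma
    if p_neg == 1.0:
        return ConcentrationEstimate(
            c_per_volume=0.0, lambda_mean=0.0, model="poisson_plus"
        )
    if sigma / v0 < SIGMA_SWITCH:
        c = -math.log(p_neg) / v0
        return ConcentrationEstimate(
            c_per_volume=c,
            lambda_mean=c * v0,
            model="poisson_plus",
            notes="sigma ~ 0: constant-volume formula used",
        )

    def f(c: float) -> float:
        return p_negative_forward(np.array([c]), vol)[0] - p_neg

    c_hi = 10.0 * (-math.log(p_neg) / v0)
    for _ in range(60):
        if f(c_hi) < 0.0:
            break
        c_hi *= 2.0
    else:
        raise NumericalError(
            f"could not bracket root for p_neg={p_neg:.6g}, "
            f"v0={v0:.6g}, sigma={sigma:.6g} after 60 doublings (c_hi={c_hi:.6g})"
        )
    try:
        c = optimize.brentq(f, 0.0, c_hi, rtol=1e-12, xtol=1e-15 * c_hi)
    except Exception as exc:  # pragma: no cover - defensive
        raise NumericalError(f"root finding failed: {exc}") from exc
    return ConcentrationEstimate(c_per_volume=c, lambda_mean=c * v0, model="poisson_plus")


_ESTIMATORS: dict[str, Callable] = {
    "poisson": lambda p, vol: estimate_poisson(p, vol.v0),
    "poisson_plus_approx": estimate_poisson_plus_approx,
    "poisson_plus": estimate_poisson_plus,
}


def estimate(model: str, p_neg: float, vol: VolumeModel) -> ConcentrationEstimate:
    """Dispatch to the named estimator (one of :data:`MODEL_NAMES`)."""
    try:
        fn = _ESTIMATORS[model]
    except KeyError:
        raise InvalidInputError(
            f"unknown model {model!r}; choose from {MODEL_NAMES}"
        ) from None
    return fn(p_neg, vol)


def to_copies_per_microliter(est) -> float:
    """Convert an estimate (or a bare copies/pL value) to copies per microliter."""
    if isinstance(est, ConcentrationEstimate):
        return est.copies_per_microliter
    return float(est) * PL_PER_UL


def volume_model_from_moments(
    mean: float, sd: float, moment_match: bool = False
) -> VolumeModel:
    """Build a :class:`VolumeModel` from sample moments of measured volumes.

    By default the sample mean and SD are used directly as (v0, sigma), the
    behaviour adequate whenever cv is moderate.  With ``moment_match=True``
    the (v0, sigma) of the zero-truncated normal whose first two moments
    equal (mean, sd) are solved for instead; this only matters at large cv,
    where truncation shifts the moments away from the parameters.
    """
    if not mean > 0:
        raise InvalidInputError(f"mean volume must be positive, got {mean}")
    if sd < 0:
        raise InvalidInputError(f"sd must be non-negative, got {sd}")
    if not moment_match or sd == 0.0:
        return VolumeModel(v0=mean, sigma=sd)

    def residuals(x):
        m, log_s = x
        s = math.exp(log_s)
        mu_t, var_t = stats.truncnorm.stats(
            -m / s, np.inf, loc=m, scale=s, moments="mv"
        )
        return [float(mu_t) - mean, math.sqrt(float(var_t)) - sd]

    sol = optimize.least_squares(
        residuals, x0=[mean, math.log(sd)], xtol=1e-14, ftol=1e-14
    )
    if not sol.success or np.max(np.abs(sol.fun)) > 1e-6 * mean:
        raise NumericalError(
            f"moment matching failed for mean={mean}, sd={sd}: {sol.message}"
        )
    m, log_s = sol.x
    return VolumeModel(v0=float(m), sigma=float(math.exp(log_s)))


def binomial_resampling_ci(
    counts: PartitionCounts,
    vol: VolumeModel,
    model: str = "poisson_plus",
    level: float = 0.95,
    n_boot: int = 2000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Bootstrap confidence interval on the concentration, copies/uL.

    Resamples the negative count as Binomial(n_total, p_hat) and pushes each
    replicate through the chosen estimator.  This is a convenience added by
    this package (the estimators themselves define no interval); replicates
    that hit an estimator error are dropped.
    """
    if rng is None:
        rng = np.random.default_rng()
    if not 0 < level < 1:
        raise InvalidInputError(f"level must be in (0, 1), got {level}")
    p_hat = observed_p_negative(counts)
    neg = rng.binomial(counts.n_total, p_hat, size=n_boot)
    values = []
    for k in neg:
        try:
            values.append(
                estimate(model, k / counts.n_total, vol).copies_per_microliter
            )
        except (SaturatedChipError, BelowValidityLimitError):
            continue
    if len(values) < max(20, n_boot // 10):
        raise NumericalError("too few valid bootstrap replicates for a CI")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(values, [alpha, 1.0 - alpha])
    return float(lo), float(hi)
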