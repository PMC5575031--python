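# Methods

## Model

A digital PCR chip splits a reaction across N partitions.  Partition
occupancy is Poisson with mean proportional to the partition's effective
load volume, λ(v) = C·v, so a partition of volume v is negative with
probability e^(−Cv).  Three volume assumptions give three estimators of C
from the observed negative fraction p:

1. **poisson** — all partitions share volume v₀: C = −ln p / v₀.
2. **poisson_plus_approx** — v ~ Normal(v₀, σ).  The marginal negative
   probability is exp(σ²C²/2 − Cv₀); of the two roots of the resulting
   quadratic in C, the one with the negative square-root sign is kept
   because it reduces to the Poisson form as σ → 0.  The discriminant
   v₀² + 2σ² ln p is non-negative only for p ≥ exp(−(v₀/σ)²/2) — the
   *validity limit*; below it the estimator raises an error, exactly at it
   (within 1e−12·v₀² of zero) it returns the boundary solution C = v₀/σ²
   flagged `at_validity_limit`.
3. **poisson_plus** — v follows a normal truncated at zero, removing the
   unphysical negative-volume mass.  The forward map is
   P(neg) = erfc(−(v₀/σ − Cσ)/√2) / erfc(−(v₀/σ)/√2) · exp(−Cv₀ + σ²C²/2),
   strictly decreasing in C; C is recovered by root finding.

All volumes are picoliters; concentrations are carried as copies/pL and
reported as copies/µL (×10⁶).  λ per mean partition is C·v₀.

The parameters (v₀, σ) are used directly as the mean and SD of the volume
distribution.  This identification degrades as cv = σ/v₀ grows (the
truncated normal's moments drift away from its parameters); models flag
cv > 0.5 and an optional moment-matching solver
(`volume_model_from_moments(..., moment_match=True)`) recovers the
truncated-normal parameters from measured moments when needed.

## Numerics

* **Forward-map stability.**  With a = v₀/σ and t = (Cσ − a)/√2 the
  exponent −Cv₀ + σ²C²/2 equals t² − a²/2.  For t ≤ 0 the exponent is
  non-positive and the direct product is safe; for t > 0 the product
  erfc(t)·e^(t²) is evaluated as `scipy.special.erfcx(t)`, so no
  intermediate overflows however large C is.  Agreement with adaptive
  quadrature of the truncated-normal mixture integrand is verified to
  1e−9 absolute.
* **Inversion.**  Brent's method on [0, c_hi]; c_hi starts at 10× the
  Poisson estimate and doubles (≤ 60 times) until the bracket is valid;
  convergence at relative 1e−12, comfortably inside the 1e−10 contract.
  Round-trip error (forward then invert) is below 1e−8 relative for
  λ ∈ [0.01, 5] and cv up to 0.3.
* **σ = 0 switch.**  σ/v₀ < 1e−8 routes both volume-aware estimators and
  the forward map through the constant-volume formulas, avoiding the 0/0
  at σ = 0.
* **Degenerate inputs.**  p = 0 (all positive) raises a saturated-chip
  error everywhere; p = 1 returns C = 0; counts and probabilities are
  validated at construction.

## Monte Carlo study

Each iteration draws N volumes from Normal(v₀, cv·v₀) truncated at zero by
rejection (negative draws are redrawn — negative volumes are unphysical,
and rejection makes the simulated distribution exactly the truncated
normal the full model assumes), draws per-partition occupancy
Poisson(C·vᵢ), thresholds at zero, and feeds the negative fraction to each
estimator.  Estimators receive the generating (v₀, cv·v₀) — the scenario
in which the variation statistics are well characterized; per-iteration
sample moments are available via `use_sample_moments`.

Metrics over the K per-cell estimates:

* **inaccuracy** = |mean − C_true| / C_true;
* **precision_ci95** = the worse of the two relative deviations of the
  empirical 2.5% and 97.5% quantiles from C_true ("the 95% confidence
  bound" is a single bound; taking the max is the conservative reading,
  and both endpoint deviations are reported separately);
* **precision_inner90** = max relative deviation among estimates between
  the empirical 5% and 95% quantiles.

Quantiles use linear interpolation of order statistics (`numpy.quantile`
default).  Iterations where an estimator fails (saturated chip, or p below
the approximation's validity limit) are counted per model and excluded
from that model's metrics, never fatal.  Each (concentration, cv) cell
gets an independent child stream spawned from the study seed, so results
are bitwise reproducible and independent of the model list.

Reference design: 20000 partitions, v₀ = 755 pL, cv ∈ {0.1, 0.2, 0.3},
10000 iterations per cell.  The default test and acceptance profile runs
500 iterations per cell, which bounds the Monte Carlo SE of a cell mean at
roughly 0.1% of C_true — an order of magnitude below the effects asserted
(Poisson bias ≈ λ·cv²/2, e.g. 6.8% at λ = 1.5, cv = 0.3).  Expected
behaviour, verified by the suite: the Poisson bias is always downward,
grows with concentration and cv, and all three models agree to < 1% where
λ·cv²/2 ≪ 1 (at 30% cv that equivalence region ends near ~300 copies/µL;
at ≤ 20% it extends past 400 copies/µL).

## ROX calibration

Chip platforms cannot measure each well's fill volume directly, but the
ROX passive-reference dye travels with the master mix, so per-well ROX
fluorescence is a volume proxy.  If average ROX is linear in average
volume, R = s·v + b, means and SDs propagate as R̄ = s·v̄ + b and
std(R) = s·std(v), hence

    CV_R / CV_v = s·v̄ / (s·v̄ + b).

For the reference fit R = 4454.4·v − 541 at v̄ = 755 pL this factor is
1.0002: ROX CV stands in for volume CV essentially unchanged.  The package
therefore defaults to cv_volume = cv_rox; passing a `LinearProxyFit`
divides by the factor explicitly.

Per-chip CV estimation uses a single clean well population: wells strictly
inside a fractional margin of the array extent (default: the outer 15% of
rows and columns is excluded — chip edges are prone to evaporation and
related artefacts; the margin is configurable since no canonical
definition of the central region exists), negatives preferred when more
than 50 are available there, otherwise positives, undetermined wells never.
`scaling_factor` multiplies the CV before σ is formed (default 1.0; a
factor of 2 is a documented scenario for folding non-volumetric variation
into σ, deliberately not the default).

Quantification counts negatives over all qualified (pos/neg) wells of the
chip, builds VolumeModel(v̄, scaling·cv·v̄) with v̄ fixed by manufacturing
specification (default 755 pL) and cv either supplied or calibrated per
chip, and runs the chosen estimator.

## Synthetic chips

The generator emulates exactly the structure the method assumes: truncated
normal volumes, volume-proportional Poisson occupancy, ROX linear in
volume plus Gaussian noise (SD = `rox_noise_cv` × mean ROX, default 1%), a
fraction of wells relabelled undetermined, on a default 64×313 array
(20032 wells) at v̄ = 755 pL.  Default proxy line: the reference fit
above.  What it does **not** emulate — spatial gradients (evaporation,
edge effects), optical crosstalk, miscalls, volume distributions that are
not truncated normal — is precisely what passing end-to-end tests cannot
attest to on real chips; on synthetic data the central-region rule is
load-bearing only for population selection, not bias removal.

ROX noise inflates cv_rox slightly above the volume CV (in quadrature:
√(cv_v² + cv_noise²) ≈ 0.0806 for 8% volume CV and 1% noise), and
selecting negatives tilts the population toward smaller volumes; both
effects are second-order for quantification (a δcv perturbation moves the
estimate by ≈ λ·cv·δcv) and are absorbed well inside the 2% end-to-end
recovery verified at λ = 1.5, cv = 0.08 over 100 chips.

## Limitations

* Both volume-aware estimators assume the volume CV is known or well
  estimated; a misspecified CV biases the correction itself.
* The closed-form model is unusable below its validity limit
  p < exp(−(v₀/σ)²/2); the full model has no such limit but still loses
  all information at p = 0 (saturation).
* Positive/negative calls are inputs; no thresholding of raw fluorescence
  is performed, and undetermined-well identification is left to the
  caller.
* The bootstrap CI on p_neg captures sampling error only, not calibration
  error in (v₀, σ); it is a convenience of this package, not part of the
  model.
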