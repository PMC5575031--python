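# poissonplus

Digital PCR quantification that stays accurate when partitions do not all
hold the same volume.

Digital PCR spreads a sample over many thousands of partitions (on chip
arrays, "through-holes"), amplifies, and estimates the target concentration
*C* from the fraction of partitions with no amplification, *P*(neg).  The
standard estimator assumes identical partition volumes *v₀*:

    C = −ln P(neg) / v₀

When the effective load volume varies between partitions (even on arrays
with fixed geometry, the volume of mix each well actually captures varies),
this estimator is biased low — increasingly so at high concentration.  If
the per-partition occupancy is Poisson with mean λ(v) = C·v and volumes are
normally distributed with mean v₀ and SD σ, marginalising over volume gives
P(neg) = exp(σ²C²/2 − Cv₀), with the closed-form inverse

    C = (v₀ − √(v₀² + 2σ² ln P(neg))) / σ²        (real for P(neg) ≥ e^(−(v₀/σ)²/2))

Replacing the normal by the physically consistent zero-truncated normal
yields the full model

    P(neg) = erfc(−(v₀/σ − Cσ)/√2) / erfc(−(v₀/σ)/√2) · exp(−Cv₀ + σ²C²/2)

which is inverted numerically (bracketed Brent search on the strictly
decreasing forward map, evaluated through `erfcx` so large C cannot
overflow).

The package provides:

* `poissonplus.estimators` — the three estimators (`poisson`,
  `poisson_plus_approx`, `poisson_plus`), the forward map, validity limit,
  unit conversions and an optional bootstrap CI;
* `poissonplus.simulation` — the Monte Carlo study comparing the models by
  inaccuracy (|mean − truth|/truth) and precision (relative deviation of
  the 95% interval endpoints, or of the inner-90% extremes);
* `poissonplus.calibration` — per-chip volume-CV estimation using the ROX
  passive-reference dye as a volume proxy (central-region well selection,
  negatives-preferred population rule, the CV_R/CV_v propagation factor),
  and one-call chip quantification;
* `poissonplus.chipgen` — a synthetic chip generator embodying the model's
  generative assumptions, for end-to-end testing without instrument data;
* a `poissonplus` CLI with `quantify`, `simulate` and `generate`
  subcommands.

## Worked example

Generate a synthetic chip (64×313 wells, mean volume 755 pL, volume CV 8%,
true concentration 2000 copies/µL), then quantify it with the volume CV
calibrated per chip from its ROX readings:

```sh
poissonplus generate --config gen.yaml --out chip.csv --truth truth.json
poissonplus quantify --chip chip.csv --cv auto --model all
```

with `gen.yaml`:

```yaml
concentration: 2000.0
cv_volume: 0.08
seed: 42
```

prints (abridged):

```json
{
  "n_qualified": 20032,
  "n_negative": 4471,
  "p_negative": 0.2231928913738019,
  "estimates": {
    "poisson":             {"copies_per_microliter": 1986.38, "lambda_mean": 1.4997},
    "poisson_plus_approx": {"copies_per_microliter": 1996.47, "lambda_mean": 1.5073},
    "poisson_plus":        {"copies_per_microliter": 1996.47, "lambda_mean": 1.5073}
  }
}
```

The chip runs at λ ≈ 1.5 copies per mean partition.  The standard Poisson
estimate (1986.4 copies/µL) sits ~0.7% below the truth; the volume-aware
models, fed the CV calibrated from this chip's own ROX spread, land within
0.2% (1996.5 copies/µL).  At 8% volume CV the closed-form approximation and
the full truncated-normal model agree to ~13 significant figures.

The same comparison as a Monte Carlo study (`poissonplus simulate --config
study.yaml --out results.csv`, 20000 partitions, 200 iterations per cell)
gives:

```text
 concentration  cv               model  mean_estimate  inaccuracy  precision_ci95
         400.0 0.1             poisson     399.285202    0.001787        0.029276
         400.0 0.1        poisson_plus     399.889003    0.000277        0.027849
         400.0 0.3             poisson     394.927475    0.012681        0.033529
         400.0 0.3        poisson_plus     400.152564    0.000381        0.024050
        2000.0 0.1             poisson    1982.781667    0.008609        0.026157
        2000.0 0.1        poisson_plus    1997.850290    0.001075        0.018890
        2000.0 0.3             poisson    1866.560280    0.066720        0.083125
        2000.0 0.3        poisson_plus    2000.468599    0.000234        0.018689
```

The Poisson bias grows with both concentration and volume CV (6.7% at
2000 copies/µL and 30% CV) while the truncated-normal model stays unbiased
with visibly tighter precision.

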