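# nemaquant

Quantification pipelines for three *C. elegans* behavioral and
physiological assays, plus a synthetic-data generator that produces inputs
with known ground truth for all of them. The package is aimed at worm labs
quantifying locomotion from multiwell time-lapse recordings, scoring
proprioceptive responses in microfluidic channel assays, and running
lifespan-assay statistics — without re-deriving the bespoke metrics each
time.

## What it computes

**Activity and the dwelling fraction** (`nemaquant.activity`). Per-interval
activity of a single worm is the changed-pixel count of consecutive
frames: the absolute difference image, normalized by the mean intensity of
the two frames, Gaussian-filtered (σ = 1 px), binarized at 0.6, and summed.
After 5 s smoothing, each worm's activity histogram (zero/quiescence bin
excluded) is decomposed by nonlinear least squares into

    c₁·e^(−a/λ₁) + c₂·e^(−a/λ₂) + g·e^(−(a−μ)²/2σ²),

two exponential (dwelling) terms and one Gaussian (roaming) term; the
dwelling fraction is the exponentials' share of the fitted area.

**Curvature and the compensatory curvature response** (`nemaquant.curvature`).
From midline coordinates, the normalized bending curvature K(s, t) = k·L on
the body coordinate s ∈ [0, 1] (head = 0). When the mid-body is held in a
straight channel (limits within [0.35, 0.65]), the CCR score of each 3 s
period is ⟨A_const(s)/A_free(s)⟩ over s ∈ [0.1, 0.3] − 1, with A_const the
windowed maximum of |K| under constraint and A_free the window-averaged
free-locomotion amplitude profile.

**Lifespan statistics** (`nemaquant.survival`). Kaplan–Meier curves from
every-other-day score sheets with censoring, restricted-mean and
75%-mortality lifespans, pairwise Mantel–Cox log-rank tests with
Bonferroni correction, and two-sided Fisher's exact tests for 2×2
marker-penetrance tables.

The core computations are exposed as sklearn-style estimators
(`ActivityExtractor`, `ActivityHistogramMixture`, `CurvatureExtractor`,
`CCRAnalyzer`) with plain-function wrappers, and as a CLI (`nemaquant`).

## Worked example

```python
from nemaquant import (
    LocomotionSimConfig, simulate_activity_trace, smooth_activity,
    fit_activity_histogram, dwelling_fraction,
    ConstraintEpisode, KymographSimConfig, simulate_kymograph, CCRAnalyzer,
    SurvivalSimConfig, simulate_survival, lifespan_pipeline,
)

# 5 h of activity at 1 fps from a roam/dwell worm, then recover the fraction
cfg = LocomotionSimConfig(duration=18000, seed=42)
trace, truth = simulate_activity_trace(cfg)
fit = fit_activity_histogram(smooth_activity(trace), random_state=0)
print(f"true {truth.true_dwelling_fraction:.3f}, "
      f"recovered {dwelling_fraction(fit).dwelling_fraction:.3f}")
# true 0.689, recovered 0.706

# a worm constrained mid-body for 66 s with a programmed 30% anterior gain
episode = ConstraintEpisode(0.4, 0.6, 60.0, 126.0,
                            mid_suppression=0.5, anterior_gain=0.3)
kymo, ann, _ = simulate_kymograph(KymographSimConfig(
    duration=150.0, noise_sd=0.2, seed=42, constraint_episodes=[episode]))
ccr = CCRAnalyzer().fit(kymo, ann).result_
print(f"{ccr.mean_anterior_change:.3f} over {ccr.n_periods} periods")
# 0.275 over 22 periods

# two 105-worm cohorts, the second with 1.2x the Weibull scale
records, _ = simulate_survival(SurvivalSimConfig(
    groups={"control": (4.0, 20.0), "longlived": (4.0, 24.0)},
    n_worms=105, censor_prob=0.02, seed=42))
out = lifespan_pipeline(records, control="control")
for g, s in out["summaries"].items():
    print(f"{g}: mean {s.mean_lifespan:.1f} d, 75% mortality day {s.day75:.0f}")
r = out["comparisons"][0]
print(f"log-rank chi2 = {r.chi_square:.2f}, p = {r.p:.2e}")
```

prints

```
true 0.689, recovered 0.706
0.275 over 22 periods
control: mean 19.7 d, 75% mortality day 22
longlived: mean 23.7 d, 75% mortality day 28
log-rank chi2 = 25.05, p = 5.58e-07
```

The recovered dwelling fraction tracks the generating mixture's exponential
share; the CCR score recovers the programmed anterior gain (slightly
shrunk by noise, see `docs/methods.md`); the extended cohort shows the
longer mean and 75%-mortality lifespan and a decisive log-rank result.

The same pipelines are available from the shell:

```sh
nemaquant simulate survival --seed 42 --out sim/
nemaquant lifespan --scores sim/scores.csv --control control --out results/
nemaquant fisher --table 18 2 7 13
```

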