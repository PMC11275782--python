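# Methods

This note documents the quantitative procedures nemaquant implements, the
assumptions behind them, the synthetic data used to validate them, and the
numerical choices that were genuinely open.

## 1. Difference-image activity and the roaming/dwelling decomposition

**Activity metric.** For a grayscale movie of a single worm sampled at a
uniform frame interval (1 s by default, matching multiwell chamber
recordings), each consecutive frame pair (I_t, I_{t+1}) yields

1. the absolute difference image |I_{t+1} − I_t|,
2. normalized by the scalar mean intensity over all pixels of both frames,
3. smoothed with a Gaussian filter of SD 1 pixel (reflect boundary),
4. binarized at threshold 0.6,
5. summed; the count of supra-threshold pixels is the interval's activity.

The normalization constant is the *scalar* mean over both frames, not a
pixel-wise quantity: this makes the fixed 0.6 threshold invariant to
uniform illumination gain, which is tested explicitly at gains ×0.5 and ×2.
The absolute value makes motion signless. A zero-mean frame pair is a
degenerate input and raises an error naming the frame index.

**Dwelling fraction.** The activity trace is time-averaged with a 5 s
moving window (centered; the window shrinks at the trace edges so constant
traces stay constant), then histogrammed on 50 equal-width bins over
[0, max]. The bin containing zero — quiescence — is removed. Bin counts
against bin centers are fitted by bounded nonlinear least squares to a
7-parameter mixture

    c1·exp(−a/λ1) + c2·exp(−a/λ2) + g·exp(−(a−μ)²/(2σ²)),

two exponential terms for low-activity dwelling and a Gaussian for the
high-activity roaming mode. The fit is multimodal, so 10 seeded starts are
drawn around data-driven initial values (λ's from the log-slope of the
low-activity half of the histogram, the Gaussian from the highest-activity
local mode) and the lowest-residual solution wins; an analytic Jacobian
and Jacobian-based parameter scaling keep each start cheap. Convergence is
reported honestly in the result rather than raised.

The dwelling fraction is the exponential components' share of the fitted
area, with areas integrated analytically over a ≥ 0 (activity cannot be
negative): each exponential contributes c·λ; the Gaussian contributes
g·σ·√(2π)·Φ(μ/σ). The fraction is therefore in [0, 1] by construction and
monotone in the exponential amplitudes, both property-tested.

Binning (count vs density, number of bins) is not a settled convention for
this decomposition; both are exposed as parameters and recorded in output
metadata. The chosen defaults (counts, 50 bins) affect the parameter
values but not the definition of the fraction.

## 2. Curvature kymographs and the compensatory curvature response

**Normalized curvature.** Midlines (ordered head→tail) are fitted per
frame with parametric smoothing splines in normalized arc length s ∈ [0, 1]
and resampled at 100 body coordinates. Signed curvature comes from the
parametric formula k = (x′y″ − y′x″)/(x′² + y′²)^{3/2}, which is invariant
to the residual non-uniformity of the parametrization, and is multiplied
by the frame's body length L to give the dimensionless K(s, t) = k·L. The
spline smoothing parameter defaults to 0 (exact interpolation) and should
be raised for noisy tracked midlines, curvature being a second-derivative
quantity; the default suits the clean synthetic midlines used in
validation. The sign convention follows the cross product of successive
tangents; all CCR statistics use |K|, so the sign matters only for
plotting. Head/tail orientation is the caller's responsibility: reversing
the point order mirrors the spatial axis.

**CCR statistic.** Free-locomotion frames are partitioned into consecutive
non-overlapping 3 s windows; the amplitude profile of each window is
max_t |K(s, t)|, and A_free(s) is the mean across windows. Constrained
frames qualify only while both channel limits lie within the mid-body gate
[0.35, 0.65]; maximal qualifying runs are partitioned into whole 3 s
periods (leftovers dropped — the windowing is a partition, not a sliding
estimate). Each period's amplitude profile is A_const(s) = max_t |K(s, t)|,
and its normalized anterior change is the mean of A_const(s)/A_free(s)
over s ∈ [0.1, 0.3], minus 1. Interval endpoints that coincide with grid
points are included. The per-worm score is the arithmetic mean over valid
periods (median available as an option); zero valid periods yield n = 0
and a NaN score, flagged rather than raised.

The free-locomotion amplitude estimator was an open choice (windowed max,
Hilbert envelope, and per-cycle peak are all defensible); the windowed max
was chosen for symmetry with the constrained definition, which makes the
ratio A_const/A_free interpretable as a pure amplitude gain.

## 3. Lifespan statistics

Worms are scored dead/censored on an every-other-day grid; censored worms
(bagging, desiccation, contamination, handling error) leave the risk set
without counting as deaths. Per group, survival is the product-limit
(Kaplan–Meier) estimator with the standard simultaneous-death tie
convention and deaths processed before same-day censorings. Summaries:

* **mean lifespan** — restricted mean survival time, the area under the
  survival step function up to the largest observed day. This convention
  is documented in the output rather than asserted as the only reading of
  "mean lifespan";
* **75% mortality day** — the first recorded day with survival ≤ 0.25,
  undefined (and flagged) if survival never falls that far.

Groups are compared with the Mantel–Cox log-rank test (pairwise, each
1 df, matching per-strain comparisons against a shared control), with
Bonferroni correction p_bonf = min(1, p·m) over the m comparisons actually
performed. Kaplan–Meier and log-rank computations are delegated to
lifelines; the test suite checks them against hand product-limit
computations and a brute-force O−E/hypergeometric-variance oracle.

Marker-penetrance 2×2 tables are scored with the two-sided Fisher's exact
test under the probability-mass rule (the p-value sums all tables with the
observed margins whose hypergeometric probability does not exceed the
observed table's). Two-sided conventions differ between packages, so the
rule is stated here; the implementation (scipy) is verified against
exhaustive enumeration for every table with total n ≤ 30.

## 4. Synthetic data: what it emulates, and what it does not

**Roam/dwell activity.** A two-state continuous-time Markov chain with
per-second switch hazards; activity is drawn from an exponential mixture
while dwelling (scales 3 and 12 px, equal weights), from a clipped
Gaussian (mean 60, SD 8 px) while roaming, with a quiescence atom at
exactly zero (probability 0.05 per dwell sub-bout). The generator realizes
exactly the functional form the histogram fit assumes, so recovery errors
measure the estimator, not model misfit. Defaults give mean bout durations
of 150 s (dwell) and 64 s (roam) — minutes-scale bouts, as observed for
feeding worms — for a stationary dwell occupancy of 0.7. Activity is
piecewise-constant over sub-bouts of mean 10 s rather than independent
per second: difference-image activity is autocorrelated on this timescale
in real recordings, and the persistence keeps the marginal distribution
(hence the fitted form) intact through the 5 s smoothing kernel. What the
generator does *not* model: gradual speed changes within bouts, tracking
artifacts, or illumination drift; passing recovery tests bounds estimator
bias under the model, not robustness to those effects.

**Worm movies.** A thick sinusoid worm rendered without anti-aliasing on a
uniform background (so the changed-pixel ground truth is an exact pixel
set), moving with state-dependent step sizes (3 px/s roaming, 0.5 px/s
dwelling) and reflecting off the frame margins, plus Gaussian pixel noise.
This validates the image pipeline end to end; it does not emulate realistic
worm photometry or postural detail.

**Curvature kymographs.** A kinematic traveling wave
K(s, t) = envelope(s)·A₀·sin(2π(t/T − s/λ)) with A₀ = 4, wavelength 0.9
body lengths, period 1.5 s at 30 Hz, i.i.d. Gaussian noise (SD 0.2).
Constraint episodes multiply amplitude by the suppression factor on the
channel interval and by (1 + δ) anterior to it, with a 2-frame linear
taper at the episode edges to avoid step discontinuities. The period was
deliberately chosen to place an integer number of samples (45) in each
cycle: every 3 s window then samples the identical phase set, the windowed
max is identical across windows, and the noise-free recovered anterior
change equals δ to floating-point precision — which is what makes the
closed-form check meaningful. No biomechanics (forces, viscosity,
neuromuscular control) is simulated.

**Survival cohorts.** Weibull lifetimes per group (default shape 4, scale
20 days — a realistic adult-lifespan distribution with median ≈ 18 days),
rounded UP to the next observation day (a worm found dead on day d died in
(d−2, d]), with independent per-observation censoring (default 2% per
visit). Cohort size defaults to 105 per group.

All generators are bit-reproducible for a fixed seed, and each carries the
ground truth needed to predict its pipeline's output (dwelling fraction by
numeric integration of the generating density over positive activity;
changed-pixel sets; the programmed anterior gain; per-group true median
lifespans).

## 5. Validation problem sizes

The shipped validation (test suite and `scripts/acceptance.py`) uses: 20
worms × 18 000 intervals (5 h at 1 fps) for dwelling-fraction recovery and
for the dwell-heavy vs roam-heavy ordering; 5 worms × ≥20 constrained
periods per CCR condition; 200 replicate null cohorts and 100 replicate
1.2×-scale cohorts at n = 105/group for log-rank calibration and power;
all 44 515 valid 2×2 tables with n ≤ 30 for Fisher's exact. These sizes
make the stochastic checks stable across seeds while keeping a full run in
the order of a minute.

## 6. Known limitations

* The histogram fit can mis-allocate mass when roaming and dwelling
  activity distributions overlap heavily (roam_mean close to the
  exponential scales); the config forbids the degenerate case but the
  estimator degrades gracefully rather than warning.
* Recovered dwelling fractions carry a small positive bias (~0.02–0.05 at
  occupancy 0.7) from bout-boundary intervals whose smoothed activity
  falls between the two modes.
* The CCR anterior change has a small negative bias under noise (both
  amplitude maxima are inflated by noise, and the ratio of inflated
  quantities shrinks toward 1); at the default noise level this is ~0.02
  on a true gain of 0.3.
* Midline extraction from binary masks is not implemented; the package
  starts from midline coordinate tables.
* Survival analysis treats worms as independent; no plate-level frailty.
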