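# Methods

This document records the statistical model behind `ergocardia`, the
conventions and defaults each estimator uses, and the numerical decisions
that matter when interpreting or reproducing results.

## 1. Why ergodicity matters for HRV descriptors

Heart-rate-variability (HRV) research routinely summarizes a long ambulatory
recording by a single number — mean RR interval (M), RMS, NN50, pNN50, a DFA
exponent, a multifractal width — and then compares those numbers across
groups. That practice silently assumes *ergodicity*: that a descriptor
computed over one stretch of time converges to the same value as a
descriptor computed across repeated realizations, so any sufficiently long
snapshot represents the subject. Cascade-like physiological dynamics break
this assumption. For a nonergodic descriptor, two snapshots from the same
subject can differ as much as snapshots from different subjects, and group
tests on snapshot values lose power in a way that more data per snapshot
does not fix.

`ergocardia` makes the assumption testable. It quantifies ergodicity
breaking with the Thirumalai–Mountain factor E_B, applies it both to the raw
RR series and to the *epoch series of each descriptor*, and measures the
practical cost with a Monte-Carlo group-specificity experiment.

## 2. Data model

- **Beat domain** (`BeatSeries`): RR intervals in ms with per-beat labels
  `N/S/V/X` (normal, supraventricular ectopic, ventricular ectopic,
  artifact). Beat times are the cumulative sum of intervals; the container
  enforces consistency to 1 ms.
- **Sample domain** (`UniformSeries`): the RR signal interpolated onto an
  even grid (default 2 Hz) with a natural cubic spline. Fractal estimators
  (DFA, Chhabra–Jensen, t_MF) operate on this domain; linear descriptors
  operate on beats.
- **Epoch series** (`EpochDescriptorSeries`): one descriptor value per
  nonoverlapping epoch — 500 beats for linear descriptors, 1000 samples
  (500 s at 2 Hz) for fractal ones. Epochs are half-open, 0-based; a trailing
  remainder is dropped. Failed epochs carry NaN plus a logged reason.

### Preprocessing

Ectopic intervals (labels S/V) are replaced by the median of the flanking
normal intervals (a `following`-only variant is available). Consecutive
intervals differing by more than 20% are *flagged but not altered*; the
flag indexes the later beat of the offending pair. Cleaning is idempotent.

## 3. Synthetic generators

All randomness flows from `numpy.random.SeedSequence`, so every figure and
table is bit-reproducible from one integer seed.

- **Fractional Gaussian noise (fGn)** — exact Davies–Harte circulant
  embedding; if the embedding is not nonnegative definite (it is for all
  0 < H < 1 at the sizes used) an exact O(n²) Hosking recursion is the
  fallback. Fractional Brownian motion (fBm) and Brownian motion are
  cumulative sums.
- **Conservative binomial cascade** — mass splits p : (1−p) at each of
  `levels` dyadic refinements, with the large share assigned to a uniformly
  random side per node. The closed-form singularity spectrum
  α(q) = −(p^q ln p + (1−p)^q ln(1−p)) / ((p^q + (1−p)^q) ln 2)
  serves as an exact oracle for the Chhabra–Jensen estimator; for p = 0.7
  and q ∈ [−5, 5] the width Δα ≈ 1.1875.
- **RR-interval model** — RR(i) = clip(mean_rr + sd_rr · w̃(i) · z(i),
  300 ms, 2000 ms), where w̃ are unit-mean cascade weights (amplitude
  intermittency) and z is unit-variance fGn (long-range correlation). This
  couples multiplicative multifractality with tunable persistence, the two
  ingredients the analysis is designed to detect. Optional ventricular
  ectopics halve the affected interval.

## 4. Estimators

### E_B, the ergodicity-breaking factor

For lag Δ the time-averaged mean-squared displacement of a series x over
duration t is TA-MSD(t) = mean over i of (x(i+Δ) − x(i))², and

E_B(t) = ( ⟨TA-MSD²⟩ − ⟨TA-MSD⟩² ) / ⟨TA-MSD⟩²,

the relative variance across a pseudo-ensemble of segments of length t cut
from the one recording. Defaults: nonoverlapping segments; an
overlapping-window variant (stride t/4) for short epoch series. Grids:
raw series use Δ = 10 with ~20 log-spaced t from 2Δ to length/50; epoch
series use Δ = 1 with integer t from 3 to N/2. For Brownian motion
E_B = (4/3)(Δ/t); for fBm the log-log slope is −1 for H < 3/4 and −(4−4H)
for 3/4 < H < 1. A slope near 0 signals broken ergodicity; shuffling the
series restores fast decay, and the original-minus-shuffled slope gap is the
per-series summary.

Displacements are computed on the series values directly (no integration),
and E_B is invariant under affine maps of the data.

### DFA

Profile = cumulative sum of the mean-centered series; scales 4, 8, 12, …
below T/4; per-window linear detrending; pooled RMS residual; the Hurst
estimate is the OLS slope of log F(n) on log n. For fGn input the slope
estimates H; analyzing a motion directly adds 1. Scales with identically
zero fluctuation are dropped.

### Chhabra–Jensen singularity spectrum

Bin proportions P_v(n) at dyadic scales 4, 8, 16, … below T/8;
μ_v(q, n) = P_v^q / Σ P^q computed in log space with `logsumexp` so
q = ±5 does not overflow; α(q) and f(q) are OLS slopes of Σμ ln P and
Σμ ln μ against ln n. A q value is retained only if both regressions have
|r| ≥ 0.9975; Δα = α_max − α_min over retained q (default grid −5 … 5,
step 0.25). Inputs containing nonpositive values are shifted by
−min + 10⁻³·range to form a valid measure; the shift is logged and Δα is
invariant under positive rescaling.

### IAAFT surrogates and t_MF

Iterative amplitude-adjusted Fourier transform surrogates alternate spectrum
imposition with rank remapping onto the original value multiset, ending on
the value step so every surrogate is an exact permutation of the data. The
multifractal-nonlinearity statistic compares the original width with 32
surrogate widths:

t_MF = (Δα_original − mean(Δα_surrogates)) / sd(Δα_surrogates).

**Normalization.** The default divides by the surrogate *standard
deviation*, i.e. t_MF is a z-score of the original within the surrogate
distribution. Dividing by the standard error sd/√n (available via
`normalization="se"`) looks like a one-sample t statistic but is
miscalibrated here: under the linear null the original is exchangeable with
the surrogates, so the "t" would be √n times a unit z-score and would exceed
any fixed threshold for a large share of purely linear series. With the
z-score convention and the threshold 2.04 (the two-sided t critical value
with 31 degrees of freedom, kept as the conventional cut-off), linear fGn
rarely triggers while cascade-modulated RR series almost always do.
Degenerate surrogate spectra are excluded; fewer than 75% usable surrogates
is an error.

t_MF accepts either domain, but whole-recording nonlinearity screening is
most sensitive on the beat-to-beat intervals themselves: 2 Hz spline
interpolation smooths the small-scale mass ratios that carry the
multifractal signature and can shrink Δα by an order of magnitude. Epoch-
level t_MF series follow the 1000-sample convention on the interpolated
signal so that all fractal epoch series share one time base.

### Linear descriptors

M (mean RR), RMS (root mean square of the interval values; RMSSD over
successive differences is provided separately), NN50 (successive differences
strictly exceeding 50 ms) and pNN50 (NN50 as a percentage of the n−1 pairs).

## 5. Monte-Carlo group specificity

Per iteration, one random contiguous segment is drawn per subject (1000
beats for linear descriptors, 1000 interpolated samples for H_fGn/t_MF), the
descriptor is computed per subject, and group tests are run: a one-way ANOVA
omnibus plus Welch t contrasts of each group against the control (first
group by default). The *failure rate* per contrast is the share of
iterations with p ≥ α. Under a null cohort this calibrates to 1 − α; under
real group differences it measures how much descriptor nonergodicity
degrades snapshot-based inference. A pooled linear mixed-effects test
(random intercept per subject over all epochs) is provided as the
complementary analysis when full epoch series are available.

## 6. Problem sizes and numerical choices

The shipped verification suite exercises the estimators at sizes chosen to
balance statistical resolution against desk-scale runtime on one CPU:

- E_B laws: series of 10⁵ points, 20 seeds; the Brownian 4/3 ratio is
  averaged over the full default grid (small-t finite-lag bias keeps the
  single-seed ratio slightly above 4/3, within the ±15% band).
- DFA: 8192 samples, 20 seeds per H — mean absolute error < 0.05.
- Cascades: 14 levels (16384 leaves), where the estimator matches the
  closed form to within sampling noise.
- t_MF discrimination: 40 runs per class, 32 surrogates each.
- Type-I calibration: 3 × 5 null subjects of 2¹⁷ beats, 1000 iterations.
  Long recordings make subject-level means nearly identical, so the
  segment-resampling null is a faithful uniform-p null.
- Qualitative ergodicity ordering: 6 cascade subjects of 10⁵ beats
  (~22 h at 800 ms), the scale at which epoch series are long enough
  (~160–200 epochs) for stable E_B slope gaps. At this scale the raw RR
  E_B slope stays well above the ergodic −1 law while shuffled series decay
  rapidly, and M/RMS epoch series sit much farther from their shuffled
  baselines than H_fGn/t_MF epoch series — the ordering that motivates
  cascade-aware descriptors.

Other implementation notes: population (biased) variance in E_B; `polyfit`
OLS throughout; `scipy.interpolate.CubicSpline(bc_type="natural")` for
resampling; all derived seeds are below 2³¹; figures use the Agg backend so
headless runs never require a display.
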