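# Methods

## The measurement and its quality control

A tapping trial is a strictly increasing sequence of tap times (ms).  The
tempo measure is the mean inter-tap interval (ITI); tapping consistency is
the coefficient of variation CV = s/x̄ of the ITIs, with s the *sample* SD
(ddof = 1 — trials are short, so the denominator convention matters; a
switch to the population SD only requires changing one function).  A trial
is accepted when CV ≤ 0.1 **and** the trial contains at least 8 taps.  Both
boundaries are read inclusively/strictly on purpose: "maximum CV 0.1" admits
CV = 0.1, while the 100 ms tempo floor used later excludes only tempi
*strictly* faster than 100 ms.  The evenness feedback shown to participants
is modeled as max(0, 1 − CV)·100 %; only the 100 % anchor (CV = 0) is fixed
by the task description, the linear ramp is this package's choice, isolated
in `preprocess.evenness_score`.

Cohort cleaning applies five stages in a fixed order, each logged with a
reason code so the audit reproduces stage-wise Ns:

1. `INVALID_RECORD` — incomplete or out-of-scale records, and participants
   without an accepted trial (the generic structural-validity hook).
2. `REPEAT` — self-declared repeaters and later rows of duplicate ids
   (earliest date wins, ties by file order).
3. `FAST_ITI` — mean ITI < 100 ms, the motoric lower limit of tapping.
4. `AGE_OUTLIER` — age outside [Q1 − 1.5·IQR, Q3 + 1.5·IQR], quartiles by
   linear interpolation, computed **once** on the cohort surviving stage 3
   (a single pass, not iterated to a fixed point).
5. `COUNTRY` — a configurable list of implausible countries of residence.

## Tempo clustering

Participants are clustered on x = (mean ITI in ms, CV, unitless) with
K-component Gaussian mixtures whose covariances are constrained to one of
eight families (three-letter volume/shape/orientation codes): EII, VII,
EEI, VEI, EVI, VVI, EEE, VVV.  The M-steps use the classical closed forms
for parsimonious Gaussian mixtures (VEI alternates volume and shape updates
for 8 inner iterations; a derivation check is in the test suite via the
constraint assertions).  Features enter **unscaled**: with spherical or
shared-scale families this makes the CV axis nearly inert and the
clustering effectively univariate in tempo, which mirrors how the analysis
is meant to behave; `standardize_features=True` is available for
sensitivity analysis.  Note one consequence: under EII the single λ is the
average of the ITI and CV scatter, so the effective ITI bandwidth is
√2-narrower than the true within-mode SD — the BIC search in practice
prefers a diagonal family (EEI), which fits both axes on their own scales.

Numerical choices: relative log-likelihood tolerance 1e-8, max 500
iterations, variance floor 1e-6 × per-dimension data variance, degenerate
runs (collapsing weight) restarted up to 5 times with perturbed means and
otherwise flagged `converged=False`.  Initialization is deterministic: for
a single fit, a quantile split on tempo plus 10 Lloyd refinements; for the
model search, a Ward agglomeration tree built once per dataset and cut at
every K (on an evenly strided 4,000-point subsample for larger cohorts,
extended by nearest centroid).  The Ward initialization matters: k-means
style starts on strongly multimodal, very unbalanced data tend to split
heavy modes and merge small distant ones, and EM cannot cross the gaps
afterwards.  Starting covariances always come from one family M-step on the
hard initial labels, so the constraint holds from iteration one and the EM
log-likelihood is monotone throughout (an out-of-family start can legally
decrease the likelihood on the first step and would falsely trip the
degeneracy guard).

BIC = 2ℓ − p·log N (maximized), with p counting weights (K−1), means (K·d),
and the family's covariance parameters.  The selected model is the
BIC-maximal converged fit over all (K ≤ 9, family) pairs.  Components are
reported sorted by ascending mean ITI, which makes cluster labels ("Very
Fast" … "Very Slow" when K = 6) invariant to EM label permutation.

## Circular time-of-day statistics

Integer local hours map exactly to angles 2π·h/24 (minutes are ignored;
the analysis resolution is the hour).  Group summaries are the circular
mean direction μ̂ = atan2(Σsin, Σcos), the mean resultant length R̄, and the
von Mises concentration κ̂ obtained by inverting A(κ) = I₁(κ)/I₀(κ) = R̄
with Fisher's piecewise starting value plus Newton refinement (the
inversion is accurate to 1e-6 over R̄ ∈ [0.05, 0.95]).  Mean directions are
rendered as clock times (HH:MM) in reports.

Groups are compared with the Watson–Williams high-concentration F test:
F = g·(N−k)(ΣRᵢ−R) / ((k−1)(N−ΣRᵢ)) with g = 1 + 3/(8κ̂) and κ̂ estimated
from ΣRᵢ/N, referred to F(k−1, N−k).  The test assumes similar
concentrations across groups and degrades when the pooled R̄ falls below
about 0.45; the implementation then warns and flags the result rather than
suppressing it.  The reported effect size is the between share of the
resultant decomposition, (ΣRᵢ−R)/(N−R); this convention is labeled in the
output because η² conventions for circular ANOVA vary.  Post-hoc pairwise
comparisons reuse the two-group test with Holm step-down adjustment by
default; a fixed per-comparison α is available as an option.

## Linear inference

One-way ANOVA is computed from explicit sums of squares (η² = SSB/SST is
then exact); Tukey HSD p-values come from the studentized range
distribution with the Tukey–Kramer standard error for unequal group sizes.
The two-group comparison is the pooled-SD t test with Cohen's d =
mean difference / pooled SD.  Spearman's ρ uses average ranks for ties and
the t approximation for p.  These are deliberately implemented from first
principles so that scipy serves as an *independent* cross-check in the test
suite rather than as the implementation.  Skewness and excess kurtosis use
the bias-adjusted ("type 2") estimators, with

SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3))),
SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5))).

The cluster-wise z-transform standardizes each participant's tempo by the
mean and sample SD of their assigned cluster, putting all tempo modes on a
common scale; singleton or zero-variance clusters get z = 0 with a warning.
The multiple regression of z on age, arousal, PSS-4, and musical experience
is ordinary least squares with z-scored predictors by default, so the
coefficients are standardized βs (raw-scale slopes are one flag away —
whether the original analysis standardized its predictors is not
determinable, and β magnitudes ≤ 0.05 on a z-scored outcome are consistent
with the standardized convention).  Complete cases only; collinearity
(design condition number > 1e8) warns.

## Subharmonic base period

Given cluster mean tempi and a base period T, each mean is matched to the
multiple n·T, n in an allowed set, minimizing |m − nT| (ties go to the
smaller n).  The summary is the mean absolute deviation (MAD), reported at
full precision and rounded to integer ms.  The base-period estimator scans
T over a grid (default 200–300 ms in 0.5 ms steps) and returns the MAD-
minimizing T (ties to the smallest T); the grid scan *is* the optimality
guarantee.  Two multiplier presets exist: {1,2,3,4,5,7} (no cluster sits
near 6T ≈ 1,506 ms in the motivating data; the exclusion criterion for
n = 6 is not documented, so both are offered) and the full {1,…,7}.

## The synthetic cohort

The generator emulates the statistical structure the pipeline assumes — it
is the test bed, not a model of tapping physiology:

* **Tempo modes.** Latent mean ITI = n·T₀ + within-mode noise, T₀ = 251 ms,
  n ∈ {1,2,3,4,5,7}, weights proportional to the observed cluster sizes
  (223 : 1184 : 925 : 852 : 283 : 109), shared within-mode SD 60 ms (the
  equal-volume geometry; the observed per-cluster SDs of 67–77 ms for the
  well-populated clusters include assignment truncation, so the component
  SD is taken slightly below them; the split between mode jitter and
  measurement noise is a free choice, exposed in config).  Latent tempi are
  floored at 123 ms — the fastest observed participant — which also
  guarantees that uncontaminated participants can never trip the <100 ms
  filter, keeping audit counts exact.
* **Tapping noise.** Tap trains cumulate Gaussian ITIs with a
  per-participant CV drawn from a normal (mean 0.055, SD 0.015) truncated
  to (0.02, 0.09).  The truncated normal (rather than a uniform) keeps the
  CV marginal approximately Gaussian; a boxy CV distribution would invite
  flexible mixture families to split components along the CV axis, a
  generator artifact with no counterpart in the modeled study.
* **Covariate effects.** Age tilts mode log-odds (0.25 per decade per mode
  step: older → slower modes, a between-cluster effect).  Time of day adds
  a sinusoid to mean ITI (amplitude 10 ms, slowest at 05:00 — a
  within-cluster effect; the direction is the modeled finding, the
  amplitude is free since no magnitude is documented).  Arousal shifts the
  within-cluster z by β = −0.05 per standardized arousal unit, with the
  residual scaled so the total within-mode variance is preserved.
* **Contamination.** Repeats, sub-100 ms tempi (uniform 60–90 ms),
  implausible ages ({1,2,3} ∪ {85…99}), structurally invalid rows (missing
  arousal), and an implausible country are planted in *disjoint*
  participant sets at configured rates, so each cleaning stage's removal
  count equals its planted count exactly.  Legitimate ages are truncated to
  [12, 45] so that the data-driven IQR fence (≈ [6.6, 48.2] at the default
  age distribution) never clips genuine respondents.
* **Null mode.** `simulate_null_cohort` zeroes all three covariate effects
  for type-I-error calibration of every downstream test.

What the simulator does **not** emulate: two-level timing noise
(central timekeeper vs motor implementation), within-trial drift, device
latency, realistic country/language structure, or a between-cluster
time-of-day composition effect (the circadian term perturbs tempo within
clusters).  Passing recovery tests therefore show that the pipeline
estimates what this generative structure encodes — not that real tapping
data satisfies it.

## Problem sizes used in the automated checks

Recovery checks run at the study scale (3,600 simulated participants):
mixture recovery over 20 seeds, regression recovery over 50 seeds (with a
single 6-component fit per seed for cluster assignment, since model
selection is exercised separately), circular-test calibration over 2,000
null replicates (κ = 5, n = 50 per group) with a 3,000-draw permutation
oracle on small samples.  The acceptance script uses the same conditions
with 20 regression seeds and 1,000 calibration replicates.

## Known limitations

* Six of mclust's fourteen covariance families (the rotated ones) are out
  of scope; the constrained set covers all axis-aligned geometries
  including the equal-volume spherical model.
* The Watson–Williams test's equal-concentration assumption is diagnosed
  (per-group κ̂ reported, low pooled R̄ flagged) but not replaced by a
  heterogeneity-robust alternative.
* The cleaning cascade's idempotence holds for realistic cohorts but is not
  a theorem: re-fencing an already fenced age distribution can in principle
  remove further points.
* Cluster-wise z-scores condition on the fitted assignment; assignment
  uncertainty near cluster boundaries slightly attenuates regression
  effects (visible in recovery: planted −0.05 is estimated around −0.03 to
  −0.04 on average).
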