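# tempoclust

Analysis pipeline for **spontaneous motor tempo (SMT)** measured by online
finger tapping.  SMT is the self-chosen pace of regular repeated movement;
operationally it is a participant's mean inter-tap interval (ITI, ms) from a
15-second self-paced tapping trial.  Large online tapping cohorts are messy
— repeat participations, implausible ages, physically impossible tempi — and
their tempo distribution is strongly multimodal, with modes near integer
multiples of a ~251 ms base period (a ~4 Hz putative internal oscillator).
This package implements the full analysis such a cohort needs, end to end,
plus a synthetic-cohort simulator so every stage is testable without any
external data.

## What it computes

1. **Trial quality control.** ITIs from raw tap timestamps; a trial is
   accepted when the coefficient of variation CV = s/ x̄ of its ITIs is at
   most 0.1 and at least 8 taps were made.
2. **Cohort cleaning with an audit trail.** In order: structural validity,
   first participation only, mean ITI ≥ 100 ms (the motoric lower limit),
   a 1.5·IQR fence on age, and a country sanity check.  Every stage logs
   (n_before, n_removed, n_after, reason code).
3. **Tempo clustering.** Bivariate Gaussian mixtures on (mean ITI, CV) fit
   by EM under eight covariance constraints (spherical/diagonal/full ×
   equal/varying; codes EII … VVV), searched over K = 1…9 components and
   selected by BIC in the `2ℓ − p·log N` (maximize) convention.
4. **Circular time-of-day inference.** Clock hours mapped to angles
   (2π·h/24), per-cluster circular means and concentrations, the
   Watson–Williams high-concentration F test across clusters, and pairwise
   post-hocs with Holm adjustment.
5. **Linear group tests and the normalized regression.** One-way ANOVAs with
   Tukey HSD and η², pooled t tests with Cohen's d, Spearman correlations,
   bias-adjusted skewness/kurtosis with standard errors, and a multiple
   regression of the **cluster-wise z-transformed** tempo (each participant
   standardized within their own tempo cluster) on age, arousal, long-term
   stress (PSS-4), and musical experience.
6. **Subharmonic base period.** For cluster mean tempi m_k, the deviation
   |m_k − n·T| to the nearest allowed multiple n of a base period T, their
   mean absolute deviation (MAD), and a grid estimator of T.

## Worked example

```python
from tempoclust.harmonics import harmonic_fit

fit = harmonic_fit([265, 525, 754, 997, 1314, 1757],
                   T=251, allowed_n=(1, 2, 3, 4, 5, 7))
print(fit.deviations_ms)   # (14, 23, 1, 7, 59, 0)
print(fit.mad_ms)          # 17
```

The six inputs are cluster mean tempi in ms; each is matched to its nearest
allowed multiple of T = 251 ms (265→251, 525→502, …, 1757→1757).  The mean
absolute deviation of 17 ms (range 0–59 ms) is what makes the subharmonic
reading of the cluster structure quantitative.

A full pipeline run on a simulated cohort:

```bash
tempoclust simulate --out-dir sim --n 3600 --seed 1
tempoclust run --participants sim/participants.csv --trials sim/trials.csv \
    --out report.json --seed 1
```

which prints, among other lines:

```
SMT: mean 768 ms, median 734 ms, range 126-1937 ms
Mixture: K=6 (EEI), BIC=-30935.5
  Very Fast        n=  197  mean 247 ms (SD 51)
  Fast             n= 1245  mean 497 ms (SD 59)
  Moderately Fast  n=  902  mean 749 ms (SD 57)
  Moderately Slow  n=  842  mean 1001 ms (SD 59)
  Slow             n=  294  mean 1253 ms (SD 58)
  Very Slow        n=  120  mean 1753 ms (SD 72)
Harmonic fit at T=251 ms: MAD 4 ms (range 2-5 ms); estimated base period 250.5 ms
Cluster-normalized regression: R^2=0.0032; age=-0.003, arousal=-0.054, ...
```

i.e. the mixture search recovers the six planted tempo modes, and their
fitted means sit on multiples of ~250 ms.  The `analysis/` scripts run the
same steps as a numbered narrative (simulate → QC → cluster → compare →
regress → base period) and write tables under `results/`.

The simulator's defaults reproduce the study conditions: six modes at
n·251 ms for n ∈ {1,2,3,4,5,7} weighted like the observed cluster sizes,
within-mode SD 60 ms, per-participant CV in (0.02, 0.09), 15 s trials, an
age tilt toward slower modes, a small circadian modulation of tempo, and a
standardized within-cluster arousal effect of −0.05.  Contamination
(repeats, sub-100 ms tempi, implausible ages, invalid rows) is planted at
configurable rates with exact ground-truth counts.

## Layout

```
src/tempoclust/     library: io, preprocess, mixture, circular, inference,
                    harmonics, simulate, pipeline, cli
analysis/           numbered narrative drivers over the library
scripts/acceptance.py
tests/              pytest suite (unit, property, and end-to-end recovery)
docs/methods.md     models, assumptions, parameter choices, limitations
```
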