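# Methods

## The model

The pipeline operationalises "perturb the brain, watch it recover" as a
statistical analysis.  A single TMS pulse is treated as a controlled insult;
the trial-averaged EEG response (the TMS-evoked potential, TEP) quantifies
how strongly the cortex reacts.  The working hypothesis embedded in the
synthetic generator: individuals who later prove *vulnerable* to a
psychosocial stressor over-react to the perturbation of the left DLPFC in a
late time window (around the P180-vicinity component, here a bump at
230 ms), while a control parietal target shows no such dependence.  Mental
health is measured by the PHQ-4 (two 0–6 subscales, total 0–12); a subject
is *resilient* iff every pandemic-era total is at or below the pre-pandemic
total, *vulnerable* otherwise.  The regression response is each subject's
mean pandemic PHQ-4 total.

## Reactivity measures

*Global*: GMFA(t), the population standard deviation of sensor voltages at
each sample.  The population (÷N) form is the classical global field power;
a sample (÷N−1) variant is available by flag.
*Local*: the source-space series of the 100-vertex ROI around the
stimulation target — rectified per vertex, then averaged (in that order:
oppositely signed vertices must not cancel), then z-scored against the
−500…−3 ms baseline using the population SD of the baseline samples.
*Scalars*: trapezoidal AUC over the closed 15–400 ms window (the 15 ms start
excludes the interval occupied by the pulse artifact in real recordings);
"baseline activity" is the AUC of the same rectified ROI average over
−500…−3 ms.  The baseline predictor has no canonical definition; this
choice is symmetric with the response AUC.  All windows are closed intervals
on the sample grid (sample i at t₀ + i/fs·1000 ms), endpoint-inclusive with
a 1 ns-scale tolerance.

Global AUC is computed from sensor-space GMFA by default (source-space
distributed activity would also be defensible; the functions accept either).

## Cluster permutation test

Observed statistic: d(t) = mean_vulnerable(t) − mean_resilient(t) over the
15–400 ms window.  Pointwise two-sided p-values come from the permutation
distribution of |d| with add-one correction, p = (b+1)/(B+1), never zero.
Clusters are maximal runs of contiguous samples with p < α (α = .05, no gap
tolerance); cluster mass is Σ|d(t)|.  Each permutation's own pointwise
p-values are computed by ranking within the permutation ensemble, the same
clustering is applied, and (default `max_per_perm`) the per-permutation
maximum size and maximum mass form the two null distributions — the
standard family-wise-error construction.  A cluster survives only if its
size *and* its mass exceed the 95th percentiles of these nulls (the
conjunction is the stricter reading of "size and magnitude above 95%").  A
`pooled` null mode — all clusters from all permutations pooled — is
provided as an alternative reading.  Sidedness is two-sided: directionality
is treated as a finding, not an assumption.  One root seed fixes the
permutation stream; labels are scrambled per permutation, not per timepoint.
An exact mode enumerates all label assignments for small groups and is the
oracle the Monte-Carlo path is tested against.

## Regression stage

Design: full model = {local AUC, global AUC, both × targeting-method,
age, gender (female=0), education years, months since TMS}; reduced =
{local AUC, education}; reduced+baseline adds the baseline-activity AUC;
the full model is also fit with IPL-derived reactivity as a target-specificity
control.  The response is Box-Cox transformed, with λ maximising the profile
log-likelihood on a grid [−5, 5] step 10⁻³ (a positivity shift 1 − min(y)
is applied when min(y) ≤ 0 — PHQ means can be zero).  λ is estimated per
model on that model's subject subset, except for the likelihood-ratio test,
which requires a common response: there both models are refit on the common
subject set under a single transform.  AIC = −2ℓ + 2k\*, BIC = −2ℓ + k\*ln n
with k\* counting all coefficients plus σ² (the convention of the common
statistical packages whose outputs these quantities are meant to mirror).
Residual normality: Lilliefors D with a seeded Monte-Carlo null (10⁴
simulated samples) rather than the asymptotic tables.  Variance
decomposition: sequential (Type-I) sums of squares in the order local
reactivity, then education — the decomposition type behind per-predictor
"% of total variance" figures is a convention choice; sequential was chosen
as the default of the R `anova()` family.  Diagnostics: VIF by auxiliary
regressions, Durbin-Watson, Breusch-Pagan.  No multiple-testing correction
is applied across the four models.

## Synthetic cohort generator

What it emulates: (i) evoked responses as sums of Gaussian bumps at 30, 45,
60, 100, 185 and 230 ms with alternating polarity, projected with full
weight onto the stimulated target's ROI vertices and attenuated (×0.3)
elsewhere, with ±10% per-vertex gain jitter; (ii) an effect of latent
vulnerability v ~ N(0,1) that multiplies the 230 ms component by
(1 + effect_size·v) in the DLPFC ROI only; (iii) AR(1)-filtered Gaussian
noise (coefficient .95, marginal SD 2 µV) standing for the residual noise
of a ~120-trial average — enough temporal correlation to make pointwise
tests non-independent, which is the situation cluster correction exists
for; (iv) PHQ trajectories: pre ~ Binomial(12, .15); each of 1–3 pandemic
timepoints (8/23/69% of subjects) is pre − 0.4 + 1.5·v − 0.12·(edu − 18)
plus unit noise, rounded and clipped to 0–12; totals are split into PHQ-2/
GAD-2 by constrained binomial thinning; (v) PSS-14 as a noisy monotone
rescaling of mean pandemic PHQ; (vi) demographics and completion structure:
age 42–66, education 8–28 years, 34/74 female, 29/74 anatomically targeted,
76% DLPFC / 74% IPL / 50% both.

Group labels are never drawn: they emerge from applying the classification
rule to the generated trajectories, so classification and group-difference
machinery are exercised jointly.  Subject-average series are generated
directly — trial-level simulation would add cost without testing anything
new.

Calibrated constants (chosen once, by simulation, as part of the generator's
design): the PSS noise SD (1.6) and mapping (10.5 + 2.6·latent) put the
median Spearman(PSS, pandemic PHQ) near the .69 design target with a
plausible PSS median (~14) and range; the PHQ drift (−0.4) balances the
resilient/vulnerable split near 50/50; effect_size defaults to 1.0, which
under the default noise yields a late-window group separation on the order
of the between-subject spread (the vulnerability spread itself dominates
that spread, so recovery power is driven by group-mean separation after
noisy classification).

What the generator does *not* emulate: volume conduction and a real forward
model, artifacts (blink/muscle/pulse), trial-level variability, non-Gaussian
component shapes, floor/ceiling dynamics of questionnaires beyond clipping.
Passing tests therefore demonstrate that the machinery is correct and
calibrated under the assumed structure, not that the scientific effect
exists in real cohorts.

## Numerical choices and degenerate inputs

- GMFA requires ≥2 channels; z-scoring raises an explicit degenerate-baseline
  error when the baseline is constant; Spearman refuses constant vectors.
- The Box-Cox transform uses expm1 for numerical stability near λ = 0 and is
  monotone for every λ (property-tested).
- OLS refuses rank-deficient designs explicitly; the LRT accepts identical
  models (χ² = 0, p = 1) and clips tiny negative χ² from floating-point.
- Permutation p-values use add-one correction; exact enumeration omits it
  (the observed assignment is a member of the ensemble).
- Missing data: a subject missing a target simply has no TEP file;
  completed targets are derived from files present; regression drops (and
  counts) subjects with incomplete predictors rather than imputing.

## Problem sizes used in the shipped experiments

Type-I calibration: 500 effect-free datasets, 12 vs 12 subjects, 200
permutations.  Effect recovery: 100 cohorts of 48 subjects, 500
permutations.  Sign recovery: 100 cohorts of 56 subjects.  PSS calibration:
50 seeds × 500 subjects.  LRT null: 500 replicates at n=400 (the
likelihood-ratio statistic is only asymptotically χ²; at n below ~100 its
finite-sample inflation is visible, so the calibration is run in the
asymptotic regime).  Repeated-simulation studies use a shortened epoch
(−1000…+500 ms) that still covers the baseline and response windows; the
study-scale run uses the full −1000…+2000 ms epoch at 1 kHz.

## Known limitations

- The cluster test controls family-wise error per analysis; with four
  analyses per run, one false-positive cluster appears in roughly one run
  in five (visible in the worked example's IPL-global cluster).
- The pooled null mode is provided for fidelity to an alternative reading
  of the correction rule but is not separately calibrated.
- The generator's effect is multiplicative in v and can invert the late
  component for v < −1; rectification maps this to |1+v|, which slightly
  compresses the low tail of the effect distribution.
- Reported regression effect sizes in synthetic runs are generator
  artifacts; only their signs, calibration properties and the machinery's
  identities are meaningful.
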