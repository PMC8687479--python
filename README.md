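# tepkit

Analysis pipeline for testing whether the EEG response to single-pulse
transcranial magnetic stimulation (TMS) predicts resilience to a later
psychosocial stressor.  The scientific setting: healthy middle-aged adults
underwent TMS-EEG of the left dorsolateral prefrontal cortex (L-DLPFC,
experimental target) and left inferior parietal lobule (L-IPL, control
target) before the COVID-19 pandemic; mental health (PHQ-4) was measured
once before and up to three times during lockdown.  Subjects whose PHQ-4
never rose above baseline are *resilient*; everyone else is *vulnerable*.
The pipeline asks whether the pre-pandemic evoked response — months before
the stressor — already separated the two groups and predicted the pandemic
mental-health outcome.

Because no human data are deposited, the package ships a first-class
synthetic cohort generator with the assumed statistical structure (a late
local evoked component tied to a latent vulnerability score for the L-DLPFC
target only; PHQ trajectories driven by that score and, negatively, by
education; PSS-14 perceived stress rank-correlated ≈ .69 with pandemic
PHQ-4), so every stage is testable end to end.

## Methods at a glance

- **Reactivity measures.** Global: the global mean field amplitude
  GMFA(t) = √(Σᵢ(Vᵢ(t) − V̄(t))²/N) over sensors.  Local: source-space ROI
  series (100 vertices around the target), rectified, averaged, and
  z-scored against the pre-stimulus baseline, z(t) = (s(t) − μ)/σ with μ, σ
  from −500…−3 ms.  Scalar predictors are trapezoidal AUCs over 15–400 ms
  post-pulse, plus the rectified baseline activity.
- **Group comparison.** Pointwise difference of group means with a
  permutation null (1000 label scramblings); contiguous pointwise-significant
  samples form clusters; a cluster survives only if both its size and its
  mass Σ|d(t)| exceed the 95th percentile of the permutation null
  distributions (max-statistic construction; a pooled-null variant is
  available).
- **Prediction.** OLS of the Box-Cox-transformed mean pandemic PHQ-4 on
  reactivity AUCs, their interactions with the targeting method, and
  demographics; nested-model comparison by likelihood-ratio test and
  AIC/BIC (full Gaussian likelihood, σ² counted); Lilliefors residual
  normality via a seeded Monte-Carlo null; sequential (Type-I) variance
  decomposition; VIF / Durbin-Watson / Breusch-Pagan diagnostics.

## Worked example

```sh
tepkit run-all --out run1 --seed 11   # small demo via a YAML config is also possible
```

or, from Python, the in-memory study-scale analysis:

```python
from tepkit.experiments import study_run
run = study_run(seed=1, n_subjects=74, n_perm=1000)
```

At seed 1 this prints (via `analysis/03_cluster_tests.py` and
`analysis/04_regression_models.py`):

```
cohort: 44 resilient / 30 vulnerable
Spearman(PSS, pandemic PHQ): rho=0.760 (p=4e-15)
  DLPFC_local: surviving clusters -> [158, 285] ms
  DLPFC_global: surviving clusters -> none
  IPL_local: surviving clusters -> none
  IPL_global: surviving clusters -> [48, 67] ms
```

Reading: the cohort splits into resilient/vulnerable by the PHQ rule;
perceived stress tracks pandemic mental health; the vulnerable group shows a
significantly larger *local* response to L-DLPFC perturbation in a late
cluster covering the generator's injected 202–269 ms effect window, while
the global measure shows nothing (the generator puts no vulnerability
dependence there).  The short IPL-global cluster is a family-wise false
positive of the kind the calibration experiment quantifies (≈5% of tests).
The regression stage then finds a positive local-reactivity coefficient and
a negative education coefficient in the reduced model, and the
likelihood-ratio test shows the 8-predictor full model adds nothing over
them.

The numbered scripts under `analysis/` run the same stages as a narrative
sequence (simulate → score → cluster tests → regression → calibration) and
write their tables under `results/`.

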