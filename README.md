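# metabias

Publication-bias-corrected meta-analysis for study-level effect sizes.

Meta-analyses of small-sample experimental literatures — the motivating case
is religious priming of prosocial behavior — routinely pool standardized
mean differences (Hedges' *g*) whose publication depended on reaching
*p* < 0.05. The naive inverse-variance mean is then biased upward, sometimes
grossly so. This package implements two corrections that reach opposite
conclusions on exactly the same data, a simulator to study when each works,
and the descriptive and power calculations that surround them:

- **Descriptives** — per-study normal-theory CIs (mean width, where the
  lower bounds pile up) and funnel-plot coordinates (SE, *g*).
- **PET-PEESE** — the precision-effect test/estimate. PET is the WLS
  meta-regression *g*ᵢ = β₀ + β₁·SEᵢ with weights 1/SEᵢ²; its slope is
  Egger's funnel-asymmetry test and its intercept β₀ estimates the effect of
  an idealized zero-SE study. PEESE regresses on SEᵢ² instead. The
  conditional rule reports the PET intercept unless it is significant, then
  the PEESE intercept.
- **Bayesian bias correction (BBC)** — a censored-likelihood selection
  model: each study is published with probability *w*(*p*), a weight
  function of its two-sided p-value. Four selection processes (no bias;
  only-significant; nonsignificant at a constant unknown rate π; publication
  probability decaying in *p*) are crossed with a spike-and-slab prior on
  the true effect δ (point mass at 0 with probability ½, else
  δ ~ N(0, (2/3)²), which puts the median of |δ| at 0.45). Bayesian model
  averaging over the eight scenarios yields posterior scenario
  probabilities, a model-averaged posterior for δ, and the Bayes factor
  BF₀₁ for the null. Marginal likelihoods are deterministic log-space
  quadrature — no MCMC.
- **Power** — exact noncentral-*t* power and smallest even total N for
  two-group designs on the *g* scale.
- **Simulator** — generates literatures with known truth: per-group sizes
  log-uniform on [10, 100], observed *g* ~ N(δᵢ, SE²), candidates published
  with probability *w*(*p*) until *k* studies accumulate, so the file-drawer
  size is part of the output.

## Worked example

Generate a worst-case literature — 92 published studies, true effect
**zero**, only significant positive results survive — then ask both the
descriptives and PET-PEESE what they see:

```console
$ metabias --quiet simulate --k 92 --delta 0.0 --selection extreme --seed 102 -o lit.csv
$ metabias --quiet describe lit.csv
k = 92
mean 95% CI width = 1.036
mean CI bounds = [0.089, 1.126]
fraction of lower bounds in [0, 0.1] = 0.70
$ metabias --quiet petpeese lit.csv
PET:   b0 = -0.011 (p = 0.791), b1 = +2.340 (p = 3.11e-23)
PEESE: b0 = +0.272 (p = 4.93e-20), b1 = +4.601 (p = 5.51e-23)
selected model: PET
bias-corrected estimate: -0.011
publication bias signal: yes
```

Although the true effect is 0, the naive pooled mean of this literature is
+0.55 and 70% of the CI lower bounds sit just above zero — the forest-plot
fingerprint of censoring. PET sees the funnel asymmetry (slope +2.34,
p ≈ 10⁻²³), its intercept is indistinguishable from zero, and the
conditional estimate is −0.011: the "effect" was entirely publication bias.
Planning a replication instead at the bias-corrected prosocial estimate:

```console
$ metabias power --g 0.18
required total N = 766 (power 0.801 at g = 0.18, one-tailed alpha = 0.05)
```

`metabias bbc lit.csv` and `metabias run lit.csv` run the Bayesian
correction and the full pipeline; `analysis/01_…05_*.py` are narrative
drivers that run all stages over three simulated study conditions and write
their tables under `results/`.

The original 92-study religious-priming table is not redistributable; drop
it in as `data/shariff2015_religious_priming.csv` (columns `study_id, g,
se, subset`, with `prosocial` tagging the 25 prosocial-behavior studies)
and the external-reproduction tests in `tests/test_acceptance.py` will run
against it.

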