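# Methods

## Data model

A study contributes an observed standardized mean difference (Hedges' *g*),
its standard error, and optionally per-group sample sizes and a subset tag.
All estimators treat the SE as known. Where an SE must be derived from
group sizes the package uses the standard large-sample SMD variance

    Var(g) = (n1 + n2) / (n1 n2) + g² / (2 (n1 + n2)),

a convention, not a theorem; an alternative variance can be supplied by
computing SEs upstream and passing them in the CSV. The small-sample
correction from Cohen's *d* is the usual multiplicative factor
J(df) = 1 − 3/(4 df − 1). Missing group sizes are allowed; operations that
need them raise rather than impute.

## Descriptives

Per-study CIs use normal quantiles (g ± z·SE), the meta-analytic
convention when SEs are treated as known. The summary "mean CI bounds" is
the element-wise mean of lower and of upper bounds; the phrase is exposed
as a secondary summary only, because the corresponding forest-plot
statistic is ambiguous in prose descriptions. Funnel coordinates are (SE,
g) pairs in file order; no rendering is part of the library contract.

## PET-PEESE

PET fits g_i = β₀ + β₁·SE_i by weighted least squares with weights 1/SE_i²;
PEESE replaces SE_i by SE_i². Inference convention: weights are known up to
a proportionality constant and the residual scale is estimated from the
weighted residual mean square (classical WLS), which makes coefficient SEs
invariant to rescaling all weights and makes the PET slope test exactly
Egger's regression test (the suite asserts both). CIs and two-sided
p-values use t quantiles with k − 2 df. The conditional rule reports the
PET intercept when its two-sided p ≥ α_gate (default 0.05, configurable),
else the PEESE intercept; the publication-bias flag is a significantly
positive PET slope. With constant SEs neither regression is identified and
the fit raises a collinearity error — there is deliberately no fallback
estimate. Point estimates, not CIs, are the quantities this estimator is
judged on: no symmetric-CI convention reproduces every published
asymmetric interval.

## Bayesian bias correction

The sampling model is homogeneous: a single true effect δ, g_i ~ N(δ,
SE_i²), and publication with probability w(p_i) of the study's two-sided
p-value. The censored log-likelihood of a published study is

    log φ(g_i; δ, SE_i²) + log w(p_i) − log ∫ φ(u; δ, SE_i²) w(p(u, SE_i)) du.

Four selection processes are entertained, all publishing significant
results (two-sided p < 0.05, threshold configurable) with probability 1:

- **M1** no bias: w ≡ 1.
- **M2** extreme censoring: nonsignificant results never appear.
- **M3** constant rate: nonsignificant results appear with probability π,
  π ~ Uniform(0, 1).
- **M4** p-graded: w = exp(−γ (p − 0.05)) beyond the threshold,
  γ ~ Exponential(mean 10), so the median publication rate of a p = 0.5
  study is ≈ exp(−6.9·0.45) ≈ 0.04 and small γ values keep near-threshold
  results likely.

The exact parametric family of graded selection is not canonical; M4's form
and prior are the package's choice and the `BiasModel` abstraction keeps
all four replaceable. Crossing the processes with a spike-and-slab prior on
δ — P(δ = 0) = ½, else δ ~ N(0, slab_sd²) with slab_sd = 2/3, which places
the median of |δ| at 0.45 — gives eight scenarios with a uniform 1/8 prior
by default (equivalently: effect states equally likely, selection processes
uniform within each state). Model-averaged quantities are posterior-weighted
mixtures; BF₀₁ is the ratio of prior-weighted null to alternative marginal
likelihoods normalized by the prior odds.

A published study with zero selection probability (a nonsignificant study
under M2) makes the scenario log-likelihood −∞ — an explicit
"impossible under this model" value, not an exception — and its posterior
probability exactly 0. Only if every scenario is impossible does the
analysis raise.

### Quadrature

Everything is deterministic quadrature in log space with max-subtraction:

- δ grid: 1201 trapezoid points on [−3, 3]. The slab mass outside ±3 at
  slab_sd = 2/3 is < 10⁻⁵ and posterior spreads at k ≈ 92 are two orders of
  magnitude wider than the 0.005 spacing.
- Nuisance priors: 101-point midpoint rule in quantile space (equal
  weights at the prior's inverse-CDF points), so any prior with a quantile
  function plugs in.
- The M1–M3 censoring normalizers have closed forms in the normal CDF. The
  M4 normalizer is a smooth convolution integrated on a 481-point trapezoid
  grid over the nonsignificant band of the standardized effect; on large
  (δ × study) grids it is evaluated through a dense lookup table in
  δ/SE (0.02 spacing, linear interpolation, ~10⁻⁴ relative error). Scalar
  likelihood calls use 2001 direct points.

Unit and acceptance tests pin the censored likelihood and the marginal
likelihoods to adaptive-quadrature and independent brute-force grid oracles
(10⁻⁶ absolute on log-likelihoods; 3 significant digits on marginals), and
the no-selection special case to the conjugate spike-and-slab closed form.

## Power

Exact two-sample noncentral-t power with noncentrality g·√(n₁n₂/(n₁+n₂))
and df = n₁+n₂−2; required totals are the smallest even N (1:1 allocation)
meeting the target, found by monotone search from the normal-approximation
start. **Sidedness:** the default is one-tailed α = 0.05 — the convention
under which the package's headline planning totals (156 at g = 0.40, 766
at g = 0.18, 80% power) arise; two-tailed is available and gives 200 and
972. Per-group n is rounded up and the total reported as 2n.

## Simulator

`generate_literature` draws candidate studies — per-group sizes integer
log-uniform on [10, 100] (chosen so SEs span ≈ 0.14–0.45 at small effects,
a typical funnel x-range), study-level true effects N(δ, τ²), observed
effects N(δᵢ, SE²) with SE evaluated at the true effect — and publishes
each with probability w(p) until k studies accumulate. A single seeded
generator is threaded through all draws; identical configs give
byte-identical CSVs.

**Directional selection.** By default the gate is directional: only
significant results in the hypothesized (positive) direction count as
significant, and wrong-signed results enter the weight function as
maximally nonsignificant (selection p = 1). A literature testing a
directional hypothesis censors itself this way, and it is what produces
funnel asymmetry: under sign-symmetric censoring at δ = 0 the published
effects would be symmetric around zero and no correction would have
anything to correct. `direction="both"` gives the sign-symmetric variant.
The BBC likelihood keeps the symmetric w(two-sided p); at δ = 0.3 the
per-study probability of a wrong-signed significant result is ~10⁻³, so
the mismatch is negligible in the recovery studies, but at δ = 0 it is a
real misspecification — the 04 driver shows BBC attributing part of a
purely manufactured effect to a true effect in that regime, which is the
instructive failure mode, not a bug.

What the generator does **not** emulate: questionable research practices
(optional stopping, outcome selection), moderators, multi-lab structure,
or heterogeneous effects in the analysis model (τ > 0 generation against
the homogeneous BBC likelihood is deliberate misspecification for
robustness checks). Passing recovery tests therefore shows the estimators
work when publication censoring is the only distortion; they say nothing
about QRP-contaminated literatures.

## Problem sizes

The Monte-Carlo recovery studies use 200 replicates of k = 92 (matching
the motivating literature's size): constant-rate selection π = 0.2 at
δ = 0.3 for BBC recovery, and extreme censoring at δ = 0 for the
PET-PEESE/naive-mean comparison. Smaller simulations (20–50 replicates, or
single literatures of k = 200–2000) back the per-module distributional
checks.

## Known limitations

- Homogeneous-δ likelihood: between-study heterogeneity is not modeled in
  BBC; PET-PEESE has no multilevel/cluster-robust variant here.
- Selection acts only through the p-value (and optionally sign), with the
  threshold fixed at two-sided 0.05 inside w(p).
- The conditional PET-PEESE rule is a hard model selection; no shrinkage
  or averaging between PET and PEESE.
- Effect-size inputs must already be on the g scale; no conversion from r
  or odds ratios.
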