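# Methods

## Model and fitting procedure

The package models a right-censored age-at-onset outcome with a Cox
proportional-hazards model whose linear predictor is the sum of
layer-wise scores, `h(t|z_1,…,z_m) = h_0(t) exp(Σ_j β_jᵀ z_j)`.  Each
individual carries one observed age (onset for events, last follow-up
otherwise) and a binary event indicator; risk sets are formed on the
observed ages, and tied event ages are handled with the Breslow
convention (ties share one risk set, the tie count enters the baseline
increment's numerator).

Fitting is deliberately a two-step procedure:

1. Per layer, the Cox partial log-likelihood is maximized without
   penalty, giving unnormalized preliminary estimates `β̂_j`.  These act
   as adaptive-lasso weights: the penalty is `λ Σ_k |β_k/β̂_k|`, so
   covariates with small preliminary effect are shrunk harder.
2. All layers are fitted jointly by minimizing the cooperative
   objective: the summed per-layer negative partial log-likelihoods
   (divided by n), plus `(ρ/2) Σ_{pairs} ‖Z_iβ_i − Z_jβ_j‖²` over layer
   pairs, plus the adaptive penalty.  The pair set defaults to all pairs
   `i<j`; a chain scheme `(1,2),(2,3),…` is available by flag.

After optimization every `β_j` is rescaled to unit Euclidean norm (a
numerical-stability convention: only the direction of each layer score
is retained) and the Breslow cumulative baseline hazard is estimated on
the combined linear predictor of the normalized coefficients, so the
baseline is calibrated against exactly the coefficients used for
prediction.  Survival curves are `S(t) = exp(−H(t))`, exact for step
cumulative hazards; a trapezoidal integrator is provided for smooth
hazard-rate inputs.

## Tunable parameters

- **ρ ≥ 0 (agreement weight, unitless).**  Defaults to 1 for two layers
  and 0.5 for three or more, which weighs the layers evenly given the
  number of active penalty pairs; 0 decouples the layers (late fusion).
  As written, the agreement term is a plain sum over the n training
  samples while the likelihood term is divided by n, so the effective
  agreement pressure grows with cohort size; a `normalize_agreement`
  flag divides the term by n for a scale-free ρ.  The default follows
  the displayed objective (no division).
- **λ ≥ 0 (sparsity weight, unitless).**  Default grid for
  cross-validation: 20 log-spaced points in [1e-4, 1], selected by
  10-fold event-stratified CV minimizing the held-out integrated Brier
  score (largest λ on ties — the more parsimonious model).  The
  experiment runners default to a fixed mild λ = 0.01 (see *Problem
  sizes* below).
- **Optimizer.**  BFGS with central finite-difference gradients (step
  1e-6), gradient tolerance 1e-6, at most 500 iterations.  The L1 term
  is smoothed as `|x| ≈ sqrt(x² + ε²)`, ε = 1e-8.  Adaptive-weight
  denominators are floored at `1e-8 · max_k |β̂_k|` so near-zero
  preliminary estimates cannot produce infinite weights.

## Numerical choices

- **Multi-start.**  Even smoothed, the L1 kink can stall a quasi-Newton
  line search exactly at the zero vector (the gradient of the penalty
  vanishes there while a coordinate-wise descent direction still
  exists).  Penalized fits therefore run from two deterministic starts —
  the zero vector and the preliminary maximizer — and keep the lower
  final objective; joint fits with ρ > 0 additionally warm-start from
  the ρ = 0 solution.  A run that ends unconverged is restarted once
  from its last iterate with a fresh inverse-Hessian.  Everything stays
  deterministic.
- **Non-convergence and flat coordinates.**  A fit that exhausts its
  iteration budget with the gradient above tolerance raises an error
  carrying the last iterate by default.  High-dimensional layers
  (p ≳ events) have no finite unpenalized maximizer, and training
  subsets of genotype layers routinely contain rare-allele columns that
  are constant in the subset; such a column cancels out of every
  risk-set ratio, leaving the likelihood flat (and the adaptive penalty
  then shrinks it to zero).  The experiment runners therefore opt into
  `on_nonconvergence="warn"` and `allow_constant=True`; direct calls
  keep the strict contracts.
- **Baseline centering.**  The Breslow baseline is estimated at linear
  predictor 0 by default (the unambiguous mathematical object).  A
  mean-centering flag is provided for compatibility with survival
  software that reports the baseline at the covariate mean; the model
  then stores the offset and predictions are unchanged.
- **Conditional-likelihood comparator.**  The conditional partial
  likelihood sums over all individuals.  Its normalizing set defaults to
  the standard at-risk set `{j: age_j ≥ age_i}`; the reversed direction
  `{j: age_j ≤ age_i}` is available as `risk_set="as_printed"` because
  both conventions appear in the literature this comparator descends
  from.
- **Step-curve semantics.**  All curves are right-continuous step
  functions; evaluation beyond the last knot carries the last value
  forward; survival before the first knot is 1.
- **Metrics orientation.**  With case status y (1 = case), the L1 loss
  compares predicted survival at the recorded age against the target
  survival `1 − y`; the risk score for AUC and the concordance index is
  `1 − S_i(a_i)`.  The integrated Brier score is the Graf/IPCW
  estimator: inverse-probability-of-censoring weights from a reverse
  Kaplan–Meier estimate (events precede censorings at ties, left limits
  at event times), trapezoid-averaged over a grid defaulting to the
  unique validation event ages.  Confidence bands across repetitions use
  the normal approximation `mean ± z_{1−α/2}·sd/√R`, α = 0.05.

## Synthetic cohorts

`generate_cohort` emulates a matched genotype/methylation case-control
study.  Minor-allele frequencies come from a Balding–Nichols
`Beta(p(1−F)/F, (1−p)(1−F)/F)` model with fixation index F = 0.001 and
background frequencies uniform on [0, 0.1]; genotype dosages are
Binomial(2, maf).  The first `n_p` methylation columns are coupled to
their genotype partners as `v_m = b·v_g + ε` with
`b = sqrt(h²/(2·maf·(1−maf)))`, noise sd `sqrt(1−h²)`, and h = 0.3, so
an unfiltered pair has population correlation exactly h.  Retained pairs
are rejection-sampled until the empirical correlation falls in the
acceptance window [0, 0.1] (configurable; a per-pair attempt cap of
10 000 reports the acceptance rate on failure).  Because the sampling
error of a correlation at n = 100 is ≈ 0.1, this window accepts roughly
1% of draws at n = 100 and essentially none for n ≳ 1000 — at larger
cohort sizes the window must be widened.  Remaining genotype columns are
independent loci (redrawn if constant), remaining methylation columns
pure noise.  The latent age is the linear score `Xv` of the concatenated
matrix under weights `v ~ U[0,1]`, affinely rescaled into [50, 100]; a
uniform onset age on the same range decides case status (onset < age);
cases carry the onset age with event = 1, controls the latent age with
event = 0.

What this generator does *not* emulate: linkage disequilibrium between
loci, realistic methylation beta-value distributions, and — importantly
— covariate-dependent event times.  The onset age is drawn independently
of the covariates and only the censoring age depends on them, so the
true covariate-conditional hazard is flat in the covariates and the
population partial-likelihood maximizer is β = 0 (verified numerically
in the development analysis).  Passing fits on these cohorts therefore
demonstrate the machinery (optimization, prediction, evaluation,
relative effects of ρ), not absolute predictive power: validation AUC
under the package's risk orientation sits below 0.5 here, because cases
are evaluated at early onset ages and controls at later follow-up ages,
and any shared decreasing survival curve then ranks controls as
higher-risk.  This is the documented expected failure in the acceptance
suite (`test_cooperative_model_recovers_signal_above_chance`); real
cohorts with genuinely covariate-dependent hazards are needed to show
above-chance discrimination.

`bootstrap_cohort` resamples an existing cohort entry-by-entry within
the case and control pools at the empirical label frequency and then
separates the group age distributions by a configurable number of years
(default 5, applied symmetrically: cases −2.5, controls +2.5; one-sided
variants by flag).  Entry-wise resampling preserves per-feature
marginals but destroys within-layer correlation.

## Problem sizes and scaled-down choices

The repeated-experiment and ablation runners default to a 0.7/0.3
train/validation split (a fixed-count training option exists), 100
repetitions, and α = 0.05 bands.  The acceptance-level ablation runs at
n = 100 individuals, 100 genotype + 100 methylation features, 50 coupled
pairs, 20 seeded repetitions, ρ ∈ {0, 0.5, 2}.  Selecting λ by full
cross-validation inside every repetition would multiply the fit count by
the grid size times the fold count, so the runners fix λ = 0.01 (mild
shrinkage, chosen once) and leave `use_cv` as an opt-in; the CV
machinery itself is exercised at small sizes in the test suite.  Within
each ablation repetition the per-layer preliminary maximizers are shared
across ρ values and the ρ > 0 fits warm-start from the ρ = 0 solution,
which keeps the sweep deterministic and comparable across ρ.

## Known limitations

- Breslow tie handling only (no Efron or exact corrections); no
  stratified or time-varying-covariate models; no competing risks.
- The quadratic-scaling joint optimizer (numerical gradients over the
  concatenated parameter vector) is practical up to a few thousand
  individuals and a few hundred features per layer.
- The layer-weight report `w_j = sd(Z_jβ_j)/Σ_k sd(Z_kβ_k)` is a
  repository convention for summarizing linear-predictor variation, not
  an inferential quantity.
- The smoothed-L1 objective yields approximately sparse solutions
  (coefficients shrink to ~ε rather than exactly 0); an exact proximal
  solver is out of scope.
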