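# Methods

This note records the models, the synthetic-data generator, the numerical
choices and the known limitations of `natprog`, at the level of detail a
maintainer or reviewer needs to judge what the tests do and do not show.

## Study design being modeled

A natural-history study of a severe X-linked myotubular myopathy mouse
model: male mice are phenotyped weekly from weaning (week 3 of age) to week
12 — body weight, three inverted-grid hanging trials capped at 60 s, and
four ordinal clinical signs (kyphosis, walking impairment, ptosis, labored
breathing, each 0 / 0.5 / 1). Deaths occur throughout; survivors are
administratively censored at week 12. A dose–response arm doses animals
weekly from week 5 and animals dying before the first dose are replaced
(the pre-established exclusion rule). Post-mortem panels carry muscle
masses, minimum Feret fiber diameter and % fibers with mispositioned
nuclei.

## Severity scoring

* **Original (max 6):** six unit-weight factors. The hanging factor is
  categorical, anchored at the 50 s and 10 s time-to-event cutoffs
  (≥ 50 s → 0, 10–50 s → 0.5, < 10 s → 1); these anchors are a package
  convention, since only the cutoffs themselves are fixed by the study
  design. The weight factor uses the same gain/stabilization/decline rule
  as the optimized scheme.
* **Optimized (max 5):** body weight (0 / 0.5 / 1 for gain / stabilization
  / decline vs the same mouse's prior week), hanging as the continuous
  score `2·(1 − t/60)` (linear is the minimal assumption consistent with a
  continuous 0–2 score with 0 s worst and 60 s best), kyphosis and walking
  unchanged. Ptosis and breathing are dropped: their onsets are late and
  do not track early progression.
* The stabilization threshold defaults to 0.25 g — small against the
  ~2.16 g terminal loss — and is configurable. The first observed week has
  no prior weight and scores 0 (the healthy-juvenile default).

## Joint longitudinal–survival model

Transformed outcome (log grams for weight — enforcing positivity — or the
raw score for the DSS) linear in √week with correlated per-mouse random
intercept and slope; Weibull baseline hazard times `exp(α·m_i(t))` where
`m_i(t)` is the current longitudinal linear predictor; left truncation at
the first observed week. √week uses absolute age (week 0 = birth), not
time-on-study.

Estimation is maximum likelihood:

* The linear-mixed-model likelihood is evaluated in closed form per mouse
  (multivariate normal) and optimized over `(β, chol G, log σ)`; it
  initializes the joint fit together with a marginal Weibull fit.
* The joint likelihood integrates, per mouse, (normal longitudinal density)
  × (left-truncated hazard density/survival) × (bivariate normal prior)
  over the random effects by **adaptive Gauss–Hermite quadrature**: nodes
  are centered and scaled on the closed-form Gaussian posterior of `b`
  given the longitudinal data alone. This matters: the posterior is an
  order of magnitude narrower than the prior, and prior-scaled nodes
  underresolve it. 9 points per dimension leave the log-likelihood stable
  to < 1e-3 against 15 (tested), and the whole likelihood agrees with
  dense 2-D grid integration to 1e-4 on small cohorts (tested).
* The cumulative hazard over `[entry, T]` is computed exactly as a smooth
  1-D integral in `s = √t` (integrand `(2k/λᵏ)s^(2k−1)e^{cs}`) by 40-point
  Gauss–Legendre; the spec-level alternative (trapezoid on a 0.05-week
  grid) is used where a full path of `H(t)` is needed (death-time
  inversion, band simulation).
* Optimizer: L-BFGS-B with bounds on the transformed parameters
  (`log λ ∈ [log 0.05, log 10⁴]`, `log k ∈ [log 0.3, log 15]`,
  `α ∈ [−20, 20]`). A fit with no death events raises: α is not
  identifiable.

**Identifiability note.** λ and α are partially confounded (a shift in
`α·β₀` is absorbed by `λ^−k`), so at n = 200 mice the λ and α estimates
are noisy though unbiased within Monte-Carlo error; the recovery tests
measure bias against the empirical replicate spread, which reflects this.

## Prediction bands

`predict_band` simulates mice from the fitted model (random effects, fresh
residuals, death times by inverting the fitted cumulative hazard) and
reports, per grid week, the median and the outer `(1∓level)/2` quantiles,
back-transformed to grams for weight and clamped to [0, 5] for the DSS
(the score visibly saturates at its ceiling; clamping is transparent and a
logit alternative was judged not worth the interpretability cost).

Two band flavors:

* **conditional** (default): quantiles among simulated mice still alive at
  each week — bands drawn only over ages mice actually reach. The grid is
  truncated (with a warning) when fewer than 50 simulated survivors
  remain.
* **unconditional** (`conditional=False`): quantiles over all simulated
  trajectories. This is the *extrapolated* envelope used for dose–response
  evaluation and by the pipeline, because under the severe untreated
  phenotype almost no simulated mice are alive at weeks 9–12 and the
  conditional band is undefined exactly where treated cohorts must be
  judged.

Band-deviation reports classify each mouse-week as inside / beneficially
outside (below the band for DSS, above for weight) / adversely outside,
per week and overall.

## Synthetic cohort generator

The generator runs the joint model forwards and adds the phenotype
channels the estimator does not model:

* **Weight:** the LMM core, plus a terminal decline for dying mice —
  onset ~Normal(2.3, 0.8) weeks before death, total loss ~Normal(2.16,
  1.07) g, applied linearly on the gram scale over the lead window.
* **Survival:** death times by numerically inverting the cumulative hazard
  on a 0.01-week grid with linear interpolation, conditional on surviving
  to week 3 (left truncation at weaning). `simulate_death_time` without
  truncation is exactly Weibull when α = 0 (tested by KS).
* **Latent severity** ζ drives hanging, the ordinal signs and the muscle
  endpoints with one mechanism: ζ = (negative standardized random slope ×
  0.4) + an age ramp of 1/week. Hanging trials are
  `clip(start − 30·ζ, 0, 60) + trial noise` with start ~Normal(52, 5) s;
  ordinal signs step 0 → 0.5 → 1 as ζ crosses per-mouse thresholds
  (walking first, then kyphosis, with ptosis and breathing centered after
  week 7, which is what makes those two factors uninformative for early
  progression under the original score). Muscle masses and fiber diameter
  shrink log-linearly in terminal ζ (negative mass–severity correlation
  by construction); mispositioned nuclei average ~20% in mutants vs 0–2%
  in wild type.
* **Treatment** (`dose_effect ∈ (0, 1]`, per arm): from the treatment-start
  week the *disease clock slows* — severity increments are multiplied by
  `dose_effect` and the Weibull baseline advances at rate `dose_effect`
  (with the time-change rate factor). One parameter therefore attenuates
  phenotype progression and rescues survival coherently, and
  `dose_effect = 1` leaves the generated law exactly untouched (tested by
  KS). Animals dying before the first dose are redrawn, as in the study.
* **RNG:** one root seed; per-mouse substreams keyed by (seed, mouse
  index), so growing a cohort never reshuffles earlier animals.

### Calibration of the mutant defaults

Defaults were fixed once, against the study's reported conditions, and are
not tuned thereafter: β₁ = 0.20 log g/√week with G = diag(0.08², 0.025²)
and σ = 0.045 (week-3 weight SD ≈ 1.3 g, weights never reaching 20 g);
β₀ solved so the *expected* week-3 weight is 10.31 g — the lognormal mean
correction plus a constant for the average early-terminal-decline
contribution, measured once at large n; Weibull(λ = 1.55, k = 4) with
α = −2 giving deaths from week 3, median survival just under 5 weeks and
(almost) none past 12; hanging ≈ 50 s at week 3 with ~60% above 50 s,
collapsing below 10 s for ~90% of mice by week 5. Under these defaults the
simulated mean optimized DSS reaches ≈ 4.4 at week 8 among survivors,
matching the reported severity trajectory.

### What the generator does not emulate

No litter or cage structure, no within-day repeated measures, no
measurement dropout other than death, Gaussian noise throughout, and a
single latent severity axis. Passing tests therefore demonstrate the
correctness and calibration of the *methods* under a model-faithful data
law — not that real colony data meet these assumptions.

## Test-harness choices

* **Parameter recovery** uses a model-matched generator: terminal decline
  off (the decline is deliberate misspecification of the estimator's
  model and would bias any recovery check) and a milder hazard
  (λ = 3.2: ~60% deaths, ~8 observations/mouse) chosen on identifiability
  grounds, analogous to using balanced panels for mixed-model recovery.
  Under the severe default hazard mice average < 3 observations, and the
  variance components are too weakly identified at n = 200 for a
  meaningful bias check.
* **Band coverage** checks that fresh simulations from a fitted model fall
  inside its own 95% band 93–97% of the time (consistency of the band
  construction), on the conditional band over its defined grid.
* **Rank-test oracles:** the package reports the conventional chi-square
  (Kruskal–Wallis) and continuity-corrected normal (Jonckheere–Terpstra)
  p-values. Against 20 000-replicate permutation oracles the agreement
  allowance is 0.07 — Monte-Carlo error plus the documented large-sample
  approximation error at n ≤ 9. With very unbalanced tiny groups (e.g.
  sizes 2/3/2) the chi-square approximation deviates by ~0.08 from the
  exact permutation null; that is a property of the approximation, not of
  the implementation.
* Problem sizes throughout (20 replicate fits at n = 200; 3 000–4 000
  Monte-Carlo trajectories per band; 20 000-replicate permutation
  oracles) were chosen as the smallest that leave the Monte-Carlo error
  well below the tolerances being asserted.

## Known limitations

* The √week-linear trajectory cannot represent rise-then-fall weight
  curves; on severe cohorts with terminal decline, the fitted slope blends
  juvenile growth with pre-death loss and the fitted α compensates, so the
  band median can be flat or declining while the envelope remains
  calibrated. The envelope, not the median, is the reference object.
* No standard errors are reported for joint-model parameters (replicate
  spread is used in the tests); a Hessian-based SE is a natural extension
  point.
* The DSS is modeled on the identity scale with clamping; ceiling effects
  make the residual model crude near saturation.
* Current-value association and Weibull baseline are the only implemented
  choices (labeled extension points).
* One-sided dose trends use per-arm insertion order as dose order; the
  caller is responsible for ordering arms.
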