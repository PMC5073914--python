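# Methods

## Scope

The package rehearses the evaluation of a site-level quality-improvement
intervention under a nonrandomized stepped wedge rollout: it simulates
repeated cross-sectional ordinal survey outcomes with a known
intervention effect, fits a three-level cumulative-logit hierarchical
model, and checks the operating characteristics of the resulting Wald
inference. Everything is driven by one `ScenarioConfig`; the defaults
are the reference study conditions and are not tuned per run.

## The rollout design

A `WedgeSchedule` holds one `SiteProfile` per site: its first
implementation quarter (≥ 2; every site is in control at quarter 1),
its size label and its rollout phase. The default is nine sites over
twelve quarters with start quarters 2, 3, 4, 5, 5, 8, 9, 11, 12 —
58 of the 108 site-quarter cells are in the "on" state. Treatment is
an absorbing state: the per-site indicator is a monotone step.

Derived covariates per cell: `qtr` is the calendar quarter coded
1..12, uncentered — the intercept therefore refers to a control-state
respondent at `qtr = 0`, a mild extrapolation that keeps the model
formula literal. The interaction is `qtr * treat` on the calendar
scale, not quarters-since-crossover; the generator's drift, by
contrast, is indexed by quarters since crossover ("each ensuing
quarter on treatment"). This deliberate tension — the model is a
linear-in-calendar-time approximation to a crossover-indexed
improvement process — is exactly the situation the evaluation design
must cope with, and it drives several estimand subtleties discussed
below.

Phase is carried as metadata only; the model never uses it.

Site sizes (2 small, 2 medium, 5 large) enter as two reference-coded
indicators (MED, LG; small is reference). Sizes carry no simulated
effect, so the default assignment spreads each size class across the
rollout phases (small = sites 3 and 7, medium = sites 1 and 9, large =
the rest; group-mean start quarters 6.5/7.0/6.4). An assignment
ordered by site id would confound size with rollout order — early
starters accumulate improvement — and manufacture a spurious size
effect that contradicts the design intent of size as a null covariate.
The assignment is configurable per schedule.

## The outcome generator

Outcome: a 4-category ordinal access rating stored as 1 = always,
2 = usually, 3 = sometimes, 4 = never.

* **Control state.** Uniform: (0.25, 0.25, 0.25, 0.25).
* **First implementation quarter.** A site-specific jump target drawn
  once per site: p_always ~ U(0.30, 0.36), p_usually ~ U(0.29, 0.33),
  and the complementary mass split between "sometimes" (within
  [0.16, 0.23]) and "never" (within [0.11, 0.20]) by a uniform draw on
  the feasible interval. Infeasible configuration ranges raise a
  configuration error up front.
* **Ensuing quarters.** Two site-specific drift rates, each
  ~ U(0.01, 0.03) per quarter, add mass to "always" and "usually";
  the same mass is removed from "sometimes" and "never" in proportion
  to their current size, clamped at the plateau floors (sometimes
  ≥ 0.07, never ≥ 0.05) with any shortfall moved to the other
  category. Gains are clamped at the plateau caps (always ≤ 0.44,
  usually ≤ 0.42). The update conserves the simplex exactly (no
  post-hoc renormalization) and reaches a fixed point at
  (0.44, 0.42, ·, ·) because the mass available above the floors
  exceeds the headroom below the caps by 0.02 for every feasible jump
  target. The caps/floors are the union of the two printed plateau
  descriptions of the reference scenario; note they sum to 0.98, so
  the residual 0.02 stays on the worse categories.

Jump targets and drift rates are drawn once per site, not per quarter
(a per-quarter redraw mode exists, off by default): a single draw is
the simplest mechanism that produces the "marked jump, then slower
steady improvement" trajectory. Under `null_effect` every cell stays
uniform regardless of the schedule.

Covariates are independent Bernoulli draws (female 0.10, nonwhite
0.25) with no effect on the outcome; an exact-quota mode supports
deterministic tests. Respondents are fresh in every cell (no repeat
sampling), numbered sequentially over (quarter, site) blocks.

Randomness: one scenario seed spawns an independent substream per site
(`SeedSequence(entropy=seed, spawn_key=(site_id,))`), so adding or
re-ordering sites never perturbs another site's draws, and a dataset
is byte-identical across reruns of the same config.

What the generator does **not** emulate: survey nonresponse, repeat
sampling of the same patient across waves, provider-level clustering,
differential covariate effects, secular control-state trends, or
site-level shocks unrelated to the rollout. Passing tests therefore
demonstrate internal validity of the estimator under this idealized
mechanism, not robustness to those real-data features.

## The estimator

The model is a proportional-odds cumulative logit over the three
ordered splits, with shared coefficients, thresholds (0, δ2, δ3), and
two nested Gaussian random intercepts: one per site-quarter cell
(variance `variance_time`) and one per site (`variance_site`).
Orientation: the link models the probability of the better-access side
of each split, so positive coefficients move mass toward "always";
the 1..4 storage coding plays no statistical role.

* **Sufficiency/aggregation.** Respondents are aggregated to
  (site, quarter, female, nonwhite) pattern counts — a sufficient
  statistic — so likelihood cost is independent of n per cell.
* **Laplace marginal likelihood.** Random effects enter each cell's
  linear predictor as u_site + r_cell. The joint penalized
  log-likelihood is strictly concave; a damped Newton iteration with
  analytic gradient/Hessian finds the joint mode of all 117 effects at
  once. Cells couple only through their site's intercept, so each
  Newton step and the Laplace log-determinant reduce to a diagonal
  solve plus a scalar Schur complement per site.
* **Outer optimization.** L-BFGS-B over fixed effects, log threshold
  increments (δ2 = exp a2, δ3 = δ2 + exp a3, enforcing
  0 < δ2 < δ3 by construction) and log variances (bounded in
  [e−18, e5]), with finite-difference gradients; the random-effect
  modes warm-start between evaluations. The convergence flag requires
  optimizer success **and** max |gradient| < tol·n (tol = 1e−6 per
  observation, i.e. the objective is flat to ~1e−6 per respondent).
  Non-convergence is reported, never silently ignored. Fixed-effects
  starting values come from an exact proportional-odds fit with an
  analytic gradient.
* **Standard errors.** Observed information of the profile objective
  by central finite differences over coefficients and thresholds, with
  variance components held at their estimates (the usual mixed-model
  practice; variance-parameter uncertainty is not propagated, and no
  variance SEs are reported). Wald p-values are two-sided normal; no
  multiplicity adjustment. Variances below 1e−6 are flagged as
  boundary estimates rather than dropped.
* **Population-average mode.** The same fixed-effects likelihood with
  cluster-robust sandwich standard errors at the site level
  (independence working model) — a GEE-flavoured sensitivity analysis.
  With only nine clusters its SEs are themselves noisy; it is a check,
  not the default.
* **Zero-variance contract.** With both variances pinned at 0 the fit
  reduces exactly to the fixed-effects proportional-odds optimum; the
  test suite verifies agreement with statsmodels' `OrderedModel` to
  1e−4 (coefficients) as an independent route.

## Design-implied oracles

`population_or_oracle` works from the exact generating cell
distributions (no Monte-Carlo error) and reports three things:

1. **Pooled per-split odds ratios** of on vs. off cells — closed form,
   e.g. exactly 1.5 for the textbook case where every on-cell has
   p_always = 1/3 against a uniform control.
2. **The marginal projection**: the fixed-effects time-block model
   fitted to the exact cell distributions by expected-NLL
   minimization. Under this generator it has QTR exactly 0.
3. **The estimator's population value**: the same mixed model fitted
   to exact expected per-cell counts. Parameter recovery compares the
   mean fitted treatment OR across replicates to this value, because
   the treatment coefficient is *not* the pooled on/off OR once the
   calendar interaction is in the model (γ020 is the treatment
   contrast extrapolated to qtr = 0), and because the random-intercept
   estimand differs from the marginal one (next section).

## Estimand subtleties (and an honest discrepancy)

Site random intercepts absorb each site's average deviation — including
the part of the treatment effect that varies between sites and is
correlated with the (nonrandom) start quarter. Two consequences,
both reproduced exactly by the expected-count projections:

* the treatment main effect is estimated mostly from the within-site
  on/off contrast (≈ 0.21–0.35 across replicates here), well below the
  marginal projection (≈ 0.45–0.55) and with a larger SE;
* a small positive calendar trend (QTR ≈ 0.015–0.025) leaks into the
  control state even though control cells are exactly flat, because the
  site intercept compromises between a site's control and treated
  quarters. The marginal (population-average) mode shows QTR ≈ 0, as
  expected.

Consequently, on a full-scale default run the treatment Wald test
typically lands at p ≈ 0.001–0.01 rather than far below 0.001, and QTR
can cross p = 0.05. The reference evaluation this package rehearses
reported a cleanly non-significant QTR and a stronger treatment z with
the same model class; the difference is consistent with a generator
whose treated cells deviate less from the proportional-odds shape
(smaller cell-level variance) than ours, but the exact reference
generator settings are not fully specified, and we do not adjust ours
to chase a single printed run. The same shape mismatch inflates the
fitted thresholds slightly (δ2 ≈ 1.37–1.39, δ3 ≈ 2.41–2.44 vs. the
uniform-only values 1.0986 and 2.197): the plateau distributions are
strongly non-proportional relative to uniform, and the thresholds
absorb the pooled spacing.

## Operating characteristics (computed, not asserted)

The Monte-Carlo driver and the acceptance tests recompute, at 200
respondents per cell (the scaled size that keeps a replicate fit under
half a second while preserving the design structure):

* type-I error of the treatment Wald test under the null at
  α = 0.05 over 200 replicates — calibrated within 3 binomial SEs;
* parameter recovery of the design-implied treatment OR over 20
  replicates — within 3 SEs of the oracle value;
* replicate banding of every Model-1 coefficient.

Problem sizes used throughout (108 cells, 200–1000 respondents per
cell, 20–200 replicates) are the package's own defaults chosen to make
the full analysis reproducible in minutes on one core; the cell-count
aggregation means fitting cost does not grow with respondents per cell.

## Known limitations

* The Laplace approximation is excellent at these cluster sizes
  (hundreds to thousands of observations per cell) but untested here
  for very small cells; no adaptive quadrature is provided.
* Wald inference on variance components is deliberately absent
  (boundary issues); variances are reported as point estimates only.
* The sandwich SEs of the population-average mode rest on 9 site
  clusters and are anti-conservative in the usual small-cluster way.
* Four-level (provider) clustering, partial/non-proportional odds,
  Bayesian estimation and survey weighting are out of scope.
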