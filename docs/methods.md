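# Methods

## Model

The outcome is a binary indicator per runner (one horse performance in one
race). The probability of an exertional heat illness (EHI) incident is
modelled with a binomial generalised additive mixed model on the logit
scale:

    logit P(y_ir = 1) = α + f_dist(d_r) + f_wbgt(w_m) + f_prev5(a_m)
                        + f_age(age_ir) + β'x_ir + b_h(i) + b_m(r)

with smooth functions `f_·` for race distance (yards), race-day WBGT (°C),
preceding 5-day mean daily maximum temperature (°C) and horse age (years);
treatment-coded categorical effects `x` for collapsed going (5 levels),
previous-incident flag, calendar year and off-time band (pre/post 5 p.m.);
and zero-mean random intercepts for horse and race meet.

**Smooths.** Cubic regression splines in the value-at-knots
parameterisation, knots at covariate quantiles (default basis dimension
k = 10), sum-to-zero constrained over the training rows. The wiggliness
penalty (integrated squared second derivative, normalised to unit spectral
norm) is modified for shrinkage: the penalty null space — after
constraint, the linear component — receives an eigenvalue of 1e-2 times
the smallest positive one, so a large enough smoothing parameter shrinks
the entire term to the zero function while an estimable linear trend is
essentially unshrunk (both properties are asserted in the test suite).

**Random effects.** Penalised dummy-coefficient blocks with an identity
penalty — the standard penalised-regression representation of i.i.d.
Gaussian intercepts, with σ² = 1/λ. Groups unseen at training time predict
a zero intercept, which keeps cross-validated prediction well defined.

**Fitting.** Penalised IRLS with step halving on the penalised deviance;
smoothing parameters (one per smooth, one per random block) updated each
outer iteration by the extended Fellner–Schall rule, a REML-type
(marginal-likelihood) criterion that treats smoothing parameters and
random-effect variances identically. Trace terms are computed by one
batched multi-right-hand-side solve per iteration; blocks wider than 64
columns use a fixed-seed Hutchinson (Rademacher probe) estimator, so
results are deterministic. Normal equations are solved by dense Cholesky
up to 1200 coefficients and sparse LU above. Smoothing parameters are
clipped to [1e-7, 1e7] with per-step moves of at most e⁴; random blocks
start at λ = 10 (σ ≈ 0.3) and smooths at λ = 100 — starting at λ = 1
lets group effects and wiggly smooths soak up covariate signal in
iteration-capped fits, while converged fits are unaffected by the start.
The fitter reproduces R mgcv (binomial `gam`, `bs = "cs"`, REML) on shared
data to within sampling-irrelevant differences; one cross-check test runs
mgcv directly.

**Numerical edge cases.** Linear predictors are clipped at ±30; IRLS
weights are floored at 1e-10 and the normal matrix carries a negligible
1e-8 diagonal ridge, so separation-flattened weights can never make the
factorisation numerically indefinite; categorical level sets can be
supplied from a parent frame, with structurally empty columns pinned at
zero (the level then predicts like the reference — this keeps
cross-validation defined when a rare level misses a training fold);
coefficients larger than 25 in magnitude trigger
a separation warning (rare categorical levels with no cases drift to the
boundary — their fitted probabilities are effectively 0 and their contrasts
carry huge standard errors, as in any unpenalised logistic fit). Smooth
evaluation outside the training range clamps to the range endpoints with a
warning; unseen categorical levels raise.

## Rare-event handling

Fitting uses all cases plus a simple random sample of `round(ratio ×
n_cases)` controls (default ratio 10, i.e. a fitted case fraction of
1/11 ≈ 9.1%; at the reference scale of ~659 cases this yields 7,249 fitted
rows). Non-intercept coefficients are invariant to this case-control
sampling (asserted over 20 seeds in the acceptance tests). Absolute
probabilities are restored by the odds-scale prior correction

    odds_abs = odds_model · [π (1 − q)] / [q (1 − π)]

where q is the fitted case fraction and π the source prevalence. The
correction is strictly increasing, maps 0→0 and 1→1, and leaves
rank-based summaries (AUC) unchanged.

## Selection and scoring

Backward stepwise selection from the maximal model. Candidate models are
scored by 5-fold cross-validation: folds are uniform random row
partitions; only the training portion of each fold is down-sampled; test
folds stay at source prevalence and are scored on class-adjusted
probabilities with the Brier score and its scaled version. Two scalings
are implemented: the published form (1 − BS)/BS_max and the conventional
skill form 1 − BS/BS_max; both decrease in BS, and the choice is a
configuration field (`brier_scale_variant`). The published form's
magnitude is dominated by 1/BS_max (it is not a bounded skill fraction),
so the complement form is the sensible scale for the removal slack;
`selection_tolerance` (default 0.05 percentage points) is the amount by
which the best removal's mean scaled score may fall below the incumbent's
and still be accepted — small score drops must be acceptable or
performance-neutral terms would never be removed. Within a selection
round all candidates and the incumbent share the same fold assignment and
down-sampling draws, so comparisons are paired. Random-intercept terms
are never removal candidates.

## Classification

ROC curves and trapezoid AUC (tied scores get half-concordance) come from
scikit-learn behind the module surface. The decision threshold maximises
G-mean = √(TPR·(1−FPR)) over the grid {0, 0.01, …, 1} with classification
positive at prob ≥ t; ties on G-mean return the smallest threshold
(favouring sensitivity for a screening application). Race-level
aggregation flags a race if any runner is flagged and counts a race as an
observed positive if any runner had an incident.

## Synthetic-population generator

The generator emulates the statistical structure the analysis assumes; it
is the package's validation instrument, not a calibrated model of any real
jurisdiction.

* **Weather.** Per course-day: seasonal sinusoid (UK-like, ~6 °C mean
  daily maximum in late January, ~21 °C in late July) plus AR(1) anomalies
  (sd 3.5, lag-1 correlation 0.55), clipped to (−5, 38); humidity
  negatively coupled to the anomaly, clipped to [20, 100]. The persistence
  value keeps race-day WBGT and the preceding 5-day mean separately
  identifiable (their correlation is ~0.83; at 0.7 persistence it reached
  0.89 and the two environmental effects were no longer stably
  attributable).
* **Racing structure.** Meets are course-dates (~85 runners per meet at
  the default scale), seasonally weighted (flat racing in summer, jump in
  winter); going derives from a rainfall proxy anti-correlated with the
  temperature anomaly; race cards of 6–7 races with off times between
  ~13:00 and ~21:00. Horses (60% flat, debut at 2–3; 40% jump, debut at
  4–6) have overdispersed careers (mean 10 runs, negative-binomial tail)
  spread over multiple seasons so age advances within a career.
* **True effects.** Smooth closed forms sampled onto dense
  piecewise-linear tables (library-independent): logarithmic in distance,
  softplus hinge in WBGT (flat in the cold, near-linear above ~12 °C),
  exactly linear in the 5-day average, Gaussian bump in age peaking near
  4.2 years. Each curve is scaled so the published headline contrasts hold
  exactly (distance 2 mi/1 mi = 5.66; WBGT 30/20 = 10.14; 5-day 25/15 =
  0.33; age 4/2 = 1.34 and 6/4 = 0.82); categorical truths use
  previous-incident ln 18.59, off-time ln 1.478, going and year effects in
  the reported directions. Smoothness matters: a kinked truth cannot be
  tracked by any penalised-spline fit and would make recovery experiments
  test the truth's shape rather than the pipeline.
* **Outcomes.** The intercept is calibrated by bisection on the exact
  expected prevalence of the sequential process (the previous-incident
  flag switches on after a horse's first incident), then outcomes are
  drawn horse by horse in date order. Random intercepts: σ_horse = 0.3,
  σ_meet = 0.2 — modest unexplained heterogeneity, consistent with
  horse-level risk being largely captured by age and incident history.
  At the default scale the simulation reproduces the reference study's
  observable margins: ~620 incidents in ~620,000 runners, jump incidence
  roughly 10× flat, and ~15–20% of incidents occurring in horses with a
  prior incident.

What the generator does *not* emulate: real covariate joint distributions
(BHA data are not public), course geography, trainer/fitness effects,
within-day weather, or outcome misclassification. Passing recovery tests
therefore demonstrates that the pipeline estimates what it is pointed at
under the assumed structure — not that the published real-data estimates
are correct.

## Validation problem sizes

Test-suite experiments are scaled to run on one CPU in minutes; sizes are
the package's validation design:

* anchored odds-ratio recovery: 10 replicates of ~620,000 runners at 0.1%
  prevalence (the reference scale), odds ratios averaged on the log scale
  (geometric mean — the right location summary for ratios, and robust to
  the heavy right tail of the previous-incident estimate, which rests on
  only ~15–30 flagged controls after down-sampling);
* calibration: three populations of 250,000 runners, 50,000 held out each,
  logistic recalibration slope of held-out outcomes on predicted log-odds;
* case-control invariance: 20 populations of 8,000 runners at 2%
  prevalence, full-data vs down-sampled fits;
* selection behaviour: 20 populations of 4,000 runners at 5% prevalence
  over four seasons (complement scaled-Brier variant). At this compression
  the known failure modes are random-intercept leakage across row-level
  folds — well-estimated meet/horse intercepts can absorb weather or
  incident-history signal, occasionally dropping a true term — which
  shrinks as the design grows toward the reference scale.

## Known limitations

* Fellner–Schall is a fixed-point ascent on a Laplace-approximate REML; on
  rare-event data with strongly correlated covariates (environmental
  concurvity) replicate fits occasionally settle on heavily smoothed
  solutions, giving the recovery estimates a heavy-tailed error
  distribution. mgcv exhibits the same behaviour on the same frames.
* Penalised estimation attenuates weak nonlinear features; the age bump
  (0.29 log-odds amplitude) is at the edge of detectability at ~650 cases
  and its 4-vs-2-year contrast is systematically under-recovered.
* P-values for categorical contrasts use normal (z) statistics and a
  seeded Monte Carlo evaluation of the max-|Z| distribution (200,000
  draws) for the single-step adjustment.
* The intercept calibration targets the expected prevalence with the
  previous-incident feedback accounted for exactly, but realised
  prevalence still varies binomially between replicates.
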