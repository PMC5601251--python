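# Methods

## Model and estimation

Breeding success is a Bernoulli outcome per individual x season with logit
link. Every model carries two crossed random intercepts, individual and
season, with variances `s2_ind` and `s2_year`. Because the factors are
crossed, the marginal likelihood is a single high-dimensional integral that
does not factorise; we approximate it by Laplace's method at the joint
conditional mode — the convention of mainstream mixed-model software for
binomial responses at this scale, and the right default given that adaptive
quadrature cannot be factorised across crossed factors.

Estimation is nested. Inner loop: for fixed variances, Newton iterations on
the joint penalised log-likelihood in `(beta, u, v)` (penalised IRLS). The
normal equations are solved exactly by eliminating the individual block
(diagonal after weighting), leaving a small dense system in the fixed
effects and year effects; cost per iteration is linear in observations. A
step-halving line search guarantees the penalised objective never
decreases. Outer loop: bounded L-BFGS-B on `(log sigma_ind, log
sigma_year)` of the profiled Laplace log-likelihood, with three
deterministic restarts from perturbed starts on failure. Convergence: outer
`ftol` 1e-11 / `gtol` 1e-7, inner relative objective change below 1e-10
(1e-12 at the final polish).

Numerical conventions, all deliberate and tested:

* **AIC parameter count.** `k = n_fixed + n_variance_components`; a
  variance estimated at the boundary is reported as 0 but still counts.
  dAIC-based decisions depend on this convention, hence it is fixed and
  stated rather than configurable.
* **Boundary variances.** Estimates with `sigma^2 < 1e-4` are reported as
  exactly 0 with a flag. Pinning both variances to zero (`fix_sigma2=(0,
  0)`) reduces the fit to ordinary logistic regression exactly (verified
  against an independent IRLS implementation to 1e-6); pinned components do
  not count in `k`.
* **Separation.** Any fixed effect beyond +/-15 logits raises an error
  rather than returning a silently diverged fit. During breakpoint scans,
  individual candidates whose hinge segment is (near-)one-sided in outcome
  are dropped from the profile and recorded, rather than aborting the scan.
* **Standard errors.** Fixed-effect covariance is the inverse Schur
  complement of the random block in the joint observed information;
  prediction SEs on the probability scale use the delta method, with random
  effects at zero (population-typical curves).

### Exact-likelihood oracle

`loglik_oracle` evaluates the marginal likelihood exactly (to quadrature
precision) for small instances: conditional on the year effects the
individuals are independent, so the crossed integral reduces to a product
Gauss–Hermite grid over year levels (default 25 nodes per dimension, at
most 5 year levels) with a one-dimensional quadrature per individual
inside. The binding cost is exponential only in the number of *year*
levels; individuals scale linearly. On the bundled fixtures (8–20
individuals, 2–4 seasons, `s2_ind <= 0.09`) the Laplace value agrees with
the oracle to better than 0.01 absolute. The Laplace error is systematically
negative and grows with the variance components and the number of clusters
(at `s2_ind = 0.25` with five observations per cluster it reaches ~0.04 on
comparable instances), which is why the agreement tolerance is certified on
small-variance fixtures and the discrepancy is reported, not hidden.

## Age-function selection

Candidate families: null, linear, quadratic, and continuous hinge functions
with one or two breakpoints (`min(age,t)`, `max(age-t,0)`; the two-threshold
basis adds a clamped middle segment, `t2 - t1 >= 3`). Basis columns are
built from raw ages — continuity at breakpoints holds by construction — and
then centred on their fitting-sample means for conditioning; the centring
constants are stored so predictions are exact.

The default breakpoint grid is every integer age from (min observed + 2) to
(max observed - 2) with at least 25 observations strictly on each side;
this prevents degenerate hinge columns. The 95% breakpoint CI is the
contiguous run of candidates around the best whose deviance (-2 log L,
Laplace) lies within the chi-square(1) 0.95 quantile (3.841) of the
minimum — an approximation inheriting whatever error Laplace carries, and
treating the breakpoint as one degree of freedom.

Top-set membership is *strict* dAIC < 2 (a model exactly 2 units behind is
excluded); ties for best break by fewer parameters, then smaller first
threshold. Model averaging operates on response-scale predictions, never on
coefficients — coefficients of different bases are not commensurable.

**Scan-selection caveat.** The minimum AIC over a ~30-candidate breakpoint
grid is an order statistic: on data with *no* age structure it beats the
null model by 4–10 AIC units in a substantial fraction of replicates purely
through selection. Single-model comparisons (null vs linear, null vs any
one candidate) are calibrated; "best of scan vs null" is not, and
conclusions that rest on it should be checked against the profile shape.

## Early/late decomposition

The split uses the best single-threshold age per species x sex, with an
explicit override map for cases where the scan's breakpoint would leave
recruits out of the early window (e.g. forcing a female split at 18).
Eligibility filters are independent: early models use known recruits (age
at first observation = age at first reproduction); late models use birds
presumed dead under the gap rule (age at last observation = age at last
reproduction). A bird can satisfy both, either, or neither; censored birds
are excluded from late models, never imputed.

The within-individual clocks are calendar years (`age - age_first`,
`age_last - age`), not attempt counts, because biennial breeders skip
seasons. Sign convention: a *positive* `years_before_death` coefficient
means success falls as death approaches. Term importance is
`AIC(model without term) - AIC(model with term)` on identical data;
constant columns (e.g. every bird sharing one `age_last`) are dropped from
the design and recorded, not fitted. Optional robustness covariates for the
late model (partner change, years since the previous attempt, its outcome,
and their interaction) drop first-attempt rows lacking a previous attempt
and never displace the headline terms.

The sex-comparison model fits nest-level success on both parents' hinge
bases with year and pair random intercepts (pair, not individual, is the
default random unit — the two are nearly aliased in long-term pairs; a
year-only variant is available) and scores each sex by the AIC increase
when its pair of age columns is dropped. The cross-species models use
treatment-coded species contrasts (configurable reference) with
species x term interactions scored blockwise by removal dAIC.

## The simulator

`simulate_population` generates the data-generating process the models
assume, plus the scheduling and mortality structure that makes the
inference problem hard:

* latent quality `u_ind ~ N(0, 0.5^2)` and season quality
  `u_year ~ N(0, 0.3^2)` on the logit scale (defaults);
* a continuous hinge age trajectory: +0.15 logits/yr to age 20, -0.10
  after, anchored so that `beta0` (default 0.54) is the logit success at
  `anchor_age` (default midway between mean recruitment age and the
  threshold) — keeping `expit(beta0)` close to the marginal success rate;
* a first-attempt penalty (-0.8 logits) and a terminal effect (+0.7) on
  the final attempt before death;
* recruitment at a discretised normal age (mean 10, sd 2, truncated at 5),
  entry season uniform over the study;
* annual survival `expit(logit(0.95) + cost * u_ind)` with `cost = -0.5`
  by default, so good breeders die younger (selective disappearance); the
  death season is pre-drawn from this process, independent of outcomes;
* breeding schedules: the annual profile returns every season; biennial
  profiles return after 2 seasons following success and 1 after failure;
  on top of this, birds defer an extra season with configured
  probabilities (defaults anchored to roughly a third of birds deferring
  beyond the expected year in the wandering-albatross-like profile, ~10%
  in the annual profile).

The three profile presets differ in recruitment age, baseline success
(marginal rates ~0.30 annual / ~0.35 biennial-short / ~0.51
biennial-yearlong), survival and deferral, giving the qualitative
species contrasts of the study system.

**Terminal-effect coding.** The terminal boost applies when even the
earliest possible return (the failure-branch gap) falls after the
pre-drawn death season, so the flag never depends on the outcome being
generated. Attempts that become final only because a success stretched the
gap across the death season receive no boost; the retrospectively coded
`is_last_attempt` therefore mixes boosted and unboosted finals, mildly
attenuating recovery of the generative parameter — under *biennial*
schedules this is overwhelmed by the opposite, inflationary mechanism
below.

**Schedule-induced confounding (a feature, not a bug).** Under biennial
rules a success lengthens the gap to the next attempt, which (i) makes a
successful attempt mechanically more likely to be the bird's last — the
estimated last-attempt contrast then exceeds the generative terminal
effect — and (ii) lets low-quality birds attend more often, enriching older
age classes with poor breeders and creating a population-level age pattern
even under a flat generative trajectory. Both phenomena are real properties
of biennial breeding systems, not simulator artefacts. Consequently the
calibration experiments (type-I rates of the term-removal dAIC, flat-data
parsimony, unbiasedness of the terminal-effect estimate) are run under the
annual, outcome-independent schedule, where the null is genuinely null;
the biennial runs are used for sign recovery, where both mechanisms push
the same way.

**Appearance/disappearance interpretation.** Because the generative
trajectory is a function of calendar age, `age_first` (early) and
`age_last` (late) absorb the age-scale slope in addition to any genuine
selection — exactly the confounding the within-group-centring design
acknowledges in real data. "Appearance/disappearance estimates centred on
zero" is therefore expected, and tested, only under flat-slope
configurations.

What the simulator does *not* emulate: density dependence, pair-formation
dynamics and mate effects on success, bycatch or any non-constant mortality
hazard, failure-timing-dependent deferral, and environmental trends (year
effects are iid). Passing recovery tests on these simulations therefore
demonstrates correctness of the estimators under the assumed
data-generating process, not robustness to the many ways real colony data
violate it.

## Problem sizes and determinism

Monte-Carlo experiments use 800 birds (threshold and sign recovery, 25
replicates) and 600 birds (null calibration, 50 replicates) — large enough
that the per-replicate fits are stable, small enough that the full suite
runs in minutes on one CPU. All randomness flows from a single seed per
experiment through `numpy.random.default_rng`; identical seeds give
byte-identical pipeline outputs.

## Known limitations

* Laplace accuracy degrades with large variance components and many small
  clusters; published-software parity on dAIC values is not expected.
* The breakpoint CI treats the threshold as one parameter inside a
  deviance profile; its coverage is approximate (measured ~0.7–0.9 at the
  default design, consistent with the discreteness of the grid).
* The age-support filter is applied once, before model fitting, to the
  population-level dataset; the alternative treatment (pooling ages with
  <10 observations into neighbours) is not implemented.
* Real-data features such as unknown-age immigrants, mis-sexed birds or
  partner ages observed with error are out of scope; the ringing-window
  restrictions used for published life-history summaries are supported
  only as caller-side filters.

* Breakpoint recovery is certified under a correctly specified trajectory
  (pure hinge, no discontinuous attempt effects). When the generative
  process also contains first-attempt or terminal discontinuities that the
  intercept+hinge scan omits, the selected breakpoint shifts by ~1 year and
  the profile CI loses coverage — worth remembering when interpreting real
  breakpoint CIs, since real data surely contain such discontinuities.
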