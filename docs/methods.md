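# Methods

## The model

`sleepdmpm` implements a dynamic multivariate panel model (DMPM) for three
daily sleep-quality indicators recorded in a short diary (up to six
consecutive waking-to-waking cycles per subject):

* `y1` — daytime sleepiness, binary (1 = felt very sleepy);
* `y2` — ease of falling asleep, ordinal 1 < 2 < 3 (3 = fell asleep easily);
* `y3` — ease of waking up, ordinal 1 < 2 < 3 (3 = woke refreshed).

Each channel is a generalized linear model: Bernoulli-logit for `y1`,
cumulative (proportional-odds) logit for `y2` and `y3`, with
`P(y <= k) = logistic(c_k - eta)` and strictly ordered cutpoints.  The
linear predictor of each channel contains

* **serial and cross-lagged outcome terms** following a temporal-ordering
  DAG.  Within a cycle the generative order is `y3 -> y1 -> y2` (the
  morning's waking precedes the day's sleepiness, which precedes the
  night's sleep onset); across cycles each channel sees the previous
  cycle's outcomes.  Concretely: `y1` regresses on lag-1 `y1`, lag-1 `y2`
  and same-cycle `y3`; `y2` on lag-1 `y2`, same-cycle `y3` and `y1`;
  `y3` on lag-1 `y3`, `y1` and `y2`.  Ordinal parents enter as two
  indicator contrasts (levels 2 and 3 vs. level 1) rather than linear
  scores, so no equal-spacing assumption is made.
* **35 covariates** in six categories: 6 stress items (4-point scales),
  5 bedtime conditions (bedtime in signed hours relative to midnight, time
  in bed, caffeine/alcohol/ICT-use dummies), 5 daily weather variables,
  3 physical attributes (age, BMI, systolic blood pressure), 4 exercise
  participation dummies, and 12 food-group intake densities in g per
  1000 kcal.  Stress, bedtime and weather are time-varying; the rest are
  constant within subject.

Day 1 of each diary is treated as the initial condition: the likelihood
runs over cycles t = 2..T only, conditioning on the day-1 outcomes.

### Covariate lag alignment

The per-channel timing of covariates reflects the cycle structure.  A
diary row's bedtime block describes the night that ends with that
morning's waking, so bedtime conditions (and the weather on the evening of
going to bed) carry lag 0 for `y3` and lag 1 for `y1` and `y2`.  Stress is
reported during the cycle itself, so it carries lag 0 for `y1` and `y2`
and lag 1 for `y3`.  Time-invariant covariates have no lag.  These
alignments live in `CovariateSpec.lag_by_channel` and are honored
identically by the design-matrix builder, the forward simulator, and the
synthetic-data generator; a dedicated test asserts the design matrices
differ by exactly the intended shift.

## Bayesian estimation

The posterior factorizes over channels (each channel's parameters enter
only its own likelihood term), so the three channels are sampled
independently.  Priors are weakly informative: Normal(0, 2.5) on slopes on
the unit-variance predictor scale (covariates are standardized internally,
i.e. Normal(0, 2.5/sd(x)) on the raw scale — the usual autoscaled
default), Normal(0, 5) on intercepts and cutpoints at centered predictors.
Cutpoints are sampled on the ordered transform `(c1, log(c2 - c1))`, so
ordering holds in every draw by construction.

Sampling is Hamiltonian Monte Carlo with analytic gradients.  Because each
channel posterior is log-concave (logistic-family likelihood with Gaussian
priors), the sampler is preconditioned by the Laplace approximation: the
posterior mode is found with L-BFGS, the Hessian there is factorized, and
HMC runs in the whitened coordinates where the posterior is approximately
standard normal.  Warmup uses dual-averaging step-size adaptation (target
acceptance 0.8) with trajectory lengths jittered uniformly over 5–15
leapfrog steps to avoid resonance.  Defaults are 4 chains of 500 warmup +
500 kept iterations; the reference estimation settings of the original
analysis are not published, so these are the package's own choice.
Convergence is summarized per parameter by split-R-hat and bulk effective
sample size (via arviz); a fit attaches a warning when more than 5% of
parameters exceed R-hat 1.05.

On a 200-subject, 6-day panel a full three-channel fit takes well under a
minute on one CPU and recovers roughly 90% of the generating coefficients
inside their 90% posterior intervals, with all R-hat below 1.05.
Raw-scale cutpoints can show very wide intervals: they are a linear
combination of the centered cutpoint and many covariate means, some of
which (notably weather) are only weakly identified in a short panel.  This
does not affect slope recovery or the contrasts.

## Interquartile do-intervention contrasts

The effect of item k on an outcome level is

    |Pr(outcome | do(x_k = Q3)) - Pr(outcome | do(x_k = Q1))|

with Q1/Q3 the within-subsample quartiles of x_k (linear-interpolation,
"type 7"; the deposited analysis does not state its quantile rule).  The
do-operator holds the item fixed for every subject and cycle, severing any
feedback into it; all other covariates stay at their observed values
(single-variable intervention under the back-door adjustment implied by
the DAG).  Outcomes are re-simulated forward from each subject's observed
day-1 values, and the probability is averaged over all subjects and cycles
2..T.  Per-category effects are the draw-by-draw sums of their items'
absolute contrasts; summaries are posterior-predictive means with
equal-tailed 90% credibility intervals.  Both endpoints of an item are
simulated with common random numbers, so an item with zero coefficients
contributes exactly zero.

Special rules:

* **Rare binary items.**  When a dummy covariate's sample mean is low
  enough that Q1 = Q3 (the pre-bed caffeine case), the improvement width
  is 0 -> 1 instead.  This is the only sanctioned override; a zero IQR on
  a non-binary item raises a warning and the item is reported as zero.
* **AR(1) row.**  The serial-dependence contribution is the contrast
  between clamping the lag-1 outcome vector entering every channel to its
  best configuration (y1=0, y2=3, y3=3) versus its worst (1, 1, 1);
  same-cycle parents stay simulated.  An "interquartile shift" of a
  binary/ordinal outcome vector is not well defined, so the best/worst
  clamp is this package's interpretation of the improvement.

Posterior samples of the contrast include both parameter uncertainty
(across posterior draws) and outcome-simulation noise (finite replicates
per draw).  Note a structural property of this estimand: because each item
enters through an absolute value, posterior uncertainty inflates the
posterior-predictive mean of a category sum — a category of twelve mostly
null items accumulates twelve |noise| terms.  At a few hundred subjects
this inflation is visible (tens of percentage points for the dietary
category), and it shrinks as the posterior tightens.  Comparisons between
categories of similar size remain meaningful; comparisons across category
sizes should keep this bias in mind.

### Exact oracle

`exact_contrast` computes the same quantity without Monte Carlo by a
forward pass over the 2x3x3 joint outcome state space, propagating exact
state probabilities cycle by cycle (feasible for up to 5 subjects and 4
cycles).  It is written with independent scalar loops and serves as the
verification oracle for the simulator; the acceptance checks require
agreement within 3 Monte-Carlo standard errors, and a closed-form static
case (|logistic(0) - logistic(1)| = 0.23106) is reproduced exactly.

## Synthetic-data generator

The diary data the original analysis used are access-controlled, so the
generator produces panels with the statistical structure the model
assumes, under known ground-truth parameters:

* outcomes are drawn channel-by-channel in the within-cycle order with the
  exact likelihood kernels and lag alignment of the model;
* day-1 outcomes come from an approximately stationary marginal obtained
  by simulating ten discarded burn-in days per subject;
* the previous cycle's outcomes feed back into the current cycle's six
  stress items through a centered "badness" score (feedback coefficient
  0.3 by default; 0 disables it).  Feedback targets only stress — the most
  plausible recipient — while weather is physically exogenous and bedtime
  is kept exogenous for simplicity;
* one daily weather series is shared by all subjects (one study site), and
  subjects' 6-day diary windows start at calendar offsets staggered
  uniformly over 60 days, as when a field study enrolls participants over
  several weeks within a season.  Setting `stagger_days=0` gives everyone
  identical diary dates; identification of weather coefficients then rests
  on only a handful of distinct daily values and their posterior spreads
  widen accordingly;
* covariate marginals are plausible fixture choices on the scales the
  variable constructions produce (documented in
  `DEFAULT_COVARIATE_MODEL`), not estimates from the restricted data:
  4-point stress items, bedtime ~ N(0, 0.75) hours relative to midnight,
  caffeine Bernoulli(0.15) (rare enough to trigger the 0->1 override),
  lognormal food-group densities, and so on.  Default panel size is 400
  subjects per gender-by-season subsample, the order of the study's
  subsample sizes.

The ground-truth coefficient fixture (`default_true_params`) gives every
category at least one active item and at least one item that is null in
all channels, positive serial (AR) coefficients, and effect sizes
expressed per interquartile shift (0.2–0.4 on the logit scale for active
items) that put true category effects in the single-digit to high-teens
percentage-point range.  Intercepts and cutpoints are placed so daytime
sleepiness runs near a 30% base rate with non-degenerate ordinal splits.

What the generator does not emulate: subject-level random effects and
overdispersion, missing diary entries, measurement error in the FFQ-based
dietary densities, serial correlation in weather beyond the daily draws,
and real covariate dependence structures (e.g. stress–bedtime
correlation).  Passing tests therefore demonstrate internal correctness
and calibration of the method under its own assumptions, not robustness
to the ways real diary data violate them.

## Numerical and design choices

* Quantiles: linear interpolation (numpy default); quartiles computed
  within subsample, since each subsample is modeled separately.
* Missing data: complete-case by subject-day; a subject keeps only its
  maximal leading run of complete consecutive days.  The synthetic data
  contain no missingness.
* Bedtime sign convention: hours after midnight positive, so "later
  bedtime" is a larger value.
* Degenerate inputs: constant non-binary covariates are skipped with a
  warning and zero contribution; zero-probability observations make the
  log likelihood -inf with a warning; Hessians are ridge-repaired if a
  Cholesky factorization fails (it does not for these log-concave
  posteriors).
* Ordinal response family: cumulative (proportional-odds) logit — the
  standard choice for ordered three-level responses; the reference
  analysis does not print its family, and the module is structured so the
  family is swappable per channel.
* No subject-level random intercepts in the default model; whether the
  reference analysis used them is unknown.
* Determinism: every stochastic step threads a `numpy` Generator seeded
  from the run seed; identical configuration and seed reproduce
  byte-identical contrast tables end to end.

## Problem sizes used in the test-suite and acceptance runs

Oracle-agreement checks use 2 subjects x 3 cycles with 5000 replicates
(the enumeration oracle is exact there).  Parameter recovery uses 200
subjects x 6 cycles with 4 chains x (500 + 500) iterations.  Contrast
analyses in the tests thin the posterior to 25–60 draws with 8–20
replicates per draw; pipeline smoke runs use 15–25 subjects.  These sizes
were chosen to exercise every claim at comfortably interactive runtimes;
all scale linearly if increased.

## Known limitations

* Category effects inherit the absolute-value inflation discussed above.
* The contrast engine requires balanced panels (equal T per subject);
  unbalanced observed data would need masking support in the simulator.
* The AR(1) improvement magnitude is an interpretation (best/worst clamp).
* Joint interventions on several categories and interaction effects are
  out of scope by design.
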