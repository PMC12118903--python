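# Methods

`hdpsbench` benchmarks proxy-variable selection strategies for
inverse-probability-weighted (IPW) effect estimation in the
high-dimensional propensity score (hdPS) setting, using a plasmode
simulation built on a synthetic survey-like cohort.  This note records
the models, the parameters that matter, and the design choices that were
genuinely open.

## The estimation problem

A cohort contains a binary exposure `E`, a binary outcome `D`,
investigator-specified covariates (binary/categorical, always adjusted),
continuous laboratory variables, and a large block of binary proxy
("recurrence") covariates that act as surrogates for unmeasured
confounders.  The estimand is the average treatment effect, reported as
a risk difference (RD) and an odds ratio (OR).  Each selection strategy
chooses a proxy subset; the propensity score is then a maximum-likelihood
logistic regression of `E` on investigator covariates + labs + selected
proxies; subjects are weighted by the inverse probability of their
observed exposure status; and the ATE comes from weighted marginal
structural models (linear-probability for RD, logistic for OR) with
robust HC0 sandwich standard errors treating the weights as known.  The
sandwich uses squared weighted scores (weights enter squared); we verified
that statsmodels' `freq_weights` + HC0 instead treats weights as
frequencies, so the sandwich is computed directly.  With an estimated PS
this variance is conservative for the ATE, which shows up as mild
over-coverage in the oracle suite.

## Bross bias ranking

For proxy `C` with prevalence `P_C1` among exposed, `P_C0` among
unexposed, and unadjusted outcome relative risk `RR_CD`, the bias
multiplier is

    RR* = max(RR_CD, 1/RR_CD)
    B_m = (P_C1 (RR* − 1) + 1) / (P_C0 (RR* − 1) + 1)

and proxies are ranked by `|log10 B_m|` (direction-agnostic), top-100 by
default.  Zero cells in the outcome-by-proxy 2×2 table get a 0.5
continuity correction applied to all four cells, only when some cell is
empty.  Ties break lexicographically by proxy name.  A proxy constant in
the cohort is flagged and ranked last.

## Synthetic base cohort

Defaults emulate the reference analytic cohort: n = 7,585, exposure
prevalence 48.8%, outcome prevalence 23.7%, 142 proxies of which 94 are
confounder surrogates and 48 are noise, ~12 binary + ~4 categorical
investigator covariates, 6 labs.  One latent standard-normal health
factor `U` per subject induces the dependence structure:

* labs are linear in `U` (loadings 0.3–0.6) plus noise, on positive
  laboratory-like scales;
* binary investigator covariates are logistic in `U` (|coef| 0.2–0.5);
  categoricals cut a `U`-correlated score at empirical quantiles;
* each confounder proxy is Bernoulli with logit `a_j + b_j U`,
  `|b_j| ∈ [0.6, 1.0]` signed, intercept calibrated to a prevalence
  drawn from [0.05, 0.5]; noise proxies are independent Bernoulli;
* the base outcome is an exposure-free logistic model in `U`
  (coefficient 1.0), labs (0.1 per standardized lab), investigator
  covariates (|coef| 0.05–0.2), and small direct proxy effects
  (|coef| drawn from `proxy_effect_range`, default 0.05–0.15, sign
  matching the proxy's loading);
* exposure is logistic in the standardized confounder-proxy burden
  (coefficient 0.5) and the investigator covariates, intercept
  calibrated to the exposure target.

Two structural choices deserve explanation.  First, the marginal outcome
RR of a confounder proxy — the quantity the 0.8/1.2 filter sees — is
driven mainly by the shared latent factor rather than by the proxy's own
small coefficient.  Ninety-four proxies with individually large direct
effects would give the linear predictor a standard deviation above 3,
saturating the outcome probabilities and attenuating every marginal
association; shared-factor amplification is also how real comorbidity
indicators acquire their marginal associations.  The generator records
each proxy's model-implied marginal log-RR (averaging outcome
probabilities over subjects, i.e. free of outcome Bernoulli noise) as
the recovery-test truth.  Under the defaults the RR filter reproduces
the 94/48 split exactly, with zero set difference from the labels, on
every seed we tested.

Second, exposure depends on `U` only through the confounder-proxy
burden, so that `P(E = 1 | burden, investigator covariates)` is exactly
logistic.  The plasmode oracle analysis fits the propensity model on the
true outcome-model covariates; if exposure loaded on `U` or on the labs
directly, that model would be irreparably misspecified (the latent
factor is not a function of the design, and a linear lab effect is not
spanned by the transformed lab terms), and exploration showed a
persistent RD bias of about −0.007 (i.e. >2 Monte Carlo SEs at 200
replicates).  With the burden-driven exposure the oracle is correctly
specified: measured bias is below one MC SE and coverage is 95–97.5%.
Labs and the latent factor remain marginally associated with exposure
through the shared pathway.

Intercepts everywhere are calibrated by Brent root-finding on the mean
inverse-logit, tolerance 1e-4 on the prevalence scale.

### What the generator does not emulate

Survey design (strata, clusters, sampling weights), item missingness,
measurement error, time structure, and any real variable codebook.
Passing tests therefore show that the pipeline's logic is correct under
a known confounding structure — not that any method is superior on real
survey data.

## Plasmode engine

Covariates and exposure are resampled with replacement from the base
cohort, stratified on exposure so each replicate has exactly
`round(n·p_E)` exposed rows; this is how rare-exposure scenarios (5%)
are realized from a ~49%-prevalence base without altering any subject's
values.  The outcome is regenerated from

    logit P(D=1) = b0 + ln(OR_true)·E + investigator terms
                   + transformed-lab terms + 0.1·burden

with one term per transformation family (log, exp, sqrt, centered
square, pairwise interaction of standardized labs; log/sqrt operate on
the lab shifted by `1 − base minimum`, the exp argument is clipped at
±5).  Investigator coefficients are seeded draws, signs random,
magnitudes uniform in [0.1, 0.5]; lab-term coefficients in [0.1, 0.3];
all overridable.  The burden is the count of proxies passing the
outcome-RR filter on the base cohort.  `b0` is calibrated against base
subjects reweighted to the scenario's exposure mix, because the scenario
exposure prevalence (e.g. 30%) differs from the base one (48.8%) and the
replicate covariate distribution shifts accordingly; without the
reweighting the realized prevalence undershoots its target by about one
percentage point.  Replicate `r` draws all randomness from
`SeedSequence([scenario_seed, r])`, making (seed, r) → dataset a pure
function safe for any execution order.

The default scenario grid is 30%/30% (base), 5%/30% (rare exposure) and
30%/5% (rare outcome), true OR 1 (RD 0), n = 3,000, 500 iterations; a
reduced hyperparameter profile (`REDUCED_PROFILE`) is provided for smoke
runs.  For non-null true ORs the engine reports the model-implied
marginal true RD (counterfactual averaging over base covariates).

## Selection strategies

All supervised selectors model the outcome by default.  The stepwise
criterion (adjusted R² of an outcome model) and the proxy filter's
outcome orientation both point that way; the exposure-model variant is
available via `target="exposure"`.  Investigator covariates and labs are
forced: they condition every selector and are never selected or dropped.
Labs are standardized in penalized and GA models; binary proxies enter
as 0/1.

* LASSO / elastic net: penalized logistic paths with the forced block
  penalty-free.  No installed library offers per-feature penalty factors
  for logistic elastic nets at a usable speed, so the solver is a
  glmnet-style IRLS + cyclic coordinate descent with soft-thresholding
  (validated against scikit-learn's saga on shared objectives to 1e-6);
  lambda is chosen by 10-fold CV deviance on a 30-point log-spaced path,
  the elastic-net mixing on the grid {0.1, …, 0.9}.  Selected = proxies
  with exactly nonzero coefficients at the CV optimum.
* Hybrid: LASSO restricted to the Bross top-100; by construction its
  selection is a subset of the Bross set (agreement rate 1.0).
* Random forest: 500 trees, Gini importance, top-100 proxies.
* XGBoost: depth 3, 200 rounds, learning rate 0.1; selected = proxies
  with strictly positive gain, so the count is data-dependent.
* Forward / backward stepwise: greedy adjusted-R² moves on a
  linear-probability model, computed in Gram form (O(1) in n per
  candidate after one pass); strict improvement required, ties keep the
  lexicographically first proxy; backward requires n > p at the start.
* Genetic algorithm: binary chromosomes over proxies; fitness = seeded
  5-fold CV accuracy of an unpenalized logistic model on forced
  covariates + active proxies, memoized per chromosome; tournament size
  3, uniform crossover 0.8, bit-flip mutation 1/n_proxies, elitism 1,
  population 50, 40 generations.  Implemented in-package (~60 lines);
  defaults follow common GA practice since no canonical values exist.

## Performance measures

Per (method, scenario): bias, empirical SE (SD across replicates, R−1
denominator), average model SE (arithmetic mean of reported SEs —
deliberately the plain mean, not a root-mean-variance), relative error
in SE = 100·(avgSE/empSE − 1), MSE, 95% CI coverage, bias-eliminated
coverage (CIs evaluated at the mean estimate), each with the standard
Monte Carlo SE.  The identity `MSE = bias² + ((R−1)/R)·empSE²` holds to
machine precision with these denominators and is enforced by test.
Metrics default to the RD scale (the null design's truth is RD = 0);
log-OR-scale metrics are available by passing explicit columns.  The
zip-plot table gives each replicate's standardized error, |z| centile
and coverer flag.

## Numerical choices and degenerate inputs

* Logistic MLE fits use lbfgs with tolerance 1e-8; non-convergence or
  fitted probabilities at the 1e-12 boundary raise an estimation error,
  and the study runner records the (method, scenario, replicate) failure
  and continues.
* Weight truncation is off by default (percentile clipping available).
* Constant proxies: flagged, rank score 0, classified noise.
* Degenerate outcome: penalized selectors raise; XGBoost returns an
  empty selection (no split can reduce impurity).
* CSV round trips rely on pandas' shortest-round-trip float formatting;
  categorical expansion is reference-cell with the lexicographically
  first level as reference, so model matrices are deterministic.
* Complete-case handling on load, with the dropped-row count logged.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the oracle-calibration
suite at 200 replicates of n = 3,000, the prevalence-calibration check
at 100 replicates, the RR-filter recovery over 20 generator seeds, and
the selector-recovery suites over 20 seeded runs of n = 2,000 toys; the
full 500-iteration, all-method grid is available through
`run_simulation_study` / `hdpsbench run-study`.

## Known limitations

* The plasmode true model is conditional; the reported true RD for
  non-null ORs is model-implied by counterfactual averaging.
* Sandwich SEs ignore PS estimation; expect mild over-coverage for
  well-specified models (visible in the oracle suite).
* The GA is the slowest method by an order of magnitude at full budget,
  consistent with its reputation.
* Elastic-net CV over the full mixing grid on the full cohort is
  minutes, not seconds; the reduced profile trades grid resolution for
  speed.
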