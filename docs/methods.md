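# Methods

## The problem

Longitudinal cohorts lose participants. When the probability of permanent
dropout (attrition) depends on the value of the outcome that would have
been measured — lower cognitive function making continued participation
less likely — the missingness is *informative* (MNAR) and analyses that
assume ignorability can be biased. `attrisim` rebuilds, as a tested
pipeline, a Monte-Carlo comparison of three analyses of such data:

1. **Available cases (AC)** — fit the substantive linear mixed model to
   every record with an observed outcome and observed baseline covariates,
   letting the random-effects structure borrow strength across phases;
2. **Multiple imputation (MI)** — impute with the two-fold
   fully-conditional-specification (FCS) algorithm, fit the model to each
   completed panel, pool with Rubin's rules;
3. **Pattern-mixture delta adjustment (PMM)** — shift the MI-imputed
   outcome values that are missing for the non-ignorable reason by a fixed
   offset `k` before fitting, encoding an assumed departure from
   ignorability.

## Substantive model

For participant *i* at analysis phase *t* (time in decades since
baseline):

Y_it = β0 + β1·X_i + β2·t·X_i + b0_i + b1_i·t + ε_it

where X_i collects the baseline (phase-5) values of smoking status
(never/ex/current), age band (5 levels), occupational grade (3) and
education (3), each entering as dummy main effects and dummy×time
interactions; (b0_i, b1_i) is a correlated Gaussian random
intercept/slope pair and ε_it is i.i.d. Gaussian. Estimation is REML.
The quantity of interest is the adjusted 10-year decline: the reference
slope β2(time) and, per category, reference + contrast.

The default fit engine is an exact profiled REML written for this design:
participants fall into a handful of observation patterns over the five
phases, so per-pattern sufficient statistics are accumulated once and each
REML objective evaluation is O(patterns), independent of cohort size.
`statsmodels.MixedLM` is retained as an alternative engine and as a
cross-check in the tests (fixed effects agree to ~1e-13 on shared data);
the profiled engine falls back to it on optimizer failure. A degenerate
zero-residual panel (e.g. a constant outcome) short-circuits to the exact
least-squares solution, since REML is unbounded there.

Full-data and available-case confidence intervals use normal quantiles
(cohorts are large); MI/PMM intervals use t quantiles with the classic
Rubin degrees of freedom ν = (M−1)(1 + W/((1+1/M)B))². The
Barnard–Rubin small-sample correction was considered and not enabled: at
these cohort sizes it is indistinguishable.

## Synthetic cohorts

The generator emulates a 10,000-man, five-phase occupational cohort
(phases labelled 3, 5, 7, 9, 11; time −0.5, 0, 0.5, 1.0, 1.5 decades, so
phase 5 is the analysis baseline and phases 5→9 span one decade).

* **Covariates** come from a latent Gaussian copula thresholded at the
  marginal quantiles. Latent pairwise correlations are calibrated by
  root-finding so the *coded* (ordinal 1..K) Pearson correlations hit the
  published pairwise values (e.g. grade–education −0.3666). The published
  marginals are used directly (age bands 24.2/29.7/20.1/19.0/7.1%, grade
  58.1/38.8/3.1%, education 5.6/46.8/47.7%).
* **Smoking** is an absorbing current→ex chain: never-smokers (49.4%) are
  fixed for life, no initiation, no relapse. Per-interval quit
  probabilities reproduce the current-smoker decline 7.2→6.2→5.0% over
  the analysis phases; the first-interval and last-interval values (0.100,
  0.210) continue the same trend and are exposed in the configuration.
* **Main effects** are linear in the ordinal codes, solved from a small
  linear system so that the phase-5 covariate–outcome correlations match
  their published values; the intercept sets the phase-5 mean (0.00 for
  the global score, 0.05 for memory). Slope contrasts are fixed at the
  published per-category adjusted declines (reference + contrast reading),
  e.g. global reference −0.3120.
* **Variance components** (σ_b0, σ_b1, ρ, σ_ε) are solved by
  least-squares root-finding so the closed-form marginal covariance —
  between-person fixed-effect covariance plus the random-effect quadratic
  plus residual — reproduces the phase-5 SD (0.78 global / 0.71 memory)
  and the three analysis-phase lag correlations (~0.97 global / ~0.44-0.45
  memory). The memory correlation triplet is marginally infeasible for a
  proper random-intercept/slope model (the exact solution needs a slightly
  negative slope variance), so the memory defaults accept the nearest
  feasible point (correlation residuals < 1e-3); the global targets are
  met to 1e-4.

The two outcome regimes ("global": highly correlated repeated measures;
"memory": moderately correlated) share one code path and differ only in
targets and truth slopes.

A consequence worth stating: with the published per-category declines and
the published covariate distribution, the implied population mean decline
between phases 5 and 9 is 0.404 SD (global) and 0.304 SD (memory). The
published narrative rounds these to 0.42 and 0.26; the 0.26 in particular
is inconsistent with the published phase means (0.05 and −0.26, a 0.31
difference). The generator follows the tables; the acceptance checks
against the narrative values therefore sit slightly off for the declines.

## Participation and missingness

Statuses: response, non-response, death, attrition. Phases 3 and 5 admit
only response/non-response (phase 5 stratified by the phase-3 status);
phases 7/9/11 admit all four, stratified by the previous
response/non-response status, with death and attrition absorbing.

Non-response and death probabilities are multinomial-logistic in the
ordinal covariate codes (modest default log-odds; age strongly predicts
death). Intercepts are calibrated per phase and stratum by root-finding
so the realized marginals reproduce the published census: response
87.1/78.4/75.5% at phases 5/7/9; cumulative attrition 4.3% then 6.0%;
cumulative death 2.4% then 5.6%. Non-response is strongly persistent
(chronic non-responders), which the census requires. Phase-11 rates are
not published and continue the phase-9 conditional rates.

Attrition is drawn as a separate Bernoulli overlay, covariate-flat under
the ignorable default, so that the informative mechanism

logit(p_ij) = λ0_j + λ1·Y_ij

nests it exactly at λ1 = 0. Calibration is nested root-finding on a
frozen ignorably-assigned cohort: the inner loop solves each phase's λ0
so the expected attrition mass is preserved; the outer loop solves λ1 so
the probability-weighted mean outcome of attriters sits 0.5 SD below the
ignorable mechanism's (matching the delta offset k = −0.5 used by the
pattern-mixture adjustment). Achieved tolerances: rate to <0.1 pp, shift
to <0.02 (in practice ~1e-10; realized draws deviate only by Monte-Carlo
noise).

Blanking: under the default `smoking_missing` mechanism, outcome and
smoking are blanked at non-response/death/attrition phases, plus a small
age-dependent item non-response among responders (default rate 0.002);
under `education_missing`, the outcome blanks per status, baseline
education blanks for an age-dependent ~10% of participants, and the
status models condition on baseline smoking instead of education.
The non-ignorable flag R marks attrition phases (optionally plus
non-response under the sensitivity variant) and is the set to which the
PMM offset applies.

The published aggregate "≈22% of participants with any missing value" is
not attainable as a phases-5–9 union under the published census (response
marginals alone bound it below by 24.5%); the engine yields ≈28–29% and
reports it honestly. The published 22% is consistent with a per-phase
cross-section (14.9 + 2.4 + 4.3 ≈ 21.6% at phase 7).

## Two-fold FCS imputation

Per imputation *m*: initialize every missing cell from the observed
per-phase marginal; then for each of `b_A` among-time iterations sweep
phases in time order, running `b_W` within-time FCS cycles at each phase.
A within-time cycle imputes each incomplete variable at phase *t* from a
univariate model conditioning on the other analysis variables at *t*, the
outcome at the adjacent phases (window 1), the time-independent
covariates, and baseline smoking in place of any other smoking terms
(repeated smoking correlates ~0.95 and destabilizes the categorical
models). Observed values are never modified. Defaults M=20, b_W=5,
b_A=20 follow the reference configuration; scaled studies in the tests
use smaller chains.

Continuous targets use proper imputation: σ² drawn from the scaled
inverse-χ², β from its Gaussian given σ², then value = linear predictor
+ Gaussian noise. Categorical targets fit a multinomial logit on
completers (newton-cg, a tiny ridge C=1e4 purely for numerical stability)
and draw the category from the predicted probabilities. Degeneracy
ladder: indicator columns with <3 positive completers are dropped (the
sparse category merges into the reference); on failure the adjacent-phase
predictors are dropped; last resort is a marginal draw. Every fallback is
logged. Education (time-independent) is imputed within the phase-5 block.

The pattern-mixture step adds exactly `k` (default −0.5) to imputed
outcome values flagged R=1 and touches nothing else.

## Evaluation

Across replicates, per coefficient and method: bias = mean(θ̂)−θ;
empirical variance (denominator M−1); MSE = variance + bias² (an exact
identity, asserted); % bias = 100·bias/|θ|; MSE ratio vs the AC analysis;
coverage = fraction of 95% intervals containing θ (t quantiles when a
Rubin df is present, normal otherwise). Correlation diagnostics compute
Pearson matrices over outcome and smoking at the analysis phases plus the
coded covariates, per data state (full / blanked pairwise-complete / MI /
PMM, the latter two averaged over imputations), and differences against
the full state.

## Problem sizes used in the checks

The reference experiment (1,000 replicates × 10,000 participants × M=20)
is far beyond a desk run for the MI arms. The test suite therefore uses,
as its own design choice: 20 cohorts of n=10,000 for census and
missingness aggregates (no MI); 200 (global) and 100 (memory) full-data
replicates at n=2,000 for truth recovery and coverage; and paired
replicate studies at n=1,000 with M=5, b_W=2, b_A=5 (48 memory / 20
global replicates, sized for ~95% power from a pilot of the paired-bias
dispersion) for the qualitative bias orderings. Ordering bias is measured
within-cohort (method estimate minus the same cohort's full-data
estimate), which removes the shared cohort-sampling noise; the full-data
estimator's own unbiasedness is verified separately. At these scales the
absolute biases are larger than in the reference experiment (less
information per cohort and shorter chains), but their ordering — the
claim under test — is preserved and, if anything, sharpened.

## What the generator does not emulate

Individual cognitive tests and their z-score averaging (outcomes are
generated directly at composite level); sex stratification (males only);
cause-specific mortality; real-data quirks such as practice effects,
measurement-error dependence of dropout, or auxiliary variables. Passing
tests therefore demonstrate correctness of the pipeline under the stated
generative model, not robustness of PMM on any particular real cohort.

## Known limitations

* Deceased participants' outcomes are imputed like other missing values;
  whether the reference analysis excluded them is unstated there, and
  death-aware imputation is out of scope.
* The two-fold FCS algorithm conditions on neither random effects nor
  future information beyond the adjacent window; its known tendency to
  overstate random-slope variance is not investigated here.
* `k` is a single constant; distributional or pattern-specific offsets
  are not implemented.
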