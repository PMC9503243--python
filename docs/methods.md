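# Methods

## The model

`dbnsurv` treats right-censored survival data as a discrete-time stochastic
process on a *slice grid*: one slice per unique observed event time, slice
*j* spanning the half-open interval `[t_j, t_{j+1})` (the last slice is
unbounded).  Each subject *i* carries two binary state trajectories:

* `N[i,t] = 1` while the subject is known to be alive at slice *t*
  (failure is absorbing),
* `Q[i,t] = 1` once the subject has been censored at or before slice *t*
  (censoring is absorbing).

These states, together with time-stationary discrete covariates
`Z = (Z_1, …, Z_q)`, form a two-slice temporal Bayesian network (2-TBN):
a prior network over the slice-1 variables and covariates, and per-slice
transition models in which a slice-*t* state may depend only on the two
slice-(t−1) states and on covariates (Markov order 1).

The survival estimator is the product of conditional survival factors

    S(t | z) = P(N1 = 1 | Z_par(N1) = z)
               × ∏_{u=2..t} P(Nu = 1 | N_{u−1} = 1, Q_{u−1} = 0, Z_par(Nu) = z),

where each factor conditions only on the covariates selected (by structure
learning) as parents of that slice's `N` node.  With no covariate parents,
every factor is the empirical per-interval survival fraction
`(Y_u − d_u)/Y_u` of the at-risk set, and the product is the Kaplan–Meier
product-limit estimator term for term.  The package computes both through
the same float expression, so the equality is bit-exact, and the Greenwood
formula `V(t) = S(t)² Σ d_u / (Y_u (Y_u − d_u))` applies unchanged in the
covariate-free case.  Population-level ("marginal") curves mix
profile-conditional curves over the *empirical joint* covariate
distribution, not a product of marginals, preserving covariate dependence.

### Interval conventions

The conventions are the unique set under which the network estimator
reproduces Kaplan–Meier exactly (this is enforced by tests, not assumed):

* an event at a slice time turns `N` off at that slice;
* a censoring time inside slice *j* (including exactly `t_j`) sets
  `Q[i,j] = 1`, so the subject still counts in the slice-*j* risk set —
  the standard events-before-censorings tie rule;
* a subject censored strictly before the first event time is flagged
  `pre_censored`; it contributes `Q` from slice 1 onward but is excluded
  from the slice-1 risk set, exactly as in classic KM accounting.  The
  slice-1 survival probability is therefore estimated on the slice-1 risk
  set, not the whole cohort.

### Parameter learning

All conditional probability tables are maximum-likelihood (empirical
conditional frequencies).  Transition rows for the non-at-risk parent
configurations are deterministic by the absorbing dynamics (failed stays
failed, censored stays censored).  At-risk rows with zero support are
filled uniformly and flagged; when such a flagged row is hit during
estimation the factor falls back to the pooled (covariate-free) per-slice
probability, and the event is logged.  An optional Dirichlet pseudo-count
is available but defaults to 0 because any smoothing breaks the exact KM
equivalence; the hold-out validator is the one component that uses
pseudo-count 0.5 by default, so that held-out evidence never has
probability exactly zero under a trained network.

### Structure learning

Score-based search over the *unrolled* panel (one column per covariate and
per state node).  Scores: multinomial log-likelihood, AIC
(`loglik − k`), BIC (`loglik − (k/2) ln n`, `k = (r−1)·∏ parent
cardinalities`), BDeu with configurable imaginary sample size (default 1),
BDs (imaginary mass spread only over parent configurations observed in the
data), and K2 (Cooper–Herskovits); all in log space via log-gamma.
Hill-climbing and tabu search use the canonical add/delete/reverse move
set with family-score caching; ties between equal-score moves break
lexicographically by (child, parent, move-type), so searches replay
deterministically.  The tabu list keeps the undo moves of the last
`tabu_length` (default 10) accepted moves; up to 100 consecutive
non-improving moves are allowed and the best structure visited is
returned.

For survival networks the temporal topology is enforced by constraints:
the N/Q chain (both slice-(t−1) states parenting both slice-t states) is
whitelisted, and everything except covariate→covariate and
covariate→state edges is blacklisted — no edges out of state nodes, no
within-slice state edges, no links between non-adjacent slices, no
future→past edges.

### Inference and validation

Posterior queries use likelihood weighting (importance sampling with
evidence nodes clamped and weighted by their conditional probabilities),
vectorized over samples.  Validation is repeated hold-out: by default ten
repetitions each holding out 30% of subjects, re-learning structure *and*
parameters on the complement, then predicting every state node of every
held-out subject from all its other observed variables (a covariates-only
evidence mode is available).  The loss is the posterior classification
error — the fraction of maximum-posterior predictions that are wrong.
When classifying node *v* under full evidence, only the weight factors of
*v*'s children vary across samples; the implementation skips the constant
factors, which leaves the normalized posterior unchanged and keeps the
validator fast.

## The simulation benchmark

Each replicate draws five independent Bernoulli covariates with success
probabilities (0.1, 0.2, 0.5, 0.7, 0.9); survival times are Weibull with
shape `α_S ∈ {0.5, 1, 2}` and scale `θ_S = ΣX ∈ {0,…,5}` (the `ΣX = 0`
atom, probability ≈ 0.00108, yields an event at time 0 — a config flag can
resample instead); censoring times are Weibull with shape `α_C` and a
single scale `θ_C` calibrated by deterministic quadrature plus bracketing
root search so that `P(C < S)` equals the target censoring rate
(tolerance 1e−6, covariate mixture integrated exactly).  True marginal
survival mixes the 32 covariate patterns; percentile times invert it by
root search (tolerance 1e−8).

Three estimators are compared: Kaplan–Meier; Cox proportional hazards
(lifelines, partial likelihood with Breslow baseline), whose marginal
prediction averages the per-subject predicted curves (the mean-covariate
curve is a config alternative); and the dynamic-network estimator, which
places slices at the unique event times, forces the N/Q chain, and selects
covariate parents for each slice's survival node by greedy forward BIC
search.  That greedy selection is exactly equivalent to constrained
hill-climbing here because the score decomposes by family and the
structural blacklist removes all cycle interactions (a test asserts the
equivalence against the generic search); an exact log-likelihood bound
skips slices where no covariate split could overcome the BIC penalty.
Censor-state parents are not selected inside the simulation loop since
they cannot change the survival estimate; the general pipeline learns
them.

**Evaluation protocol.**  Each replicate is evaluated at the empirical
20/50/80% percentiles of its *own* simulated uncensored survival times, so
the true survival probability at each evaluation point is 0.8/0.5/0.2 by
construction.  Coupling the evaluation times to the sample cancels the
binomial sampling noise an estimator would show at a fixed time (without
censoring the KM estimate at the sample percentile is exactly `1 − p`),
so bias and RMSE isolate the effect of censoring and model
misspecification.  A `population` mode (fixed theoretical percentiles) is
available in config.  Bias is `mean(estimate − truth)`, RMSE is the root
mean squared deviation, and the Monte-Carlo SE of the bias is reported per
cell.  Replicates are seeded from (master seed, replicate index), so
results are independent of execution order.

Known behavior worth flagging: in heavily censored scenarios with
light-tailed censoring (e.g. `α_S = 0.5`, `α_C = 2`, rate 60%) the
calibrated censoring scale truncates the entire observation window far
below the 80% percentile of true survival time; no estimator has data
near the evaluation point and all of them carry their last value, giving
a large positive bias there.  This is a property of the generating
process, not of any estimator.

Problem sizes used by the test suite: benchmark cells run at 300
replicates and the qualitative pattern checks at 200 (the reported
tolerances include 3× or 1× the Monte-Carlo SE, which absorbs the extra
noise); the acceptance script runs its scenario at the full 1000
replicates.

## The synthetic cohort fixture

`fixtures.generate_fixture` emulates a post-gastrectomy gastric-cancer
cohort: 760 subjects, whole-year follow-up with 14 event years (no event
in year 13, horizon censoring at year 16), and eight discrete covariates
(sex, age group, tumour site, smoking, pathology, metastasis, surgery
type, stage) whose marginals match the descriptive statistics of such a
cohort and whose dependencies (sex→smoking, smoking→metastasis,
metastasis→stage, sex→pathology, site→surgery) are sampled ancestrally.
Survival dynamics: a large age-dependent death hazard in year 1
(0.12/0.25/0.45 by age group), a small age effect in year 2, a metastasis
effect in year 4, and a flat 6% baseline hazard elsewhere; censoring is a
flat 2% per year with pathology effects in years 3 and 5 and age effects
in years 6 and 7.  All effect sizes are synthetic calibrations chosen once
so that (a) covariate effects are strong enough for structure recovery to
have a known ground truth and (b) adjacent-slice event masses stay below
~4% of the cohort, which keeps every state node predictable to better
than 95% accuracy under full-evidence classification.  The generator does
**not** reproduce any real patient data, and passing validation on it
shows that the pipeline recovers planted structure under these
conditions — not that real cohorts are equally predictable.

## Numerical choices and limitations

* Level order in CPTs is the declared domain order (sorted labels when
  inferred); ties in posterior classification resolve to the first level.
* Scores of empty parent configurations contribute nothing to the
  log-likelihood (`0·log 0 ≡ 0`).
* Greenwood variance is NaN from the first slice where `Y = d` with the
  curve still positive (undefined sum), and 0 where the curve itself is 0.
* Interval-censored or left-truncated data, time-varying covariates,
  competing risks, k-fold cross-validation, logic sampling and bootstrap
  variance alternatives are out of scope.
* The mixture variance of a covariate-adjusted marginal curve is not
  reported (NaN): Greenwood is exact only within a profile, and a
  principled combined variance would need a different derivation.
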