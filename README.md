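# dbnsurv

Dynamic Bayesian-network survival analysis: a two-slice temporal Bayesian
network (2-TBN) that generalizes the Kaplan–Meier product-limit estimator
to covariate-aware, graphically interpretable survival estimation — for
biostatisticians and epidemiologists who want nonparametric survival
curves *and* data-driven covariate structure in one model.

## The idea

Partition follow-up time into slices at the unique observed event times
and give each subject two binary state chains: `N_t = 1` while alive at
slice *t* (failure absorbing) and `Q_t = 1` once censored by slice *t*
(censoring absorbing).  With time-stationary discrete covariates
`Z = (Z_1, …, Z_q)` these form a 2-TBN — a prior network `M1` over the
slice-1 variables and a transition network `M→` in which slice-*t* states
depend only on slice-(t−1) states and covariates.  The survival estimator
is

    Ŝ(t | z) = P(N_1 = 1 | Z) · ∏_{u=2}^{t} P(N_u = 1 | N_{u−1} = 1, Q_{u−1} = 0, Z),

each factor conditioning only on the covariates that structure learning
selected as parents of that slice's `N` node.  With no covariate parents
every factor is the at-risk survival fraction `(Y_u − d_u)/Y_u`, so the
estimator **equals Kaplan–Meier exactly** (bit-for-bit in this package)
and the Greenwood variance `Ŝ(t)² Σ d_u/(Y_u(Y_u − d_u))` applies
unchanged.

The package provides: state encoding from delimited survival tables;
discrete BN/CPT machinery; six decomposable scores (log-likelihood, AIC,
BIC, BDe, BDs, K2); constrained hill-climbing and tabu structure search;
maximum-likelihood parameter fitting; survival estimation with covariate
conditioning and empirical-mixture marginalization; likelihood-weighting
inference with repeated hold-out validation; a Weibull simulation
benchmark against Kaplan–Meier and Cox PH; and a synthetic gastrectomy-like
cohort generator.  See `docs/methods.md` for the full model account.

## Worked example

```python
from dbnsurv import dbn_survival, evaluate_at
from dbnsurv.fixtures import FixtureSpec, fixture_frame, run_pipeline

cohort = fixture_frame(FixtureSpec(seed=42))      # 760 synthetic subjects
bundle = run_pipeline(cohort, algorithm="tabu", score_name="bde", seed=0)

dag = bundle["dag"]
print(sorted(e for e in dag.edges if not e[0].startswith(("N@", "Q@"))))
# [('age', 'N@1'), ('pathology', 'N@3'), ('smoking', 'Q@8'),
#  ('smoking', 'sex'), ('stage', 'metastasis'), ('surgery', 'site')]

km, marg = bundle["km_curve"], bundle["marginal_curve"]
# year 1: KM 0.7329 (var 0.00026), DBN marginal 0.7329
# year 5: KM 0.5927 (var 0.00032), DBN marginal 0.5931

old = dbn_survival(bundle["tbn"], {"age": ">70", "pathology": "Adeno"})
young = dbn_survival(bundle["tbn"], {"age": "<61", "pathology": "Adeno"})
print(evaluate_at(old, 1), evaluate_at(young, 1))   # 0.5405 vs 0.8901
```

The learned covariate→state edge `age → N@1` is the planted ground truth
of the generator (baseline age shifts the year-1 death hazard), and the
covariate↔covariate edges recover the planted dependency structure up to
Markov-equivalent edge reversals.  The one-year survival split by age
(0.54 vs 0.89) reflects the planted hazards; the marginal network curve
tracks Kaplan–Meier to three decimals because only two slices carry
covariate effects.

A CLI mirrors the library: `dbnsurv fit|simulate|validate|fixture --help`.

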