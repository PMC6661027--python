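# Methods

## The screening algorithm

The AGS/BGS fall-prevention guidelines describe a yearly screening of all
community-dwelling adults aged 65+ that stratifies each person as at high
or low risk of falling. `fallscreen` implements the screening flowchart as
a deterministic classifier:

1. Ask about falls in the previous 12 months and about difficulty walking
   across a small room (annotation B).
2. Two or more prior falls (annotation D): **high risk**, referred directly
   to the multifactorial fall-risk assessment (annotation C) without any
   functional testing.
3. One prior fall, or walking difficulty: evaluate gait and balance with a
   functional test (annotation E). An abnormal result is high risk, a
   normal one low risk.
4. No falls and no difficulty: **low risk**.

The branch for patients presenting with an acute fall is not modelled.
Three functional tests are supported, each with the direction conventional
for it: Timed Up and Go (abnormal when strictly *above* the cutoff,
default 13.5 s), SPPB (strictly *below*, default 9) and comfortable gait
speed (strictly *below*, default 0.8 m/s). Abnormality is a strict
inequality, so a value exactly at the cutoff is normal. A consequence
worth making explicit: an infinite cutoff decides the comparison for any
real measurement, so the two "extreme assignments" (every assessed person
normal, every assessed person abnormal) are well defined even for records
whose test value is missing, and they are identical whichever functional
test is configured — only the routing, which does not involve the test,
matters. These are the endpoints of every ROC sweep.

Missing data make a risk class *indeterminate* when a required datum is
absent: unknown prior-fall history; no falls but unknown difficulty; or a
required functional test without a usable result. A person with exactly
one prior fall is routed to assessment even if their difficulty answer is
missing, since the single fall suffices to trigger the evaluation. Under
the default policy indeterminate is reported as its own class (so
high + low + indeterminate = 1); the `exclude` policy instead renormalizes
summaries over the determinate subset.

## Direct age–sex standardization

Crude cohort fractions reflect the cohort's age–sex composition, which for
an oversampled-very-old cohort is far from the national population of
older adults. Every reported population fraction is therefore directly
standardized: records are assigned to joint age-band × sex strata
(default bands 65–69, …, 85–89, 90+), the indicator's mean is taken within
each stratum, and stratum means are combined with reference-population
weights. Strata with no cohort members are dropped and the remaining
weights renormalized (logged), so fractions over a partition of the
population still sum to one. Standardization is joint over age × sex, not
marginal. The screening-versus-outcome cross-classification is
standardized the same way, class by class, giving population fractions
TP, FP, FN, TN plus a standardized indeterminate fraction; TP + FN is the
standardized prevalence of falling and does not depend on the classifier.

Predictive accuracy is computed from these standardized fractions after
renormalizing over the determinate mass: Se = TP/(TP+FN), Sp = TN/(TN+FP),
PPV, NPV, and Acc = (TP+TN)/determinate. Ratios with a zero denominator
are reported as undefined (`None`), never coerced to 0. Two outcome
definitions are available: at least one prospective fall (`ge1`, the
headline definition) and at least two (`ge2`).

## The impact model

Co is the fraction of the population referred to the multifactorial
assessment and intervention (service size/cost); F is the fraction of the
population falling at least once in the following year (effectiveness).
The intervention multiplies an individual's probability of being a faller
by a relative risk RR (default 0.78, 95% CI 0.64–0.94), assumed equal
across risk strata. Four policies:

| policy                 | Co      | F                        |
|------------------------|---------|--------------------------|
| screening (treat high) | TP + FP | RR·TP + FN               |
| none                   | 0       | TP + FN                  |
| everyone               | 1       | RR·(TP + FN)             |
| random coverage c      | c       | (TP + FN)(1 − c + c·RR)  |

Derived comparisons: the *parity coverage* is the c at which the random
policy matches screening's F, found by root bracketing on [0, 1]
(tolerance 1e-13) on the two formulas — algebraically it equals Se, an
identity the tests verify against the numerical solution rather than
assume; the *delta fallers* is F_random(Co_screening) − F_screening, the
extra fallers a risk-blind policy of equal coverage would leave; and the
*relative reduction* 1 − F_screening/F_none equals Se·(1 − RR), again
checked, not hard-coded. Screening beats the equal-coverage random policy
exactly when PPV exceeds the population prevalence.

## The synthetic cohort generator

No individual-level data are distributed with the package; the generator
emulates the structure of the template cohort (a community sample of 438
adults 65+, with the very old oversampled) so every downstream stage runs
end-to-end. Defaults are the template's crude descriptive statistics: age
82.4 ± 6.5 y (truncated at 65), 60.7% women, prior falls 73.1/16.9/10.0%
(0/1/2+), walking difficulty 22.8%, TUG 12.2 ± 5.5 s, SPPB 8.1 ± 3.6,
gait speed 1.08 ± 0.30 m/s, prospective falls 80.1/12.1/7.8%, and
item-level missingness equal to the template's NA counts (TUG 164/438,
SPPB 124/438, gait speed 171/438, prior falls 7/438), applied completely
at random per variable.

All dependence flows through one standard-normal latent frailty factor:

- Age and frailty share a Gaussian copula (age is the truncated-normal
  inverse CDF of a uniform whose normal score is correlated with frailty,
  coupling 0.4), so frailty stays exactly N(0, 1).
- Prior falls and walking difficulty are produced by thresholding latents
  correlated with frailty (loadings 0.5), which preserves their category
  probabilities exactly at any coupling strength.
- Functional tests are Gaussian in the frailty latent with loadings
  (TUG +0.55, SPPB −0.6, speed −0.6) *inside* the total variance, then
  floored (TUG at 0.1 s, speed at 0) or rounded and clipped (SPPB to
  0–12).
- Prospective falls are Poisson with log-rate log λ0 + b·frailty. The
  pair (λ0, b) is exactly identified by P(0 falls) and P(1 fall); the
  defaults are solved at import time by Gauss–Hermite quadrature and root
  finding (λ0 ≈ 0.0912 falls/yr, b ≈ 1.807), reproducing 80.1/12.1/7.8%.

Truncation, flooring and rounding would bias delivered moments away from
the nominal parameters (for TUG the sd shrinks by ≈0.07 s, several Monte
Carlo standard errors at n = 100 000). The generator therefore solves for
the latent location/scale such that the *delivered* marginal has exactly
the nominal mean and sd — a two-equation moment match per variable,
cached. Consequently every marginal parameter is recovered from a large
generated cohort within Monte Carlo error, which is what the fidelity
tests assert.

The latent loadings themselves cannot be calibrated to the template,
which reports only marginals; they are fixed at values giving a screener
of plausible informativeness (PPV > prevalence, TUG–fall association of
the right sign). Passing tests therefore show that the *pipeline* behaves
correctly on cohorts with this single-factor dependence; they do not show
that any real cohort's joint distribution is single-factor, nor reproduce
cohort-specific point estimates, which require the original data.
Reference weights default to a truncated-Gaussian age pyramid with the
standardized-population parameters (75.9 ± 7.6 y, 56.8% women), so
standardization is exercised non-trivially against the older, more female
crude cohort.

## Uncertainty

Confidence intervals are nonparametric percentile bootstrap over
participants (default 2000 replicates, 95% level), reproducible from a
seed. The construction behind the published intervals is not documented;
the percentile bootstrap is the conventional choice for standardized
fractions and their smooth functions. Replicates where a statistic is
undefined (e.g. an empty determinate subset in a small resample) are
dropped with a logged count; more than 20% dropped aborts with advice to
use a larger cohort. Uncertainty in the intervention effect can be
propagated on request by drawing RR per replicate from a log-normal
matched to (0.64, 0.94) as a central 95% interval around 0.78; it is off
by default because it is unclear whether the published F intervals include
it. Both modes are available; neither is asserted as the original choice.

## Numerical and testing choices

- Cohorts are DataFrame-backed; screening and standardization are
  vectorized, with a scalar per-record flowchart kept as the reference
  implementation and a property test pinning the two together.
- CSV round-trips are bit-exact: floats are written with `repr` (shortest
  exact form), missing values as empty cells, booleans as 0/1.
- Test problem sizes: marginal fidelity at n = 100 000; bootstrap coverage
  with 500 cohorts of n = 400 and 1000 replicates each (the ideal-bootstrap
  coverage at these sizes is ≈0.948, computable exactly from binomial
  quantiles); structural identities over 1000 random confusion matrices to
  1e-10; standardization against brute-force per-person enumeration to
  1e-12 on cohorts of ≤50.
- Known limitations: single-factor dependence only; missingness is MCAR
  while real missingness is likely frailty-related; the fall process has
  no within-year timing; RR acts uniformly across strata; no AUC or
  smoothed ROC (none are needed for the reported comparisons).
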