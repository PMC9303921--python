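# Methods

## The problem

In a sequentially randomized two-arm trial, prognostic baseline covariates
can drift out of balance by chance, clouding the interpretation of the
treatment effect. Covariate-adaptive randomization counteracts this, but
most schemes interfere with every allocation. Minimal-sufficient-balance
(MSB) methods interfere only when the accumulated imbalance is
statistically convincing, preserving as much allocation randomness as
possible. This package implements two such randomizers and the simulation
machinery needed to configure and compare them:

* **classic MSB** — each covariate is tested with a conventional statistic
  (Student's *t* for numeric covariates, Pearson's χ² — or Fisher's exact
  test on sparse 2×2 tables — for categorical ones, a WMW-odds *z*-test
  for ordinal ones). Each significantly imbalanced covariate votes for the
  arm whose hypothetical assignment of the incoming patient would most
  reduce its test statistic; a strict majority of votes triggers a coin
  biased at a fixed ξ ∈ (0.5, 1] toward the winning arm; otherwise the
  coin stays fair.
* **common-scale MSB (CS-MSB)** — every covariate's imbalance is expressed
  on one scale, the Wilcoxon–Mann–Whitney (WMW) odds, and the signed log
  imbalances are pooled into a single decision.

## The common scale

For covariate *i*, the WMW odds is

    WMWOR_i = (wins + ties/2) / (losses + ties/2)

over all cross-arm patient pairs, where a "win" is an arm-A value
exceeding an arm-B value. It is defined identically for numeric, ordinal
(rank-coded) and dummy-coded categorical data, is clinically interpretable
(the odds that a random arm-A patient scores higher than a random arm-B
patient), and log(WMWOR) is asymptotically normal — which is what makes
pooling legitimate.

Nominal covariates are dummy-coded *per decision* on the incoming
patient's own category, so imbalance concentrated in categories the
patient cannot affect is ignored.

**Standard error.** `SE(log WMWOR)` is the delta-method transform of the
consistent (DeLong-type structural-component) variance of the
tie-corrected win probability p = U/(n_A·n_B):
`SE = sqrt(Var(p)) / (p(1-p))`. When the structural-component variance is
exactly zero (perfect separation, or one constant arm) the tie-corrected
null variance of the Mann–Whitney statistic is substituted; when even that
is zero (every value tied) the covariate carries no information and
abstains. The analytic SE is validated against a 10,000-replicate
bootstrap in the acceptance suite (agreement within a few percent at
n = 50 per arm).

**Degenerate counts.** When one of the half-counts `wins + ties/2` or
`losses + ties/2` is exactly zero, 0.5 is added to both (Haldane-style),
keeping the log odds finite during the early trial.

## The CS-MSB decision

For the incoming patient, each eligible covariate (at least two observed
values in both arms) computes its current |log WMWOR_i| with SE_i and its
two *prospective* imbalances — |log WMWOR_i| recomputed with the patient
hypothetically appended to arm A and to arm B. The covariate's direction
is the arm with the smaller prospective imbalance (sgn_i = −1 for A, +1
for B, 0 on an exact tie at relative tolerance 1e−12). All eligible
covariates then contribute, regardless of individual significance, to the
weighted bias direction

    BD     = Σ w_i · sgn_i · |log WMWOR_i| / SE_i²  /  Σ w_i / SE_i²
    SE(BD)² = Σ w_i² / SE_i²  /  (Σ w_i / SE_i²)²

with user weights w_i > 0 (all-equal weights reduce SE(BD)² to
1/Σ SE_i⁻², i.e. inverse-variance pooling; rescaling all weights by a
constant changes nothing). Covariates with tied prospective imbalances
keep their weight in the denominator but add nothing to the numerator.
The coin is biased iff Φ(|BD|/SE(BD)) > 1 − α/2 — the two-sided reading;
a one-sided reading could never trigger for BD < 0, contradicting the
rule that BD < 0 favors arm A. The favored arm (A if BD < 0, B if BD > 0)
receives probability ξ (static coin) or f(|BD|) = min(0.5 + s·|BD|, 1)
(linear coin of slope s > 0).

Voting variants on the same scale are provided: *majority* (only
significant covariates vote; with a linear coin the magnitude is the
summed w_j·|log WMWOR_j| of the winning side's significant votes) and
*weighted* (each significant vote weighs w_i·|log WMWOR_i|; the heavier
side wins; a linear coin uses f(|x_A − x_B|)).

## Trial engine

Patients are processed strictly in stream order; each decision sees only
previously allocated patients, and the realized arm is Bernoulli(prob_A)
from a generator consumed *only* for those draws, so trials are exactly
reproducible from (stream, configuration, seed). The log stores the
pre-draw probability because the intervention metrics are defined on
probabilities:

* intervention rate IR = share of allocations with a biased coin;
* expected bias EB = mean |prob_A − 0.5|, which for a static coin equals
  IR × (ξ − 0.5) exactly (asserted to machine precision in the tests).

The engine exists twice: a readable reference path built from the
per-covariate vote functions, and a numba-compiled replica used by the
replicated-simulation harness. A test asserts record-for-record equality
of the two on seeded streams covering every method/voting/coin variant,
with and without missing values. One consequence worth noting: Fisher
exact p-values on small tables are rational numbers that can equal α
exactly, so significance there is declared only below α·(1 − 1e−9) —
otherwise the two float routes could disagree at measure-zero boundaries.

Missing covariate values are excluded pairwise per covariate; a patient
whose incoming value is missing leaves that covariate abstaining. Before
any covariate reaches two observations per arm, allocations are fair by
construction.

## Synthetic populations

The populations emulate the published structure of four stroke trials
(thrombolysis / thrombectomy; n = 70–300) whose patient-level data are not
public: mixed covariate kinds with matched marginals, and a 7-level mRS
outcome (0 no symptoms … 6 death). Choices:

* **Numeric marginals** are matched to published median/IQR by a
  shifted-scaled gamma (reflected when the target is left-skewed, e.g.
  age), the minimal-information fit when only quartiles are known;
  samples are clipped to plausible clinical ranges (age 18–100,
  NIHSS 0–42). Categorical covariates are multinomial with the published
  proportions.
* **Outcome source model**: proportional odds of mRS on the covariates,
  with cumulative logits anchored at a typical control mRS distribution
  and a treatment benefit of 0.6 common log-odds (common OR ≈ 1.8, the
  size of effect reperfusion trials are powered for). Prognostic
  coefficients (age, stroke severity, occlusion site, comorbidities) are
  set to clinically plausible magnitudes of 0.1–0.8 log-odds.
* **Counterfactual vectors**: each patient carries outcome distributions
  under treatment, under control, and under no effect, estimated by
  distance-weighted k-nearest neighbors (default k = 10) trained on,
  respectively, the treatment arm, the control arm, and all patients of a
  50/50-randomized source population. Distances are Euclidean on
  standardized numerics plus one-hot categoricals, every column rescaled
  to unit variance; neighbor weights are 1/d with zero-distance matches
  taking the limit (all) weight. Because the queries are the training
  patients themselves, the "no effect" vector is dominated by the
  patient's own observed outcome — under the null the outcome is then a
  fixed patient attribute, independent of the re-randomized arm, which is
  exactly what a Type-I simulation needs.

What the generator does *not* emulate: covariate correlation beyond what
the prognostic model induces, accrual dynamics, dropout, measurement
error, or any calibration to the real trials beyond their published
marginals. Passing tests therefore demonstrate the randomizers' operating
characteristics under realistic *marginal* structure, not a reanalysis of
the source trials.

## Evaluation harness

* **Calibration**: the α ↔ IR map is nonlinear and population dependent,
  so α is chosen by simulation — a 17-point log grid over [1e−4, 0.99]
  with one local refinement, selecting the α whose chosen IR percentile
  (25/50/75) is closest to target. Unattainable targets return the best
  achievable α, flagged.
* **Power/Type-I**: replicate trials; outcomes drawn per patient from the
  scenario- and arm-matched counterfactual vector; the arm effect tested
  at level 0.05 by a proportional-odds model and by binary logistic
  models at all six mRS cutpoints. With a single binary regressor both
  models collapse onto their sufficient tables, so they are fit from
  counts (closed-form Wald log-odds-ratio test; a small BFGS fit of the
  2×7 proportional-odds likelihood with analytic gradients) and validated
  against statsmodels `Logit` and `OrderedModel` in the tests. Separated
  cutpoints (zero cells) are excluded and counted, never silently
  dropped.
* **Paired design**: when two randomizers are compared, replicates share
  their allocation and outcome uniforms (common random numbers), so
  differences reflect the methods rather than Monte-Carlo noise.
* **Agreement**: Lin's concordance correlation coefficient (moment form,
  1/n variances) plus reduced-major-axis regression
  (slope = sign(r)·sd(y)/sd(x)) with asymptotic tests of slope 1 /
  intercept 0.

## Problem sizes and defaults

Replicate budgets default to 150–500 for calibration and 1,000 for power
(the acceptance script uses 2,500), on fixtures of n = 200–300 — sizes at
which the qualitative results (dominance of CS-MSB at matched IR, the
larger α CS-MSB needs, CCC > 0.995 between the methods' power vectors)
are stable across seeds. Dynamically-biased coins are supported
throughout, but no directional claim is made about static vs linear
coins: that comparison is empirically inconclusive.

## Known limitations

Two-arm, 1:1 allocation only; covariates are treated as uncorrelated by
both methods; no arm-size balancing, interim analyses or rerandomization
inference. The delta-method SE and the kNN settings (k, metric, scaling)
are this package's documented choices where the methods literature leaves
them open; all are isolated behind single functions and configurable.
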