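# Methods

## Model and search procedure

`levelopt` treats the specification of a two-level categorical predictor —
n specific chief complaints partitioned into mutually exclusive complaint
categories — as a combinatorial optimization over binary masks
b ∈ {0,1}ⁿ. The objective (fitness) of a mask is the 5-fold
cross-validated AUC of a binary logistic regression predicting the
critical-care outcome from:

* fixed one-of-K indicator blocks: age band (8 levels), gender (2),
  arrival mode (2), and five vital signs discretized into clinical bins,
  each with a dedicated `missing` level;
* the complaint-level block induced by the mask under one of two
  restructurings. *Flattened*: selected complaints replace their parent
  category for their carriers, giving a single mutually exclusive level.
  *Hierarchical*: category indicators are kept for everyone and selected
  complaints add a supplementary indicator. Two single-level baselines
  (complaints only, categories only) bracket the search space.

The genetic algorithm uses the control parameters established for this
application: population N = 40, tournament selection with k = 3, uniform
crossover applied to a parent pair with probability 0.6 exchanging each
bit with probability 0.2 (the mixing ratio), mutation applied to an
offspring with probability 0.2 flipping each bit with probability 0.05,
and 100 generations by default. Uniform crossover is appropriate because
complaint bits carry no positional structure worth preserving.

### Design choices where the scheme was open

* **Offspring count and elitism.** "Top N retained" is realized as a
  (μ+λ) generational scheme with λ = N: each generation produces N
  offspring by tournament + crossover, mutates offspring only, and keeps
  the best N of parents ∪ offspring. This guarantees a non-decreasing
  best fitness, which the stability analysis of top candidates relies on.
* **Mutation rate is per individual** (0.2 chance an offspring is mutated
  at all), with the 0.05 bit-flip rate applied within a mutated
  individual.
* **Ranking ties** are broken deterministically: higher fitness, then
  fewer selected complaints (parsimony), then lexicographic mask order.
* **Fitness caching.** Fold assignment is fixed per run by `fold_seed`,
  making fitness a pure function of the mask; evaluations are memoized and
  the cache may be shared with the exhaustive oracle — this changes cost,
  never results.
* **Hall of fame** keeps the top 20 distinct masks seen in a run, the
  granularity at which selection stability is assessed.

## Fitness details

* **Folds** are stratified by outcome (at ~3% prevalence unstratified
  folds risk single-class training splits) and shuffled once per run with
  `fold_seed` (common random folds across all candidate masks, so fitness
  differences reflect masks rather than fold noise).
* **Pooled AUC.** The headline fitness pools all out-of-fold probabilities
  into one AUC rather than averaging per-fold AUCs, because the downstream
  evaluation (subgroup AUCs, DeLong tests, probability shifts) operates on
  aligned per-patient probability vectors. Per-fold averaging is available
  via `fold_average=True`.
* **Estimator.** `fit_logistic` is backed by scikit-learn's lbfgs solver.
  Each mutually exclusive indicator block drops its most frequent level as
  the reference (deterministic; keeps the design full rank with an
  intercept); hierarchical-mode complaint indicators are supplementary and
  never dropped. Coefficients are re-expanded with zeros at reference
  columns, so equivalence invariants between modes are stated — and tested
  — on the raw indicator matrices, where they hold bit-exactly.
* **Ridge default 1e-6**: effectively unpenalized, but prevents divergence
  under complete separation by rare complaint indicators. An exactly
  unpenalized fit (`ridge=0`) raises a diagnostic error when a coefficient
  diverges (|β| > 30 log-odds).
* **Numerical tolerances.** Reference fits use lbfgs tol 1e-8; the GA's
  cross-validated fitness uses tol 1e-4, which changes AUCs by far less
  than any fitness difference the search acts on, and is deterministic.
  Out-of-fold probabilities are clipped to [1e-12, 1 − 1e-12].
* **AUC** is computed from midranks — algebraically identical to the
  all-pairs Mann–Whitney count with ties weighted 1/2, and exactly equal
  to it in floating point at realistic sizes.

## Evaluation

* **Bullseye partition.** Inner = patient's complaint selected; middle =
  complaint unselected but a sibling in the same category is selected;
  outer = category untouched. The partition is exhaustive and mutually
  exclusive by construction.
* **DeLong tests** use the placement-value (structural component)
  formulation with midranks; variances use sample covariances (ddof 1)
  of the per-observation components. Comparisons are always paired (same
  patients, common folds), two-sided, with subgroup tests run within the
  subgroup. A self-comparison returns p = 1 exactly; a zero variance with
  unequal AUCs raises a degeneracy error rather than guessing.
* **Undefined cells.** A subgroup with a single outcome class gets `None`
  rather than an imputed 0.5.
* **Probability-shift histograms** default to bin width 0.01 over [−1, 1]
  (configurable) with counts intended for a log frequency axis.
* **Agreement** between the flattened and hierarchical selections reports
  jointly selected / jointly excluded / disagreement percentages of n
  (summing to 100); **stability** reports each complaint's inclusion
  fraction across the hall of fame and the share strictly between 0 and 1.

## Synthetic cohorts

The five real study populations (74.6K–144.9K visits, 288–686 unique
complaints, prevalence 1.68–3.45%) are private, so the generator emulates
their structure with known ground truth:

* **Complaint frequencies** follow a power law (default exponent 1.2) over
  a random rank assignment, giving the long tail implied by hundreds of
  unique complaints; `POPULATION_PRESETS` carries the five populations'
  sample sizes and prevalences at reduced hierarchy width.
* **Outcome model**: logit p = intercept + demographic/vital level effects
  (iid N(0, 0.3), centered) + category effect (N(0, 0.5)) + δ·1[complaint
  ∈ S]. The informative set S (default 8 complaints of 40) is sampled from
  mid-frequency complaints — ubiquitous ones would make recovery trivial,
  singletons hopeless — and δ is split half +0.8, half −0.8, so selection
  shifts some carriers toward higher and some toward lower risk.
* **Intercept calibration** by bisection on the realized linear predictors
  so expected prevalence hits the target (default 3%); the realized rate
  then deviates only by binomial noise.
* **Default scale** 50,000 visits with 5 categories × 8 complaints: large
  enough for stable AUCs at 3% prevalence, small enough for desk-scale
  search studies.

What the generator does **not** emulate: temporal arrival patterns,
inter-hospital heterogeneity, correlated vital signs, informative
missingness, or free-text complaint noise. Passing recovery tests
therefore shows the machinery is correct and the search is effective under
the assumed signal structure — not that any particular real population
carries recoverable complaint-level signal.

## Problem sizes used in validation

The validation suite scales studies to desk size as the package's own
test design: oracle-equivalence uses n = 10 complaints (1,024 masks,
~5,000 visits) with 50-generation searches over 10 seeds; parameter
recovery uses the default 50,000-visit scale with 30-generation searches
over 5 replicates (hierarchical mode); null calibration uses 20,000-visit
zero-effect cohorts with short 8-generation searches. The acceptance
script (`scripts/acceptance.py`) uses a 20,000-visit, 20-complaint signal
study, a 10-complaint exhaustive cross-check, and a 10,000-visit null run,
all derived from a single `--seed`.

## Data interfaces

Cohorts are CSV with columns `age_years` *or* `age_band`, `gender`,
`arrival_mode`, the five vitals (raw numeric with blanks for missing, or
pre-binned labels), `complaint`, `outcome`; the hierarchy is a two-column
`complaint,category` CSV. Identifiers are matched case-insensitively after
whitespace/dash normalization. Discretization bins are half-open
[lower, upper): a printed boundary belongs to the upper bin (the bin
tables print overlapping endpoints, e.g. pulse 49–59 / 59–105, so the
convention is a documented package choice); ages 80–89 mean [80, 90) and
">90" means [90, ∞), leaving no gap at 90. Rows whose complaint cell
contains multiple complaints are rejected rather than silently resolved.

## Known limitations

* Logistic regression is the only shipped estimator (it is deterministic
  and fast, which the search relies on); the fitness seam accepts other
  estimators in principle but none are provided.
* The search optimizes the same cross-validated AUC it later reports, so
  the GA model's pooled CV-AUC is mildly optimistic. Under a pure null
  this optimism is *systematic*: the best of hundreds of correlated
  CV-AUC draws sits a few standard errors above 0.5, so a DeLong test
  against a baseline on the search data rejects even though no signal
  exists. The null-calibration study therefore bounds the in-sample best
  fitness (0.5 ± 0.05 at 20,000 visits) but runs its significance checks
  on a held-out cohort drawn from the same null process, where a
  specification chosen by luck cannot generalize.
* Exhaustive search is capped (default n ≤ 16) and exists as an oracle,
  not a practical solver.
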