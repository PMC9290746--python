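# Methods

This note documents the models, conventions and numerical choices behind
`ravenshort`, in the spirit of a statistical package's methods appendix. It
states no empirical result beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Data model and cleaning

The universal container is a persons × items matrix of binary responses with
per-person metadata (opaque id, decimal age which may be unknown, source
dataset). Cleaning applies four rules in a fixed order so that every removal
is attributed to exactly one rule:

1. drop practice-item columns (A1, A2 by convention for the younger cohort);
2. drop rows with any missing response;
3. drop duplicate rows — *identical responses and metadata*, keeping the
   first occurrence (the person id, being an arbitrary label, does not enter
   the comparison);
4. drop rows with age below the cut-off (12.5 years for the older cohort);
   rows with unknown age always pass, and requesting the filter on data with
   no recorded ages at all is a configuration error.

The ordering makes the report's arithmetic identity
`n_output = n_input − missing − duplicates − under-age` hold by construction,
and cleaning is idempotent. A row that is simultaneously missing-valued and
under-age is counted once, under the earlier rule.

Cohort totals are always computed over the *administered* items (58 for the
younger cohort after the practice items are dropped, 60 otherwise); the item
count is carried in every score vector rather than assumed.

## Synthetic cohorts

The generating model is the two-parameter logistic (2PL):
`P_i(θ) = σ(a_i (θ − b_i))` with discrimination `a_i > 0`, difficulty `b_i`,
and ability `θ ~ Normal(θ_mean, θ_sd²)`. An optional lower asymptote turns it
into a 3PL; it is off by default because the base model is the simplest one
with varying item quality, and the same model serves the IRT baseline.

Default item bank (60 items):

| parameter | default | rationale |
|---|---|---|
| difficulty grid | equally spaced on (−2.5, 2.5) in canonical order | items get progressively harder A→E; ±2.5 logits spans near-certain success to near-certain failure for an average examinee |
| difficulty jitter | 0 (optional, re-sorted within set) | keeps both monotonicity invariants when used |
| discriminations | log-normal, median 1, log-SD 0.3 | moderate, realistic spread of item quality |
| bank seed | 60 | fixed so both cohorts share one bank |

Calibration adjusts only `(θ_mean, θ_sd)` — never the bank — so one test
serves two populations of different ability. The analytic total-score moments
are computed by Gauss–Hermite quadrature (61 nodes): mean `E_θ[T(θ)]` with
`T(θ) = Σ_i P_i(θ)`, and variance `E_θ[Σ_i P_i(1−P_i)] + Var_θ[T(θ)]`
(binomial within-person part plus between-person part). A hybrid-Powell root
find in `(θ_mean, log θ_sd)` drives both moments to the targets; the result
is deterministic, and failure to reach the tolerance (default 1e-4 score
points) raises an error carrying the best achieved moments. The younger
cohort's targets (37.17 ± 6.91) and the older cohort's (43.83 ± 6.97, pooled
over sources of 557/157/273) are preset in `ravenshort.cohorts`.

Defect injection picks pairwise-disjoint row sets for missing cells,
appended exact duplicates, and under-age rewrites (uniform on 10–12.45
years), so a subsequent cleaning pass removes exactly the injected counts and
the pre-defect matrix remains recoverable.

What the generator does *not* emulate: multidimensional structure (e.g. the
speed/ability mixture of timed administrations), practice and fatigue
effects, response times, and any discrimination profile beyond the log-normal
law above. Calibration matches only the first two moments of the total score.
Consequently, passing tests demonstrate the pipeline's correctness and its
behaviour on clean unidimensional data; they do not certify performance
levels on real cohorts. In particular, the attainable short-form/full-form
correlation is bounded by the generator's discrimination scale: with the
default bank the bound sits somewhat below the correlations reported for
comparable real cohorts, whose items evidently discriminate more sharply at
equal total-score SD. The package reports whatever the data admit rather than
tuning the generator to flatter the method.

## Elastic net

Objective convention (the one used by the standard R implementation, stated
prominently because λ is scale-dependent):

```
(1/(2n)) Σ_i (y_i − β0 − x_i'β)² + λ [ α‖β‖₁ + ((1−α)/2)‖β‖₂² ]
```

The intercept is unpenalized. Predictors are standardized internally to unit
population (1/n) variance by default and coefficients reported back on the
original scale; the outcome is centred but never scaled. This combination is
what makes a λ range of 2–3.5 meaningful against a sum-score outcome whose SD
is around 7. Zero-variance predictors receive coefficient exactly 0.

The solver is cyclic coordinate descent on precomputed Gram quantities
(`X'X/n`, `X'y/n`), so a full sweep is O(p²) regardless of n and the grid
search can afford hundreds of fits. Convergence: maximum absolute coefficient
change on a sweep below 1e-7, capped at 10,000 sweeps; the penalized
objective is recorded after every sweep and is non-increasing. Along each α
the λ path is solved in descending order with warm starts (an optimization
only; results are identical without it). The test suite checks the solver
against the normal equations at λ = 0, the closed-form ridge estimator at
α = 0, the KKT subgradient conditions, and an independent reference solver.

## Splitting and the grid search

Validation is drawn first: per source when stratified, with size
`ceil(0.2 × source size)` — the only rounding convention that reproduces both
published validation sizes (58 from 289, and 112+32+55 = 199 from
557/157/273). The remaining development rows are halved into train/test,
train taking the odd row. All assignments derive from a single seed.

The grid defaults to λ ∈ [2.0, 3.5] × α ∈ [0.5, 1.0] at step 0.05 for both
axes (every published grid point is a multiple of 0.05). At each point the
items with nonzero coefficients form a candidate; candidates are scored by
the Pearson correlation between their sum score and the *full administered*
sum score (part–whole, including the candidate's own items) on the test
partition. The chosen form maximizes the test correlation among candidates
with 1–15 items; ties break toward the shorter form, then the larger λ, then
the larger α (a convention of this package — only the correlation criterion
is inherited). An empty eligible set raises an explicit no-solution error
suggesting a wider grid. The length sweep reports, per length 11–20, the best
candidate of exactly that length with its test and (when a validation matrix
is supplied) validation correlations; both are reported because published
accounts are ambiguous about which partition their per-length table used.

## Validation apparatus

- **Monte Carlo stability** (default 100 iterations): the development set is
  re-halved with derived seed `master_seed + i` and the grid search rerun;
  the result is each item's selection frequency across iterations. Iterations
  with no solution are counted separately and contribute no selections.
- **Random-subset baseline** (default 100 draws of k = 15): subsets are drawn
  uniformly from the *administered* items — items never administered cannot
  be scored, so the younger cohort draws from 58. "Outperforms x% of draws"
  uses strict inequality with all draws in the denominator. Zero-variance
  draws are redrawn and logged.
- **Cronbach's alpha**: `(k/(k−1)) (1 − Σ_j var_j / var_total)` with the n−1
  variance convention used consistently for items and total.
- **Ceiling diagnostics**: histogram of the total score over 0..max,
  adjusted Fisher–Pearson sample skewness, and the probability mass at or
  above 90% of the scale maximum. Constant scores have undefined skewness;
  the report is still produced with skewness set to NaN (the histogram and
  decile mass remain informative — an all-maximum sample is precisely the
  ceiling case one wants flagged).

## IRT baseline

The comparator is a reconstruction of a classical information-based
short-form recipe, with its defaults documented here because the original
procedure's details are not available: a 2PL fitted by Bock–Aitkin
marginal-maximum-likelihood EM with a fixed Normal(0, 1) ability prior (which
identifies the scale) on 21 Gauss–Hermite nodes. The M-step maximizes each
item's expected complete-data log-likelihood with vectorized Newton steps and
per-item step halving, so the marginal log-likelihood is non-decreasing
across EM iterations (asserted in tests). Convergence: absolute
log-likelihood change below 1e-4, capped at 500 iterations. Items answered
identically by everyone are flagged inestimable and excluded from selection.
A Rasch-type variant constrains all discriminations equal.

Selection keeps the k = 15 items with the largest expected information under
the ability prior, `E_θ[a² P(θ)(1−P(θ))]`; information at a fixed θ or over a
custom grid is available through the same interface. The method comparison
scores each method's form on the same validation partition (correlation with
the full test, Cronbach's alpha).

## Problem sizes and determinism

The test suite exercises the full study-scale pipeline (cohorts of 289 and
987, the complete 31 × 11 grid) but runs the more repetitive diagnostics at
reduced size: Monte Carlo stability properties use 10 iterations on a coarse
grid, parameter recovery uses one 2,000-person fit, and large-sample checks
use 10,000–100,000 Bernoulli draws — sizes chosen so the whole suite
completes in well under a minute while the statistical assertions retain
3-standard-error headroom. Every random quantity in the package traces to an
explicit integer seed (numpy `SeedSequence`); identical configurations
reproduce bit-identical matrices, splits, search results and report bundles.

## Known limitations

- Single held-out validation, as in the original design; no nested
  cross-validation, so the reported validation correlation of the *chosen*
  form retains mild selection optimism.
- Part–whole correlations are inflated relative to correlations with the
  disjoint remainder; they are the target quantity here by design.
- The synthetic generator's unidimensionality and moment-only calibration
  mean absolute performance numbers on synthetic data should not be read as
  predictions for real cohorts (see the synthetic-cohorts section).
- No polytomous or timed-response scoring; no standard errors on 2PL item
  parameters; no model-fit statistics for the IRT baseline.
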