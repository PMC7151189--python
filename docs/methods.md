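# Methods

## Problem and scope

`distscreen` screens multiple-choice items for *ability-related distractor
discrimination*: whether, among the people who fail an item, the choice of
wrong option still carries information about ability.  Items with such
distractors are the ones worth scaling with nested logit (2PNL) models,
which model accuracy first and distractor choice second and thereby gain
measurement precision at the low end of the ability range.  Because fitting
a nested logit model needs far more data than a pilot study provides, the
package works entirely with descriptive effect sizes computed from raw
number-correct scores — no latent-ability estimation anywhere.

## Data-generating model

Responses are simulated from a two-stage nested logit model.  Person *j*
with ability θ_j solves item *i* with the 2PL probability

    P(solve) = logistic(β_i + α_i θ_j),

where β_i is an easiness intercept (all "difficult" levels are negative)
and α_i > 0 the discrimination slope.  Conditional on *not* solving,
distractor *v* is chosen with nominal-response-model probability

    P(v | not solved) = softmax_v(ζ_iv + λ_iv θ_j)

over the item's m distractors.  The λ slopes are the quantity of interest:
λ ≡ 0 makes distractor choice independent of ability given failure.

Parameter levels used throughout (uniform sampling ranges per item):

| facet | levels |
|---|---|
| sample size N | 100, 200, 500 |
| test length I | 10, 20, 50 |
| distractors m | 3, 7 |
| difficulty β | moderate U(−0.15, 0.15); difficult U(−1.15, −0.85); very difficult U(−2.25, −1.85) |
| discrimination α | low U(0.25, 0.55); moderate U(0.85, 1.15); high U(1.60, 1.90) |
| NRM slopes λ | fixed zero-centred ladders with step 0 / 0.40 / 1.00 / 1.75 (see `LAMBDA_GRIDS`) |

NRM intercepts ζ are i.i.d. U(−1, 1).  Abilities are i.i.d. standard
normal; this is not dictated by the model but is the universal IRT
simulation default, and every downstream rate depends on it.  λ ladders
are assigned to distractor slots in listed order (most negative first);
because the ζ are i.i.d., any permutation is distributionally equivalent,
and the fixed order exists purely for reproducibility.  Option codes:
`"0"` is the correct option, `"1"`..`"m"` the distractors in λ order.

What the generator deliberately does *not* emulate: guessing/slipping
(3PNL/4PNL stages), multidimensional ability, person misfit, speededness,
or missing responses.  Passing tests therefore show that the effect sizes
behave as intended *under the 2PNL*; on real data with heavy guessing the
accuracy stage is misspecified and the screens should be read more
cautiously.

## Effect sizes

All item-level statistics first apply a retention screen: a distractor is
kept iff at least 5% of *all* participants chose it (boundary inclusive;
both denominator and boundary are configurable).  Statistics are then
computed on retained distractors only.

**Cohen's ω_G** builds the (retained distractor) × (ability group)
contingency table over the item's non-solvers and reports
ω = √(χ²/n) with the Pearson χ² (no continuity correction — this is an
effect size, not a test) and n the table total.  Ability groups are score
quantiles, G = 2 and G = 5 by default.  Quantile rule: breakpoint k is the
smallest observed score whose empirical CDF reaches k/G; persons fall in
the first group whose breakpoint is ≥ their score.  Interpolated quantiles
are ill-defined on heavily tied integer scores; this rule is deterministic,
never splits ties, and lets groups genuinely fail to occur (which the study
tracks as a diagnostic).  Breakpoints come from the non-solver score
distribution by default — the table contains only non-solvers, and using
the same population keeps its columns balanced; a flag switches to
all-person quantiles, and the worked-example values are insensitive to the
choice (well within their reported tolerance).

**R_CC**, the canonical correlation between distractor choice and score,
is computed from K−1 choice indicator variables (drop-one coding; the K
indicators sum to one, so the full correlation matrix is singular and the
Cholesky step would fail) against the non-solvers' total scores: with
r₁₂ the vector of indicator–score correlations and H₁ the Cholesky factor
of the indicator correlation matrix, R_CC is the single singular value of
r₁₂′H₁⁻¹.  With one continuous variable on the second side this equals the
correlation ratio η of the one-way distractor-group layout, which the test
suite exploits as an independent oracle and which guarantees invariance to
the dropped column.

**Classical per-distractor indices** are reported alongside: PB_D, the
point-biserial between the "chose D" indicator and total score over all
participants; PB_DC, the same restricted to the subgroup choosing D or the
correct option (the √(P_D/P_C) factor is fixed by requiring exact equality
with the subgroup Pearson correlation, which the tests assert); ω_D, the
Haladyna-Downing uniformity effect size √(χ²_D/n_D) of one distractor's
counts across realized ability groups; and Goodman-Kruskal's γ for rising
selection ratios, computed over the 2 × J (correct vs. D) × (rest-score
level) table as concordance of the estimated P(correct) across score-level
pairs, ties dropped, unweighted over levels (a table-weighted variant sits
behind a flag).  γ uses rest scores (total minus the item's own
correctness) so the item under test never contributes to its own
performance axis; for the non-solver statistics the distinction is inert,
because a failed item contributes zero to the total anyway.

Undefined statistics propagate as NaN with an enumerated reason
(`insufficient_distractors`, `degenerate_groups`, `zero_variance`,
`no_nonsolvers`) rather than raising; the study counts them as missing
effect sizes.

## Simulation study

The design is the full 3 × 3 × 2 × 3 × 3 × 4 = 648-cell cross of the
facets above.  Each cell simulates fresh item banks and datasets, analyses
every item, and pools all item × replicate effect sizes:

* **detection rate** — share of non-missing effect sizes strictly above a
  threshold (0.10 / 0.30 / 0.50); under zero NRM slopes this is the
  type-I error of the screening rule, otherwise its power;
* a cell's type-I behaviour is *acceptable* when the rate is ≤ 0.05, its
  power *adequate* when ≥ 0.80 (both inclusive);
* power can be re-evaluated under boundary conditions — a detection also
  requires the item's mean γ > 0.30 or mean PB_DC < −0.30 — and
  measure × threshold combinations whose matching null cell (same non-NRM
  facets) had unacceptable type-I error are screened out of the power
  summary first;
* **substance diagnostics** — proportions of sub-5% distractors, missing
  effect sizes (with the share attributable to the screen), and realized
  ability groups — are averaged with equal cell weights.

Reproducibility: every (cell, replicate) derives its RNG stream from
`(master_seed, canonical cell index, replicate)`, so any subset of cells,
in any order, reproduces bit-identically.

## Problem sizes used in the checked runs

The package's own verification runs scale the published design down to
desk scale: the type-I summary uses all 162 null cells at 100 replications
(the three-threshold percentages are stable to a few points at this size),
the substance summary uses all 648 cells at 50 replications in a
substance-only mode that skips effect-size values, and the worked examples
use the full N = 10,000.  Full-scale runs (1000 replications) go through
the same `study` command unchanged.

## Numerical and design choices

* Point-biserials use the population (ddof = 0) standard deviation, which
  is what makes them exactly Pearson correlations of indicators.
* R_CC is clipped at 1 against rounding overshoot; χ² tables drop all-zero
  rows/columns before testing dimensions.
* The 5% screen denominator is all participants ("chosen by at least 5% of
  the participants"), not non-solvers — the empirical pattern of easy items
  losing almost all distractors only reproduces under this reading.
* Detection uses strict `>`; acceptability/adequacy use inclusive
  comparisons.
* The mean PB_DC / mean γ boundary summaries average over retained
  distractors with defined values.
* `DesignCell` validates level names but deliberately leaves N and I free
  (the worked examples use N = 10,000).

## Known limitations

* With λ_max ≥ α the generating model itself violates rising selection
  ratios at the low-ability end for the λ_max distractor (the derivative of
  the log-odds of correct vs. that distractor is α − λ_max + E[λ|θ] < 0 for
  low θ), so γ < 1 is *expected* for strongly discriminating distractors —
  γ and the item-level effect sizes measure genuinely different things.
* The effect sizes are descriptive screens, not estimators of λ; their
  null distributions shift with difficulty and m, which is why threshold
  calibration (the type-I study) matters before use.
* Empirical datasets enter only through the `analyze` command; 2PL item
  parameter estimation is out of scope and left to IRT software.
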