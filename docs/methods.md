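# Methods

This note documents the models, algorithms and numerical choices behind the
package, in the order the pipeline uses them: instance ensembles → exact
solvers and effort → hardness metrics and thresholds → stratified designs →
synthetic behavior → mixed-effects inference.

## Random-instance ensembles

**3SAT.** An instance with `N` variables and target constrainedness `α`
gets `M = round(α·N)` clauses (half-values round away from zero). Each
clause draws 3 distinct variables uniformly without replacement; each
literal's sign is an independent fair coin. Clauses are pairwise *distinct*
by default: at `N = 5` only 80 clauses exist, so sampling with replacement
wastes a substantial fraction of the `M ≈ 24` constraints on duplicates and
pushes the empirical half-satisfiable point from 4.8 up to roughly 5.6. The
distinct-clause ensemble reproduces the reference threshold of 4.8; a
config flag (`distinct_clauses=False`) restores the with-replacement
ensemble. The clause count is capped at 36 (the number that fits on the
task display); consequently the default threshold sweep runs `α` over
[1.0, 7.2] in steps of 0.1, the largest cap-consistent range at `N = 5`.

**TSP.** `N` city coordinates are i.i.d. uniform on a square of side
`M_side = 1000` map units; the decision limit follows from the
constrainedness parameter through `L = −α · M_side · √N`. All distances are
full-precision Euclidean. The on-disk TSPLIB files declare `EUC_2D` for
interoperability, but the package never applies TSPLIB's
round-to-integer convention — the order parameter and the threshold live in
continuous geometry, and integer rounding would perturb satisfiability for
instances near the boundary.

**Knapsack.** `N = 6` items with weights and values i.i.d. uniform integers
on [1, 100] (the source ensemble's item distribution is not published in
more detail; both ranges are config-exposed). Capacity and profit ratios
are drawn uniformly from bands (defaults `α_c ∈ [0.40, 0.45]`,
`α_p ∈ [0.60, 0.65]`), the integer capacity/profit are rounded, and the
draw is rejected unless the *realized* post-rounding ratios still lie
inside the bands.

Every sampler consumes a `numpy.random.Generator`; named per-stage streams
are derived from a master seed (`stage_rng`), so regenerating one problem
family never perturbs another.

## Exact solvers and the effort counter

All optima are exact; there is no heuristic fallback (oversized instances
raise).

- **3SAT / MAX-SAT**: vectorised exhaustive evaluation of all `2^N`
  assignments (`N ≤ 20`). The optimum is the maximum number of
  simultaneously satisfiable clauses; the instance is satisfiable iff that
  equals `M`.
- **TSP**: Held–Karp dynamic programming over subsets (`N ≤ 22`,
  O(2^N N²)); the witness is an optimal closed tour. Tours are closed
  Hamiltonian cycles: the limiting threshold constant −0.7124 and the
  empirical `N = 20` threshold −0.85 are both reproduced under the
  closed-tour reading, which fixes the convention.
- **Knapsack**: vectorised subset enumeration (`N ≤ 20`); the optimum is
  the maximum value subject to the weight constraint, and the instance is
  satisfiable iff it reaches the target profit.

**Solver effort** is the deterministic node count of a reference
branch-and-bound with fixed, documented heuristics — a hardness-correlated
stand-in for algorithm-specific difficulty counters (e.g. constraint-solver
propagation counts), which are not reproducible across solvers. Only the
within-ensemble *median split* consumes this number, so any deterministic,
hardness-monotone count serves.

- 3SAT: DPLL-style search minimising falsified clauses; static variable
  order by descending formula frequency, TRUE branch first; prune when the
  falsified count reaches the incumbent.
- TSP: depth-first branch-and-bound with nearest-neighbour child ordering,
  a minimum-spanning-tree lower bound over the unvisited cities plus the
  two path endpoints, and the *known optimum* (from Held–Karp) seeding the
  incumbent — the count therefore measures how hard the optimum is to
  *certify* on that map, independent of incumbent luck. The count is
  truncated at 10⁶ nodes: the ensemble median at `N = 20` is ≈ 9 × 10⁴, so
  the cap never moves an instance across the median split, but it stops a
  handful of pathological maps from dominating runtime.
- Knapsack: branch-and-bound over density-sorted items, include-branch
  first, fractional (LP) upper bound.

## Hardness metrics

**Witness counts.** 3SAT counts satisfying assignments and KP counts
feasible-and-profitable subsets exhaustively. TSP counts *directed tours
with a fixed start city* (reversals distinct), halting at a cap of 30 000
with a truncation flag. The symmetry convention only shifts log-counts by a
constant, which any downstream linear term absorbs; witness counts enter
models on the natural-log scale for TSP. The enumeration is pruned with an
exact completion-cost table `e[R, j]` (minimum cost of finishing the tour
from city `j` through the remaining set `R`), computed by one extra
subset-DP pass; with an exact bound the search tree is proportional to the
number of tours found rather than to the near-miss space, which is what
makes counting under loose limits affordable.

**Instance complexity.** `IC = |α − α*|` with `α*` the realized optimum's
constrainedness: `(M − maxsat)/N` for 3SAT, `|L − opt|/(M_side √N)` for
TSP, `|p − opt|/Σv` for KP. Satisfiable 3SAT instances have IC = 0
identically. Note that among *satisfiable* instances IC and the witness
count both measure slack past the decision boundary and are therefore
positively rank-correlated; hardness rises as either approaches zero/one.

**TCC.** A design declares three closed α-bands (underconstrained /
threshold / overconstrained); TCC is `high` exactly on the threshold band.
Values outside every declared band raise rather than snapping to the
nearest band.

**Thresholds.** The satisfiability curve Monte-Carlo-estimates the
satisfiable fraction per grid point (fresh instances per point for 3SAT;
for TSP the same `n` maps are shared across the grid, each solved once,
with only the limit varying — the ensemble's own construction). The
threshold estimate is the grid point whose fraction is nearest 0.5, ties
(to float tolerance 10⁻¹²) resolving toward the less-constrained side.
Study-scale settings: 3SAT `N = 5`, 1000 instances per 0.1 step; TSP
`N = 20`, 100 maps, grid [−1.25, −0.25] step 0.02.

## Stratified designs

Packaged designs: 3SAT 16/32/16 at α ∈ {2, 4.8, 7} (64 instances); TSP
18/36/18 at α ∈ {−0.99, −0.85, −0.71} (72, no two sharing a coordinate
set); KP 18/36/18 by `α_p` band at fixed `α_c ∈ [0.40, 0.45]` (72).
Under-/over-constrained strata are sampled from their pools without further
screening. The threshold stratum balances satisfiability × effort: the
median is computed on the full candidate pool at that α (1000 instances for
3SAT/KP, 100 coordinate sets for TSP, automatically extended if a cell
cannot be filled), instances at or below the median are labelled `low`, and
equal cell counts (8 for 3SAT, 9 for TSP/KP) are drawn per
{satisfiable, unsatisfiable} × {low, high} cell.

## Synthetic behavior

One row per participant × instance. Accuracy is Bernoulli with a
logit-linear predictor over instance metrics plus a Gaussian participant
intercept. Time-on-task is modelled as a proportion of the trial limit
(110 s 3SAT, 40 s TSP; the 25 s knapsack task was not self-paced, so KP
trials carry no time outcome): linear predictor + participant intercept +
Gaussian residual, right-censored at 1.0 and floored at ε = 0.01 so the
censored-Gaussian likelihood stays well-defined. Clicks are negative
binomial with rate increasing in hardness, hard-capped at 20 (mirroring the
task's click limit qualitatively). Trials go missing (no response) with a
small probability (default 0.007, matching the observed order of ~10 missed
trials per ~1500). Presentation order is re-randomized per participant.

The packaged ground-truth effect sizes are the reference study's reported
coefficients (TCC→accuracy: −1.58 3SAT, −2.10 TSP, −1.327 KP; TCC→time:
+0.149 3SAT, +0.118 TSP; ic→accuracy 21.13 TSP used in the recovery
harness). Intercepts and dispersions are *not* published; they were fixed
once so that simulated cohorts land at the summary statistics the tasks
were tuned to (mean accuracy ≈ 0.85–0.87, mean time fraction ≈ 0.55–0.80)
and are inputs, never estimands. What the generator does *not* emulate:
learning/order effects across the session, realistic response-time shapes
beyond the censored Gaussian, item-level residual variance beyond the
metric-driven predictor, and strategy structure. Passing recovery tests
therefore show that the *inference machinery* is calibrated for data of the
assumed structure — not that real behavior follows that structure.

Exclusion rules mirror the study's: missing-response trials are dropped,
and participants with overall accuracy below 0.6 (near chance on a
two-alternative task) are removed, each exclusion logged with its rule.

## Inference

Both model families marginalise a Gaussian participant intercept out of the
likelihood with 25-node Gauss–Hermite quadrature:

- accuracy: logistic GLMM;
- time: right-censored Gaussian (Tobit) mixed model on the
  proportion-of-limit scale — censored rows contribute the upper-tail
  survival term.

The **MLE backend** (default for tests and recovery) maximises the marginal
likelihood with BFGS and reports intervals from the numerical Hessian using
a Student-t critical value with `n_groups − k` degrees of freedom — the
plain Wald-z interval is measurably anticonservative with a few dozen
participants. Non-positive-definite Hessians fall back to a pseudo-inverse;
fits with implausible slopes (> 15 logits per predictor standard deviation,
a separation symptom) or failed optimisation are flagged `converged=False`
and recovery summaries count them rather than dropping them silently.

The **Bayesian backend** samples the same marginal posterior with an
affine-invariant ensemble sampler under weakly-informative priors (flat on
slopes, Student-t(3, 0, 2.5) on the intercept, half-t(3, 0, 2.5) on scale
parameters — mirroring common mixed-model defaults), default 2000 draws
after 1000 burn-in across ≥16 walkers, reporting posterior medians, 95%
highest-density intervals and split-R̂. Any parameter with R̂ > 1.01 flags
the fit and triggers one retry with doubled draws. An effect is termed
significant when its 95% interval excludes zero; no multiplicity correction
is applied, matching per-model interval reporting.

`instance_r2` reports the squared correlation between per-instance mean
observed accuracy and the population-averaged (intercept-integrated)
predicted probability. The recovery harness simulates replicate cohorts at
study scale (23–24 participants), refits the matched model, and tabulates
bias, RMSE, interval coverage and sign recovery per coefficient.

## Problem sizes and limitations

Exact-regime caps: `2^N` enumeration for 3SAT/KP (`N ≤ 20`), `N ≤ 22` for
the TSP subset DP (~80 MB per solve at `N = 20`). The acceptance script and
test suite run at the study's own scales (1000 × 71 3SAT solves, 100
20-city maps, 100-replicate recovery) on one CPU in a few minutes. Known
limitations: the TSP witness symmetry convention is a choice (counts are
comparable only within it); TCC inherits the sampling distribution it was
defined on and does not transfer to other ensembles; the effort counter is
a proxy whose absolute scale is meaningless (only within-pool order is
used); and the Bayesian backend's ensemble sampler is adequate for the
low-dimensional fixed-effect posteriors here but is not a general
hierarchical-model engine.
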