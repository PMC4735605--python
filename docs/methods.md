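# Methods

## Persistence model

Species persistence over a 20-year horizon is a Bayesian belief network on
the trophic DAG: node *i* is binary (extant/extinct), its parents are its
prey *F_i*. Conditional persistence is linear in the prey-dependence weights:

* consumer, prey subset *f* present: `p_i(f) = (1 − e_i) · Σ_{j∈f} w_ij / Σ_{j∈F_i} w_ij`
  — equal to `1 − e_i` with the full diet, proportional to the surviving
  weight fraction otherwise, and 0 with no food;
* basal species: `p_i = 1 − e_i`, independent of the rest of the web;
* managed species (action `a_i = 1`): extinction chance scaled by `1 − η`,
  i.e. `p → 1 − (1 − η)(1 − p)`, except that a consumer with no surviving
  prey dies regardless of management. At `η = 1` a managed species with at
  least one resource — or a managed basal species — persists with
  probability 1. Treating managed *basal* species as safe is an
  interpretation choice: the "at least one prey present" condition cannot
  apply to species without prey, and bottom-up prioritization would be
  meaningless if protecting producers did nothing.

The assumptions worth keeping in mind: extinction risks `e_i` are i.i.d.
draws, uncorrelated with trophic position; prey dependence is additive in
weights (no prey-switching dynamics, no saturation); there is no temporal
dynamics — the network encodes a single equilibrium marginalization; and no
biomass/energy-flow bookkeeping is attempted.

## Inference backends

CPTs are never materialized as `2^|F_i|` tables except where the elimination
backend builds the factors it needs; everywhere else the conditional law is
evaluated functionally from the weight sums.

* **enumeration** — sums the joint over all `2^n` community states, chunked
  at 2^16 states and vectorized over species. Exact; guarded at `n ≤ 22`.
  This is the oracle all other backends are tested against.
* **elimination** — exact variable elimination, one run per target species,
  with greedy min-fill ordering. If any intermediate factor would exceed the
  width cap (22 binary variables) the call logs a notice and falls back to
  Monte-Carlo. On 30-species niche webs at C = 0.1–0.2 the induced widths
  are comfortably small and a full marginalization takes ~0.1 s.
* **montecarlo** — ancestral forward sampling in topological order,
  vectorized across samples; 20,000 samples by default, with per-species
  binomial standard errors. Strategy comparisons reuse one pre-drawn uniform
  matrix (common random numbers) so that argmax decisions between similar
  strategies are not dominated by sampling noise.
* **auto** — enumeration for `n ≤ 16`; above that, elimination when the
  min-fill width estimate fits the cap, else Monte-Carlo. Inside the strategy
  evaluator (many evaluations per call) `auto` skips elimination and goes
  straight to Monte-Carlo, which is the right cost profile for greedy loops.

An additional closed form, `closed_form_unmanaged_marginals`, propagates
`q_i = (1 − e_i) Σ w_ij q_j / Σ w_ij` in topological order. Because the
unmanaged conditional law is linear in the prey indicators, linearity of
expectation makes this *exact* despite dependence among prey — an
independent oracle used in the tests. Management breaks the linearity (the
no-food clause), so the closed form deliberately refuses to model it.

## Strategy search

`V(a) = Σ U_i q_i(a)` with `U_i = 1` by default, so V counts expected
survivors. The optimal search enumerates subsets by size then
lexicographically, capped at the largest size whose cheapest fill fits the
budget; ties resolve to the lexicographically smallest managed set, and
every evaluation is cached by managed set. Exhaustive search is refused
above 20 species. The greedy heuristic adds the affordable species with the
largest value gain, never removes, and stops when nothing affordable
remains; with `η = 1` additions can never lower V (management monotonicity,
verified exhaustively on small webs), so no improvement check is applied.

Feasible-strategy counting uses an exact dynamic program over integer costs
and subset sizes; unit-cost `exactly_k` short-circuits to `C(n, k)`.

## Niche-model generator

Webs follow the Williams–Martinez niche model: niche values
`n_i ~ U(0,1)`, diet width `r_i = x·n_i` with `x ~ Beta(1, (1−2C)/(2C))`
(mean `2C`), diet centre `c_i ~ U(r_i/2, n_i)`; `j` is prey of `i` iff `n_j`
lies in the diet interval. The species with the smallest niche value is
basal by construction. The acyclicity adjustment relabels species by
ascending niche value and keeps only links from strictly lower to higher
niche values, which removes cannibalism and all loops. A draw is rejected
(whole-web resampling, never patching) when a species whose drawn diet was
non-empty loses every prey under the adjustment, when any species is
isolated, or when the realized connectance `L/n²` misses the target by more
than the relative tolerance (default 5%; cap 10,000 attempts). At the study
conditions (n = 30, C ∈ {0.1, 0.2}) roughly one draw in twenty is accepted,
so generation is effectively instantaneous.

Scenario defaults are the study conditions: `e_i ~ Beta(2, 8)` (mean 20-year
extinction risk 0.20; the low-risk variant Beta(2, 38) has mean 0.05),
`w_ij ~ LogNormal(−3.0, 1.5)`, utilities 1, and either unit costs or costs
uniform on {1,…,5}. Costs are drawn on {1,…,5} rather than {0,…,5}: a
zero-cost species would make management free and the ROI score undefined,
while the 1–5 range preserves the intended "five times more than the
cheapest" spread.

## Prioritization indices

Twelve ranked heuristics are implemented; all rankings are full
permutations, record their raw scores and polarity, and break ties by
species label.

* Degree, betweenness, closeness are computed on the *undirected* view of
  the web (directed variants would leave basal or apex species with
  degenerate scores). Closeness is `reach / ((n−1)·Σd)`, which equals the
  inverse total shortest-path length on connected webs and decays gracefully
  on fragmented ones. Weighted variants use link length `1/w_ij` — strong
  dependence is a short distance.
* The keystone index runs Jordán's two recursions over the DAG: a bottom-up
  component spreading `(1 + K)/d` from consumers to their prey and a
  top-down mirror through predators.
* The modified PageRank reverses all links (importance flows from consumers
  to what supports them), wires every basal species to a root node and the
  root back to all species — the detritus-recycling loop closure that makes
  the chain irreducible without teleportation damping. The stationary
  distribution is obtained by a direct linear solve, which is exact and
  immune to the periodicity that defeats plain power iteration on small
  webs; the root's mass is discarded and species scores renormalized.
* The dominator index roots the flow graph at a virtual source feeding the
  basal species and scores each species by how many others it strictly
  dominates (every energy path to them passes through it).
* The cascading-extinction index removes each species in turn and iterates
  secondary extinctions (consumers whose prey set empties die; species basal
  in the original web never starve); fewer survivors ranks better.
* Bottom-up prioritization sorts by ascending trophic level (longest-chain
  convention, basal = 1), then by descending predator count.
* ROI scores `η·e_i / c_i`: with unit costs, manage the riskiest species
  first.
* Random is a seeded uniform permutation.

Budgeted selection walks any ranking, managing each species whose cost fits
the remaining budget and skipping unaffordable ones.

## Comparison pipeline

`run_comparison` draws a fresh scenario per iteration (risks and weights
jointly, costs too under the random cost model) from a sub-seed derived via
`SeedSequence(master, web_index, iteration)`, fixes the budget at a fraction
of total management cost (default 25%), lets every method choose a strategy,
and scores all of them with one shared evaluator on common random numbers.
Structural indices are ranked once per web; scenario-dependent ones (ROI,
weighted centralities, random) re-rank per iteration. "Optimal" switches to
greedy above 14 species. Competition ranking gives the best method rank *m*
(the number of methods), ties share a rank, and the next distinct value
takes the next integer down. Trophic investment divides per-level management
counts by level occupancy and normalizes across levels.

## Problem sizes in the shipped checks

The calibration script regenerates 20 webs per connectance target and ~60k
risk draws, and runs in about a second. The test suite cross-validates
elimination against enumeration on 200 random managed webs (n ≤ 12),
measures the greedy-vs-optimal gap on another 200 (budget 25%; gap median
must stay ≤ 1%), and runs the directional method comparison on 5 niche webs
per connectance with 10 iterations each — Monte-Carlo backend, the scale at
which the qualitative ordering (greedy above every index) is stable.

## What the generator does and does not emulate

Generated webs reproduce the size, connectance and DAG structure of the
study systems, and the scenario draws reproduce the stated risk and
interaction-strength distributions. They do not emulate empirical degree
correlations, compartmentalization, body-size-ordered interaction strengths,
or any correlation between risk and trophic position — so passing tests
demonstrate correctness of the machinery and robustness of the qualitative
method ordering on niche-model webs, not quantitative predictions for any
real ecosystem. Real webs in the two supported plain-text dialects drop in
wherever generated webs are used.

## Known limitations

* One directional expectation is *not* reproduced: ROI does not underperform
  the random baseline here. Under this model the value gain from managing a
  species increases with its drawn risk while indirect effects are
  uncorrelated with it, so risk-first selection cannot do worse than uniform
  selection in expectation; the corresponding check is left failing rather
  than redefining the index, and the test suite documents the measured
  ordering (ROI is in fact among the strongest indices on generated webs).
* Exhaustive search is exponential; beyond ~20 species only the greedy path
  is available, and its near-optimality is verified empirically, not
  guaranteed (V is monotone but not submodular in general).
* Cyclic webs (including cannibalism) are out of scope by model choice, as
  are biomass flows, temporal dynamics, and learning conditional
  probabilities from occurrence data.
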