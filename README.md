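# foodwebopt

Conservation managers rarely have the budget to protect every species in an
ecosystem, and food-web structure means that protecting one species changes
the survival prospects of others: a consumer whose resources collapse is lost
to secondary extinction no matter how much is invested in it directly.
`foodwebopt` is a toolkit for deciding *which* species to manage in a trophic
network under a budget. It is aimed at quantitative ecologists and
conservation decision scientists who want to move beyond single-species
prioritization rules.

## The model

A food web is a directed acyclic graph whose edges point from resource to
consumer. Species persistence over a 20-year horizon is modelled as a
Bayesian belief network: each species *i* is a binary node whose parents are
its prey set *F_i*. With baseline extinction risk *e_i* and prey-dependence
weights *w_ij*, the conditional persistence probability given the surviving
prey subset *f_i* is

```
p_i(f_i) = (1 - e_i) * Σ_{j∈f_i} w_ij / Σ_{j∈F_i} w_ij      (consumers)
p_i      = 1 - e_i                                           (basal species)
```

so a consumer that loses its whole diet dies with certainty, and one with its
full diet persists with probability 1 − *e_i*. Managing species *i*
(action *a_i* = 1) rescales its extinction chance by (1 − η); with full
effectiveness (η = 1) a managed species with at least one surviving resource
cannot go extinct. A management strategy **a** must satisfy the budget
constraint Σ *c_i a_i* ≤ *B*, and its value is the expected utility-weighted
number of survivors

```
V(a) = Σ_i U_i · q_i(x_i = 1 | a)
```

with the marginals *q_i* computed by exact enumeration, variable elimination,
or seeded ancestral Monte-Carlo sampling. The package finds the optimal
strategy by exhaustive search over affordable subsets (small webs), a greedy
forward-selection heuristic (any size), and benchmarks both against twelve
prioritization indices from network theory — node degree, (weighted)
betweenness and closeness centrality, Jordán's keystone index, a modified
PageRank with a detritus-loop root node, dominator-tree bottleneck scores,
cascading-extinction counts, bottom-up prioritization, return-on-investment
and a random baseline. Study webs are generated with the Williams–Martinez
niche model, adjusted to be acyclic and cannibalism-free, with scenario
parameters drawn as *e_i* ~ Beta(2, 8) and *w_ij* ~ LogNormal(−3.0, 1.5).

## Worked example

```python
from foodwebopt import (NicheParams, generate_niche_web, draw_scenario,
                        greedy_strategy, pagerank_index, select_under_budget,
                        expected_value)

web = generate_niche_web(NicheParams(n=30, C_target=0.1, seed=1))
scenario = draw_scenario(web, seed=1)          # e ~ Beta(2,8), w ~ LogNormal
budget = 0.25 * scenario.total_cost            # manage a quarter of the web

best = greedy_strategy(web, scenario, budget)
print(sorted(best.strategy.managed), round(best.value, 2))

ranking = pagerank_index(web)
chosen = select_under_budget(ranking, scenario, budget)
print(round(expected_value(web, scenario, chosen), 2))
```

prints

```
['S02', 'S03', 'S08', 'S09', 'S15', 'S24', 'S29'] 24.28
21.95
```

i.e. with a budget covering 7 of 30 species, the greedy strategy is expected
to keep 24.28 species alive at the horizon, while managing the top-PageRank
species keeps 21.95 — the gap is the price of ranking species by structure
alone rather than by the probabilistic impact of protection. The same
comparison across many webs, methods and scenario draws is automated by
`foodwebopt.experiments.run_comparison` (or `foodwebopt compare` on the
command line), which also reports per-iteration competition ranks and the
trophic levels each method invests in.

A CLI mirrors the library: `foodwebopt generate`, `rank`, `optimize` and
`compare --config cfg.yaml`.

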