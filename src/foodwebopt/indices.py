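"""Network-theoretic species prioritization indices and budgeted selection.

Each index returns a :class:`Ranking` — a full ordering of the species, best
first, with the raw scores and the polarity ("higher is better" or not)
recorded so callers never have to guess.  Ties are always broken by
lexicographic species label.

Centralities are computed on the undirected view of the web; their weighted
variants use the prey-dependence weights with link length 1/w (a strong
dependence is a short distance, the Opsahl convention).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import FoodWeb, FoodWebError, basal_species, trophic_levels, validate_web
from .generators import Scenario
from .bbn import ManagementStrategy

__all__ = [
    "Ranking",
    "degree_index",
    "centrality_index",
    "keystone_index",
    "pagerank_index",
    "dominator_index",
    "cascade_index",
    "bottom_up_index",
    "roi_index",
    "random_index",
    "select_under_budget",
    "INDEX_BUILDERS",
]


@dataclass(frozen=True)
class Ranking:
    """A full prioritization of the species of one web."""

    method: str
    order: tuple[str, ...]
    scores: dict[str, float]
    higher_is_better: bool = True
    deterministic: bool = True


def _make_ranking(web, scores, method, higher=True, deterministic=True, tiebreak=None):
    sign = -1.0 if higher else 1.0
    if tiebreak is None:
        key = lambda s: (sign * scores[s], s)
    else:
        key = lambda s: (sign * scores[s],) + tuple(tiebreak(s)) + (s,)
    order = tuple(sorted(web.species_ids, key=key))
    return Ranking(method, order, {s: float(v) for s, v in scores.items()},
                   higher_is_better=higher, deterministic=deterministic)


def degree_index(web: FoodWeb) -> Ranking:
    """Node degree: number of predators plus prey; higher is better."""
    scores = {s: len(web.prey_of(s)) + len(web.predators_of(s))
              for s in web.species_ids}
    return _make_ranking(web, scores, "degree")


def centrality_index(
    web: FoodWeb,
    kind: str = "betweenness",
    weighted: bool = False,
    scenario: Scenario | None = None,
) -> Ranking:
    """Betweenness or closeness centrality on the undirected web.

    Betweenness counts the fraction of shortest paths through a species
    (unnormalized pair counts).  Closeness is reach/((n-1) * sum of shortest
    path lengths to reachable species), which on a connected web reduces to
    the inverse total distance and degrades to 0 for isolated species.
    """
    if weighted and scenario is None:
        raise FoodWebError("weighted centrality requires a scenario for w_ij")
    g = nx.Graph()
    g.add_nodes_from(web.species_ids)
    for r, c in sorted(web.links):
        length = 1.0 / scenario.w[(r, c)] if weighted else 1.0
        # parallel up/down links collapse; keep the shortest length
        if g.has_edge(r, c):
            length = min(length, g[r][c]["length"])
        g.add_edge(r, c, length=length)
    dist = "length" if weighted else None
    if kind == "betweenness":
        scores = nx.betweenness_centrality(g, normalized=False, weight=dist)
    elif kind == "closeness":
        n = web.n
        scores = {}
        for s in web.species_ids:
            lengths = nx.single_source_dijkstra_path_length(g, s, weight=dist or "x")
            reach = len(lengths) - 1
            total = sum(lengths.values())
            scores[s] = 0.0 if reach == 0 else reach / ((n - 1) * total)
    else:
        raise FoodWebError(f"unknown centrality kind {kind!r}")
    name = ("weighted_" if weighted else "") + kind
    return _make_ranking(web, scores, name, deterministic=not weighted)


def keystone_index(web: FoodWeb) -> Ranking:
    """Jordán's keystone index K = Kb + Kt.

    Kb_i spreads importance down from consumers: each consumer c with d_c
    prey passes (1 + Kb_c)/d_c to every one of its prey.  Kt_i mirrors it
    upward through prey: each prey e with f_e predators passes (1 + Kt_e)/f_e
    to every predator.  Both recursions are well defined on a DAG.
    """
    if not validate_web(web).is_valid:
        raise FoodWebError("keystone index requires a valid (acyclic) web")
    kb: dict[str, float] = {}
    kt: dict[str, float] = {}
    topo = list(nx.topological_sort(web.graph()))
    for s in reversed(topo):  # consumers before their prey
        kb[s] = sum((1.0 + kb[c]) / len(web.prey_of(c))
                    for c in web.predators_of(s))
    for s in topo:  # prey before their consumers
        kt[s] = sum((1.0 + kt[e]) / len(web.predators_of(e))
                    for e in web.prey_of(s))
    scores = {s: kb[s] + kt[s] for s in web.species_ids}
    return _make_ranking(web, scores, "keystone")


def pagerank_index(web: FoodWeb) -> Ranking:
    """Modified PageRank for food webs (Allesina & Pascual).

    Links are reversed so importance flows from consumers to the resources
    that support them; a root node closes the loop (every basal species
    points to the root, the root redistributes to all species), making the
    chain irreducible without any teleportation damping.  The score is the
    stationary distribution of the resulting column-stochastic walk, with the
    root discarded and the rest renormalized to sum to 1.
    """
    ids = sorted(web.species_ids)
    n = len(ids)
    pos = {s: i for i, s in enumerate(ids)}
    root = n
    out: list[list[int]] = [[] for _ in range(n + 1)]
    for r, c in web.links:
        out[pos[c]].append(pos[r])  # reversed: consumer -> resource
    for s in basal_species(web):
        out[pos[s]].append(root)
    out[root] = list(range(n))
    P = np.zeros((n + 1, n + 1))
    for j, targets in enumerate(out):
        for i in targets:
            P[i, j] = 1.0 / len(targets)
    # stationary distribution: solve (I - P) pi = 0 with sum(pi) = 1
    A = np.eye(n + 1) - P
    A[-1, :] = 1.0
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi = np.linalg.solve(A, b)
    species_pi = pi[:n]
    species_pi = species_pi / species_pi.sum()
    scores = {s: species_pi[pos[s]] for s in ids}
    return _make_ranking(web, scores, "pagerank")


def dominator_index(web: FoodWeb) -> Ranking:
    """Dominator-tree energy-bottleneck score.

    A virtual root feeds every basal species; a species dominates another
    when every energy path from the root to the latter passes through the
    former.  The score is the number of species strictly dominated (the
    dominator-tree subtree size minus one); species unreachable from the root
    score 0 and count as dominated only by the root.
    """
    g = web.graph().copy()
    root = "__root__"
    while root in g:
        root += "_"
    g.add_node(root)
    for s in sorted(basal_species(web)):
        g.add_edge(root, s)
    idom = nx.immediate_dominators(g, root)
    children: dict[str, list[str]] = {}
    for v, d in idom.items():
        if v != d:
            children.setdefault(d, []).append(v)
    sizes: dict[str, int] = {}

    def subtree(v: str) -> int:
        if v not in sizes:
            sizes[v] = 1 + sum(subtree(c) for c in children.get(v, ()))
        return sizes[v]

    subtree(root)
    scores = {s: float(sizes.get(s, 1) - 1) for s in web.species_ids}
    return _make_ranking(web, scores, "dominator")


def cascade_index(web: FoodWeb) -> Ranking:
    """Cascading-extinction (topological removal) score.

    Remove each species in turn, then iteratively remove every species that
    was a consumer in the *original* web and has no prey left; the score is
    the number of surviving species.  Fewer survivors means the removed
    species was more important, so lower is better.
    """
    originally_basal = basal_species(web)
    scores: dict[str, float] = {}
    for target in web.species_ids:
        alive = set(web.species_ids) - {target}
        changed = True
        while changed:
            changed = False
            for s in list(alive):
                if s in originally_basal:
                    continue
                if not any(p in alive for p in web.prey_of(s)):
                    alive.discard(s)
                    changed = True
        scores[target] = float(len(alive))
    return _make_ranking(web, scores, "cascade", higher=False)


def bottom_up_index(web: FoodWeb) -> Ranking:
    """Bottom-up prioritization: lowest trophic level first; within a level,
    the species with the most predators first."""
    levels = trophic_levels(web)
    npred = {s: len(web.predators_of(s)) for s in web.species_ids}
    # score encodes the primary sort only; predator count is the tiebreak
    scores = {s: float(levels[s]) for s in web.species_ids}
    return _make_ranking(web, scores, "bottom_up", higher=False,
                         tiebreak=lambda s: (-npred[s],))


def roi_index(web: FoodWeb, scenario: Scenario) -> Ranking:
    """Return-on-investment: risk reduction per unit cost, eta*e_i/c_i.
    With equal costs and effectiveness this orders species by initial
    extinction risk."""
    scores = {}
    for s in web.species_ids:
        if scenario.c[s] <= 0:
            raise FoodWebError(f"ROI undefined for zero-cost species {s}")
        scores[s] = scenario.eta * scenario.e[s] / scenario.c[s]
    return _make_ranking(web, scores, "roi", deterministic=False)


def random_index(web: FoodWeb, seed: int | None = None) -> Ranking:
    """Uniform random permutation of the species (seeded)."""
    rng = np.random.default_rng(seed)
    ids = sorted(web.species_ids)
    order = tuple(str(s) for s in rng.permutation(ids))
    scores = {s: float(len(ids) - order.index(s)) for s in ids}
    return Ranking("random", order, scores, higher_is_better=True,
                   deterministic=False)


def select_under_budget(
    ranking: Ranking, scenario: Scenario, budget: float
) -> ManagementStrategy:
    """Walk the ranked list, managing every species whose cost still fits the
    remaining budget; unaffordable species are skipped, not terminal."""
    managed = []
    remaining = budget
    for s in ranking.order:
        if scenario.c[s] <= remaining:
            managed.append(s)
            remaining -= scenario.c[s]
    return ManagementStrategy(managed)


def _structural(builder):
    return lambda web, scenario, seed: builder(web)


#: method name -> builder(web, scenario, seed) for every ranked heuristic
INDEX_BUILDERS = {
    "degree": _structural(degree_index),
    "betweenness": _structural(lambda w: centrality_index(w, "betweenness")),
    "closeness": _structural(lambda w: centrality_index(w, "closeness")),
    "weighted_betweenness": lambda web, scenario, seed: centrality_index(
        web, "betweenness", weighted=True, scenario=scenario
    ),
    "weighted_closeness": lambda web, scenario, seed: centrality_index(
        web, "closeness", weighted=True, scenario=scenario
    ),
    "keystone": _structural(keystone_index),
    "pagerank": _structural(pagerank_index),
    "dominator": _structural(dominator_index),
    "cascade": _structural(cascade_index),
    "bottom_up": _structural(bottom_up_index),
    "roi": lambda web, scenario, seed: roi_index(web, scenario),
    "random": lambda web, scenario, seed: random_index(web, seed),
}
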