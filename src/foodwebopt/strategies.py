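"""Strategy valuation, exhaustive optimal search, greedy heuristic and
feasible-strategy counting.

The value of a management strategy a is the expected utility-weighted number
of surviving species, V(a) = sum_i U_i * q_i(x_i = 1 | a), with the marginals
q taken from the persistence network.  The optimal strategy maximizes V over
every subset of species whose total management cost fits the budget; the
greedy heuristic adds one affordable species at a time, never removing any.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .bbn import (
    MC_SAMPLES,
    ManagementStrategy,
    MarginalResult,
    _montecarlo_marginals,
    build_model,
    marginal_persistence,
)
from .core import FoodWeb, FoodWebError
from .generators import Scenario

__all__ = [
    "StrategyResult",
    "StrategyEvaluator",
    "expected_value",
    "optimal_strategy",
    "greedy_strategy",
    "count_feasible_strategies",
]

#: exhaustive search is refused above this many species
OPTIMAL_GUARD = 20


@dataclass(frozen=True)
class StrategyResult:
    strategy: ManagementStrategy
    value: float
    marginals: MarginalResult
    evaluations: int


class StrategyEvaluator:
    """Scores management strategies on one (web, scenario) pair.

    Marginal evaluations are cached by managed set, and the Monte-Carlo
    backend reuses one pre-drawn matrix of uniforms (common random numbers)
    so that comparisons between strategies are not blurred by sampling noise.
    ``auto`` resolves to exact enumeration for n <= 16 and Monte-Carlo above.
    """

    def __init__(
        self,
        web: FoodWeb,
        scenario: Scenario,
        backend: str = "auto",
        mc_samples: int = MC_SAMPLES,
        seed: int | None = None,
    ):
        if not scenario.aligned_to(web):
            raise FoodWebError("scenario is not aligned to the web")
        self.web = web
        self.scenario = scenario
        if backend == "auto":
            backend = "enumeration" if web.n <= 16 else "montecarlo"
        self.backend = backend
        self.mc_samples = mc_samples
        self.seed = seed
        self._uniforms = None
        if backend == "montecarlo":
            rng = np.random.default_rng(seed)
            self._uniforms = rng.random((mc_samples, web.n))
        self._U = np.array([scenario.U[s] for s in web.species_ids])
        self._cache: dict[frozenset[str], tuple[float, MarginalResult]] = {}
        self.evaluations = 0

    def evaluate(self, managed) -> tuple[float, MarginalResult]:
        """V(a) and the marginals for the given managed set."""
        key = frozenset(managed)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        model = build_model(self.web, self.scenario, ManagementStrategy(key))
        if self.backend == "montecarlo":
            q, se = _montecarlo_marginals(
                model, self.mc_samples, self.seed, uniforms=self._uniforms
            )
            marg = MarginalResult(self.web.species_ids, q, "montecarlo", mc_stderr=se)
        else:
            marg = marginal_persistence(model, backend=self.backend, seed=self.seed)
        value = float(self._U @ marg.q)
        self.evaluations += 1
        self._cache[key] = (value, marg)
        return value, marg


def expected_value(
    web: FoodWeb,
    scenario: Scenario,
    strategy: ManagementStrategy,
    backend: str = "auto",
    mc_samples: int = MC_SAMPLES,
    seed: int | None = None,
) -> float:
    """V(a) for a single strategy; feasibility is deliberately not checked."""
    ev = StrategyEvaluator(web, scenario, backend, mc_samples, seed)
    value, _ = ev.evaluate(strategy.managed)
    return value


def _label_order(web: FoodWeb) -> list[str]:
    return sorted(web.species_ids)


def optimal_strategy(
    web: FoodWeb,
    scenario: Scenario,
    budget: float,
    backend: str = "auto",
    guard: int = OPTIMAL_GUARD,
    evaluator: StrategyEvaluator | None = None,
) -> StrategyResult:
    """Exhaustive search over every affordable managed set.

    Subsets are enumerated by size, then lexicographically by species label,
    so the first maximum found is the lexicographically smallest optimal set.
    Sizes stop at the largest k whose k cheapest species still fit the
    budget.  Refused for n above *guard* (use :func:`greedy_strategy`).
    """
    if web.n > guard:
        raise FoodWebError(
            f"exhaustive search refused for n={web.n} > {guard}; use greedy_strategy"
        )
    ev = evaluator or StrategyEvaluator(web, scenario, backend)
    species = _label_order(web)
    costs = sorted(scenario.c[s] for s in species)
    kmax = 0
    acc = 0.0
    for cst in costs:
        if acc + cst <= budget:
            acc += cst
            kmax += 1
    best_set: frozenset[str] | None = None
    best_value = -math.inf
    scored = 0
    for k in range(kmax + 1):
        for combo in combinations(species, k):
            if sum(scenario.c[s] for s in combo) > budget:
                continue
            value, _ = ev.evaluate(combo)
            scored += 1
            if value > best_value:
                best_value = value
                best_set = frozenset(combo)
    value, marg = ev.evaluate(best_set)
    return StrategyResult(ManagementStrategy(best_set), value, marg, scored)


def greedy_strategy(
    web: FoodWeb,
    scenario: Scenario,
    budget: float,
    backend: str = "auto",
    evaluator: StrategyEvaluator | None = None,
) -> StrategyResult:
    """Greedy forward selection: repeatedly add the affordable species whose
    addition raises V(a) the most (ties to the lexicographically first
    label), until no remaining species fits the leftover budget.  Species are
    never removed once added."""
    ev = evaluator or StrategyEvaluator(web, scenario, backend)
    managed: set[str] = set()
    spent = 0.0
    scored = 0
    while True:
        candidates = [
            s
            for s in _label_order(web)
            if s not in managed and scenario.c[s] <= budget - spent
        ]
        if not candidates:
            break
        best_s, best_value = None, -math.inf
        for s in candidates:
            value, _ = ev.evaluate(managed | {s})
            scored += 1
            if value > best_value:
                best_s, best_value = s, value
        managed.add(best_s)
        spent += scenario.c[best_s]
    value, marg = ev.evaluate(managed)
    return StrategyResult(ManagementStrategy(managed), value, marg, scored)


def count_feasible_strategies(
    n: int,
    costs,
    budget: float,
    mode: str = "at_most",
    k: int | None = None,
) -> int:
    """Count management strategies, in exact integer arithmetic.

    ``at_most``
        Subsets of the n species with total cost <= budget (dynamic program
        over integer costs; includes the empty strategy).
    ``exactly_k``
        Subsets of size exactly *k* with total cost <= budget.  With unit
        costs and a sufficient budget this is the binomial coefficient
        C(n, k) — e.g. managing half of a 30-species web admits
        C(30, 15) = 155,117,520 alternatives.
    """
    if np.isscalar(costs):
        costs = [costs] * n
    costs = [int(c) for c in costs]
    if len(costs) != n or any(c < 0 for c in costs):
        raise ValueError("costs must be n non-negative integers")
    if mode == "exactly_k":
        if k is None:
            raise ValueError("mode='exactly_k' requires k")
        if set(costs) == {1} and budget >= k:
            return math.comb(n, k)
    elif mode != "at_most":
        raise ValueError(f"unknown mode {mode!r}")
    cap = int(min(budget, sum(costs)))
    if budget < 0:
        return 0
    # ways[j][c] = number of subsets of size j and total cost c
    ways = [[0] * (cap + 1) for _ in range(n + 1)]
    ways[0][0] = 1
    for cost in costs:
        for j in range(n - 1, -1, -1):
            row, nxt = ways[j], ways[j + 1]
            for c in range(cap - cost, -1, -1):
                if row[c]:
                    nxt[c + cost] += row[c]
    if mode == "at_most":
        return sum(sum(row) for row in ways)
    return sum(ways[k])
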