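"""Species-persistence Bayesian belief network and its inference backends.

Each species i is a binary node (extant / extinct at the 20-year horizon)
whose parents are its prey.  The conditional persistence law is linear in the
prey-dependence weights: with prey subset f present out of the full diet F,

    unmanaged, non-basal:  p_i(f) = (1 - e_i) * sum_{j in f} w_ij / sum_{j in F} w_ij
    unmanaged, basal:      p_i     = 1 - e_i                (independent of prey)
    managed, f nonempty or basal:  p = 1 - (1 - eta) * (1 - p_unmanaged)
    managed, non-basal, f empty:   p = 0   (no food: management cannot help)

so with full effectiveness (eta = 1) a managed species with at least one prey
present cannot go extinct, while no species survives without resources.

Three marginalization backends are provided and cross-check one another:

``enumeration``
    Sums the joint over all 2**n community states (chunked, vectorized);
    exact, the ground-truth oracle for small webs.
``elimination``
    Exact variable elimination with greedy min-fill ordering; falls back to
    Monte-Carlo when the induced factor width exceeds a cap.
``montecarlo``
    Seeded ancestral (topological-order) forward sampling with per-species
    standard errors.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import FoodWeb, FoodWebError, basal_species, validate_web
from .generators import Scenario

__all__ = [
    "ManagementStrategy",
    "BBNModel",
    "MarginalResult",
    "build_model",
    "marginal_persistence",
    "closed_form_unmanaged_marginals",
]

log = logging.getLogger(__name__)

#: largest n for which full 2**n enumeration may be requested
ENUMERATION_GUARD = 22
#: largest factor width (number of binary variables) allowed in elimination
WIDTH_CAP = 22
#: default number of Monte-Carlo forward samples
MC_SAMPLES = 20_000

_STATE_CHUNK = 1 << 16


@dataclass(frozen=True)
class ManagementStrategy:
    """A binary choice of species to manage, stored as the managed set."""

    managed: frozenset[str]

    def __init__(self, managed=()):
        object.__setattr__(self, "managed", frozenset(managed))

    def cost(self, scenario: Scenario) -> float:
        return float(sum(scenario.c[s] for s in self.managed))

    def feasible(self, scenario: Scenario, budget: float) -> bool:
        return self.cost(scenario) <= budget

    def vector(self, web: FoodWeb) -> np.ndarray:
        """0/1 action vector aligned to ``web.species_ids``."""
        return np.array([int(s in self.managed) for s in web.species_ids])

    def __len__(self) -> int:
        return len(self.managed)


class BBNModel:
    """Conditional persistence tables for one (web, scenario, strategy) triple.

    The conditional law is represented functionally through the prey weight
    sums; per-species tables of size 2**|F_i| are only materialized by the
    elimination backend, and only for the species it needs.
    """

    def __init__(self, web: FoodWeb, scenario: Scenario, strategy: ManagementStrategy):
        report = validate_web(web)
        if not report.is_valid:
            raise FoodWebError("invalid web: " + "; ".join(report.violations))
        if not scenario.aligned_to(web):
            raise FoodWebError("scenario is not aligned to the web's species/links")
        unknown = strategy.managed - set(web.species_ids)
        if unknown:
            raise FoodWebError(f"strategy manages unknown species: {sorted(unknown)}")
        self.web = web
        self.scenario = scenario
        self.strategy = strategy
        ids = web.species_ids
        self.index = {s: i for i, s in enumerate(ids)}
        self.topo_order = [
            self.index[s] for s in nx.topological_sort(web.graph())
        ]
        self.e = np.array([scenario.e[s] for s in ids])
        self.managed = np.array([s in strategy.managed for s in ids])
        basal = basal_species(web)
        self.basal = np.array([s in basal for s in ids])
        self.eta = scenario.eta
        self.prey_idx: list[np.ndarray] = []
        self.prey_w: list[np.ndarray] = []
        self.wsum = np.zeros(len(ids))
        for i, s in enumerate(ids):
            prey = web.prey_of(s)
            self.prey_idx.append(np.array([self.index[p] for p in prey], dtype=int))
            w = np.array([scenario.w[(p, s)] for p in prey])
            self.prey_w.append(w)
            self.wsum[i] = w.sum()
            if prey and self.wsum[i] <= 0:
                raise FoodWebError(f"zero prey-weight sum for species {s}")

    @property
    def n(self) -> int:
        return self.web.n

    def conditional_persistence(self, species: str, present_prey) -> float:
        """p(species persists | the given prey subset is present)."""
        i = self.index[species]
        present = frozenset(present_prey)
        full = set(self.web.prey_of(species))
        if not present <= full:
            raise FoodWebError(f"{sorted(present - full)} are not prey of {species}")
        if self.basal[i]:
            p = 1.0 - self.e[i]
        elif not present:
            return 0.0  # no food, managed or not
        else:
            frac = sum(self.scenario.w[(p, species)] for p in present) / self.wsum[i]
            p = (1.0 - self.e[i]) * frac
        if self.managed[i]:
            p = 1.0 - (1.0 - self.eta) * (1.0 - p)
        return float(p)

    def _persistence_given_states(self, i: int, x: np.ndarray) -> np.ndarray:
        """Vector p_i over rows of the 0/1 state matrix ``x`` (columns =
        species, aligned to web order)."""
        if self.basal[i]:
            p = np.full(x.shape[0], 1.0 - self.e[i])
            can_eat = None
        else:
            frac = x[:, self.prey_idx[i]].astype(float) @ self.prey_w[i] / self.wsum[i]
            p = (1.0 - self.e[i]) * frac
            can_eat = frac > 0
        if self.managed[i]:
            boosted = p + self.eta * (1.0 - p)
            p = boosted if can_eat is None else np.where(can_eat, boosted, p)
        return p


@dataclass(frozen=True)
class MarginalResult:
    """Per-species marginal persistence probabilities q_i(x_i = 1 | a)."""

    species: tuple[str, ...]
    q: np.ndarray
    method: str
    mc_stderr: np.ndarray | None = None

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.species, map(float, self.q)))


def build_model(
    web: FoodWeb, scenario: Scenario, strategy: ManagementStrategy | None = None
) -> BBNModel:
    """Assemble the persistence network for a (web, scenario, strategy)."""
    return BBNModel(web, scenario, strategy or ManagementStrategy())


def marginal_persistence(
    model: BBNModel,
    backend: str = "auto",
    mc_samples: int = MC_SAMPLES,
    seed: int | None = None,
    enum_guard: int = ENUMERATION_GUARD,
    width_cap: int = WIDTH_CAP,
) -> MarginalResult:
    """Marginal persistence probability of every species under the model.

    ``auto`` uses enumeration for n <= 16, otherwise exact elimination if the
    estimated induced width fits under ``width_cap``, otherwise Monte-Carlo.
    """
    if backend == "auto":
        if model.n <= 16:
            backend = "enumeration"
        elif _estimated_width(model) <= width_cap:
            backend = "elimination"
        else:
            backend = "montecarlo"
    if backend == "enumeration":
        if model.n > enum_guard:
            raise FoodWebError(
                f"enumeration over 2**{model.n} states refused (guard {enum_guard});"
                " use elimination or montecarlo"
            )
        q = _enumeration_marginals(model)
        return MarginalResult(model.web.species_ids, q, "enumeration")
    if backend == "elimination":
        try:
            q = _elimination_marginals(model, width_cap)
            return MarginalResult(model.web.species_ids, q, "elimination")
        except _WidthExceeded as exc:
            log.warning(
                "elimination factor width %d exceeds cap %d; "
                "falling back to Monte-Carlo", exc.width, width_cap
            )
            backend = "montecarlo"
    if backend == "montecarlo":
        q, se = _montecarlo_marginals(model, mc_samples, seed)
        return MarginalResult(model.web.species_ids, q, "montecarlo", mc_stderr=se)
    raise ValueError(f"unknown backend {backend!r}")


def closed_form_unmanaged_marginals(web: FoodWeb, scenario: Scenario) -> MarginalResult:
    """Exact marginals for the *unmanaged* web by linearity of expectation.

    Without management every conditional law is linear in the prey presence
    indicators, so q_i = (1 - e_i) * sum_j w_ij q_j / sum_j w_ij propagated in
    topological order equals the exact marginal.  Management breaks linearity
    (a managed species with no food still dies), so this closed form serves as
    an independent oracle for the baseline only.
    """
    model = build_model(web, scenario, ManagementStrategy())
    q = np.zeros(model.n)
    for i in model.topo_order:
        if model.basal[i]:
            q[i] = 1.0 - model.e[i]
        else:
            q[i] = (1.0 - model.e[i]) * (
                q[model.prey_idx[i]] @ model.prey_w[i] / model.wsum[i]
            )
    return MarginalResult(web.species_ids, q, "closed_form")


# ---------------------------------------------------------------------------
# enumeration backend
# ---------------------------------------------------------------------------

def _state_matrix(n: int, start: int, stop: int) -> np.ndarray:
    states = np.arange(start, stop, dtype=np.int64)
    return (states[:, None] >> np.arange(n)) & 1


def _enumeration_marginals(model: BBNModel) -> np.ndarray:
    n = model.n
    q = np.zeros(n)
    total = 1 << n
    for start in range(0, total, _STATE_CHUNK):
        x = _state_matrix(n, start, min(start + _STATE_CHUNK, total))
        joint = np.ones(x.shape[0])
        for i in range(n):
            p = model._persistence_given_states(i, x)
            joint *= np.where(x[:, i] == 1, p, 1.0 - p)
        q += joint @ x
    return q


# ---------------------------------------------------------------------------
# elimination backend
# ---------------------------------------------------------------------------

class _WidthExceeded(Exception):
    def __init__(self, width: int):
        self.width = width


def _cpt_factor(model: BBNModel, i: int) -> tuple[tuple[int, ...], np.ndarray]:
    """CPT of species i as a factor over (prey..., i), axes of size 2."""
    prey = tuple(int(j) for j in model.prey_idx[i])
    k = len(prey)
    x = np.zeros((1 << k, model.n), dtype=np.int64)
    if k:
        # bits MSB-first so that a C-order reshape puts prey[0] on axis 0
        states = np.arange(1 << k, dtype=np.int64)
        x[:, list(prey)] = (states[:, None] >> np.arange(k - 1, -1, -1)) & 1
    p = model._persistence_given_states(i, x)
    table = np.stack([1.0 - p, p], axis=-1).reshape((2,) * k + (2,))
    return prey + (i,), table


def _multiply(f1, f2):
    v1, t1 = f1
    v2, t2 = f2
    union = tuple(sorted(set(v1) | set(v2)))
    pos = {v: ax for ax, v in enumerate(union)}

    def expand(vars_, table):
        shape = [1] * len(union)
        src = sorted(range(len(vars_)), key=lambda a: pos[vars_[a]])
        table = np.transpose(table, src)
        for ax, v in enumerate(union):
            if v in vars_:
                shape[ax] = 2
        return table.reshape(shape)

    return union, expand(v1, t1) * expand(v2, t2)


def _min_fill_order(domains: list[set[int]], keep: int) -> list[int]:
    """Greedy min-fill elimination order over the factor interaction graph."""
    adj: dict[int, set[int]] = {}
    for dom in domains:
        for v in dom:
            adj.setdefault(v, set()).update(dom - {v})
    order = []
    remaining = set(adj) - {keep}
    while remaining:
        best, best_fill = None, None
        for v in sorted(remaining):
            nbrs = adj[v]
            fill = sum(
                1
                for a, b in itertools.combinations(sorted(nbrs), 2)
                if b not in adj[a]
            )
            if best_fill is None or fill < best_fill:
                best, best_fill = v, fill
        nbrs = adj[best]
        for a, b in itertools.combinations(sorted(nbrs), 2):
            adj[a].add(b)
            adj[b].add(a)
        for u in nbrs:
            adj[u].discard(best)
        del adj[best]
        remaining.discard(best)
        order.append(best)
    return order


def _estimated_width(model: BBNModel) -> int:
    """Induced width estimate from a min-fill simulation (in variables)."""
    domains = [
        set(int(j) for j in model.prey_idx[i]) | {i} for i in range(model.n)
    ]
    adj: dict[int, set[int]] = {i: set() for i in range(model.n)}
    for dom in domains:
        for v in dom:
            adj[v].update(dom - {v})
    remaining = set(range(model.n))
    width = 1
    while remaining:
        v = min(remaining, key=lambda u: len(adj[u] & remaining))
        nbrs = adj[v] & remaining - {v}
        width = max(width, len(nbrs) + 1)
        for a in nbrs:
            adj[a].update(nbrs - {a})
            adj[a].discard(v)
        remaining.discard(v)
    return width


def _elimination_marginals(model: BBNModel, width_cap: int) -> np.ndarray:
    n = model.n
    cpts = [_cpt_factor(model, i) for i in range(n)]
    q = np.zeros(n)
    for target in range(n):
        factors = list(cpts)
        order = _min_fill_order([set(v) for v, _ in factors], keep=target)
        for v in order:
            bucket = [f for f in factors if v in f[0]]
            factors = [f for f in factors if v not in f[0]]
            prod = bucket[0]
            for f in bucket[1:]:
                prod = _multiply(prod, f)
                if len(prod[0]) > width_cap:
                    raise _WidthExceeded(len(prod[0]))
            axis = prod[0].index(v)
            factors.append(
                (prod[0][:axis] + prod[0][axis + 1:], prod[1].sum(axis=axis))
            )
        result = factors[0]
        for f in factors[1:]:
            result = _multiply(result, f)
        table = result[1].reshape(2)
        q[target] = table[1] / table.sum()
    return q


# ---------------------------------------------------------------------------
# Monte-Carlo backend
# ---------------------------------------------------------------------------

def _montecarlo_marginals(
    model: BBNModel,
    samples: int,
    seed: int | None,
    uniforms: np.ndarray | None = None,
):
    """Ancestral forward sampling in topological order.

    ``uniforms`` may carry a pre-drawn (samples, n) matrix of U(0,1) numbers
    so that several strategies can be scored on common random numbers.
    """
    n = model.n
    if uniforms is None:
        rng = np.random.default_rng(seed)
        uniforms = rng.random((samples, n))
    x = np.zeros((uniforms.shape[0], n), dtype=np.int64)
    for col, i in enumerate(model.topo_order):
        p = model._persistence_given_states(i, x)
        x[:, i] = uniforms[:, col] < p
    q = x.mean(axis=0)
    se = np.sqrt(q * (1.0 - q) / uniforms.shape[0])
    return q, se
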