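"""Niche-model food-web generation and stochastic scenario sampling.

The generator implements the Williams–Martinez niche model with the standard
acyclicity adjustment for Bayesian-network use: species are relabelled by
ascending niche value and only links from a lower- to a strictly higher-niche
species are kept, which guarantees a DAG with no cannibalism.  Webs are
rejection-sampled until the realized directed connectance L/n**2 lies within a
relative tolerance of the target.

A :class:`Scenario` bundles the stochastic ecological parameters of one
simulation draw: per-species baseline 20-year extinction probabilities
(Beta-distributed), per-link prey-dependence weights (lognormal), management
costs, species utilities and the management effectiveness eta.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .core import FoodWeb, validate_web

__all__ = [
    "NicheParams",
    "Scenario",
    "GenerationError",
    "generate_niche_web",
    "draw_scenario",
    "scenario_from_config",
    "write_scenario",
    "read_scenario",
]

#: Default Beta shape parameters: mean extinction risk 2/(2+8) = 0.2 over the
#: 20-year horizon (an "endangered" level of threat).  The low-risk variant
#: uses beta=38 for a mean of 0.05.
DEFAULT_ALPHA = 2.0
DEFAULT_BETA = 8.0

#: Default lognormal parameters of the prey-dependence weights w_ij.
DEFAULT_WEIGHT_LOGMEAN = -3.0
DEFAULT_WEIGHT_LOGSD = 1.5


class GenerationError(RuntimeError):
    """Rejection sampling exhausted its attempt budget."""


@dataclass(frozen=True)
class NicheParams:
    """Parameters of the niche-model generator.

    ``C_target`` is the directed connectance L/n**2 the rejection sampler
    aims for; a web is accepted when ``|C - C_target| / C_target <=
    tolerance``.
    """

    n: int = 30
    C_target: float = 0.1
    tolerance: float = 0.05
    max_attempts: int = 10_000
    seed: int | None = None

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if not 0.0 < self.C_target < 0.5:
            raise ValueError("C_target must lie in (0, 0.5)")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if self.max_attempts < 1:
            raise ValueError("max_attempts must be >= 1")


@dataclass(frozen=True)
class Scenario:
    """One stochastic draw of the ecological and economic parameters."""

    e: dict[str, float]
    w: dict[tuple[str, str], float]
    c: dict[str, float]
    U: dict[str, float]
    eta: float = 1.0

    def __post_init__(self):
        if not 0.0 < self.eta <= 1.0:
            raise ValueError("eta must lie in (0, 1]")
        for s, v in self.e.items():
            if not 0.0 < v < 1.0:
                raise ValueError(f"extinction risk for {s} must lie in (0, 1)")
        for link, v in self.w.items():
            if v <= 0:
                raise ValueError(f"prey-dependence weight for {link} must be > 0")
        for s, v in self.c.items():
            if v < 0:
                raise ValueError(f"cost for {s} must be >= 0")
        for s, v in self.U.items():
            if v <= 0:
                raise ValueError(f"utility for {s} must be > 0")

    @property
    def total_cost(self) -> float:
        return float(sum(self.c.values()))

    def aligned_to(self, web: FoodWeb) -> bool:
        """True when the scenario covers exactly the web's species and links."""
        ids = set(web.species_ids)
        return (
            set(self.e) == ids
            and set(self.c) == ids
            and set(self.U) == ids
            and set(self.w) == set(web.links)
        )


def _draw_niche_structure(n: int, C: float, rng: np.random.Generator):
    """One raw draw of niche values, diet ranges and centres (pre-adjustment).

    Returns arrays sorted by ascending niche value.  Exposed for
    distributional testing of the Beta(1, (1-2C)/(2C)) range draw.
    """
    nv = np.sort(rng.uniform(size=n))
    shape2 = (1.0 - 2.0 * C) / (2.0 * C)
    x = rng.beta(1.0, shape2, size=n)
    r = x * nv
    r[0] = 0.0  # species with the smallest niche value is basal by construction
    centre = rng.uniform(r / 2.0, nv)
    return nv, r, centre


def generate_niche_web(params: NicheParams) -> FoodWeb:
    """Generate one niche-model food web.

    Species are labelled ``S01, S02, ...`` by ascending niche value, so every
    link points from a lower to a strictly higher label.  A draw is rejected
    and redone when (a) the acyclicity adjustment empties the diet of a
    species that had drawn a non-empty one, (b) any species ends up isolated,
    (c) the web fails structural validation, or (d) the realized connectance
    misses the target beyond the relative tolerance.

    Raises
    ------
    GenerationError
        If ``max_attempts`` draws are exhausted without an accepted web.
    """
    rng = np.random.default_rng(params.seed)
    n, C = params.n, params.C_target
    width = len(str(n))
    labels = [f"S{i + 1:0{width}d}" for i in range(n)]
    for _ in range(params.max_attempts):
        nv, r, centre = _draw_niche_structure(n, C, rng)
        lo = centre - r / 2.0
        hi = centre + r / 2.0
        # raw diet of consumer i: all j with niche value inside [lo_i, hi_i]
        in_range = (nv[None, :] >= lo[:, None]) & (nv[None, :] <= hi[:, None])
        # acyclicity adjustment: keep prey strictly below the consumer's
        # niche value (removes self-links and all up-links)
        kept = in_range & (nv[None, :] < nv[:, None])
        had_diet = in_range.any(axis=1)
        if np.any(had_diet & ~kept.any(axis=1)):
            continue  # a consumer lost its whole diet: resample, don't patch
        degree = kept.sum(axis=1) + kept.sum(axis=0)
        if np.any(degree == 0):
            continue  # isolated species
        L = int(kept.sum())
        realized = L / n**2
        if abs(realized - C) / C > params.tolerance:
            continue
        cons, prey = np.nonzero(kept)
        web = FoodWeb(labels, [(labels[j], labels[i]) for i, j in zip(cons, prey)])
        if validate_web(web).is_valid:
            return web
    raise GenerationError(
        f"no acceptable web after {params.max_attempts} attempts for {params}"
    )


def draw_scenario(
    web: FoodWeb,
    alpha: float = DEFAULT_ALPHA,
    beta: float = DEFAULT_BETA,
    weight_logmean: float = DEFAULT_WEIGHT_LOGMEAN,
    weight_logsd: float = DEFAULT_WEIGHT_LOGSD,
    cost_model: str = "unit",
    eta: float = 1.0,
    seed: int | None = None,
) -> Scenario:
    """Draw a :class:`Scenario` for *web*.

    Extinction risks are i.i.d. Beta(alpha, beta) for every species,
    including basal ones; prey-dependence weights are i.i.d. lognormal over
    the links; costs are all 1 (``unit``) or i.i.d. uniform on {1,...,5}
    (``uniform_int``); utilities are 1 so that the objective counts surviving
    species.
    """
    if alpha <= 0 or beta <= 0:
        raise ValueError("Beta shape parameters must be positive")
    if weight_logsd <= 0:
        raise ValueError("weight_logsd must be positive")
    rng = np.random.default_rng(seed)
    species = list(web.species_ids)
    links = sorted(web.links)
    e = dict(zip(species, rng.beta(alpha, beta, size=len(species))))
    w = dict(
        zip(links, rng.lognormal(weight_logmean, weight_logsd, size=len(links)))
    )
    if cost_model == "unit":
        c = {s: 1.0 for s in species}
    elif cost_model == "uniform_int":
        c = dict(zip(species, rng.integers(1, 6, size=len(species)).astype(float)))
    else:
        raise ValueError(f"unknown cost_model {cost_model!r}")
    U = {s: 1.0 for s in species}
    return Scenario(e=e, w=w, c=c, U=U, eta=eta)


def scenario_from_config(web: FoodWeb, config: dict) -> Scenario:
    """Draw a scenario from a flat config mapping (YAML/JSON friendly)."""
    return draw_scenario(
        web,
        alpha=config.get("alpha", DEFAULT_ALPHA),
        beta=config.get("beta", DEFAULT_BETA),
        weight_logmean=config.get("weight_logmean", DEFAULT_WEIGHT_LOGMEAN),
        weight_logsd=config.get("weight_logsd", DEFAULT_WEIGHT_LOGSD),
        cost_model=config.get("cost_model", "unit"),
        eta=config.get("eta", 1.0),
        seed=config.get("seed"),
    )


def write_scenario(scenario: Scenario, species_path, weights_path) -> None:
    """Serialize a scenario to two CSVs: per-species parameters and per-link
    prey-dependence weights."""
    with open(species_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species", "e", "cost", "utility"])
        for s in sorted(scenario.e):
            writer.writerow([s, repr(float(scenario.e[s])),
                             repr(float(scenario.c[s])),
                             repr(float(scenario.U[s]))])
    with open(weights_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["resource", "consumer", "w"])
        for (r, c) in sorted(scenario.w):
            writer.writerow([r, c, repr(float(scenario.w[(r, c)]))])


def read_scenario(species_path, weights_path, eta: float = 1.0) -> Scenario:
    e, c, U, w = {}, {}, {}, {}
    with open(species_path, newline="") as fh:
        for row in csv.DictReader(fh):
            s = row["species"]
            e[s] = float(row["e"])
            c[s] = float(row["cost"])
            U[s] = float(row["utility"])
    with open(weights_path, newline="") as fh:
        for row in csv.DictReader(fh):
            w[(row["resource"], row["consumer"])] = float(row["w"])
    return Scenario(e=e, w=w, c=c, U=U, eta=eta)
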