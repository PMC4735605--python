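"""Benchmark pipeline: score every management method on every web across
repeated scenario draws, rank methods per iteration, and summarize where in
the trophic hierarchy each method invests.

Each iteration redraws the stochastic scenario (extinction risks and
prey-dependence weights jointly, plus costs when the cost model is random)
from a sub-seed derived from (master seed, web, iteration), sets the budget
to a fixed fraction of the cost of managing everything, lets every method
pick a strategy, and scores all strategies with one shared inference backend
on common random numbers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from .bbn import MC_SAMPLES
from .core import FoodWeb, FoodWebError, trophic_levels
from .generators import scenario_from_config
from .indices import INDEX_BUILDERS, select_under_budget
from .strategies import StrategyEvaluator, greedy_strategy, optimal_strategy

__all__ = [
    "ComparisonResult",
    "TrophicInvestment",
    "ALL_METHODS",
    "run_comparison",
    "competition_rank",
    "trophic_investment",
    "report",
]

#: species-count threshold above which "optimal" silently runs greedy
OPTIMAL_N_THRESHOLD = 14

ALL_METHODS = ("optimal", "greedy") + tuple(INDEX_BUILDERS)


@dataclass(frozen=True)
class ComparisonResult:
    """Tidy per-(web, method, iteration) results plus the run configuration."""

    records: pd.DataFrame
    webs: dict[str, FoodWeb]
    config: dict

    def mean_values(self) -> pd.DataFrame:
        """Mean expected survivors per (web, method) across iterations."""
        return (
            self.records.groupby(["web", "method"])["value"].mean().unstack("method")
        )

    def rank_table(self) -> pd.DataFrame:
        """Per-(web, iteration) competition rank of every method."""
        def _ranks(group: pd.DataFrame) -> pd.Series:
            return pd.Series(
                competition_rank(group["value"].to_numpy()),
                index=group["method"].to_numpy(),
            )

        out = (
            self.records.groupby(["web", "iteration"])[["method", "value"]]
            .apply(_ranks)
            .reset_index()
            .melt(id_vars=["web", "iteration"], var_name="method", value_name="rank")
            .dropna(subset=["rank"])
        )
        return out


@dataclass(frozen=True)
class TrophicInvestment:
    """Normalized management investment per trophic level for one
    (web, method) cell; shares sum to 1 over the occupied levels."""

    shares: dict[int, float]
    managed_counts: dict[int, int]
    species_per_level: dict[int, int]


def _subseed(master: int, web_index: int, iteration: int) -> int:
    ss = np.random.SeedSequence(entropy=[int(master), web_index, iteration])
    return int(ss.generate_state(1)[0] % (2**31))


def run_comparison(
    webs,
    methods=ALL_METHODS,
    budget_fraction: float = 0.25,
    iterations: int = 10,
    scenario_config: dict | None = None,
    seed: int = 0,
    backend: str = "auto",
    mc_samples: int = MC_SAMPLES,
    optimal_n_threshold: int = OPTIMAL_N_THRESHOLD,
) -> ComparisonResult:
    """Run the full method comparison.

    Parameters
    ----------
    webs
        Mapping name -> :class:`FoodWeb`, or a sequence of webs (named
        ``web00``, ``web01``, ...).
    methods
        Names among :data:`ALL_METHODS`.  ``optimal`` is computed exactly for
        webs with up to *optimal_n_threshold* species and by the greedy
        heuristic above that.
    budget_fraction
        Budget as a fraction of the cost of managing every species.
    scenario_config
        Keyword overrides for the scenario draw (alpha, beta, cost_model,
        eta, ...); the per-iteration seed is injected automatically.
    """
    if not 0.0 < budget_fraction <= 1.0:
        raise FoodWebError("budget_fraction must lie in (0, 1]")
    unknown = set(methods) - set(ALL_METHODS)
    if unknown:
        raise FoodWebError(f"unknown methods: {sorted(unknown)}")
    if not isinstance(webs, dict):
        webs = {f"web{i:02d}": w for i, w in enumerate(webs)}
    scenario_config = dict(scenario_config or {})
    rows = []
    for web_index, (web_name, web) in enumerate(webs.items()):
        # structural indices ignore the scenario: rank once per web
        structural = ("degree", "betweenness", "closeness", "keystone",
                      "pagerank", "dominator", "cascade", "bottom_up")
        structural_rankings = {
            m: INDEX_BUILDERS[m](web, None, None)
            for m in methods
            if m in structural
        }
        for iteration in range(iterations):
            it_seed = _subseed(seed, web_index, iteration)
            cfg = dict(scenario_config)
            cfg["seed"] = it_seed
            scenario = scenario_from_config(web, cfg)
            budget = budget_fraction * scenario.total_cost
            evaluator = StrategyEvaluator(
                web, scenario, backend=backend, mc_samples=mc_samples, seed=it_seed
            )
            for method in methods:
                if method in ("optimal", "greedy"):
                    use_optimal = method == "optimal" and web.n <= optimal_n_threshold
                    run = optimal_strategy if use_optimal else greedy_strategy
                    result = run(web, scenario, budget, evaluator=evaluator)
                    strategy, value = result.strategy, result.value
                else:
                    ranking = structural_rankings.get(method)
                    if ranking is None:
                        ranking = INDEX_BUILDERS[method](web, scenario, it_seed)
                    strategy = select_under_budget(ranking, scenario, budget)
                    value, _ = evaluator.evaluate(strategy.managed)
                rows.append(
                    {
                        "web": web_name,
                        "method": method,
                        "iteration": iteration,
                        "seed": it_seed,
                        "value": value,
                        "cost": strategy.cost(scenario),
                        "budget": budget,
                        "n_managed": len(strategy),
                        "managed": ";".join(sorted(strategy.managed)),
                    }
                )
    records = pd.DataFrame(rows)
    config = {
        "methods": list(methods),
        "budget_fraction": budget_fraction,
        "iterations": iterations,
        "scenario_config": {k: v for k, v in scenario_config.items() if k != "seed"},
        "seed": seed,
        "backend": backend,
        "mc_samples": mc_samples,
        "optimal_n_threshold": optimal_n_threshold,
    }
    return ComparisonResult(records=records, webs=dict(webs), config=config)


def competition_rank(values) -> list[int]:
    """Standard competition ranks as printed in the field: with m methods the
    best value receives rank m, ties share a rank, and the next *distinct*
    value gets the next integer down (pattern 10,10,9,8,...)."""
    values = list(values)
    if not values:
        raise FoodWebError("competition_rank requires at least one value")
    m = len(values)
    distinct = sorted(set(values), reverse=True)
    level = {v: m - i for i, v in enumerate(distinct)}
    return [level[v] for v in values]


def trophic_investment(
    comparison: ComparisonResult, web_name: str, method: str
) -> TrophicInvestment:
    """How a method's management effort distributes over trophic levels.

    For each level, the count of (species, iteration) management events is
    divided by the number of species at that level, and the resulting rates
    are normalized to sum to one across levels.
    """
    web = comparison.webs[web_name]
    sub = comparison.records.query("web == @web_name and method == @method")
    if sub.empty:
        raise FoodWebError(f"no records for ({web_name}, {method})")
    levels = trophic_levels(web)
    per_level: dict[int, int] = {}
    species_per_level: dict[int, int] = {}
    for s, lv in levels.items():
        species_per_level[lv] = species_per_level.get(lv, 0) + 1
    for managed in sub["managed"]:
        for s in filter(None, managed.split(";")):
            lv = levels[s]
            per_level[lv] = per_level.get(lv, 0) + 1
    raw = {
        lv: per_level.get(lv, 0) / species_per_level[lv]
        for lv in sorted(species_per_level)
    }
    total = sum(raw.values())
    shares = {lv: (v / total if total else 0.0) for lv, v in raw.items()}
    return TrophicInvestment(
        shares=shares,
        managed_counts={lv: per_level.get(lv, 0) for lv in sorted(species_per_level)},
        species_per_level=species_per_level,
    )


def report(comparison: ComparisonResult, out_dir) -> dict[str, str]:
    """Write tidy CSV tables and a JSON manifest under *out_dir*.

    Produces per-iteration values, the mean-performance table, the rank
    distribution (median, quartiles, whisker limits per method), the trophic
    investment table, and a manifest sufficient to replay the run.
    """
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    per_iter = out / "per_iteration.csv"
    comparison.records.to_csv(per_iter, index=False)
    paths["per_iteration"] = str(per_iter)

    mean_path = out / "mean_performance.csv"
    comparison.mean_values().to_csv(mean_path)
    paths["mean_performance"] = str(mean_path)

    ranks = comparison.rank_table()
    def _whiskers(g: pd.Series) -> pd.Series:
        q1, med, q3 = g.quantile([0.25, 0.5, 0.75])
        iqr = q3 - q1
        return pd.Series(
            {
                "median": med,
                "q25": q1,
                "q75": q3,
                "whisker_low": max(g.min(), q1 - 1.5 * iqr),
                "whisker_high": min(g.max(), q3 + 1.5 * iqr),
            }
        )

    rank_path = out / "rank_distribution.csv"
    ranks.groupby(["web", "method"])["rank"].apply(_whiskers).unstack().to_csv(
        rank_path
    )
    paths["rank_distribution"] = str(rank_path)

    rows = []
    for web_name in comparison.webs:
        for method in comparison.config["methods"]:
            ti = trophic_investment(comparison, web_name, method)
            for lv, share in ti.shares.items():
                rows.append(
                    {
                        "web": web_name,
                        "method": method,
                        "trophic_level": lv,
                        "share": share,
                        "managed_count": ti.managed_counts[lv],
                        "species_at_level": ti.species_per_level[lv],
                    }
                )
    ti_path = out / "trophic_investment.csv"
    pd.DataFrame(rows).to_csv(ti_path, index=False)
    paths["trophic_investment"] = str(ti_path)

    manifest = {
        "config": comparison.config,
        "webs": {
            name: {"n": w.n, "L": w.L, "links": sorted(map(list, w.links))}
            for name, w in comparison.webs.items()
        },
        "versions": {
            "foodwebopt": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = str(manifest_path)
    return paths


def plot_ranks(comparison: ComparisonResult, web_name: str, ax=None):
    """Boxplot of per-iteration method ranks for one web (requires
    matplotlib)."""
    import matplotlib.pyplot as plt

    ranks = comparison.rank_table().query("web == @web_name")
    methods = comparison.config["methods"]
    data = [ranks.query("method == @m")["rank"].to_numpy() for m in methods]
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(methods), 4))
    ax.boxplot(data, tick_labels=methods, whis=1.5)
    ax.set_ylabel("competition rank (higher is better)")
    ax.set_title(web_name)
    ax.tick_params(axis="x", rotation=60)
    return ax
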