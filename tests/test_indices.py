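import networkx as nx
import numpy as np
import pytest
from scipy import stats

from foodwebopt.core import FoodWeb, FoodWebError, basal_species
from foodwebopt.generators import draw_scenario
from foodwebopt.indices import (
    INDEX_BUILDERS,
    bottom_up_index,
    cascade_index,
    centrality_index,
    degree_index,
    dominator_index,
    keystone_index,
    pagerank_index,
    random_index,
    roi_index,
    select_under_budget,
)

from conftest import equal_weight_scenario, small_niche_webs


class TestDegree:
    def test_chain_and_star(self, chain, star):
        assert degree_index(chain).scores == {"A": 1, "B": 2, "C": 1}
        assert degree_index(chain).order[0] == "B"
        assert degree_index(star).order[0] == "A"

    def test_isolated_species_ranks_last(self):
        web = FoodWeb(["A", "B", "Z"], [("A", "B")])
        r = degree_index(web)
        assert r.scores["Z"] == 0 and r.order[-1] == "Z"


class TestCentrality:
    def test_chain_betweenness(self, chain):
        r = centrality_index(chain, "betweenness")
        assert r.scores == {"A": 0.0, "B": 1.0, "C": 0.0}

    def test_chain_closeness_inverse_distance_sums(self, chain):
        r = centrality_index(chain, "closeness")
        assert r.scores["B"] == pytest.approx(1 / 2)
        assert r.scores["A"] == pytest.approx(1 / 3)
        assert r.scores["C"] == pytest.approx(1 / 3)

    def test_weighted_closeness_favours_strong_links(self, chain):
        sc = equal_weight_scenario(chain)
        sc.w.update({("A", "B"): 10.0, ("B", "C"): 0.1})
        r = centrality_index(chain, "closeness", weighted=True, scenario=sc)
        # hand all-pairs distances with length 1/w:
        # d(A,B)=0.1, d(B,C)=10, d(A,C)=10.1
        assert r.scores["A"] == pytest.approx(2 / (2 * (0.1 + 10.1)))
        assert r.scores["C"] == pytest.approx(2 / (2 * (10 + 10.1)))
        assert r.scores["A"] > r.scores["C"]

    def test_weighted_needs_scenario(self, chain):
        with pytest.raises(FoodWebError, match="scenario"):
            centrality_index(chain, "betweenness", weighted=True)

    def test_unknown_kind(self, chain):
        with pytest.raises(FoodWebError):
            centrality_index(chain, "eigenvector")


class TestKeystone:
    def test_star_by_hand(self, star):
        assert keystone_index(star).scores == {"A": 2.0, "B": 0.5, "C": 0.5}

    def test_chain_all_equal(self, chain):
        assert keystone_index(chain).scores == {"A": 2.0, "B": 2.0, "C": 2.0}

    def test_isolated_species_scores_zero(self):
        web = FoodWeb(["A", "B", "Z"], [("A", "B")])
        assert keystone_index(web).scores["Z"] == 0.0


class TestPageRank:
    def test_scores_sum_to_one(self):
        for web in small_niche_webs(5):
            assert sum(pagerank_index(web).scores.values()) == pytest.approx(1.0)

    def test_star_symmetry_forces_tie(self, star):
        r = pagerank_index(star)
        assert r.scores["B"] == pytest.approx(r.scores["C"], abs=1e-14)

    def test_chain_order_matches_power_iteration(self, chain):
        r = pagerank_index(chain)
        assert r.order == ("A", "B", "C")
        # independent power-iteration oracle on the 4x4 root-augmented matrix
        # reversed links C->B->A, A->root, root->everything
        P = np.zeros((4, 4))
        P[1, 2] = 1.0  # C -> B
        P[0, 1] = 1.0  # B -> A
        P[3, 0] = 1.0  # A -> root
        P[0:3, 3] = 1 / 3
        pi = np.full(4, 0.25)
        for _ in range(500):
            pi = 0.5 * pi + 0.5 * (P @ pi)  # lazy walk kills periodicity
        pi = pi[:3] / pi[:3].sum()
        for s, expect in zip("ABC", pi):
            assert r.scores[s] == pytest.approx(expect, abs=1e-8)

    def test_relabeling_equivariance(self):
        web = small_niche_webs(1, n=8, seed0=5)[0]
        mapping = {s: f"X{i}" for i, s in enumerate(reversed(web.species_ids))}
        relabeled = FoodWeb(
            [mapping[s] for s in web.species_ids],
            [(mapping[r], mapping[c]) for r, c in web.links],
        )
        r1 = pagerank_index(web).scores
        r2 = pagerank_index(relabeled).scores
        for s in web.species_ids:
            assert r2[mapping[s]] == pytest.approx(r1[s], abs=1e-12)


class TestDominator:
    def test_chain_counts_descendants(self, chain):
        assert dominator_index(chain).scores == {"A": 2.0, "B": 1.0, "C": 0.0}

    def test_diamond_redundant_paths(self, diamond):
        assert dominator_index(diamond).scores == {
            "A": 3.0, "B": 0.0, "C": 0.0, "D": 0.0,
        }

    def test_basal_only_web(self):
        web = FoodWeb(["A", "B"], [])
        assert set(dominator_index(web).scores.values()) == {0.0}

    def test_matches_disconnection_oracle(self):
        # species i dominates exactly the nodes that lose all paths from the
        # root when i is removed
        for web in small_niche_webs(8, n=8, C=0.2, tolerance=0.4):
            scores = dominator_index(web).scores
            g = web.graph().copy()
            g.add_node("__root__")
            for s in basal_species(web):
                g.add_edge("__root__", s)
            base_reach = set(nx.descendants(g, "__root__"))
            for i in web.species_ids:
                h = g.copy()
                h.remove_node(i)
                cut_off = base_reach - {i} - set(nx.descendants(h, "__root__"))
                assert scores[i] == len(cut_off)


class TestCascade:
    def test_chain_cascade_by_hand(self, chain):
        r = cascade_index(chain)
        assert r.scores == {"A": 0.0, "B": 1.0, "C": 2.0}
        assert r.order == ("A", "B", "C")  # fewest survivors ranks first

    def test_star_collapse(self, star):
        assert cascade_index(star).order[0] == "A"

    def test_redundant_prey_blocks_cascade(self):
        web = FoodWeb(["A1", "A2", "B"], [("A1", "B"), ("A2", "B")])
        assert cascade_index(web).scores["A1"] == 2.0

    def test_survivor_bounds(self):
        for web in small_niche_webs(8):
            s = cascade_index(web).scores
            assert all(0 <= v <= web.n - 1 for v in s.values())


class TestBottomUp:
    def test_chain_is_bottom_first(self, chain):
        assert bottom_up_index(chain).order == ("A", "B", "C")

    def test_predator_count_breaks_level_ties(self):
        web = FoodWeb(
            ["A1", "A2", "B", "C"],
            [("A1", "B"), ("A1", "C"), ("A2", "C")],
        )
        # both basal; A1 has 2 predators, A2 has 1
        assert bottom_up_index(web).order[:2] == ("A1", "A2")

    def test_all_basal_pure_predator_order(self):
        web = FoodWeb(["A", "B"], [])
        assert bottom_up_index(web).order == ("A", "B")


class TestROI:
    def test_unit_costs_order_by_risk(self, chain):
        sc = equal_weight_scenario(chain, e={"A": 0.1, "B": 0.5, "C": 0.3})
        assert roi_index(chain, sc).order == ("B", "C", "A")

    def test_cost_division(self, chain):
        sc = equal_weight_scenario(chain, e={"A": 0.4, "B": 0.2, "C": 0.1})
        sc.c.update({"A": 4.0, "B": 1.0, "C": 1.0})
        r = roi_index(chain, sc)
        assert r.scores["A"] == pytest.approx(0.1)
        assert r.scores["B"] == pytest.approx(0.2)
        assert r.order[0] == "B"

    def test_eta_scales_scores_not_order(self, chain):
        sc1 = equal_weight_scenario(chain, e={"A": 0.4, "B": 0.2, "C": 0.1})
        sc2 = equal_weight_scenario(chain, e={"A": 0.4, "B": 0.2, "C": 0.1},
                                    eta=0.5)
        r1, r2 = roi_index(chain, sc1), roi_index(chain, sc2)
        assert r1.order == r2.order
        for s in chain.species_ids:
            assert r2.scores[s] == pytest.approx(0.5 * r1.scores[s])


class TestRandom:
    def test_seeded_determinism(self, chain):
        assert random_index(chain, 7).order == random_index(chain, 7).order

    def test_first_position_uniform(self):
        web = FoodWeb(list("ABCDE"), [("A", "B")])
        counts = {s: 0 for s in web.species_ids}
        for seed in range(2000):
            counts[random_index(web, seed).order[0]] += 1
        assert stats.chisquare(list(counts.values())).pvalue > 0.01

    def test_single_species(self):
        web = FoodWeb(["A"], [])
        assert random_index(web, 0).order == ("A",)


class TestRankingContract:
    @pytest.mark.parametrize("method", sorted(INDEX_BUILDERS))
    def test_every_ranking_is_a_permutation(self, method):
        for i, web in enumerate(small_niche_webs(3)):
            sc = draw_scenario(web, seed=i)
            r = INDEX_BUILDERS[method](web, sc, i)
            assert sorted(r.order) == sorted(web.species_ids)

    @pytest.mark.parametrize(
        "method",
        ["degree", "betweenness", "closeness", "keystone", "pagerank",
         "dominator", "cascade", "bottom_up"],
    )
    def test_structural_indices_are_deterministic(self, method):
        web = small_niche_webs(1)[0]
        r1 = INDEX_BUILDERS[method](web, None, None)
        r2 = INDEX_BUILDERS[method](web, None, None)
        assert r1.order == r2.order and r1.deterministic


class TestSelectUnderBudget:
    def test_takes_in_rank_order(self, chain, chain_scenario):
        r = degree_index(chain)  # B first
        strat = select_under_budget(r, chain_scenario, budget=2)
        assert strat.managed == frozenset({"A", "B"})

    def test_skip_rule(self, chain):
        sc = equal_weight_scenario(chain)
        sc.c.update({"B": 3.0, "A": 1.0, "C": 1.0})
        r = degree_index(chain)  # order B, A, C
        strat = select_under_budget(r, sc, budget=2)
        assert strat.managed == frozenset({"A", "C"})

    def test_budget_zero(self, chain, chain_scenario):
        strat = select_under_budget(degree_index(chain), chain_scenario, 0)
        assert strat.managed == frozenset()

    def test_cost_never_exceeds_budget(self):
        for i, web in enumerate(small_niche_webs(5)):
            sc = draw_scenario(web, cost_model="uniform_int", seed=i)
            for method in ("degree", "roi", "random"):
                r = INDEX_BUILDERS[method](web, sc, i)
                budget = 0.3 * sc.total_cost
                assert select_under_budget(r, sc, budget).cost(sc) <= budget
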