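"""DAG mechanics, decomposable scoring, hill climbing and tabu search."""

import math

import numpy as np
import pytest

from hcynet.dataset import CategoricalDataset, VariableSpec
from hcynet.structure import (DAG, Move, ScoreCache, SearchConfig,
                              family_score, hill_climb, neighborhood,
                              tabu_search, total_score)

from oracles import all_dags, binary_dataset


class TestDAG:
    def test_cycle_rejected(self):
        dag = DAG.from_edges(("a", "b", "c"), [("a", "b"), ("b", "c")])
        with pytest.raises(ValueError, match="cycle"):
            dag.add_edge("c", "a")

    def test_self_loop_and_duplicate_rejected(self):
        dag = DAG.empty(("a", "b"))
        with pytest.raises(ValueError):
            dag.add_edge("a", "a")
        dag = dag.add_edge("a", "b")
        with pytest.raises(ValueError):
            dag.add_edge("a", "b")

    def test_topological_order_respects_edges(self):
        dag = DAG.from_edges(tuple("abcd"), [("c", "a"), ("a", "d"), ("b", "d")])
        order = dag.topological_order()
        for u, v in dag.edges:
            assert order.index(u) < order.index(v)

    def test_move_apply_then_inverse_restores(self):
        dag = DAG.from_edges(("a", "b", "c"), [("a", "b")])
        for move in neighborhood(dag):
            restored = dag.apply(move).apply(move.inverse())
            assert restored.parents == dag.parents


class TestNeighborhood:
    def test_two_isolated_nodes(self):
        moves = neighborhood(DAG.empty(("u", "v")))
        assert moves == [Move("add", ("u", "v")), Move("add", ("v", "u"))]

    def test_three_node_chain(self):
        """a->b->c: the only legal addition is a->c (c->a would close the
        cycle), both edges can be deleted, and both can be reversed."""
        dag = DAG.from_edges(("a", "b", "c"), [("a", "b"), ("b", "c")])
        moves = neighborhood(dag)
        assert set(moves) == {Move("add", ("a", "c")),
                              Move("delete", ("a", "b")),
                              Move("delete", ("b", "c")),
                              Move("reverse", ("a", "b")),
                              Move("reverse", ("b", "c"))}
        assert len(moves) == 5

    def test_complete_dag_has_no_additions(self):
        dag = DAG.from_edges(("a", "b", "c"),
                             [("a", "b"), ("a", "c"), ("b", "c")])
        assert all(m.kind != "add" for m in neighborhood(dag))

    def test_results_always_acyclic(self, rng):
        dag = DAG.empty(tuple("abcde"))
        for _ in range(30):
            moves = neighborhood(dag)
            dag = dag.apply(moves[rng.integers(len(moves))])
            dag.topological_order()  # raises if cyclic

    def test_max_parents_respected(self):
        dag = DAG.from_edges(("a", "b", "c"), [("a", "c"), ("b", "c")])
        for m in neighborhood(dag, max_parents=2):
            if m.kind == "add":
                assert m.edge[1] != "c"


class TestFamilyScore:
    def test_parentless_hand_arithmetic(self):
        """BIC of a root node from the published group sizes."""
        n0, n1 = 4110, 8175
        codes = np.r_[np.zeros(n0, dtype=np.int64), np.ones(n1, dtype=np.int64)]
        ds = CategoricalDataset([VariableSpec("Hcy", ("Normal", "HHcy"))],
                                codes[:, None])
        n = n0 + n1
        expect = (n0 * math.log(n0 / n) + n1 * math.log(n1 / n)
                  - 0.5 * math.log(n) * 1)
        assert family_score("Hcy", (), ds) == pytest.approx(expect, abs=1e-9)

    def test_independent_parent_lowers_bic(self):
        rng = np.random.default_rng(2)
        n = 10_000
        ds = binary_dataset({"A": rng.integers(0, 2, n),
                             "B": rng.integers(0, 2, n)})
        assert family_score("A", ("B",), ds) < family_score("A", (), ds)

    def test_empty_dataset_rejected(self):
        ds = binary_dataset({"A": np.zeros(0, dtype=int)})
        with pytest.raises(ValueError):
            ScoreCache(ds)

    def test_decomposability(self, rng, vstructure_dataset):
        """Total score equals the independent sum of family scores."""
        cache = ScoreCache(vstructure_dataset)
        for dag in all_dags(("X", "Y", "Z")):
            total = total_score(dag, vstructure_dataset)
            parts = sum(family_score(v, dag.parents[v], vstructure_dataset)
                        for v in dag.nodes)
            assert total == pytest.approx(parts, abs=1e-9)
            assert cache.total(dag) == pytest.approx(parts, abs=1e-9)

    def test_cache_matches_recomputation_after_moves(self, vstructure_dataset):
        cache = ScoreCache(vstructure_dataset)
        dag = DAG.empty(("X", "Y", "Z"))
        for _ in range(4):
            new = dag.apply(neighborhood(dag)[0])
            fresh = ScoreCache(vstructure_dataset)
            for v in new.nodes:
                assert cache.family(v, new.parents[v]) == \
                    pytest.approx(fresh.family(v, new.parents[v]), abs=1e-12)
            dag = new


class TestSearch:
    def test_hill_climb_recovers_v_structure_skeleton(self, vstructure_dataset):
        dag, trace = hill_climb(vstructure_dataset)
        skeleton = {frozenset(e) for e in dag.edges}
        assert skeleton == {frozenset({"X", "Z"}), frozenset({"Y", "Z"})}
        scores = [r["score"] for r in trace.records]
        assert all(b > a for a, b in zip(scores, scores[1:]))

    def test_hill_climb_matches_exhaustive_optimum(self, vstructure_dataset):
        cache = ScoreCache(vstructure_dataset)
        best = max(cache.total(d) for d in all_dags(("X", "Y", "Z")))
        dag, _ = hill_climb(vstructure_dataset)
        assert cache.total(dag) == pytest.approx(best, abs=1e-9)

    def test_independent_variables_yield_empty_dag(self, independent_dataset):
        dag, _ = hill_climb(independent_dataset)
        assert dag.edges == []
        dag, _ = tabu_search(independent_dataset)
        assert dag.edges == []

    def test_single_variable_trivial(self):
        ds = binary_dataset({"A": np.array([0, 1, 0, 1])})
        dag, trace = hill_climb(ds)
        assert dag.edges == [] and trace.records == []

    def test_tabu_matches_hill_climb_on_easy_landscape(self, vstructure_dataset):
        cache = ScoreCache(vstructure_dataset)
        hc, _ = hill_climb(vstructure_dataset)
        tb, _ = tabu_search(vstructure_dataset)
        assert cache.total(tb) >= cache.total(hc) - 1e-9
        assert {frozenset(e) for e in tb.edges} == \
            {frozenset(e) for e in hc.edges}

    def test_tabu_escapes_planted_local_optimum(self, xor_dataset):
        """Greedy search cannot see a parity dependence through any single
        edge, but tabu search walks through worsening moves and finds the
        exhaustive-enumeration optimum."""
        cache = ScoreCache(xor_dataset)
        dags = all_dags(("A", "B", "C", "D"))
        assert len(dags) == 543
        best = max(cache.total(d) for d in dags)
        hc, _ = hill_climb(xor_dataset)
        tb, _ = tabu_search(xor_dataset)
        assert hc.edges == []                       # stuck at the empty graph
        assert cache.total(tb) == pytest.approx(best, abs=1e-9)
        assert cache.total(tb) > cache.total(hc) + 100

    def test_degenerate_tabu_config_reduces_to_hill_climbing(
            self, vstructure_dataset, xor_dataset):
        cfg = SearchConfig(tabu_tenure=0, max_nonimproving=1)
        for ds in (vstructure_dataset, xor_dataset):
            cache = ScoreCache(ds)
            hc, _ = hill_climb(ds, cfg)
            tb, _ = tabu_search(ds, cfg)
            assert cache.total(tb) == pytest.approx(cache.total(hc), abs=1e-9)

    def test_best_score_trace_non_decreasing(self, xor_dataset):
        _, trace = tabu_search(xor_dataset)
        best = trace.best_scores
        assert all(b >= a for a, b in zip(best, best[1:]))

    def test_every_visited_graph_acyclic(self, xor_dataset):
        dag, trace = tabu_search(xor_dataset)
        replay = DAG.empty(("A", "B", "C", "D"))
        for r in trace.records:
            replay = replay.apply(r["move"])
            replay.topological_order()

    def test_whitelist_and_blacklist(self, vstructure_dataset):
        cfg = SearchConfig(blacklist=frozenset({("X", "Z"), ("Z", "X")}))
        dag, _ = hill_climb(vstructure_dataset, cfg)
        assert not dag.has_edge("X", "Z") and not dag.has_edge("Z", "X")
        cfg = SearchConfig(whitelist=frozenset({("X", "Y")}))
        dag, _ = hill_climb(vstructure_dataset, cfg)
        assert dag.has_edge("X", "Y")
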