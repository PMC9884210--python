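"""Exact inference against full-joint enumeration oracles."""

import itertools

import numpy as np
import pytest

from hcynet.inference import (joint_distribution, marginal, posterior,
                              predict_proba)
from hcynet.parameters import CPT, BayesianNetwork, fit_mle
from hcynet.structure import DAG
from hcynet.synthetic import GroundTruthSpec, sample_bn

from oracles import binary_dataset, brute_marginal, random_network


class TestMarginal:
    def test_parentless_node_returns_its_prior(self):
        bn = BayesianNetwork(
            DAG.empty(("Hcy",)),
            {"Hcy": CPT("Hcy", (), (), np.array([[0.335, 0.665]]))},
            {"Hcy": ("Normal", "HHcy")})
        assert marginal(bn, "Hcy").p("HHcy") == pytest.approx(0.665)

    def test_deterministic_chain_propagates_root_prior(self):
        eye = np.eye(2)
        bn = BayesianNetwork(
            DAG.from_edges(("A", "B", "C"), [("A", "B"), ("B", "C")]),
            {"A": CPT("A", (), (), np.array([[0.3, 0.7]])),
             "B": CPT("B", ("A",), (2,), eye),
             "C": CPT("C", ("B",), (2,), eye)},
            {v: ("0", "1") for v in "ABC"})
        assert marginal(bn, "C").distribution == pytest.approx([0.3, 0.7])

    def test_matches_enumeration_on_random_networks(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            bn = random_network(rng, n_nodes=4, max_states=3)
            for v in bn.nodes:
                assert marginal(bn, v).distribution == \
                    pytest.approx(brute_marginal(bn, v), abs=1e-10)

    def test_unknown_variable(self):
        rng = np.random.default_rng(0)
        with pytest.raises(KeyError):
            marginal(random_network(rng), "nope")


class TestPosterior:
    def test_matches_enumeration_with_evidence(self):
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            bn = random_network(rng, n_nodes=5, max_states=3)
            nodes = list(bn.nodes)
            ev_var = nodes[int(rng.integers(len(nodes)))]
            q_var = next(v for v in nodes if v != ev_var)
            ev = {ev_var: int(rng.integers(bn.card(ev_var)))}
            try:
                got = posterior(bn, q_var, ev).distribution
            except ValueError:
                continue  # zero-probability evidence draw
            assert got == pytest.approx(
                brute_marginal(bn, q_var, ev), abs=1e-10)

    def test_d_separated_evidence_leaves_prior(self):
        # A -> B, C isolated: evidence on C cannot move B
        bn = BayesianNetwork(
            DAG.from_edges(("A", "B", "C"), [("A", "B")]),
            {"A": CPT("A", (), (), np.array([[0.4, 0.6]])),
             "B": CPT("B", ("A",), (2,), np.array([[0.9, 0.1], [0.2, 0.8]])),
             "C": CPT("C", (), (), np.array([[0.5, 0.5]]))},
            {v: ("0", "1") for v in "ABC"})
        prior = marginal(bn, "B").distribution
        post = posterior(bn, "B", {"C": 1}).distribution
        assert post == pytest.approx(prior, abs=1e-12)

    def test_evidence_on_query_is_point_mass(self):
        rng = np.random.default_rng(4)
        bn = random_network(rng)
        v = bn.nodes[0]
        res = posterior(bn, v, {v: 1})
        assert res.distribution[1] == 1.0

    def test_elimination_order_invariance(self):
        rng = np.random.default_rng(7)
        bn = random_network(rng, n_nodes=5, max_states=3)
        q = bn.nodes[0]
        ev = {bn.nodes[4]: 0}
        hidden = [v for v in bn.nodes if v != q and v not in ev]
        ref = posterior(bn, q, ev).distribution
        for _ in range(5):
            order = list(rng.permutation(hidden))
            got = posterior(bn, q, ev, order=order).distribution
            assert got == pytest.approx(ref, abs=1e-12)

    def test_chained_equals_joint_evidence(self):
        """Conditioning step by step equals conditioning at once."""
        rng = np.random.default_rng(12)
        bn = random_network(rng, n_nodes=5, max_states=3)
        e1 = {bn.nodes[1]: 0}
        e2 = {bn.nodes[3]: 1}
        joint = posterior(bn, bn.nodes[0], {**e1, **e2}).distribution
        assert joint == pytest.approx(
            brute_marginal(bn, bn.nodes[0], {**e1, **e2}), abs=1e-10)

    def test_zero_probability_evidence_raises(self):
        bn = BayesianNetwork(
            DAG.from_edges(("A", "B"), [("A", "B")]),
            {"A": CPT("A", (), (), np.array([[1.0, 0.0]])),
             "B": CPT("B", ("A",), (2,), np.array([[1.0, 0.0], [0.5, 0.5]]))},
            {"A": ("0", "1"), "B": ("0", "1")})
        with pytest.raises(ValueError, match="zero"):
            posterior(bn, "B", {"A": 1})


class TestJointDistribution:
    def test_matches_enumeration(self):
        from oracles import enumerate_joint
        rng = np.random.default_rng(3)
        bn = random_network(rng, n_nodes=4, max_states=3)
        vars = list(bn.nodes)[:2]
        joint = joint_distribution(bn, vars)
        assert joint.sum() == pytest.approx(1.0, abs=1e-12)
        full = enumerate_joint(bn)
        nodes = list(bn.nodes)
        expect = np.zeros(joint.shape)
        for cfg, p in full.items():
            expect[cfg[nodes.index(vars[0])], cfg[nodes.index(vars[1])]] += p
        assert joint == pytest.approx(expect, abs=1e-12)


class TestPredictProba:
    def test_isolated_target_predicts_prior(self):
        bn = BayesianNetwork(
            DAG.from_edges(("T", "X"), []),
            {"T": CPT("T", (), (), np.array([[0.3, 0.7]])),
             "X": CPT("X", (), (), np.array([[0.6, 0.4]]))},
            {"T": ("0", "1"), "X": ("0", "1")})
        ds = binary_dataset({"T": [0, 1, 0], "X": [1, 0, 1]})
        proba = predict_proba(bn, "T", ds)
        assert np.allclose(proba, [[0.3, 0.7]] * 3)

    def test_matches_per_row_bayes_rule(self):
        rng = np.random.default_rng(21)
        bn = random_network(rng, n_nodes=3, max_states=3)
        target = bn.nodes[1]
        others = [v for v in bn.nodes if v != target]
        combos = list(itertools.product(*[range(bn.card(v)) for v in others]))
        from hcynet.dataset import CategoricalDataset, VariableSpec
        specs = [VariableSpec(v, bn.states[v]) for v in bn.nodes]
        rows = []
        for cfg in combos:
            row = {v: s for v, s in zip(others, cfg)}
            row[target] = 0
            rows.append([row[v] for v in bn.nodes])
        ds = CategoricalDataset(specs, np.array(rows))
        proba = predict_proba(bn, target, ds)
        for i, cfg in enumerate(combos):
            ev = {v: s for v, s in zip(others, cfg)}
            expect = brute_marginal(bn, target, ev)
            assert proba[i] == pytest.approx(expect, abs=1e-10)

    def test_sampling_consistency(self):
        """Averaged per-row predictions converge to the target marginal on
        data sampled from the same network."""
        rng = np.random.default_rng(33)
        bn = random_network(rng, n_nodes=4, max_states=3)
        ds = sample_bn(GroundTruthSpec(bn, 50_000, 99))
        target = bn.nodes[2]
        proba = predict_proba(bn, target, ds)
        avg = proba.mean(axis=0)
        assert avg == pytest.approx(marginal(bn, target).distribution,
                                    abs=0.01)

    def test_conflicting_row_dropped_with_warning(self):
        bn = BayesianNetwork(
            DAG.from_edges(("A", "T"), [("A", "T")]),
            {"A": CPT("A", (), (), np.array([[1.0, 0.0]])),
             "T": CPT("T", ("A",), (2,), np.array([[0.8, 0.2], [0.5, 0.5]]))},
            {"A": ("0", "1"), "T": ("0", "1")})
        # the A=1 row has prior probability zero under the network
        ds = binary_dataset({"A": [0, 1], "T": [0, 0]})
        with pytest.warns(RuntimeWarning):
            proba = predict_proba(bn, "T", ds)
        assert np.allclose(proba.sum(axis=1), 1.0)
        with pytest.raises(ValueError):
            predict_proba(bn, "T", ds, on_conflict="error")
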