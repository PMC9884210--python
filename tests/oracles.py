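"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive — explicit loops, exhaustive
enumeration, numerical integration — and shares no code with the package
paths it checks.
"""

import itertools
import math

import numpy as np
from scipy import integrate

from hcynet.dataset import CategoricalDataset, VariableSpec
from hcynet.parameters import CPT, BayesianNetwork
from hcynet.structure import DAG


def brute_chi_square(counts, correction=True):
    """Pearson/Yates statistic by explicit loops; p by numerically
    integrating the chi-square density."""
    counts = np.asarray(counts, dtype=float)
    r, c = counts.shape
    total = counts.sum()
    stat = 0.0
    for i in range(r):
        for j in range(c):
            e = counts[i].sum() * counts[:, j].sum() / total
            dev = abs(counts[i, j] - e)
            if correction and (r, c) == (2, 2):
                dev = max(dev - 0.5, 0.0)
            stat += dev**2 / e
    df = (r - 1) * (c - 1)

    def density(x):
        return x ** (df / 2 - 1) * math.exp(-x / 2) / \
            (2 ** (df / 2) * math.gamma(df / 2))

    p, _ = integrate.quad(density, 0, stat, limit=200)
    return stat, df, min(max(1 - p, 0.0), 1.0)


def auc_pair_counting(scores, labels):
    """O(n^2) concordant-pair fraction with ties counted 1/2."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def enumerate_joint(bn: BayesianNetwork):
    """Full joint as {config tuple: probability}, nodes in bn.nodes order."""
    nodes = list(bn.nodes)
    out = {}
    for cfg in itertools.product(*[range(bn.card(v)) for v in nodes]):
        assign = dict(zip(nodes, cfg))
        p = 1.0
        for v in nodes:
            cpt = bn.cpts[v]
            row = cpt.table[0] if not cpt.parents else \
                cpt.table[int(_cfg_index(cpt, assign))]
            p *= row[assign[v]]
        out[cfg] = p
    return out


def _cfg_index(cpt: CPT, assign):
    idx = 0
    for p, card in zip(cpt.parents, cpt.parent_cards):
        idx = idx * card + assign[p]
    return idx


def brute_marginal(bn, var, evidence=None):
    """P(var | evidence) by summing the enumerated joint."""
    evidence = evidence or {}
    ev = {v: bn.state_index(v, s) for v, s in evidence.items()}
    joint = enumerate_joint(bn)
    nodes = list(bn.nodes)
    i = nodes.index(var)
    dist = np.zeros(bn.card(var))
    for cfg, p in joint.items():
        if all(cfg[nodes.index(v)] == s for v, s in ev.items()):
            dist[cfg[i]] += p
    return dist / dist.sum()


def all_dags(nodes):
    """Every DAG over ``nodes`` (3 nodes -> 25, 4 nodes -> 543)."""
    nodes = tuple(nodes)
    pairs = list(itertools.combinations(nodes, 2))
    out = []
    for choice in itertools.product((0, 1, 2), repeat=len(pairs)):
        edges = []
        for (u, v), c in zip(pairs, choice):
            if c == 1:
                edges.append((u, v))
            elif c == 2:
                edges.append((v, u))
        try:
            out.append(DAG.from_edges(nodes, edges))
        except ValueError:
            continue
    return out


def random_network(rng, n_nodes=4, max_states=3):
    """A random DAG with random (Dirichlet) CPTs over small cardinalities."""
    names = tuple(f"X{i}" for i in range(n_nodes))
    cards = {v: int(rng.integers(2, max_states + 1)) for v in names}
    order = list(names)
    rng.shuffle(order)
    parents = {}
    for i, v in enumerate(order):
        pool = order[:i]
        k = int(rng.integers(0, min(2, len(pool)) + 1))
        parents[v] = tuple(sorted(rng.choice(pool, size=k, replace=False)))
    dag = DAG.from_edges(names, [(p, v) for v, ps in parents.items() for p in ps])
    states = {v: tuple(f"s{j}" for j in range(cards[v])) for v in names}
    cpts = {}
    for v in names:
        pcards = tuple(cards[p] for p in parents[v])
        q = int(np.prod(pcards)) if pcards else 1
        table = rng.dirichlet(np.ones(cards[v]), size=q)
        cpts[v] = CPT(v, parents[v], pcards, table)
    return BayesianNetwork(dag, cpts, states)


def binary_dataset(columns: dict):
    """CategoricalDataset from named binary 0/1 integer columns."""
    names = list(columns)
    specs = [VariableSpec(nm, ("0", "1")) for nm in names]
    codes = np.column_stack([np.asarray(columns[nm], dtype=np.int64)
                             for nm in names])
    return CategoricalDataset(specs, codes)
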