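"""Exact probabilistic inference by variable elimination.

Supports the sequential risk queries of the analysis — e.g. P(HHcy),
then P(HHcy | high SBP), then P(HHcy | high SBP, age 71-91, abnormal
MCR) — as well as per-subject prediction with every other variable as
evidence, which feeds the ROC comparison of the learned networks.

Factors are dense numpy arrays labelled by variable; elimination order is
min-fill with deterministic name tie-breaks (exact answers are
order-invariant, the heuristic only affects cost).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataset import CategoricalDataset
from .parameters import CPT, BayesianNetwork

__all__ = ["Evidence", "QueryResult", "marginal", "posterior", "predict_proba"]

Evidence = dict  # variable -> observed state (label or index)


@dataclass(frozen=True)
class QueryResult:
    variable: str
    distribution: np.ndarray
    states: tuple[str, ...]
    evidence: dict
    elimination_order: tuple[str, ...]

    def __post_init__(self):
        d = np.asarray(self.distribution, dtype=float)
        object.__setattr__(self, "distribution", d)
        if (d < 0).any() or abs(d.sum() - 1.0) > 1e-10:
            raise ValueError("distribution must be a normalized probability vector")

    def p(self, state) -> float:
        return float(self.distribution[self.states.index(state)])


class _Factor:
    __slots__ = ("vars", "values")

    def __init__(self, vars: tuple[str, ...], values: np.ndarray):
        self.vars = vars
        self.values = values

    @classmethod
    def from_cpt(cls, cpt: CPT, card) -> "_Factor":
        vars = cpt.parents + (cpt.node,)
        shape = tuple(card(v) for v in vars)
        return cls(vars, cpt.table.reshape(shape))

    def reduce(self, var: str, state: int) -> "_Factor":
        if var not in self.vars:
            return self
        ax = self.vars.index(var)
        values = np.take(self.values, state, axis=ax)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:], values)

    def multiply(self, other: "_Factor") -> "_Factor":
        vars = self.vars + tuple(v for v in other.vars if v not in self.vars)

        def aligned(f: "_Factor") -> np.ndarray:
            missing = tuple(v for v in vars if v not in f.vars)
            vals = f.values.reshape(f.values.shape + (1,) * len(missing))
            cur = f.vars + missing
            return vals.transpose([cur.index(v) for v in vars])

        return _Factor(vars, aligned(self) * aligned(other))

    def marginalize(self, var: str) -> "_Factor":
        ax = self.vars.index(var)
        return _Factor(self.vars[:ax] + self.vars[ax + 1:],
                       self.values.sum(axis=ax))


def _min_fill_order(factors: list[_Factor], eliminate: set[str]) -> list[str]:
    adjacency: dict[str, set] = {v: set() for v in eliminate}
    cliques = [set(f.vars) for f in factors]
    for c in cliques:
        for v in c:
            if v in adjacency:
                adjacency[v] |= c - {v}
    order = []
    remaining = set(eliminate)
    while remaining:
        def fill(v):
            nbrs = list(adjacency[v])
            return sum(1 for i, a in enumerate(nbrs) for b in nbrs[i + 1:]
                       if b not in adjacency.get(a, set())
                       and a not in adjacency.get(b, set()))
        v = min(sorted(remaining), key=fill)
        order.append(v)
        nbrs = adjacency[v]
        for a in nbrs:
            if a in adjacency:
                adjacency[a] |= (nbrs - {a})
                adjacency[a].discard(v)
        for w in adjacency:
            adjacency[w].discard(v)
        remaining.remove(v)
    return order


def _eliminate(bn: BayesianNetwork, query: str, evidence: dict,
               order: list[str] | None = None) -> tuple[np.ndarray, tuple[str, ...]]:
    ev = {v: bn.state_index(v, s) for v, s in evidence.items()}
    factors = [_Factor.from_cpt(bn.cpts[v], bn.card) for v in bn.nodes]
    for v, s in ev.items():
        factors = [f.reduce(v, s) for f in factors]
    hidden = set(bn.nodes) - set(ev) - {query}
    order = list(order) if order is not None else _min_fill_order(factors, hidden)
    if set(order) != hidden:
        raise ValueError("elimination order must cover exactly the hidden variables")
    for v in order:
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(v)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    if result.vars != (query,):
        ax = result.vars.index(query)
        values = np.moveaxis(result.values, ax, 0).reshape(bn.card(query), -1).sum(1)
    else:
        values = result.values
    return values, tuple(order)


def joint_distribution(bn: BayesianNetwork, vars: list[str]) -> np.ndarray:
    """Exact joint P(vars) with axes in the requested order."""
    unknown = [v for v in vars if v not in bn.nodes]
    if unknown:
        raise KeyError(f"unknown variables {unknown}")
    factors = [_Factor.from_cpt(bn.cpts[v], bn.card) for v in bn.nodes]
    hidden = set(bn.nodes) - set(vars)
    for v in _min_fill_order(factors, hidden):
        involved = [f for f in factors if v in f.vars]
        rest = [f for f in factors if v not in f.vars]
        prod = involved[0]
        for f in involved[1:]:
            prod = prod.multiply(f)
        factors = rest + [prod.marginalize(v)]
    result = factors[0]
    for f in factors[1:]:
        result = result.multiply(f)
    # every node appears in its own CPT factor, so result covers all vars
    return result.values.transpose([result.vars.index(v) for v in vars])


def marginal(bn: BayesianNetwork, var: str) -> QueryResult:
    """Exact marginal P(var) by summing out all other variables."""
    return posterior(bn, var, {})


def posterior(bn: BayesianNetwork, var: str, evidence: dict,
              order: list[str] | None = None) -> QueryResult:
    """Exact P(var | evidence) by variable elimination.

    Sequential accumulation of evidence is just dict union:
    ``posterior(bn, y, {**e1, **e2})``.  Zero-probability (inconsistent)
    evidence raises, naming the assignment.
    """
    if var not in bn.nodes:
        raise KeyError(f"unknown variable {var!r}")
    if var in evidence:
        dist = np.zeros(bn.card(var))
        dist[bn.state_index(var, evidence[var])] = 1.0
        return QueryResult(var, dist, bn.states[var], dict(evidence), ())
    values, used = _eliminate(bn, var, evidence, order)
    z = values.sum()
    if z <= 0:
        raise ValueError(f"evidence has probability zero: {evidence}")
    return QueryResult(var, values / z, bn.states[var], dict(evidence), used)


def predict_proba(
    bn: BayesianNetwork,
    target: str,
    ds: CategoricalDataset,
    on_conflict: str = "drop",
) -> np.ndarray:
    """Per-row posterior of ``target`` given every other variable as evidence.

    With full evidence only the target's Markov-blanket factors matter, so
    rows are scored vectorised:  P(t=s | rest) ∝ P(s | pa_t) ·
    Π_children P(x_c | pa_c, t=s).  A row whose evidence has probability
    zero under the network (possible with pure-MLE CPTs) is re-scored after
    dropping the minimal conflicting assignments, with a warning
    (``on_conflict="drop"``), or raises (``on_conflict="error"``).
    """
    extra = set(ds.names) - set(bn.nodes)
    data_nodes = [v for v in bn.nodes if v != target]
    missing = [v for v in data_nodes if v not in ds.names]
    if missing:
        raise ValueError(f"dataset lacks evidence variables {missing}")
    n, r = ds.n, bn.card(target)
    scores = np.ones((n, r))
    cols = {v: ds.column(v) for v in data_nodes}
    # target's own CPT
    tcpt = bn.cpts[target]
    if tcpt.parents:
        cfg = tcpt.config_index(np.column_stack([cols[p] for p in tcpt.parents]))
        scores *= tcpt.table[cfg]
    else:
        scores *= tcpt.table[0]
    # children of the target; other nodes' factors are row constants that
    # cancel on normalization, except that a zero marks inconsistent evidence
    conflict = np.zeros(n, dtype=bool)
    for child in bn.nodes:
        if child == target:
            continue
        ccpt = bn.cpts[child]
        if target not in bn.dag.parents[child]:
            if ccpt.parents:
                cfg = ccpt.config_index(
                    np.column_stack([cols[p] for p in ccpt.parents]))
                vals = ccpt.table[cfg, cols[child]]
            else:
                vals = ccpt.table[0][cols[child]]
            conflict |= vals == 0
            continue
        for s in range(r):
            pcols = [cols[p] if p != target else np.full(n, s, dtype=np.int64)
                     for p in ccpt.parents]
            cfg = ccpt.config_index(np.column_stack(pcols))
            scores[:, s] *= ccpt.table[cfg, cols[child]]
    z = scores.sum(axis=1)
    bad = np.flatnonzero((z <= 0) | conflict)
    if bad.size and on_conflict == "error":
        raise ValueError(f"{bad.size} rows have zero-probability evidence")
    if bad.size:
        warnings.warn(
            f"{bad.size} rows had zero-probability evidence; conflicting "
            "assignments dropped for those rows", RuntimeWarning, stacklevel=2)
        for i in bad:
            scores[i] = _row_fallback(bn, target, {v: int(cols[v][i])
                                                   for v in data_nodes})
        z = scores.sum(axis=1)
    return scores / z[:, None]


def _row_fallback(bn: BayesianNetwork, target: str, evidence: dict) -> np.ndarray:
    """Drop conflicting assignments one at a time until the query is consistent."""
    ev = dict(evidence)
    while ev:
        try:
            return posterior(bn, target, ev).distribution
        except ValueError:
            # drop the assignment whose removal best restores consistency:
            # greedily drop the first variable (sorted) whose removal yields
            # positive evidence probability
            for v in sorted(ev):
                trial = {k: s for k, s in ev.items() if k != v}
                try:
                    dist = posterior(bn, target, trial).distribution
                except ValueError:
                    continue
                return dist
            ev.pop(sorted(ev)[0])
    return marginal(bn, target).distribution
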