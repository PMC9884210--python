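"""Conditional probability tables and maximum-likelihood parameter fitting.

Given a structure, each node's CPT is the table of conditional relative
frequencies P(x | pa) estimated from the coded data, optionally smoothed by
a pseudocount.  Parent configurations are enumerated row-major in sorted
parent-name order, so serialized tables are byte-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataset import CategoricalDataset
from .structure import DAG

__all__ = ["CPT", "BayesianNetwork", "fit_mle"]


@dataclass
class CPT:
    """P(node | parents) as a (parent-configurations × node-states) table."""

    node: str
    parents: tuple[str, ...]            # sorted; row-major in this order
    parent_cards: tuple[int, ...]
    table: np.ndarray                   # shape (q, r), rows sum to 1
    counts: np.ndarray | None = None    # underlying frequencies, same shape

    def __post_init__(self):
        self.table = np.asarray(self.table, dtype=float)
        q = int(np.prod(self.parent_cards)) if self.parents else 1
        if self.table.ndim != 2 or self.table.shape[0] != q:
            raise ValueError(f"{self.node}: table must have {q} rows")
        if (self.table < 0).any():
            raise ValueError(f"{self.node}: negative probability")
        if not np.allclose(self.table.sum(axis=1), 1.0, rtol=0, atol=1e-12):
            raise ValueError(f"{self.node}: CPT rows must sum to 1")
        if tuple(sorted(self.parents)) != self.parents:
            raise ValueError(f"{self.node}: parents must be sorted")

    @property
    def r(self) -> int:
        return self.table.shape[1]

    def config_index(self, parent_states: np.ndarray | list) -> np.ndarray:
        """Row index for parent state indices (row-major, first parent slowest)."""
        arr = np.atleast_2d(np.asarray(parent_states, dtype=np.int64))
        out = np.zeros(arr.shape[0], dtype=np.int64)
        for k, card in enumerate(self.parent_cards):
            out = out * card + arr[:, k]
        return out

    def row(self, parent_states) -> np.ndarray:
        if not self.parents:
            return self.table[0]
        return self.table[int(self.config_index([list(parent_states)])[0])]


@dataclass
class BayesianNetwork:
    """A DAG plus one CPT per node and the state labels of every node."""

    dag: DAG
    cpts: dict[str, CPT]
    states: dict[str, tuple[str, ...]]

    def __post_init__(self):
        for v in self.dag.nodes:
            if v not in self.cpts:
                raise ValueError(f"missing CPT for {v}")
            cpt = self.cpts[v]
            if cpt.parents != tuple(sorted(self.dag.parents[v])):
                raise ValueError(f"{v}: CPT parents do not match the DAG")
            if cpt.r != len(self.states[v]):
                raise ValueError(f"{v}: CPT width does not match states")
            expect = tuple(len(self.states[p]) for p in cpt.parents)
            if cpt.parent_cards != expect:
                raise ValueError(f"{v}: parent cardinalities inconsistent")

    @property
    def nodes(self) -> tuple[str, ...]:
        return self.dag.nodes

    def card(self, v: str) -> int:
        return len(self.states[v])

    def state_index(self, var: str, state) -> int:
        if isinstance(state, (int, np.integer)):
            if not 0 <= state < self.card(var):
                raise ValueError(f"{var}: state index {state} out of range")
            return int(state)
        try:
            return self.states[var].index(state)
        except ValueError:
            raise ValueError(
                f"{var}: unknown state {state!r}; states are {self.states[var]}"
            ) from None


def fit_mle(
    dag: DAG, ds: CategoricalDataset, pseudocount: float = 0.0
) -> BayesianNetwork:
    """Maximum-likelihood CPTs for ``dag`` from coded data.

    P(x | pa) = (count(x, pa) + pseudocount) / (count(pa) + pseudocount·r).
    With pseudocount 0 an unobserved parent configuration would be 0/0; its
    row falls back to the uniform distribution.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be non-negative")
    missing = [v for v in dag.nodes if v not in ds.names]
    if missing:
        raise ValueError(f"dataset lacks variables {missing}")
    cpts = {}
    for v in dag.nodes:
        parents = tuple(sorted(dag.parents[v]))
        cards = tuple(len(ds.var(p).states) for p in parents)
        r = len(ds.var(v).states)
        q = int(np.prod(cards)) if parents else 1
        code = ds.column(v).copy()
        size = r
        for p in reversed(parents):  # row-major: first parent slowest
            code = code + size * ds.column(p)
            size *= len(ds.var(p).states)
        counts = np.bincount(code, minlength=q * r).reshape(q, r).astype(float)
        num = counts + pseudocount
        den = num.sum(axis=1, keepdims=True)
        table = np.divide(num, den, out=np.full_like(num, 1.0 / r),
                          where=den > 0)
        cpts[v] = CPT(v, parents, cards, table, counts)
    states = {v: ds.var(v).states for v in dag.nodes}
    return BayesianNetwork(dag, cpts, states)
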