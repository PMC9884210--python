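"""Score-based Bayesian-network structure learning.

The DAG is learned by local search over single-edge moves (add / delete /
reverse) scored with a decomposable criterion, by default BIC with natural
logs:

    score(G) = Σ_i [ Σ_{j,k} n_ijk · ln(n_ijk / n_ij) ] − (ln n / 2) · (r_i − 1) · q_i

where node i has r_i states and q_i parent configurations.  Two searchers
are provided: plain greedy hill climbing, and tabu search, which keeps
moving through the best non-tabu neighbour even when no move improves,
forbids re-touching recently moved arcs for a tenure, and admits a tabu
move only when it beats the best score seen (the aspiration criterion).
Tabu search can therefore escape local optima — e.g. parity-like
dependencies invisible to any single improving edge — that stop greedy
search cold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dataset import CategoricalDataset

__all__ = ["DAG", "Move", "SearchConfig", "SearchTrace", "ScoreCache",
           "family_score", "total_score", "neighborhood", "hill_climb",
           "tabu_search"]

_EPS = 1e-10  # strict-improvement threshold for float score deltas


@dataclass(frozen=True)
class DAG:
    """Directed acyclic graph as per-node parent sets."""

    nodes: tuple[str, ...]
    parents: dict[str, frozenset]

    @classmethod
    def empty(cls, nodes) -> "DAG":
        nodes = tuple(nodes)
        if len(set(nodes)) != len(nodes):
            raise ValueError("duplicate node names")
        return cls(nodes, {v: frozenset() for v in nodes})

    @classmethod
    def from_edges(cls, nodes, edges) -> "DAG":
        dag = cls.empty(nodes)
        for u, v in edges:
            dag = dag.add_edge(u, v)
        return dag

    @property
    def edges(self) -> list[tuple[str, str]]:
        return sorted((u, v) for v, ps in self.parents.items() for u in ps)

    def has_edge(self, u: str, v: str) -> bool:
        return u in self.parents[v]

    def has_path(self, u: str, v: str) -> bool:
        """Is there a directed path u ⇝ v (including u == v)?"""
        children = {w: [c for c in self.nodes if w in self.parents[c]]
                    for w in self.nodes}
        stack, seen = [u], set()
        while stack:
            w = stack.pop()
            if w == v:
                return True
            if w in seen:
                continue
            seen.add(w)
            stack.extend(children[w])
        return False

    def add_edge(self, u: str, v: str) -> "DAG":
        if u == v:
            raise ValueError("self-loop")
        if u not in self.nodes or v not in self.nodes:
            raise KeyError(f"unknown node in edge ({u}, {v})")
        if self.has_edge(u, v):
            raise ValueError(f"duplicate edge ({u}, {v})")
        if self.has_path(v, u):
            raise ValueError(f"edge ({u}, {v}) would create a cycle")
        parents = dict(self.parents)
        parents[v] = parents[v] | {u}
        return DAG(self.nodes, parents)

    def remove_edge(self, u: str, v: str) -> "DAG":
        if not self.has_edge(u, v):
            raise ValueError(f"no edge ({u}, {v})")
        parents = dict(self.parents)
        parents[v] = parents[v] - {u}
        return DAG(self.nodes, parents)

    def reverse_edge(self, u: str, v: str) -> "DAG":
        return self.remove_edge(u, v).add_edge(v, u)

    def apply(self, move: "Move") -> "DAG":
        u, v = move.edge
        if move.kind == "add":
            return self.add_edge(u, v)
        if move.kind == "delete":
            return self.remove_edge(u, v)
        if move.kind == "reverse":
            return self.reverse_edge(u, v)
        raise ValueError(f"unknown move kind {move.kind!r}")

    def topological_order(self) -> list[str]:
        order, done = [], set()
        pending = dict(self.parents)
        while pending:
            ready = sorted(v for v, ps in pending.items() if ps <= done)
            if not ready:
                raise ValueError("graph contains a cycle")
            for v in ready:
                order.append(v)
                done.add(v)
                del pending[v]
        return order


@dataclass(frozen=True)
class Move:
    kind: str  # add | delete | reverse
    edge: tuple[str, str]

    def inverse(self) -> "Move":
        u, v = self.edge
        if self.kind == "add":
            return Move("delete", (u, v))
        if self.kind == "delete":
            return Move("add", (u, v))
        return Move("reverse", (v, u))

    @property
    def arc(self) -> frozenset:
        return frozenset(self.edge)


@dataclass(frozen=True)
class SearchConfig:
    score: str = "bic"            # bic | aic | loglik
    tabu_tenure: int = 10
    max_nonimproving: int = 15
    max_iter: int = 10_000
    max_parents: int | None = None
    seed: int = 0
    blacklist: frozenset = frozenset()   # forbidden directed edges
    whitelist: frozenset = frozenset()   # forced directed edges

    def __post_init__(self):
        if self.tabu_tenure < 0 or self.max_iter < 1:
            raise ValueError("invalid search budgets")
        if self.score not in ("bic", "aic", "loglik"):
            raise ValueError(f"unknown score {self.score!r}")


@dataclass
class SearchTrace:
    records: list = field(default_factory=list)

    def log(self, iteration, move, score, best_score, tabu_arcs):
        self.records.append({
            "iteration": iteration,
            "move": move,
            "score": score,
            "best_score": best_score,
            "tabu": tuple(sorted(tuple(sorted(a)) for a in tabu_arcs)),
        })

    @property
    def best_scores(self) -> list:
        return [r["best_score"] for r in self.records]


class ScoreCache:
    """Decomposable family scores over one dataset, memoised.

    ``family(node, parents)`` is the node's local score; the total score of
    a DAG is the sum of its family scores.
    """

    def __init__(self, ds: CategoricalDataset, score: str = "bic"):
        if ds.n == 0:
            raise ValueError("empty dataset")
        self.ds = ds
        self.score = score
        self.n = ds.n
        self._cols = {nm: ds.column(nm) for nm in ds.names}
        self._cards = {nm: len(ds.var(nm).states) for nm in ds.names}
        self._cache: dict[tuple, float] = {}

    def family(self, node: str, parents) -> float:
        if node not in self._cols:
            raise KeyError(f"unknown node {node!r}")
        parents = tuple(sorted(parents))
        if node in parents:
            raise ValueError("node cannot be its own parent")
        key = (node, parents)
        if key not in self._cache:
            self._cache[key] = self._compute(node, parents)
        return self._cache[key]

    def total(self, dag: DAG) -> float:
        return sum(self.family(v, dag.parents[v]) for v in dag.nodes)

    def _compute(self, node: str, parents: tuple) -> float:
        r = self._cards[node]
        code = self._cols[node].copy()
        size = r
        for p in parents:
            code += size * self._cols[p]
            size *= self._cards[p]
        counts = np.bincount(code, minlength=size).reshape(-1, r)
        nij = counts.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = counts * np.log(counts / nij)
        ll = float(np.nansum(terms))  # 0·ln0 = 0
        q = size // r
        if self.score == "bic":
            return ll - 0.5 * math.log(self.n) * (r - 1) * q
        if self.score == "aic":
            return ll - (r - 1) * q
        return ll


def family_score(node, parents, ds: CategoricalDataset, score: str = "bic") -> float:
    """Local score of one (node, parent set) family; see module docstring."""
    return ScoreCache(ds, score).family(node, parents)


def total_score(dag: DAG, ds: CategoricalDataset, score: str = "bic") -> float:
    return ScoreCache(ds, score).total(dag)


def neighborhood(dag: DAG, max_parents: int | None = None,
                 blacklist=frozenset(), whitelist=frozenset()) -> list[Move]:
    """All valid single-edge moves, in deterministic lexicographic order.

    A move is valid when the resulting graph is acyclic, respects
    ``max_parents``, adds no blacklisted edge, and removes no whitelisted
    edge.  Order: additions, then deletions, then reversals, each sorted by
    edge.
    """
    moves: list[Move] = []
    nodes = sorted(dag.nodes)
    for u in nodes:
        for v in nodes:
            if u == v or dag.has_edge(u, v) or dag.has_edge(v, u):
                continue
            if (u, v) in blacklist:
                continue
            if max_parents is not None and len(dag.parents[v]) >= max_parents:
                continue
            if not dag.has_path(v, u):
                moves.append(Move("add", (u, v)))
    for u, v in dag.edges:
        if (u, v) not in whitelist:
            moves.append(Move("delete", (u, v)))
    for u, v in dag.edges:
        if (u, v) in whitelist or (v, u) in blacklist:
            continue
        if max_parents is not None and len(dag.parents[u]) >= max_parents:
            continue
        if not dag.remove_edge(u, v).has_path(u, v):
            moves.append(Move("reverse", (u, v)))
    return moves


def _move_delta(cache: ScoreCache, dag: DAG, move: Move) -> float:
    """Score change of a move; touches only the affected families."""
    u, v = move.edge
    if move.kind == "add":
        return cache.family(v, dag.parents[v] | {u}) - cache.family(v, dag.parents[v])
    if move.kind == "delete":
        return cache.family(v, dag.parents[v] - {u}) - cache.family(v, dag.parents[v])
    return (cache.family(v, dag.parents[v] - {u}) - cache.family(v, dag.parents[v])
            + cache.family(u, dag.parents[u] | {v}) - cache.family(u, dag.parents[u]))


def _initial(ds: CategoricalDataset, config: SearchConfig) -> DAG:
    dag = DAG.empty(ds.names)
    for u, v in sorted(config.whitelist):
        dag = dag.add_edge(u, v)
    return dag


def hill_climb(ds: CategoricalDataset, config: SearchConfig = SearchConfig()
               ) -> tuple[DAG, SearchTrace]:
    """Greedy ascent: apply the best strictly improving move until none exists."""
    cache = ScoreCache(ds, config.score)
    dag = _initial(ds, config)
    score = cache.total(dag)
    trace = SearchTrace()
    for it in range(config.max_iter):
        best_move, best_delta = None, _EPS
        for move in neighborhood(dag, config.max_parents,
                                 config.blacklist, config.whitelist):
            delta = _move_delta(cache, dag, move)
            if delta > best_delta:
                best_move, best_delta = move, delta
        if best_move is None:
            break
        dag = dag.apply(best_move)
        score += best_delta
        trace.log(it, best_move, score, score, ())
    return dag, trace


def tabu_search(ds: CategoricalDataset, config: SearchConfig = SearchConfig()
                ) -> tuple[DAG, SearchTrace]:
    """Tabu search over DAG space.

    Each iteration enumerates the neighbourhood, takes the best admissible
    move — admissible when its arc is not tabu, or, by aspiration, when the
    resulting score strictly beats the best seen — even if it worsens the
    score, then marks the moved arc tabu for ``tabu_tenure`` iterations
    (which also forbids the inverse move).  Stops after
    ``max_nonimproving`` iterations without a new best, or at ``max_iter``,
    and returns the best-scoring DAG visited.
    """
    cache = ScoreCache(ds, config.score)
    dag = _initial(ds, config)
    score = cache.total(dag)
    best_dag, best_score = dag, score
    tabu: dict[frozenset, int] = {}   # arc -> first iteration it is free again
    trace = SearchTrace()
    stall = 0
    for it in range(config.max_iter):
        if stall >= config.max_nonimproving:
            break
        best_move, best_delta = None, None
        for move in neighborhood(dag, config.max_parents,
                                 config.blacklist, config.whitelist):
            delta = _move_delta(cache, dag, move)
            is_tabu = tabu.get(move.arc, 0) > it
            if is_tabu and not score + delta > best_score + _EPS:
                continue  # tabu and fails aspiration
            if best_delta is None or delta > best_delta + _EPS:
                best_move, best_delta = move, delta
        if best_move is None:
            break  # every move tabu and none aspires
        dag = dag.apply(best_move)
        score += best_delta
        tabu[best_move.arc] = it + 1 + config.tabu_tenure
        if score > best_score + _EPS:
            best_dag, best_score = dag, score
            stall = 0
        else:
            stall += 1
        trace.log(it, best_move, score, best_score,
                  [a for a, exp in tabu.items() if exp > it + 1])
    return best_dag, trace
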