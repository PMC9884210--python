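"""Network and graph serialization: BIF, JSON and DOT.

The BIF (Bayesian Interchange Format) writer/reader covers the discrete
subset used here — ``network``, ``variable`` blocks with ``type discrete``,
and ``probability`` blocks with per-parent-configuration rows — and
round-trips every network this package produces.
"""

from __future__ import annotations

import itertools
import json
import re

import numpy as np

from .parameters import CPT, BayesianNetwork
from .structure import DAG

__all__ = ["write_bif", "read_bif", "network_to_json", "network_from_json",
           "dag_to_dot", "dag_to_json", "dag_from_json"]


def _parent_configs(cards):
    return itertools.product(*[range(c) for c in cards])


def write_bif(bn: BayesianNetwork, path) -> None:
    with open(path, "w") as fh:
        fh.write('network "hcynet" { }\n')
        for v in bn.nodes:
            states = ", ".join(bn.states[v])
            fh.write(f"variable {v} {{\n"
                     f"  type discrete [ {bn.card(v)} ] {{ {states} }};\n}}\n")
        for v in bn.nodes:
            cpt = bn.cpts[v]
            if not cpt.parents:
                row = ", ".join(repr(float(x)) for x in cpt.table[0])
                fh.write(f"probability ( {v} ) {{\n  table {row};\n}}\n")
                continue
            head = ", ".join(cpt.parents)
            fh.write(f"probability ( {v} | {head} ) {{\n")
            for i, cfg in enumerate(_parent_configs(cpt.parent_cards)):
                labels = ", ".join(bn.states[p][s]
                                   for p, s in zip(cpt.parents, cfg))
                row = ", ".join(repr(float(x)) for x in cpt.table[i])
                fh.write(f"  ( {labels} ) {row};\n")
            fh.write("}\n")


_VAR_RE = re.compile(
    r"variable\s+(\w+)\s*\{\s*type\s+discrete\s*\[\s*\d+\s*\]\s*"
    r"\{([^}]*)\}\s*;\s*\}", re.S)
_PROB_RE = re.compile(r"probability\s*\(([^)]*)\)\s*\{([^}]*)\}", re.S)


def read_bif(path) -> BayesianNetwork:
    text = open(path).read()
    states: dict[str, tuple[str, ...]] = {}
    for name, raw in _VAR_RE.findall(text):
        states[name] = tuple(s.strip() for s in raw.split(",") if s.strip())
    cpts: dict[str, CPT] = {}
    edges = []
    for head, body in _PROB_RE.findall(text):
        if "|" in head:
            child, rest = head.split("|")
            child = child.strip()
            parents = tuple(p.strip() for p in rest.split(","))
        else:
            child, parents = head.strip(), ()
        order = tuple(sorted(parents))
        cards = tuple(len(states[p]) for p in order)
        r = len(states[child])
        q = int(np.prod(cards)) if order else 1
        table = np.zeros((q, r))
        if not parents:
            m = re.search(r"table([^;]*);", body)
            table[0] = [float(x) for x in m.group(1).split(",")]
        else:
            for m in re.finditer(r"\(([^)]*)\)([^;]*);", body):
                labels = [s.strip() for s in m.group(1).split(",")]
                idx = 0
                for p, lab in sorted(zip(parents, labels)):
                    idx = idx * len(states[p]) + states[p].index(lab)
                table[idx] = [float(x) for x in m.group(2).split(",")]
        cpts[child] = CPT(child, order, cards, table)
        edges += [(p, child) for p in parents]
    dag = DAG.from_edges(tuple(states), edges)
    return BayesianNetwork(dag, cpts, states)


def network_to_json(bn: BayesianNetwork, path=None) -> dict:
    payload = {
        "nodes": list(bn.nodes),
        "states": {v: list(bn.states[v]) for v in bn.nodes},
        "cpts": {
            v: {"parents": list(bn.cpts[v].parents),
                "table": bn.cpts[v].table.tolist()}
            for v in bn.nodes
        },
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return payload


def network_from_json(src) -> BayesianNetwork:
    if not isinstance(src, dict):
        src = json.load(open(src))
    states = {v: tuple(s) for v, s in src["states"].items()}
    edges = [(p, v) for v, c in src["cpts"].items() for p in c["parents"]]
    dag = DAG.from_edges(tuple(src["nodes"]), edges)
    cpts = {}
    for v, c in src["cpts"].items():
        parents = tuple(c["parents"])
        cards = tuple(len(states[p]) for p in parents)
        cpts[v] = CPT(v, parents, cards, np.asarray(c["table"]))
    return BayesianNetwork(dag, cpts, states)


def dag_to_json(dag: DAG, path=None) -> dict:
    payload = {"nodes": list(dag.nodes), "edges": [list(e) for e in dag.edges]}
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    return payload


def dag_from_json(src) -> DAG:
    if not isinstance(src, dict):
        src = json.load(open(src))
    return DAG.from_edges(tuple(src["nodes"]),
                          [tuple(e) for e in src["edges"]])


def dag_to_dot(dag: DAG, path=None) -> str:
    lines = ["digraph G {"]
    lines += [f'  "{v}";' for v in dag.nodes]
    lines += [f'  "{u}" -> "{v}";' for u, v in dag.edges]
    lines.append("}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
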