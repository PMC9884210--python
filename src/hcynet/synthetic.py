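"""Synthetic categorical populations with known ground truth.

The study's raw survey data are not deposited, so every pipeline stage is
exercised on populations sampled from fully specified Bayesian networks:

* :func:`make_hhcy_population` — the 10-node risk-factor network
  (Hcy ← Age, Sex, MCR, FPG, Diet, SBP; Age → SBP ← BMI;
  Sex → Smoking; MCR → FPG ← GHb), the structure-recovery ground truth.
* :func:`make_survey_population` — the full 21-variable survey table, the
  core network plus socioeconomic/lifestyle/lipid variables hanging off it
  and two variables (Exercise, ACR) independent of everything, emulating
  the published univariate screen's pattern.
* :func:`table1_tables` — the published group-by-variable count tables
  verbatim, for worked-example tests on printed numbers.

CPTs use adjacent-category logit links: a node with states 0..r−1 and
parent effect sizes β_p gets row logits ``base_s + s · Σ_p β_p · x_p``.
Base logits are calibrated by exact inference so every node's marginal
matches the published pooled frequency (in particular P(HHcy) = 0.665).
Effect sizes are fixed design constants (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .dataset import CategoricalDataset, VariableSpec, study_schema
from .inference import joint_distribution
from .parameters import CPT, BayesianNetwork
from .screen import ContingencyTable
from .structure import DAG

__all__ = ["GroundTruthSpec", "sample_bn", "make_hhcy_population",
           "make_survey_population", "table1_tables", "table1_counts"]


# Published group-wise counts: variable -> (states, Normal-Hcy column,
# HHcy column).  Column totals are 4110 and 8175 (overall 12,285).
TABLE1_COUNTS: dict[str, tuple[tuple[str, ...], tuple[int, ...], tuple[int, ...]]] = {
    "Sex": (("Male", "Female"), (1195, 2915), (4011, 4164)),
    "Age": (("40-50", "51-60", "61-70", "71-91"),
            (1113, 1584, 1075, 338), (1585, 2907, 2568, 1115)),
    "Education": (("Primary", "Middle", "High", "Bachelor"),
                  (1199, 2154, 541, 216), (2816, 4101, 919, 339)),
    "Income": (("<5k", "5k-10k", "10k-20k", ">20k"),
               (1742, 897, 467, 1004), (3399, 2232, 805, 1739)),
    "Exercise": (("No", "Yes"), (2420, 1690), (4752, 3423)),
    "TG": (("No", "Yes"), (3159, 951), (6437, 1738)),
    "TC": (("No", "Yes"), (3918, 192), (7862, 313)),
    "LDL": (("No", "Yes"), (3978, 132), (7990, 185)),
    "HDL": (("No", "Yes"), (3464, 646), (6540, 1635)),
    "FPG": (("Normal", "Impaired", "High"), (3519, 305, 286), (7382, 413, 380)),
    "GHb": (("No", "Yes"), (3577, 533), (7407, 768)),
    "SBP": (("Low", "Normal", "High"), (701, 2016, 1393), (1130, 3694, 3351)),
    "DBP": (("Low", "Normal", "High"), (1514, 1670, 926), (2868, 3204, 2103)),
    "BMI": (("Underweight", "Normal", "Overweight", "Obesity"),
            (73, 1655, 1772, 610), (129, 3203, 3455, 1388)),
    "Smoking": (("No", "Yes"), (3454, 656), (5905, 2270)),
    "Alcohol": (("Seldom", "Sometimes", "Always"), (3680, 379, 51), (6729, 1237, 209)),
    "Salt": (("Light", "Balanced", "Salt"), (972, 2686, 452), (2263, 4751, 1161)),
    "Diet": (("Vegetable", "Balanced", "Meat"), (1105, 2832, 173), (3011, 4770, 394)),
    "ACR": (("Normal", "Abnormal"), (3600, 510), (7117, 1058)),
    "MCR": (("Normal", "Abnormal"), (3710, 400), (7129, 1046)),
}

GROUP_SIZES = (4110, 8175)  # Normal Hcy, HHcy


def table1_counts(var: str) -> np.ndarray:
    """The published r×2 count table (rows = states, cols = Normal/HHcy)."""
    states, normal, hhcy = TABLE1_COUNTS[var]
    return np.column_stack([normal, hhcy])


def table1_tables() -> dict[str, ContingencyTable]:
    """Every published group-wise contingency table, verbatim."""
    out = {}
    for var, (states, normal, hhcy) in TABLE1_COUNTS.items():
        out[var] = ContingencyTable(np.column_stack([normal, hhcy]),
                                    states, ("Normal", "HHcy"))
    return out


def _pooled(var: str) -> np.ndarray:
    """Pooled (both groups) state frequencies of a published variable."""
    if var == "Hcy":
        c = np.asarray(GROUP_SIZES, dtype=float)
    else:
        c = table1_counts(var).sum(axis=1)
    return c / c.sum()


@dataclass(frozen=True)
class GroundTruthSpec:
    """A fully specified generating network plus sampling parameters."""

    network: BayesianNetwork
    n: int
    seed: int

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("n must be positive")


def sample_bn(spec: GroundTruthSpec) -> CategoricalDataset:
    """Ancestral sampling: draw each node in topological order given its
    sampled parents.  Byte-reproducible for a given seed (PCG64 generator)."""
    bn = spec.network
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    n = spec.n
    cols: dict[str, np.ndarray] = {}
    for v in bn.dag.topological_order():
        cpt = bn.cpts[v]
        if cpt.parents:
            cfg = cpt.config_index(np.column_stack([cols[p] for p in cpt.parents]))
            rows = cpt.table[cfg]
        else:
            rows = np.broadcast_to(cpt.table[0], (n, cpt.r))
        u = rng.random(n)
        cols[v] = (u[:, None] > np.cumsum(rows, axis=1)).sum(axis=1).astype(np.int64)
        np.minimum(cols[v], cpt.r - 1, out=cols[v])  # guard float round-off
    variables = [VariableSpec(v, bn.states[v],
                              "outcome" if v == "Hcy" else "exposure")
                 for v in bn.nodes]
    codes = np.column_stack([cols[v] for v in bn.nodes])
    return CategoricalDataset(variables, codes)


# --- network construction --------------------------------------------------

def _logit_table(cards: tuple[int, ...], r: int, base: np.ndarray,
                 effects: np.ndarray) -> np.ndarray:
    """Adjacent-category logit CPT: row logits base_s + s·(effects·config)."""
    q = int(np.prod(cards)) if cards else 1
    if cards:
        grids = np.meshgrid(*[np.arange(c) for c in cards], indexing="ij")
        cfg = np.stack([g.ravel() for g in grids], axis=1)  # (q, k) row-major
        eta = cfg @ effects
    else:
        eta = np.zeros(1)
    logits = base[None, :] + np.arange(r)[None, :] * eta[:, None]
    logits -= logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    return p


def _calibrated_cpt(node: str, parents: dict[str, int], r: int,
                    effects: dict[str, float], target: np.ndarray,
                    parent_joint: np.ndarray | None) -> CPT:
    """CPT whose base logits are tuned so the node's marginal hits ``target``.

    ``parents`` maps sorted parent names to cardinalities; ``parent_joint``
    is the exact joint over the parents in that order (flattened row-major).
    Fixed-point iteration on the base logits converges in a few dozen steps.
    """
    names = tuple(sorted(parents))
    cards = tuple(parents[p] for p in names)
    eff = np.array([effects.get(p, 0.0) for p in names])
    target = np.asarray(target, dtype=float)
    base = np.log(target / target[0])
    if parent_joint is None:
        parent_joint = np.ones(1)
    w = parent_joint.reshape(-1)
    for _ in range(500):
        table = _logit_table(cards, r, base, eff)
        m = w @ table
        if np.abs(m - target).max() < 1e-12:
            break
        base = base + np.log(target / m) - np.log(target[0] / m[0])
        base -= base[0]
    table = _logit_table(cards, r, base, eff)
    table /= table.sum(axis=1, keepdims=True)
    return CPT(node, names, cards, table)


def _build_network(spec: dict, states: dict[str, tuple[str, ...]]
                   ) -> BayesianNetwork:
    """Assemble and calibrate a network from {node: (parents, effects)}.

    Nodes are built in topological order; each node's base logits are
    calibrated against the exact parent joint of the partially built
    network so that its marginal equals the published pooled frequency.
    """
    dag = DAG.from_edges(tuple(states),
                         [(p, v) for v, (ps, _) in spec.items() for p in ps])
    built: dict[str, CPT] = {}
    for v in dag.topological_order():
        parent_names, effects = spec[v]
        target = _pooled(v)
        r = len(states[v])
        parents = {p: len(states[p]) for p in parent_names}
        if parent_names:
            sub_nodes = [w for w in built]  # ancestors already built
            sub_dag = DAG(tuple(sub_nodes),
                          {w: frozenset(spec[w][0]) for w in sub_nodes})
            sub_bn = BayesianNetwork(
                sub_dag, {w: built[w] for w in sub_nodes},
                {w: states[w] for w in sub_nodes})
            pj = joint_distribution(sub_bn, sorted(parent_names))
        else:
            pj = None
        built[v] = _calibrated_cpt(v, parents, r, effects, target, pj)
    return BayesianNetwork(dag, built, dict(states))


# Per-level effect logits of the generating networks.  Signs mirror the
# published multivariable directions (female, high FPG and vegetable diet
# protective; age, SBP and abnormal MCR adverse); magnitudes are design
# constants chosen for structure recoverability at the study's scale
# (docs/methods.md) and frozen.
_CORE_SPEC: dict[str, tuple[tuple[str, ...], dict[str, float]]] = {
    "Sex": ((), {}),
    "Age": ((), {}),
    "MCR": ((), {}),
    "GHb": ((), {}),
    "BMI": ((), {}),
    "Diet": ((), {}),
    "SBP": (("Age", "BMI"), {"Age": 0.55, "BMI": 0.9}),
    "FPG": (("MCR", "GHb"), {"MCR": 1.3, "GHb": 2.0}),
    "Smoking": (("Sex",), {"Sex": -2.8}),
    "Hcy": (("Age", "Sex", "MCR", "FPG", "Diet", "SBP"),
            {"Age": 0.28, "Sex": -0.65, "MCR": 0.55, "FPG": -0.33,
             "Diet": -0.40, "SBP": 0.28}),
}

_SURVEY_EXTRA: dict[str, tuple[tuple[str, ...], dict[str, float]]] = {
    "Education": (("Age",), {"Age": -0.55}),
    "Income": (("Age",), {"Age": -0.40}),
    "DBP": (("SBP",), {"SBP": 1.5}),
    "TG": (("SBP",), {"SBP": 0.9}),
    "TC": (("SBP",), {"SBP": 0.9}),
    "LDL": (("SBP",), {"SBP": 1.0}),
    "HDL": (("Sex",), {"Sex": 0.90}),
    "Alcohol": (("Sex",), {"Sex": -2.0}),
    "Salt": (("Diet",), {"Diet": 0.70}),
    "Exercise": ((), {}),
    "ACR": ((), {}),
}


def _states_for(names) -> dict[str, tuple[str, ...]]:
    schema = {v.name: v.states for v in study_schema()}
    return {nm: schema[nm] for nm in names}


@lru_cache(maxsize=1)
def hhcy_network() -> BayesianNetwork:
    """The 10-node ground-truth risk-factor network."""
    return _build_network(_CORE_SPEC, _states_for(_CORE_SPEC))


@lru_cache(maxsize=1)
def survey_network() -> BayesianNetwork:
    """The full 21-variable survey-generating network."""
    spec = {**_CORE_SPEC, **_SURVEY_EXTRA}
    return _build_network(spec, _states_for(spec))


def make_hhcy_population(n: int, seed: int
                         ) -> tuple[CategoricalDataset, GroundTruthSpec]:
    """Sample the 10-node risk-factor population; returns data + truth."""
    if n < 100:
        raise ValueError("n must be at least 100")
    spec = GroundTruthSpec(hhcy_network(), n, seed)
    return sample_bn(spec), spec


def make_survey_population(n: int = 12285, seed: int = 0
                           ) -> tuple[CategoricalDataset, GroundTruthSpec]:
    """Sample the full 21-variable survey table; returns data + truth."""
    spec = GroundTruthSpec(survey_network(), n, seed)
    return sample_bn(spec), spec
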