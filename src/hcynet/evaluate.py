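"""Model and algorithm comparison: ROC/AUC and structural distance.

AUC is the Mann–Whitney pair-counting statistic (ties count 1/2), computed
from midranks; its 95% CI uses DeLong's asymptotic variance of the placement
values.  Structural comparison reports the edge diff (added / missing /
reversed), structural Hamming distance and skeleton precision/recall/F1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .structure import DAG

__all__ = ["ROCResult", "StructureDiff", "roc_auc", "compare_structures"]


@dataclass(frozen=True)
class ROCResult:
    auc: float
    ci95: tuple[float, float]
    n_pos: int
    n_neg: int
    curve: np.ndarray  # (k, 2) columns (fpr, tpr), threshold decreasing

    def __post_init__(self):
        if not 0 <= self.auc <= 1:
            raise ValueError("AUC outside [0, 1]")
        lo, hi = self.ci95
        if not lo <= self.auc <= hi:
            raise ValueError("CI does not contain the AUC")


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def roc_auc(scores, labels) -> ROCResult:
    """AUC with DeLong 95% CI for binary ``labels`` scored by ``scores``."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and congruent")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be 0/1")
    m = int(labels.sum())
    n = int(len(labels) - m)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    pos, neg = scores[labels == 1], scores[labels == 0]
    tz = _midrank(np.concatenate([pos, neg]))
    tx, ty = _midrank(pos), _midrank(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2) / (m * n)
    # DeLong placement values
    v01 = (tz[:m] - tx) / n
    v10 = 1.0 - (tz[m:] - ty) / m
    var = (np.var(v01, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v10, ddof=1) / n if n > 1 else 0.0)
    half = 1.96 * np.sqrt(var)
    lo, hi = max(0.0, auc - half), min(1.0, auc + half)
    return ROCResult(float(auc), (float(lo), float(hi)), m, n,
                     _roc_curve(scores, labels))


def _roc_curve(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """(FPR, TPR) at every distinct threshold, from (0,0) to (1,1)."""
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    distinct = np.r_[np.flatnonzero(np.diff(s)), len(s) - 1]
    tp = np.cumsum(y)[distinct]
    fp = (distinct + 1) - tp
    tpr = np.r_[0.0, tp / y.sum()]
    fpr = np.r_[0.0, fp / (len(y) - y.sum())]
    return np.column_stack([fpr, tpr])


@dataclass(frozen=True)
class StructureDiff:
    added: tuple        # edges in learned, arc absent from truth
    missing: tuple      # arcs in truth absent from learned
    reversed: tuple     # arcs present in both, orientation flipped
    n_learned: int
    n_truth: int
    skeleton_precision: float
    skeleton_recall: float
    skeleton_f1: float

    @property
    def shd(self) -> int:
        return len(self.added) + len(self.missing) + len(self.reversed)


def compare_structures(learned: DAG, truth: DAG) -> StructureDiff:
    """Edge-set diff and skeleton metrics between two DAGs on the same nodes."""
    if set(learned.nodes) != set(truth.nodes):
        raise ValueError("DAGs are over different node sets")
    le, te = set(learned.edges), set(truth.edges)
    lsk = {frozenset(e) for e in le}
    tsk = {frozenset(e) for e in te}
    added = tuple(sorted(e for e in le if frozenset(e) not in tsk))
    missing = tuple(sorted(e for e in te if frozenset(e) not in lsk))
    rev = tuple(sorted(e for e in te if (e[1], e[0]) in le))
    tp = len(lsk & tsk)
    prec = tp / len(lsk) if lsk else 1.0
    rec = tp / len(tsk) if tsk else 1.0
    f1 = 2 * prec * rec / (prec + rec) if prec + rec > 0 else 0.0
    return StructureDiff(added, missing, rev, len(le), len(te), prec, rec, f1)


def plot_roc(results: dict[str, ROCResult], path) -> None:
    """Optional ROC plot (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    for name, r in results.items():
        ax.plot(r.curve[:, 0], r.curve[:, 1],
                label=f"{name}: AUC {r.auc:.3f} ({r.ci95[0]:.3f}-{r.ci95[1]:.3f})")
    ax.plot([0, 1], [0, 1], "k:", lw=0.8)
    ax.set_xlabel("False positive rate")
    ax.set_ylabel("True positive rate")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
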