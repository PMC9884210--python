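"""Univariate screening: contingency tables and chi-square tests.

Each baseline variable is cross-tabulated against the binary outcome group
and tested with Pearson's chi-square; 2×2 tables get the Yates continuity
correction by default.  Variables with p below the screening level proceed
to the multivariable logistic stage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .dataset import CategoricalDataset

__all__ = ["ContingencyTable", "ChiSquareResult", "crosstab", "chi_square_test",
           "screen_variables"]


@dataclass(frozen=True)
class ContingencyTable:
    """r×c observed counts with labelled margins."""

    counts: np.ndarray
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("labels do not match counts shape")
        if (counts < 0).any():
            raise ValueError("negative counts")
        if counts.sum() == 0:
            raise ValueError("empty table")

    @property
    def row_margins(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_margins(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def expected(self) -> np.ndarray:
        return np.outer(self.row_margins, self.col_margins) / self.total


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p: float
    corrected: bool


def crosstab(ds: CategoricalDataset, var: str, group: str) -> ContingencyTable:
    """Counts of ``var`` states (rows) by ``group`` states (columns).

    Unobserved states are retained as zero rows/columns so the table shape
    always matches the declared category systems.
    """
    if var == group:
        raise ValueError("var and group must differ")
    vs, gs = ds.var(var), ds.var(group)
    r, c = len(vs.states), len(gs.states)
    flat = np.bincount(ds.column(var) * c + ds.column(group), minlength=r * c)
    return ContingencyTable(flat.reshape(r, c), vs.states, gs.states)


def chi_square_test(table: ContingencyTable, correction: bool = True) -> ChiSquareResult:
    """Pearson chi-square test of independence.

    ``correction`` applies Yates' continuity correction — the numerator
    becomes ``(|O−E| − 0.5)²`` — to 2×2 tables only, the convention that
    reproduces the study's printed 2×2 p-values; larger tables always use
    the plain Pearson statistic.
    """
    O = table.counts.astype(float)
    if (table.row_margins == 0).any():
        bad = table.row_labels[int(np.argmax(table.row_margins == 0))]
        raise ValueError(f"zero margin for row {bad!r}")
    if (table.col_margins == 0).any():
        bad = table.col_labels[int(np.argmax(table.col_margins == 0))]
        raise ValueError(f"zero margin for column {bad!r}")
    E = table.expected()
    corrected = bool(correction and O.shape == (2, 2))
    dev = np.abs(O - E)
    if corrected:
        dev = np.maximum(dev - 0.5, 0.0)
    stat = float((dev**2 / E).sum())
    df = (O.shape[0] - 1) * (O.shape[1] - 1)
    return ChiSquareResult(stat, df, float(stats.chi2.sf(stat, df)), corrected)


def screen_variables(
    ds: CategoricalDataset,
    outcome: str,
    alpha: float = 0.05,
    correction: bool = True,
) -> tuple[list[str], dict[str, ChiSquareResult]]:
    """Chi-square screen of every non-outcome variable against ``outcome``.

    Returns the names with p < alpha (in dataset order) and all per-variable
    results.  No multiplicity adjustment is applied across the screens.
    """
    if not 0 < alpha <= 1:
        raise ValueError("alpha must be in (0, 1]")
    if len(ds.var(outcome).states) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary")
    results: dict[str, ChiSquareResult] = {}
    selected: list[str] = []
    for name in ds.names:
        if name == outcome:
            continue
        res = chi_square_test(crosstab(ds, name, outcome), correction=correction)
        results[name] = res
        # alpha == 1 means "no screening": keep even exact-fit tables (p = 1)
        if res.p < alpha or alpha >= 1:
            selected.append(name)
    return selected, results


def screen_tables(
    tables: dict[str, ContingencyTable], alpha: float = 0.05, correction: bool = True
) -> tuple[list[str], dict[str, ChiSquareResult]]:
    """Screen pre-built contingency tables (e.g. published count tables)."""
    results = {nm: chi_square_test(t, correction=correction) for nm, t in tables.items()}
    selected = [nm for nm, r in results.items() if r.p < alpha]
    return selected, results
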