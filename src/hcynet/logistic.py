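"""Binary logistic regression and stepwise variable selection.

Fits use Newton/IRLS (via statsmodels) with standard errors from the inverse
observed information.  Multi-level categorical predictors enter as single
ordinal integer scores by default — one coefficient per variable, i.e. one
odds ratio per step up the category ladder, matching how the study reports a
single OR for each multi-level factor — with dummy coding as an option.

Stepwise selection is forward entry / backward removal on likelihood-ratio
p-values with entry level ``alpha_in`` and removal level ``alpha_out``.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .dataset import CategoricalDataset

__all__ = ["LogisticFit", "StepwiseConfig", "fit_logistic", "odds_ratio",
           "stepwise_select"]

_Z95 = 1.96  # 95% CI multiplier used throughout


@dataclass(frozen=True)
class LogisticFit:
    """Coefficients and Wald/OR summaries for one fitted model."""

    terms: tuple[str, ...]          # includes "Constant" first
    B: np.ndarray
    SE: np.ndarray
    wald_p: np.ndarray
    loglik: float
    converged: bool
    n: int

    @property
    def OR(self) -> np.ndarray:
        return np.exp(self.B)

    @property
    def CI95(self) -> np.ndarray:
        return np.stack([np.exp(self.B - _Z95 * self.SE),
                         np.exp(self.B + _Z95 * self.SE)], axis=1)

    def coef(self, term: str) -> float:
        return float(self.B[self.terms.index(term)])


@dataclass(frozen=True)
class StepwiseConfig:
    alpha_in: float = 0.05
    alpha_out: float = 0.10
    max_steps: int = 100

    def __post_init__(self):
        if not 0 < self.alpha_in <= self.alpha_out < 1:
            raise ValueError("need 0 < alpha_in <= alpha_out < 1")


def odds_ratio(B: float, SE: float) -> tuple[float, tuple[float, float]]:
    """OR = exp(B) with 95% CI exp(B ± 1.96·SE)."""
    if not SE > 0:
        raise ValueError("SE must be positive")
    return float(np.exp(B)), (float(np.exp(B - _Z95 * SE)),
                              float(np.exp(B + _Z95 * SE)))


def _design(ds: CategoricalDataset, predictors: list[str], coding: str):
    """Build (columns, column names, per-predictor column spans)."""
    cols, names, spans = [], ["Constant"], {}
    cols.append(np.ones(ds.n))
    for p in predictors:
        k = len(ds.var(p).states)
        x = ds.column(p).astype(float)
        start = len(names)
        if coding == "score" or k == 2:
            cols.append(x)
            names.append(p)
        elif coding == "dummy":
            for s in range(1, k):
                cols.append((ds.column(p) == s).astype(float))
                names.append(f"{p}[{ds.var(p).states[s]}]")
        else:
            raise ValueError(f"unknown coding {coding!r}")
        spans[p] = (start, len(names))
    return np.column_stack(cols), names, spans


def fit_logistic(
    ds: CategoricalDataset,
    outcome: str,
    predictors: list[str],
    coding: str = "score",
) -> LogisticFit:
    """Maximum-likelihood logistic fit of a binary outcome.

    The outcome is the indicator of its second state (index 1).  Raises on a
    constant outcome or a singular design (naming the collinear columns);
    complete separation is flagged via ``converged=False`` with a warning.
    """
    if len(ds.var(outcome).states) != 2:
        raise ValueError(f"outcome {outcome!r} must be binary")
    y = ds.column(outcome).astype(float)
    if y.min() == y.max():
        raise ValueError(f"outcome {outcome!r} is constant")
    X, names, _ = _design(ds, predictors, coding)
    if ds.n <= X.shape[1]:
        raise ValueError("more terms than observations")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns by greedy QR-style elimination
        keep, bad = [], []
        for j in range(X.shape[1]):
            trial = X[:, keep + [j]]
            if np.linalg.matrix_rank(trial) > len(keep):
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"singular design; collinear terms: {bad}")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # separation warnings handled below
        try:
            res = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=100,
                                     tol=1e-10, warn_convergence=False)
            converged = bool(res.mle_retvals.get("converged", False))
        except np.linalg.LinAlgError:
            # Hessian became singular (typical of complete separation);
            # fall back to a gradient method and flag the fit
            res = sm.Logit(y, X).fit(disp=0, method="bfgs", maxiter=200,
                                     warn_convergence=False)
            converged = False
    if not converged or np.abs(res.params).max() > 20:
        converged = False
        warnings.warn(
            "logistic fit did not converge (possible complete separation)",
            RuntimeWarning, stacklevel=2,
        )
    B = np.asarray(res.params, dtype=float)
    SE = np.asarray(res.bse, dtype=float)
    SE = np.where(np.isfinite(SE), SE, np.inf)
    z = np.divide(B, SE, out=np.zeros_like(B), where=SE > 0)
    wald_p = 2 * stats.norm.sf(np.abs(z))
    return LogisticFit(tuple(names), B, SE, wald_p, float(res.llf), converged, ds.n)


def _lrt_p(ll_full: float, ll_reduced: float, df: int) -> float:
    lr = max(2.0 * (ll_full - ll_reduced), 0.0)
    return float(stats.chi2.sf(lr, df))


def stepwise_select(
    ds: CategoricalDataset,
    outcome: str,
    candidates: list[str],
    config: StepwiseConfig = StepwiseConfig(),
    coding: str = "score",
) -> tuple[list[str], LogisticFit, list[dict]]:
    """Forward/backward stepwise selection on likelihood-ratio p-values.

    Each forward step adds the candidate with the smallest LRT p-value
    below ``alpha_in`` (ties broken lexicographically); each backward step
    removes the included term with the largest LRT p-value above
    ``alpha_out``.  Iterates to a fixed point, recording every move in the
    trace.  If a model state repeats (cycling), stops with a warning and
    returns the best-log-likelihood state visited.
    """
    if not candidates:
        raise ValueError("no candidate predictors")
    cache: dict[frozenset, LogisticFit] = {}

    def fit(sel: frozenset) -> LogisticFit:
        if sel not in cache:
            cache[sel] = fit_logistic(ds, outcome, sorted(sel), coding=coding)
        return cache[sel]

    def df_of(name: str) -> int:
        k = len(ds.var(name).states)
        return 1 if (coding == "score" or k == 2) else k - 1

    selected: frozenset = frozenset()
    trace: list[dict] = []
    seen = {selected}
    best_state, best_ll = selected, fit(selected).loglik
    for _ in range(config.max_steps):
        current = fit(selected)
        # forward
        entry = []
        for cand in sorted(set(candidates) - selected):
            p = _lrt_p(fit(selected | {cand}).loglik, current.loglik, df_of(cand))
            entry.append((p, cand))
        added = None
        if entry:
            p, cand = min(entry)  # lexicographic tie-break via tuple order
            if p < config.alpha_in:
                selected = selected | {cand}
                trace.append({"action": "add", "term": cand, "p": p})
                added = cand
        # backward
        removed = None
        current = fit(selected)
        if selected:
            removal = []
            for term in sorted(selected):
                p = _lrt_p(current.loglik, fit(selected - {term}).loglik, df_of(term))
                removal.append((p, term))
            p, term = max(removal)
            if p > config.alpha_out:
                selected = selected - {term}
                trace.append({"action": "remove", "term": term, "p": p})
                removed = term
        if fit(selected).loglik > best_ll:
            best_state, best_ll = selected, fit(selected).loglik
        if added is None and removed is None:
            break
        if selected in seen and (added or removed):
            warnings.warn("stepwise selection cycled; returning best state",
                          RuntimeWarning, stacklevel=2)
            selected = best_state
            break
        seen.add(selected)
    order = [c for c in candidates if c in selected]
    return order, fit(frozenset(selected)), trace
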