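"""End-to-end analysis: screen → stepwise select → learn → fit → infer → evaluate.

Mirrors the study's modelling chain: chi-square screening of every baseline
variable against the outcome, stepwise logistic selection among the
significant ones, score-based structure learning over the selected
variables plus the outcome (tabu search and/or hill climbing), ML parameter
fitting, prior/posterior queries, and per-target ROC evaluation.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dataset as dsmod
from .dataset import CategoricalDataset, load_dataset, study_schema
from .evaluate import ROCResult, compare_structures, roc_auc
from .inference import marginal, posterior, predict_proba
from .logistic import StepwiseConfig, stepwise_select
from .netio import dag_to_dot, dag_to_json, network_to_json, write_bif
from .parameters import BayesianNetwork, fit_mle
from .screen import screen_variables
from .structure import SearchConfig, hill_climb, tabu_search
from .synthetic import make_hhcy_population, make_survey_population

log = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Everything one run needs; defaults mirror the study's settings."""

    input: str | None = None          # CSV path; None -> simulate
    simulate: str = "survey"          # survey | core
    n: int = 12285
    seed: int = 0
    outcome: str = "Hcy"
    alpha_screen: float = 0.05
    alpha_in: float = 0.05
    alpha_out: float = 0.10
    algorithms: tuple[str, ...] = ("tabu", "hc")
    score: str = "bic"
    tabu_tenure: int = 10
    max_nonimproving: int = 15
    max_iter: int = 10_000
    max_parents: int | None = None
    pseudocount: float = 0.0
    roc_targets: tuple[str, ...] = ()   # defaults to (outcome,)
    output_dir: str | None = None

    def __post_init__(self):
        for a in (self.alpha_screen, self.alpha_in, self.alpha_out):
            if not 0 < a < 1:
                raise ValueError("thresholds must lie in (0, 1)")
        if self.input is not None and not Path(self.input).exists():
            raise FileNotFoundError(self.input)
        bad = set(self.algorithms) - {"tabu", "hc"}
        if bad:
            raise ValueError(f"unknown algorithms {sorted(bad)}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("algorithms", "roc_targets"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class RunReport:
    config: PipelineConfig
    n: int
    screen_table: pd.DataFrame
    screened: list
    selected: list
    stepwise_table: pd.DataFrame
    stepwise_trace: list
    dags: dict
    networks: dict
    priors: dict
    roc: dict                      # (algorithm, target) -> ROCResult
    structure_diff: object | None  # tabu vs hc, when both run
    timings: dict

    def summary(self) -> str:
        lines = [f"subjects: {self.n}",
                 f"screen: {len(self.screened)} of "
                 f"{len(self.screen_table)} variables significant "
                 f"(alpha={self.config.alpha_screen})",
                 f"stepwise: selected {', '.join(self.selected)}"]
        for alg, dag in self.dags.items():
            lines.append(f"{alg}: {len(dag.nodes)} nodes, "
                         f"{len(dag.edges)} directed edges; "
                         f"P({self.config.outcome}) prior = "
                         f"{self.priors[alg]:.3f}")
        for (alg, tgt), r in self.roc.items():
            lines.append(f"AUC[{alg}, {tgt}] = {r.auc:.3f} "
                         f"(95% CI {r.ci95[0]:.3f}-{r.ci95[1]:.3f})")
        if self.structure_diff is not None:
            d = self.structure_diff
            lines.append(f"tabu vs hc: SHD {d.shd}, skeleton F1 {d.skeleton_f1:.3f}")
        return "\n".join(lines)


def _get_data(cfg: PipelineConfig):
    if cfg.input is not None:
        return load_dataset(cfg.input, study_schema()), None
    maker = make_survey_population if cfg.simulate == "survey" else make_hhcy_population
    return maker(cfg.n, cfg.seed)


def run_pipeline(cfg: PipelineConfig) -> RunReport:
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}

    def stage(name):
        timings[name] = time.perf_counter()
        log.info("stage %s", name)

    def done(name):
        timings[name] = time.perf_counter() - timings[name]

    stage("data")
    ds, truth = _get_data(cfg)
    done("data")

    stage("screen")
    screened, chi = screen_variables(ds, cfg.outcome, cfg.alpha_screen)
    screen_table = pd.DataFrame(
        [{"variable": v, "statistic": r.statistic, "df": r.df, "p": r.p,
          "corrected": r.corrected, "selected": v in screened}
         for v, r in chi.items()])
    done("screen")

    stage("select")
    selected, fit, trace = stepwise_select(
        ds, cfg.outcome, screened,
        StepwiseConfig(cfg.alpha_in, cfg.alpha_out))
    rows = []
    for i, t in enumerate(fit.terms):
        lo, hi = fit.CI95[i]
        rows.append({"term": t, "B": fit.B[i], "SE": fit.SE[i],
                     "p": fit.wald_p[i], "OR": fit.OR[i],
                     "CI95_low": lo, "CI95_high": hi})
    stepwise_table = pd.DataFrame(rows)
    done("select")

    nodes = selected + [cfg.outcome]
    sub = ds.subset(nodes)
    search = SearchConfig(score=cfg.score, tabu_tenure=cfg.tabu_tenure,
                          max_nonimproving=cfg.max_nonimproving,
                          max_iter=cfg.max_iter, max_parents=cfg.max_parents)
    dags, networks, priors, roc = {}, {}, {}, {}
    targets = cfg.roc_targets or (cfg.outcome,)
    for alg in cfg.algorithms:
        stage(alg)
        learner = tabu_search if alg == "tabu" else hill_climb
        dag, _ = learner(sub, search)
        bn = fit_mle(dag, sub, cfg.pseudocount)
        dags[alg], networks[alg] = dag, bn
        priors[alg] = float(marginal(bn, cfg.outcome).distribution[1])
        for tgt in targets:
            proba = predict_proba(bn, tgt, sub)
            labels = (sub.column(tgt) == len(sub.var(tgt).states) - 1).astype(int)
            roc[(alg, tgt)] = roc_auc(proba[:, -1], labels)
        done(alg)

    diff = None
    if "tabu" in dags and "hc" in dags:
        diff = compare_structures(dags["tabu"], dags["hc"])

    report = RunReport(cfg, ds.n, screen_table, screened, selected,
                       stepwise_table, trace, dags, networks, priors, roc,
                       diff, timings)
    if out:
        _write_artifacts(report, out)
    return report


def _write_artifacts(report: RunReport, out: Path) -> None:
    report.screen_table.to_csv(out / "screen.csv", index=False)
    report.stepwise_table.to_csv(out / "stepwise.csv", index=False)
    with open(out / "stepwise_trace.json", "w") as fh:
        json.dump(report.stepwise_trace, fh, indent=1)
    for alg, dag in report.dags.items():
        dag_to_json(dag, out / f"dag_{alg}.json")
        dag_to_dot(dag, out / f"dag_{alg}.dot")
        write_bif(report.networks[alg], out / f"network_{alg}.bif")
        network_to_json(report.networks[alg], out / f"network_{alg}.json")
    rows = [{"algorithm": alg, "target": tgt, "auc": r.auc,
             "ci_low": r.ci95[0], "ci_high": r.ci95[1],
             "n_pos": r.n_pos, "n_neg": r.n_neg}
            for (alg, tgt), r in report.roc.items()]
    pd.DataFrame(rows).to_csv(out / "roc.csv", index=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(report.summary() + "\n")
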