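"""Variable definitions, categorical coding, and subject tables.

The study population is a rural screening cohort in which every analysis
variable is categorical: demographics (sex, age band, education, income),
lifestyle (exercise, smoking, alcohol, salt, diet), clinical chemistry coded
against guideline cut-offs (TG, TC, LDL, HDL, FPG, GHb), blood pressure
(SBP, DBP), anthropometry (BMI), urinary ratios (ACR, MCR) and the outcome,
hyperhomocysteinemia (serum Hcy > 15 μmol/L).

This module holds the category systems and turns raw measurements into the
integer-coded table every downstream stage consumes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CodingRule",
    "VariableSpec",
    "CategoricalDataset",
    "code_value",
    "derive_ratios",
    "apply_exclusions",
    "load_dataset",
    "write_dataset",
    "study_schema",
]


class CodingError(ValueError):
    """A cell value could not be mapped to a category."""


class SchemaError(ValueError):
    """Input columns do not match the declared schema."""


@dataclass(frozen=True)
class CodingRule:
    """Map a numeric measurement onto ordered category labels.

    ``breaks`` are strictly increasing cut-offs splitting the real line into
    ``len(breaks) + 1`` intervals labelled by ``labels``.  ``at_break[i]``
    says which side an exact hit on ``breaks[i]`` belongs to: ``"right"``
    means the cut-off opens the upper interval (e.g. SBP ``>= 140`` is High),
    ``"left"`` means it closes the lower one (e.g. Hcy ``> 15`` is HHcy, so
    15.0 itself is Normal).
    """

    breaks: tuple[float, ...]
    labels: tuple[str, ...]
    at_break: tuple[str, ...]
    units: str = ""

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.breaks) + 1:
            raise ValueError("need one label per interval")
        if len(self.at_break) != len(self.breaks):
            raise ValueError("need one closure flag per break")
        if any(s not in ("left", "right") for s in self.at_break):
            raise ValueError("closure flags must be 'left' or 'right'")
        if any(b2 <= b1 for b1, b2 in zip(self.breaks, self.breaks[1:])):
            raise ValueError("breaks must be strictly increasing")

    def code(self, x: float) -> str:
        if not math.isfinite(x):
            raise CodingError(f"cannot code non-finite value {x!r}")
        i = 0
        for b, side in zip(self.breaks, self.at_break):
            if x > b or (x == b and side == "right"):
                i += 1
        return self.labels[i]


@dataclass(frozen=True)
class VariableSpec:
    """One analysis variable: its ordered states and optional numeric coding."""

    name: str
    states: tuple[str, ...]
    role: str = "exposure"  # exposure | outcome | demographic
    coding: CodingRule | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise ValueError(f"{self.name}: need at least 2 states")
        if len(set(self.states)) != len(self.states):
            raise ValueError(f"{self.name}: duplicate state labels")
        if self.coding is not None and set(self.coding.labels) - set(self.states):
            raise ValueError(f"{self.name}: coding labels not a subset of states")

    def index_of(self, label: str) -> int:
        try:
            return self.states.index(label)
        except ValueError:
            raise CodingError(
                f"{self.name}: {label!r} is not one of {list(self.states)}"
            ) from None


def code_value(x: float, rule: CodingRule) -> str:
    """Category label of the unique interval containing ``x``."""
    return rule.code(float(x))


def derive_ratios(malb: float, a1mg: float, ucr: float) -> tuple[float, float]:
    """Urinary ratios from morning-urine chemistry.

    ACR = mAlb / Ucr × 8.84 and MCR = α1-MG / Ucr × 8.84, both in mg/g, with
    mAlb and α1-MG in mg/L and urine creatinine in mmol/L (8.84 converts
    mmol/L creatinine to g/L).  Downstream coding flags ACR ≥ 30 mg/g and
    MCR > 23 mg/g as abnormal.
    """
    if not ucr > 0:
        raise ValueError(f"urine creatinine must be positive, got {ucr}")
    return malb / ucr * 8.84, a1mg / ucr * 8.84


@dataclass
class CategoricalDataset:
    """Integer-coded subjects × variables table.

    ``codes[i, j]`` indexes ``variables[j].states``.  Construction validates
    every cell; there are no missing values (exclusion is complete-case and
    happens upstream via :func:`apply_exclusions`).
    """

    variables: list[VariableSpec]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if self.codes.ndim != 2 or self.codes.shape[1] != len(self.variables):
            raise ValueError("codes must be n × len(variables)")
        for j, v in enumerate(self.variables):
            col = self.codes[:, j]
            if col.size and (col.min() < 0 or col.max() >= len(v.states)):
                raise ValueError(f"{v.name}: state index out of range")

    @property
    def n(self) -> int:
        return self.codes.shape[0]

    @property
    def names(self) -> list[str]:
        return [v.name for v in self.variables]

    def var(self, name: str) -> VariableSpec:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def column(self, name: str) -> np.ndarray:
        return self.codes[:, self.names.index(name)]

    def cardinalities(self, names: list[str] | None = None) -> list[int]:
        names = names or self.names
        return [len(self.var(nm).states) for nm in names]

    def subset(self, names: list[str]) -> "CategoricalDataset":
        idx = [self.names.index(nm) for nm in names]
        return CategoricalDataset([self.variables[i] for i in idx], self.codes[:, idx])

    def to_frame(self) -> pd.DataFrame:
        data = {
            v.name: pd.Categorical.from_codes(self.codes[:, j], list(v.states))
            for j, v in enumerate(self.variables)
        }
        return pd.DataFrame(data)

    @classmethod
    def from_frame(
        cls, frame: pd.DataFrame, schema: list[VariableSpec]
    ) -> "CategoricalDataset":
        """Code a label/numeric DataFrame against ``schema``.

        Cells may be state labels, or raw numbers for variables with a
        coding rule.  Unknown labels raise :class:`CodingError` naming the
        row and column.
        """
        missing = [v.name for v in schema if v.name not in frame.columns]
        if missing:
            raise SchemaError(f"input lacks columns {missing}")
        codes = np.empty((len(frame), len(schema)), dtype=np.int64)
        for j, v in enumerate(schema):
            col = frame[v.name]
            for i, (row_label, cell) in enumerate(col.items()):
                codes[i, j] = _code_cell(cell, v, row_label)
        return cls(list(schema), codes)


def _code_cell(cell, v: VariableSpec, row_label) -> int:
    if isinstance(cell, str):
        s = cell.strip()
        if s in v.states:
            return v.states.index(s)
        if v.coding is not None:
            try:
                x = float(s)
            except ValueError:
                raise CodingError(
                    f"row {row_label}, column {v.name}: {cell!r} is neither a "
                    f"state of {list(v.states)} nor numeric"
                ) from None
            return v.index_of(v.coding.code(x))
        raise CodingError(
            f"row {row_label}, column {v.name}: unknown state {cell!r}"
        )
    # numeric cell
    if v.coding is None:
        raise CodingError(
            f"row {row_label}, column {v.name}: numeric cell {cell!r} but "
            "variable has no coding rule"
        )
    try:
        return v.index_of(v.coding.code(float(cell)))
    except (TypeError, ValueError):
        raise CodingError(
            f"row {row_label}, column {v.name}: cannot code {cell!r}"
        ) from None


def apply_exclusions(
    frame: pd.DataFrame,
    min_age: float = 40,
    age_column: str = "Age",
) -> pd.DataFrame:
    """Complete-case exclusion plus the minimum-age inclusion rule.

    Drops rows with any missing/blank cell, and — when ``age_column`` holds
    numeric ages — rows below ``min_age``.  Removal counts are logged.
    Raises if nothing survives.
    """
    cleaned = frame.replace(r"^\s*$", np.nan, regex=True)
    complete = cleaned.dropna()
    n_missing = len(frame) - len(complete)
    n_young = 0
    if age_column in complete.columns:
        ages = pd.to_numeric(complete[age_column], errors="coerce")
        if ages.notna().any():  # numeric ages, not pre-coded bands
            keep = ages >= min_age
            n_young = int((~keep).sum())
            complete = complete[keep]
    log.info(
        "exclusions: %d incomplete, %d below age %s; %d rows retained",
        n_missing, n_young, min_age, len(complete),
    )
    if complete.empty:
        raise ValueError("no rows remain after exclusions")
    return complete.reset_index(drop=True)


def load_dataset(path, schema: list[VariableSpec]) -> CategoricalDataset:
    """Read a subjects × variables CSV and code it against ``schema``."""
    frame = pd.read_csv(path, dtype=str)
    ds = CategoricalDataset.from_frame(frame, schema)
    log.info("loaded %d subjects × %d variables from %s", ds.n, len(schema), path)
    return ds


def write_dataset(ds: CategoricalDataset, path) -> None:
    """Write state labels (not integer codes) as CSV."""
    ds.to_frame().to_csv(path, index=False)


def schema_to_json(schema: list[VariableSpec], path) -> None:
    payload = []
    for v in schema:
        item: dict = {"name": v.name, "states": list(v.states), "role": v.role}
        if v.coding is not None:
            item["coding"] = {
                "breaks": list(v.coding.breaks),
                "labels": list(v.coding.labels),
                "at_break": list(v.coding.at_break),
                "units": v.coding.units,
            }
        payload.append(item)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


# --- The study's category systems -----------------------------------------
#
# Boundary conventions follow the explicit inequalities of the guidelines the
# study cites: intervals are lower-closed/upper-open except where a strict
# ">" is stated (Hcy > 15 is abnormal, so 15.0 is Normal; MCR > 23 likewise;
# FPG impaired spans [6.1, 7.0] with High strictly > 7.0).

def _rule(breaks, labels, at_break=None, units=""):
    at_break = at_break or ("right",) * len(breaks)
    return CodingRule(tuple(breaks), tuple(labels), tuple(at_break), units)


def study_schema() -> list[VariableSpec]:
    """The 20 baseline variables plus the Hcy outcome, in table order."""
    V = VariableSpec
    return [
        V("Sex", ("Male", "Female"), "demographic"),
        V("Age", ("40-50", "51-60", "61-70", "71-91"), "demographic",
          _rule([51, 61, 71], ["40-50", "51-60", "61-70", "71-91"], units="years")),
        V("Education", ("Primary", "Middle", "High", "Bachelor"), "demographic"),
        V("Income", ("<5k", "5k-10k", "10k-20k", ">20k"), "demographic",
          _rule([5000, 10000, 20000], ["<5k", "5k-10k", "10k-20k", ">20k"],
                units="yuan/year")),
        V("Exercise", ("No", "Yes")),
        V("TG", ("No", "Yes"),
          coding=_rule([2.26], ["No", "Yes"], units="mmol/L")),
        V("TC", ("No", "Yes"),
          coding=_rule([6.22], ["No", "Yes"], units="mmol/L")),
        V("LDL", ("No", "Yes"),
          coding=_rule([4.14], ["No", "Yes"], units="mmol/L")),
        # HDL abnormality is *low* HDL (< 1.04), so the upper interval is "No"
        V("HDL", ("No", "Yes"),
          coding=_rule([1.04], ["Yes", "No"], units="mmol/L")),
        V("FPG", ("Normal", "Impaired", "High"),
          coding=_rule([6.1, 7.0], ["Normal", "Impaired", "High"],
                       at_break=("right", "left"), units="mmol/L")),
        V("GHb", ("No", "Yes"),
          coding=_rule([6.5], ["No", "Yes"], units="mmol/L")),
        V("SBP", ("Low", "Normal", "High"),
          coding=_rule([120, 140], ["Low", "Normal", "High"], units="mmHg")),
        V("DBP", ("Low", "Normal", "High"),
          coding=_rule([80, 90], ["Low", "Normal", "High"], units="mmHg")),
        V("BMI", ("Underweight", "Normal", "Overweight", "Obesity"),
          coding=_rule([18.5, 24.0, 28.0],
                       ["Underweight", "Normal", "Overweight", "Obesity"],
                       units="kg/m2")),
        V("Smoking", ("No", "Yes")),
        V("Alcohol", ("Seldom", "Sometimes", "Always")),
        V("Salt", ("Light", "Balanced", "Salt")),
        V("Diet", ("Vegetable", "Balanced", "Meat")),
        V("ACR", ("Normal", "Abnormal"),
          coding=_rule([30], ["Normal", "Abnormal"], units="mg/g")),
        V("MCR", ("Normal", "Abnormal"),
          coding=_rule([23], ["Normal", "Abnormal"], at_break=("left",),
                       units="mg/g")),
        V("Hcy", ("Normal", "HHcy"), "outcome",
          _rule([15], ["Normal", "HHcy"], at_break=("left",), units="μmol/L")),
    ]
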