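"""Variable coding, ratio derivation, exclusions and CSV round-trips."""

import io

import numpy as np
import pandas as pd
import pytest

from hcynet.dataset import (CategoricalDataset, CodingRule, VariableSpec,
                            apply_exclusions, code_value, derive_ratios,
                            load_dataset, study_schema, write_dataset)
from hcynet.dataset import CodingError, SchemaError


def _schema_var(name):
    for v in study_schema():
        if v.name == name:
            return v
    raise KeyError(name)


@pytest.mark.parametrize("var,x,expected", [
    ("BMI", 25.0, "Overweight"),
    ("BMI", 24.0, "Overweight"),     # lower-closed band
    ("BMI", 18.49, "Underweight"),
    ("SBP", 140, "High"),            # >= 140 is High
    ("SBP", 139.9, "Normal"),
    ("FPG", 6.0, "Normal"),
    ("FPG", 6.1, "Impaired"),
    ("FPG", 7.0, "Impaired"),        # High is strictly > 7.0
    ("FPG", 7.01, "High"),
    ("Hcy", 15.0, "Normal"),         # HHcy is strictly > 15
    ("Hcy", 15.000001, "HHcy"),
    ("MCR", 23.0, "Normal"),         # abnormal is strictly > 23
    ("ACR", 30.0, "Abnormal"),       # abnormal is >= 30
    ("HDL", 1.03, "Yes"),            # low HDL is the abnormal state
    ("HDL", 1.04, "No"),
    ("Age", 50, "40-50"),
    ("Age", 51, "51-60"),
    ("Age", 71, "71-91"),
])
def test_guideline_cutoffs(var, x, expected):
    spec = _schema_var(var)
    assert code_value(x, spec.coding) == expected


def test_coding_is_total_and_matches_interval_membership(rng):
    """Coding any finite value agrees with an explicit interval scan."""
    for spec in study_schema():
        rule = spec.coding
        if rule is None:
            continue
        lo = min(rule.breaks) - 10
        hi = max(rule.breaks) + 10
        xs = rng.uniform(lo, hi, size=10_000)
        for x in xs:
            # oracle: count of breaks strictly below x, plus boundary side
            k = sum(1 for b, side in zip(rule.breaks, rule.at_break)
                    if x > b or (x == b and side == "right"))
            assert code_value(x, rule) == rule.labels[k]


def test_boundary_neighbours_fall_in_adjacent_categories():
    eps = 1e-9
    for spec in study_schema():
        rule = spec.coding
        if rule is None:
            continue
        for i, b in enumerate(rule.breaks):
            assert code_value(b - eps, rule) == rule.labels[i]
            assert code_value(b + eps, rule) == rule.labels[i + 1]


try:
    from hypothesis import given, settings, strategies as st

    @given(st.floats(min_value=-1e6, max_value=1e6,
                     allow_nan=False, allow_infinity=False))
    @settings(max_examples=300, derandomize=True, deadline=None)
    def test_every_finite_value_maps_to_exactly_one_interval(x):
        """The coding intervals of every rule partition the real line."""
        for spec in study_schema():
            rule = spec.coding
            if rule is None:
                continue
            label = code_value(x, rule)
            hits = [i for i in range(len(rule.labels))
                    if _in_interval(x, rule, i)]
            assert hits == [rule.labels.index(label)]

    def _in_interval(x, rule, i):
        lo = rule.breaks[i - 1] if i > 0 else None
        hi = rule.breaks[i] if i < len(rule.breaks) else None
        ok = True
        if lo is not None:
            ok &= x > lo or (x == lo and rule.at_break[i - 1] == "right")
        if hi is not None:
            ok &= x < hi or (x == hi and rule.at_break[i] == "left")
        return ok
except ImportError:  # hypothesis is an optional test dependency
    pass


def test_code_value_rejects_non_finite():
    rule = _schema_var("BMI").coding
    for bad in (float("nan"), float("inf")):
        with pytest.raises(CodingError):
            code_value(bad, rule)


class TestDeriveRatios:
    def test_acr_boundary_arithmetic(self):
        acr, _ = derive_ratios(34, 0, 10)
        assert acr == pytest.approx(30.056)
        assert code_value(acr, _schema_var("ACR").coding) == "Abnormal"
        acr2, _ = derive_ratios(33.9, 0, 10)
        assert acr2 == pytest.approx(29.9676)
        assert code_value(acr2, _schema_var("ACR").coding) == "Normal"

    def test_zero_numerator(self):
        _, mcr = derive_ratios(10, 0, 3.7)
        assert mcr == 0.0
        assert code_value(mcr, _schema_var("MCR").coding) == "Normal"

    def test_nonpositive_creatinine_rejected(self):
        with pytest.raises(ValueError):
            derive_ratios(10, 10, 0)


class TestExclusions:
    def test_incomplete_rows_dropped(self):
        frame = pd.DataFrame({"Sex": ["Male", "Female", None, "Male", "Female"],
                              "Smoking": ["Yes", "No", "No", "Yes", "No"]})
        out = apply_exclusions(frame)
        assert len(out) == 4

    def test_minimum_age(self):
        frame = pd.DataFrame({"Age": [39, 40, 77], "Sex": ["Male"] * 3})
        out = apply_exclusions(frame, min_age=40)
        assert list(pd.to_numeric(out["Age"])) == [40, 77]

    def test_complete_data_identity(self):
        frame = pd.DataFrame({"Sex": ["Male", "Female"], "Age": [45, 60]})
        assert apply_exclusions(frame).shape == frame.shape

    def test_empty_result_raises(self):
        frame = pd.DataFrame({"Age": [20, 25]})
        with pytest.raises(ValueError):
            apply_exclusions(frame, min_age=40)


class TestLoadAndRoundTrip:
    schema = [VariableSpec("Sex", ("Male", "Female")), _schema_var("Hcy")]

    def test_label_and_numeric_cells(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Sex,Hcy\nMale,15.0\nFemale,17.2\nMale,HHcy\n")
        ds = load_dataset(p, self.schema)
        assert ds.column("Sex").tolist() == [0, 1, 0]
        # 15.0 is Normal (rule is strict >), 17.2 is HHcy
        assert ds.column("Hcy").tolist() == [0, 1, 1]

    def test_round_trip_preserves_labels(self, tmp_path):
        p, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        p.write_text("Sex,Hcy\nMale,Normal\nFemale,HHcy\n")
        ds = load_dataset(p, self.schema)
        write_dataset(ds, p2)
        assert load_dataset(p2, self.schema).codes.tolist() == ds.codes.tolist()

    def test_unknown_label_names_row_and_column(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Sex,Hcy\nMaybe,Normal\n")
        with pytest.raises(CodingError, match="Sex"):
            load_dataset(p, self.schema)

    def test_missing_column_is_schema_error(self, tmp_path):
        p = tmp_path / "d.csv"
        p.write_text("Sex\nMale\n")
        with pytest.raises(SchemaError):
            load_dataset(p, self.schema)


def test_dataset_validates_state_indices():
    with pytest.raises(ValueError):
        CategoricalDataset([VariableSpec("A", ("x", "y"))],
                           np.array([[2]]))


def test_coding_rule_validation():
    with pytest.raises(ValueError):
        CodingRule((2.0, 1.0), ("a", "b", "c"), ("right", "right"))
    with pytest.raises(ValueError):
        CodingRule((1.0,), ("a",), ("right",))
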