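"""Size adjustment, body condition, instance selection, covariate tables."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cmrselect.capture_io import Dataset
from cmrselect.trait_prep import (
    TraitPrepError,
    TraitSeries,
    add_body_condition,
    build_covariate_table,
    condition_residuals,
    fit_size_adjustment,
    select_instance,
    size_adjust,
    trait_series,
)


def _events(svl, trait, name="head_depth"):
    return pd.DataFrame({"svl": svl, name: trait})


class TestSizeAdjustment:
    def test_exact_proportionality_gives_zero_residuals(self):
        svl = np.array([40.0, 50.0, 60.0, 70.0])
        adj = fit_size_adjustment(_events(svl, 0.1 * svl), "head_depth")
        assert adj.slope == pytest.approx(0.1, abs=1e-12)
        assert np.allclose(adj.residuals(svl, 0.1 * svl), 0.0, atol=1e-12)

    def test_collinear_points(self):
        # trait rises 1 mm per 10 mm of SVL: slope 0.1, exact fit
        adj = fit_size_adjustment(
            _events([50.0, 60.0, 70.0], [10.0, 11.0, 12.0]), "head_depth"
        )
        assert adj.slope == pytest.approx(0.1, abs=1e-12)
        res = adj.residuals(np.array([50.0, 60.0, 70.0]), np.array([10.0, 11.0, 12.0]))
        assert np.allclose(res, 0.0, atol=1e-10)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = rng.integers(5, 40)
            svl = rng.normal(55, 5, n)
            trait = 2.0 + 0.08 * svl + rng.normal(0, 0.4, n)
            adj = fit_size_adjustment(_events(svl, trait), "head_depth")
            X = np.column_stack([np.ones(n), svl])
            coef, *_ = np.linalg.lstsq(X, trait, rcond=None)
            oracle = trait - X @ coef
            ours = adj.residuals(svl, trait)
            assert np.allclose(ours, oracle, atol=1e-10)
            assert abs(ours.mean()) < 1e-10 * max(1.0, np.abs(trait).mean())

    def test_degenerate_svl_rejected(self):
        with pytest.raises(TraitPrepError, match="zero variance"):
            fit_size_adjustment(_events([50.0] * 4, [1.0, 2.0, 3.0, 4.0]), "head_depth")

    def test_needs_three_complete_pairs(self):
        with pytest.raises(TraitPrepError, match=">=3"):
            fit_size_adjustment(
                _events([50.0, 60.0, 70.0], [1.0, np.nan, 2.0]), "head_depth"
            )

    def test_svl_shift_changes_intercept_only(self):
        rng = np.random.default_rng(1)
        svl = rng.normal(55, 5, 30)
        trait = 1.0 + 0.1 * svl + rng.normal(0, 0.2, 30)
        a = fit_size_adjustment(_events(svl, trait), "head_depth")
        b = fit_size_adjustment(_events(svl + 100.0, trait), "head_depth")
        assert b.slope == pytest.approx(a.slope, abs=1e-9)
        assert np.allclose(
            a.residuals(svl, trait), b.residuals(svl + 100.0, trait), atol=1e-8
        )


class TestBodyCondition:
    def test_proportional_weight_gives_zero_condition(self):
        svl = np.array([40.0, 50.0, 60.0])
        events = pd.DataFrame({"svl": svl, "weight": 0.002 * svl})
        assert np.allclose(condition_residuals(events), 0.0, atol=1e-12)

    def test_event_above_the_line_has_positive_condition(self):
        events = pd.DataFrame(
            {"svl": [40.0, 50.0, 60.0, 50.0], "weight": [4.0, 5.0, 6.0, 5.9]}
        )
        cond = condition_residuals(events)
        assert cond.iloc[3] > 0

    def test_matches_least_squares_oracle(self):
        rng = np.random.default_rng(2)
        svl = rng.normal(55, 6, 50)
        weight = 0.5 + 0.09 * svl + rng.normal(0, 0.3, 50)
        events = pd.DataFrame({"svl": svl, "weight": weight})
        X = np.column_stack([np.ones(50), svl])
        coef, *_ = np.linalg.lstsq(X, weight, rcond=None)
        assert np.allclose(condition_residuals(events), weight - X @ coef, atol=1e-10)


class TestInstanceSelection:
    def test_three_observation_series(self):
        s = TraitSeries("a", "t", ((1, 3.1), (2, 2.9), (3, 3.5)))
        assert select_instance(s, "first") == pytest.approx(3.1)
        assert select_instance(s, "last") == pytest.approx(3.5)
        assert select_instance(s, "median") == pytest.approx(3.1)

    def test_even_count_median_averages_central_pair(self):
        s = TraitSeries("a", "t", ((1, 2.0), (4, 4.0)))
        assert select_instance(s, "median") == pytest.approx(3.0)

    def test_single_capture_same_under_all_selectors(self):
        s = TraitSeries("a", "t", ((2, 7.7),))
        assert {select_instance(s, sel) for sel in ("first", "median", "last")} == {7.7}

    @given(
        value=st.floats(-50, 50),
        occasions=st.lists(st.integers(1, 9), min_size=1, max_size=5, unique=True),
    )
    def test_constant_series_invariant_to_selector(self, value, occasions):
        s = TraitSeries("a", "t", tuple((o, value) for o in sorted(occasions)))
        picks = [select_instance(s, sel) for sel in ("first", "median", "last")]
        assert all(p == pytest.approx(value) for p in picks)

    def test_occasions_must_increase(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            TraitSeries("a", "t", ((3, 1.0), (1, 2.0)))


class TestCovariateTable:
    def test_standardization_two_values(self, design5):
        frame = pd.DataFrame(
            {"individual_id": ["a", "b"], "species": ["fence_lizard"] * 2,
             "occasion": [1, 1], "head_depth": [1.0, 3.0]}
        )
        ds = Dataset.from_events(design5, frame)
        tab = build_covariate_table(ds, "head_depth", "first")
        # sd with n-1 denominator: (1,3) -> sd sqrt(2) -> -+0.7071
        assert tab.values["a"] == pytest.approx(-0.7071, abs=1e-4)
        assert tab.values["b"] == pytest.approx(+0.7071, abs=1e-4)
        assert abs(tab.values.mean()) < 1e-10
        assert tab.values.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_standardize_off_passes_raw_values(self, design5):
        frame = pd.DataFrame(
            {"individual_id": ["a", "b"], "species": ["fence_lizard"] * 2,
             "occasion": [1, 1], "head_depth": [1.0, 3.0]}
        )
        ds = Dataset.from_events(design5, frame)
        tab = build_covariate_table(ds, "head_depth", "first", standardize=False)
        assert list(tab.values) == [1.0, 3.0]

    def test_individuals_without_the_trait_are_excluded(self, design5, toy_dataset):
        frame = pd.DataFrame(
            {"individual_id": ["a", "a", "b", "c"],
             "species": ["fence_lizard"] * 4, "occasion": [1, 3, 2, 1],
             "dorsal_L": [70.0, 72.0, np.nan, 65.0]}
        )
        ds = Dataset.from_events(design5, frame)
        tab = build_covariate_table(ds, "dorsal_L", "last", standardize=False)
        assert tab.excluded == ("b",)
        assert tab.values["a"] == pytest.approx(72.0)
        # a single individual with data is not enough for a covariate
        with pytest.raises(TraitPrepError, match=">=2 individuals"):
            build_covariate_table(toy_dataset, "dorsal_L", "first")

    def test_standardization_idempotent(self, design5):
        rng = np.random.default_rng(3)
        frame = pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(12)],
             "species": ["fence_lizard"] * 12, "occasion": [1] * 12,
             "head_depth": rng.normal(8, 0.5, 12)}
        )
        ds = Dataset.from_events(design5, frame)
        once = build_covariate_table(ds, "head_depth", "first").values
        frame2 = frame.assign(head_depth=once.loc[frame["individual_id"]].to_numpy())
        twice = build_covariate_table(
            Dataset.from_events(design5, frame2), "head_depth", "first"
        ).values
        assert np.allclose(once.to_numpy(), twice.to_numpy(), atol=1e-10)


class TestDatasetHelpers:
    def test_size_adjust_and_condition_columns(self, design5):
        rng = np.random.default_rng(4)
        n = 30
        svl = rng.normal(55, 5, n)
        frame = pd.DataFrame(
            {"individual_id": [f"i{k}" for k in range(n)],
             "species": ["fence_lizard"] * n, "occasion": rng.integers(1, 6, n),
             "svl": svl,
             "head_depth": 0.1 * svl + rng.normal(0, 0.2, n),
             "weight": 0.002 * svl**1.5 + rng.normal(0, 0.05, n)}
        )
        frame = frame.drop_duplicates(subset=["individual_id", "occasion"])
        ds = Dataset.from_events(design5, frame)
        ds = size_adjust(ds, ["head_depth"])
        ds = add_body_condition(ds)
        assert "head_depth_adj" in ds.trait_columns
        assert "condition" in ds.trait_columns
        assert abs(ds.events["head_depth_adj"].mean()) < 1e-9
        assert abs(ds.events["condition"].mean()) < 1e-9

    def test_trait_series_extraction(self, toy_dataset):
        series = trait_series(toy_dataset, "dorsal_L")
        assert [s.individual_id for s in series] == ["a"]
        assert series[0].observations == ((1, 70.0), (3, 72.0))
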