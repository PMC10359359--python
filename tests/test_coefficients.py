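"""Coefficient derivation, the min-n rule, and relative coefficients."""

import numpy as np
import pandas as pd
import pytest

import dosekit as dk
from dosekit.coeftable import CoefficientTable
from dosekit.errors import (
    DomainError,
    EmptyDerivationError,
    InsufficientStrataError,
)
from dosekit.estimators import DoseCoefficientRegressor, StrataSpec
from .conftest import make_scans


def test_constant_ratio_gives_degenerate_quartiles():
    dlp = np.linspace(100, 500, 50)
    scans = make_scans(
        dlp=dlp, e_reference=0.05 * dlp, age=np.full(50, 7.0),
        body_region=["chest"] * 50,
    )
    table = dk.derive_coefficients(scans, StrataSpec(axes=("age_group",)))
    row = table.stratum("chest", age_group="5-9")
    assert row["median_k"] == row["q25_k"] == row["q75_k"] == pytest.approx(0.05)
    assert row["n"] == 50


def test_stratum_below_min_n_is_omitted_not_zero_filled():
    scans = make_scans(
        dlp=np.full(19, 100.0),
        e_reference=np.full(19, 5.0),
        age=np.array([0.5] * 9 + [7.0] * 10),
        body_region=["chest"] * 19,
    )
    table = dk.derive_coefficients(scans, StrataSpec(axes=("age_group",), min_n=10))
    assert len(table) == 1
    frame = table.frame
    assert "5-9" in set(frame["age_group"])
    assert "<1" not in set(frame["age_group"])


def test_quartiles_match_brute_force_order_statistics():
    """11 coefficients 0.01..0.11 against hand-computed linear-interpolation
    order statistics: median 0.06, q25 = 0.03 + 0.5*(0.04-0.03) = 0.035,
    q75 = 0.08 + 0.5*(0.09-0.08) = 0.085."""
    k = np.arange(1, 12) * 0.01
    dlp = np.full(11, 100.0)
    scans = make_scans(
        dlp=dlp, e_reference=k * dlp, age=np.full(11, 7.0),
        body_region=["chest"] * 11,
    )
    table = dk.derive_coefficients(scans, StrataSpec(axes=("age_group",)))
    row = table.stratum("chest", age_group="5-9")
    assert row["median_k"] == pytest.approx(0.06)
    assert row["q25_k"] == pytest.approx(0.035)
    assert row["q75_k"] == pytest.approx(0.085)


def test_scale_equivariance_of_derivation():
    rng = np.random.default_rng(5)
    dlp = rng.uniform(50, 500, 40)
    e = rng.uniform(0.5, 10.0, 40)
    scans = make_scans(dlp=dlp, e_reference=e, age=np.full(40, 7.0),
                       body_region=["chest"] * 40)
    base = dk.derive_coefficients(scans).frame
    scaled_scans = scans.assign(e_reference=3.0 * scans["e_reference"])
    scaled = dk.derive_coefficients(scaled_scans).frame
    for col in ("median_k", "q25_k", "q75_k"):
        np.testing.assert_allclose(scaled[col], 3.0 * base[col], rtol=1e-12)


def test_permutation_invariance_of_derivation():
    rng = np.random.default_rng(6)
    dlp = rng.uniform(50, 500, 60)
    scans = make_scans(dlp=dlp, e_reference=rng.uniform(0.5, 10, 60),
                       age=rng.uniform(0, 21.9, 60), body_region=["chest"] * 60)
    shuffled = scans.sample(frac=1.0, random_state=1).reset_index(drop=True)
    assert dk.derive_coefficients(scans) == dk.derive_coefficients(shuffled)


def test_empty_input_raises():
    with pytest.raises(EmptyDerivationError):
        dk.derive_coefficients(make_scans(dlp=np.array([])))


def test_missing_reference_dose_rejected():
    scans = make_scans(e_reference=[1.0, np.nan, 1.0, 1.0, 1.0, 1.0])
    with pytest.raises(DomainError):
        dk.derive_coefficients(scans)


def test_head_neck_excluded_from_diameter_stratified_tables():
    scans = make_scans(
        body_region=["head"] * 15 + ["chest"] * 15,
        age=np.full(30, 7.0),
        mean_effective_diameter=np.full(30, 20.0),
        dlp=np.full(30, 100.0),
        e_reference=np.full(30, 2.0),
    )
    est = DoseCoefficientRegressor(axes=("diameter_bin",), min_n=10).fit(scans)
    assert est.coefficient_table_.regions() == ("chest",)
    assert est.n_dropped_axis_missing_ == 15


@pytest.mark.parametrize(
    "region,expected",
    [("head", 13.0), ("neck", 6.9), ("chest", 6.8), ("cardiac", 4.0),
     ("abdomen_pelvis", 3.7), ("chest_abdomen_pelvis", 5.1), ("spine", 2.7)],
)
def test_age_relative_coefficients_on_published_table(age_table, region, expected):
    rc = dk.relative_coefficient(age_table, region, "age_group")
    assert rc.rounded == expected


@pytest.mark.parametrize(
    "region,expected",
    [("chest", 5.3), ("cardiac", 5.5), ("abdomen_pelvis", 5.1),
     ("chest_abdomen_pelvis", 4.3), ("spine", 1.3)],
)
def test_diameter_relative_coefficients_on_published_table(
    diameter_table, region, expected
):
    rc = dk.relative_coefficient(diameter_table, region, "diameter_bin")
    assert rc.rounded == expected


def test_spine_relative_uses_next_youngest_available_group(age_table):
    rc = dk.relative_coefficient(age_table, "spine", "age_group")
    assert rc.numerator_stratum == "1-4"
    assert rc.denominator_stratum == "15-21"


def test_equal_extreme_medians_give_ratio_one():
    table = CoefficientTable.from_records(
        [
            {"region": "chest", "age_group": "<1", "median_k": 0.05,
             "q25_k": 0.04, "q75_k": 0.06, "n": 20},
            {"region": "chest", "age_group": "15-21", "median_k": 0.05,
             "q25_k": 0.04, "q75_k": 0.06, "n": 20},
        ]
    )
    assert dk.relative_coefficient(table, "chest", "age_group").rounded == 1.0


def test_insufficient_strata_error():
    table = CoefficientTable.from_records(
        [{"region": "chest", "age_group": "<1", "median_k": 0.05,
          "q25_k": 0.04, "q75_k": 0.06, "n": 20}]
    )
    with pytest.raises(InsufficientStrataError):
        dk.relative_coefficient(table, "chest", "age_group")


def test_rounding_is_half_away_from_zero():
    """Ratios exactly at a midpoint round away from zero (6.875 -> 6.9,
    4.25 -> 4.3), not to the nearest even digit."""
    table = CoefficientTable.from_records(
        [
            {"region": "neck", "age_group": "<1", "median_k": 0.165,
             "q25_k": 0.1, "q75_k": 0.2, "n": 20},
            {"region": "neck", "age_group": "15-21", "median_k": 0.024,
             "q25_k": 0.02, "q75_k": 0.03, "n": 20},
        ]
    )
    rc = dk.relative_coefficient(table, "neck", "age_group")
    assert rc.raw == pytest.approx(6.875)
    assert rc.rounded == 6.9


class TestEstimatorAPI:
    def test_get_set_params_and_clone(self):
        from sklearn.base import clone

        est = DoseCoefficientRegressor(axes=("age_group", "diameter_bin"), min_n=25)
        params = est.get_params()
        assert params["min_n"] == 25
        cloned = clone(est)
        assert cloned.get_params() == params
        cloned.set_params(min_n=5)
        assert cloned.min_n == 5

    def test_fit_predict_and_missing_stratum_nan(self):
        dlp = np.linspace(100, 200, 30)
        scans = make_scans(
            dlp=dlp, e_reference=0.04 * dlp, age=np.full(30, 7.0),
            body_region=["chest"] * 30,
        )
        est = DoseCoefficientRegressor(axes=("age_group",)).fit(scans)
        assert est.strategy_ == "age"
        pred = est.predict(scans)
        np.testing.assert_allclose(pred, scans["e_reference"], rtol=1e-12)
        other = make_scans(age=np.full(6, 0.5), body_region=["chest"] * 6)
        assert np.isnan(est.predict(other)).all()

    def test_score_is_r2_on_covered_scans(self):
        rng = np.random.default_rng(2)
        dlp = rng.uniform(100, 400, 200)
        e = 0.04 * dlp * np.exp(0.1 * rng.standard_normal(200))
        scans = make_scans(dlp=dlp, e_reference=e, age=np.full(200, 7.0),
                           body_region=["chest"] * 200)
        est = DoseCoefficientRegressor(axes=("age_group",)).fit(scans)
        assert 0.5 < est.score(scans) <= 1.0
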