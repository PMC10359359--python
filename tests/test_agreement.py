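"""Agreement statistics: Pearson r with Fisher-z CI, relative-error rates,
legacy coefficient application, and the per-region report."""

import numpy as np
import pandas as pd
import pytest

import dosekit as dk
from dosekit.agreement import DEFAULT_LEGACY_AGE_MAP, LegacyCoefficientSet
from dosekit.errors import (
    DegenerateInputError,
    DomainError,
    InsufficientDataError,
    MissingMappingError,
)
from .conftest import make_scans


class TestPearson:
    def test_perfect_correlation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, lo, hi = dk.pearson_with_ci(x, x)
        assert r == pytest.approx(1.0)

    def test_perfect_anticorrelation(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _, _ = dk.pearson_with_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_five_point_case_matches_direct_formula(self):
        # sum(dx*dy)=10, sum(dx^2)=10, sum(dy^2)=14.8 -> r = 10/sqrt(148)
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 6]
        r, lo, hi = dk.pearson_with_ci(x, y)
        assert r == pytest.approx(10.0 / np.sqrt(148.0), abs=1e-12)
        assert lo <= r <= hi

    def test_fisher_interval_matches_closed_form(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=50)
        y = x + rng.normal(size=50)
        r, lo, hi = dk.pearson_with_ci(x, y, alpha=0.05)
        from scipy import stats

        half = stats.norm.ppf(0.975) / np.sqrt(50 - 3)
        assert lo == pytest.approx(np.tanh(np.arctanh(r) - half))
        assert hi == pytest.approx(np.tanh(np.arctanh(r) + half))

    def test_bootstrap_interval_brackets_r(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=80)
        y = 0.7 * x + rng.normal(size=80)
        r, lo, hi = dk.pearson_with_ci(x, y, method="bootstrap", seed=3)
        assert lo <= r <= hi

    def test_errors(self):
        with pytest.raises(InsufficientDataError):
            dk.pearson_with_ci([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(DegenerateInputError):
            dk.pearson_with_ci([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_ci_width_shrinks_with_n_on_nested_samples(self):
        rng = np.random.default_rng(7)
        x = rng.normal(size=4000)
        y = 0.6 * x + rng.normal(size=4000)
        widths = []
        for n in (50, 200, 1000, 4000):
            _, lo, hi = dk.pearson_with_ci(x[:n], y[:n])
            widths.append(hi - lo)
        assert widths == sorted(widths, reverse=True)


class TestErrorRate:
    def test_perfect_estimator_is_zero(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert dk.pct_relative_error_above(ref, ref).pct == 0.0

    def test_uniform_sixty_percent_error_is_total(self):
        ref = np.array([1.0, 2.0, 3.0])
        assert dk.pct_relative_error_above(1.6 * ref, ref).pct == 100.0

    def test_threshold_is_inclusive_by_default(self):
        ref = np.ones(4)
        est = np.array([1.2, 1.6, 0.4, 1.5])  # errors 0.2, 0.6, 0.6, 0.5
        res = dk.pct_relative_error_above(est, ref, threshold=0.5)
        assert res.pct == pytest.approx(75.0)
        strict = dk.pct_relative_error_above(est, ref, threshold=0.5, inclusive=False)
        assert strict.pct == pytest.approx(50.0)

    def test_missing_estimates_excluded_and_counted(self):
        ref = np.ones(4)
        est = np.array([1.0, np.nan, 2.0, np.nan])
        res = dk.pct_relative_error_above(est, ref)
        assert res.n == 2 and res.n_missing == 2
        assert res.pct == pytest.approx(50.0)

    def test_common_rescaling_invariance(self):
        rng = np.random.default_rng(4)
        ref = rng.uniform(1, 10, 100)
        est = ref * rng.uniform(0.3, 2.0, 100)
        a = dk.pct_relative_error_above(est, ref).pct
        b = dk.pct_relative_error_above(7.3 * est, 7.3 * ref).pct
        assert a == pytest.approx(b)

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(DomainError):
            dk.pct_relative_error_above([1.0], [0.0])


class TestLegacy:
    def legacy_set(self, c=0.02):
        coeffs = {
            ("chest", label): c for label in DEFAULT_LEGACY_AGE_MAP.values()
        }
        return LegacyCoefficientSet(coefficients=coeffs)

    def test_age_three_maps_to_one_year_old_coefficient(self):
        legacy = LegacyCoefficientSet(
            coefficients={("chest", "1 year old"): 0.026}
        )
        scans = make_scans(age=[3.0], dlp=[200.0], body_region=["chest"])
        doses = dk.apply_legacy_coefficients(scans, legacy)
        assert doses.iloc[0] == pytest.approx(200.0 * 0.026)

    def test_missing_region_raises(self):
        scans = make_scans(age=[3.0], dlp=[200.0], body_region=["head"])
        with pytest.raises(MissingMappingError):
            dk.apply_legacy_coefficients(scans, self.legacy_set())

    def test_legacy_equal_to_study_coefficients_gives_identical_series(self, age_table):
        # synthetic legacy set mirroring the study's chest age medians
        coeffs = {
            ("chest", DEFAULT_LEGACY_AGE_MAP[g]): age_table.lookup("chest", age_group=g)
            for g in dk.AGE_GROUPS
        }
        legacy = LegacyCoefficientSet(coefficients=coeffs)
        ages = np.array([0.5, 3.0, 7.0, 12.0, 18.0])
        scans = make_scans(age=ages, dlp=np.full(5, 200.0), body_region=["chest"] * 5)
        legacy_doses = dk.apply_legacy_coefficients(scans, legacy)
        est = dk.DoseCoefficientRegressor(axes=("age_group",))
        est.coefficient_table_ = age_table
        study_doses = est.predict(scans)
        np.testing.assert_allclose(legacy_doses.to_numpy(), study_doses, rtol=1e-12)


class TestAgreementReport:
    def test_noiseless_self_consistency(self):
        cfg = dk.default_config(n_scans=8000, seed=5, noise_sigma=0.0)
        scans = dk.generate_registry(cfg)
        report = dk.agreement_report(scans, {"age": cfg.k_true})
        assert (report["pearson_r"] - 1.0).abs().max() < 1e-12
        assert (report["pct_gt_threshold"] == 0.0).all()

    def test_default_noise_bounds(self, default_noise_registry):
        cfg, scans = default_noise_registry
        report = dk.agreement_report(scans, {"age": cfg.k_true})
        assert ((report["pearson_r"] > 0) & (report["pearson_r"] < 1)).all()
        assert ((report["pct_gt_threshold"] > 0) & (report["pct_gt_threshold"] < 100)).all()
        assert (report["ci_low"] <= report["pearson_r"]).all()
        assert (report["pearson_r"] <= report["ci_high"]).all()

    def test_doubling_noise_degrades_agreement_on_common_draws(self):
        rs, ps = [], []
        for sigma in (0.4, 0.8):
            cfg = dk.default_config(n_scans=20_000, seed=11, noise_sigma=sigma)
            scans = dk.generate_registry(cfg)
            rep = dk.agreement_report(
                scans[scans["body_region"] == "head"], {"age": cfg.k_true}
            )
            rs.append(rep["pearson_r"].iloc[0])
            ps.append(rep["pct_gt_threshold"].iloc[0])
        assert rs[1] < rs[0]
        assert ps[1] > ps[0]

    def test_age_diameter_at_least_as_good_as_age_on_size_driven_doses(self):
        """When the generating truth varies with patient diameter, adding the
        diameter axis to the lookup must not reduce correlation."""
        t3 = dk.load_diameter_coefficients()
        chest = dk.CoefficientTable(t3.frame[t3.frame["region"] == "chest"])
        cfg = dk.default_config(n_scans=15_000, seed=3, k_true=chest)
        cfg.region_mix = {r: (1.0 if r == "chest" else 0.0) for r in cfg.region_mix}
        scans = dk.generate_registry(cfg)
        age_tab = dk.derive_coefficients(scans, dk.StrataSpec(axes=("age_group",)))
        ad_tab = dk.derive_coefficients(
            scans, dk.StrataSpec(axes=("age_group", "diameter_bin"))
        )
        rep = dk.agreement_report(scans, {"age": age_tab, "age_diameter": ad_tab})
        r = rep.set_index("strategy")["pearson_r"]
        assert r["age_diameter"] >= r["age"]

    def test_head_neck_rows_omit_diameter_strategies(self, default_noise_registry):
        cfg, scans = default_noise_registry
        age_tab = cfg.k_true
        diam_tab = dk.load_diameter_coefficients()
        report = dk.agreement_report(scans, {"age": age_tab, "diameter": diam_tab})
        hn = report[report["region"].isin(["head", "neck"])]
        assert set(hn["strategy"]) == {"age"}
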