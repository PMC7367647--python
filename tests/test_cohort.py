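import numpy as np
import pandas as pd
import pytest
from scipy import stats

import plasmacin as pc
from plasmacin.cohort import LabeledCohort, load_reported_cohorts
from plasmacin.scoring import ScreeningCall


def _cohort(labels, positives, statistic=None):
    calls = [ScreeningCall(f"s{i}", bool(p), int(p), 2.702)
             for i, p in enumerate(positives)]
    return LabeledCohort(sample_ids=[f"s{i}" for i in range(len(labels))],
                         labels=list(labels), screening=calls,
                         statistic=statistic)


class TestConfusionRates:
    def test_discovery_like_ratios(self):
        labels = ["cancer"] * 23 + ["control"] * 41
        positives = [1] * 22 + [0] + [0] * 40 + [1]
        r = pc.confusion_rates(_cohort(labels, positives))
        assert r.sensitivity_pct == pytest.approx(100 * 22 / 23)
        assert round(r.sensitivity_pct, 1) == 95.7
        assert r.specificity_pct == pytest.approx(100 * 40 / 41)

    def test_validation_specificity_ratio(self):
        labels = ["cancer"] * 2 + ["control"] * 28
        positives = [1, 1] + [0] * 27 + [1]
        r = pc.confusion_rates(_cohort(labels, positives))
        assert round(r.specificity_pct, 1) == 96.4

    def test_perfect_classifier(self):
        labels = ["cancer"] * 5 + ["control"] * 5
        r = pc.confusion_rates(_cohort(labels, [1] * 5 + [0] * 5))
        assert float(r.sensitivity) == 1.0 and float(r.specificity) == 1.0

    def test_single_class_cohort_rejected(self):
        with pytest.raises(ValueError):
            pc.confusion_rates(_cohort(["cancer"] * 3, [1, 1, 0]))


class TestRocAuc:
    def test_perfect_separation(self):
        labels = ["cancer"] * 5 + ["control"] * 5
        stat = np.r_[np.arange(5, 10), np.arange(5)].astype(float)
        curve = pc.roc_auc(_cohort(labels, [1] * 5 + [0] * 5, stat))
        assert curve.auc == pytest.approx(1.0)

    def test_uninformative_statistic_near_half(self):
        rng = np.random.default_rng(0)
        n = 500
        labels = ["cancer" if x else "control" for x in rng.integers(0, 2, n)]
        stat = rng.normal(size=n)
        curve = pc.roc_auc(_cohort(labels, [0] * n, stat))
        assert abs(curve.auc - 0.5) < 0.08

    def test_trapezoid_equals_concordance_oracle(self, oracles):
        rng = np.random.default_rng(1)
        for _ in range(20):
            n = int(rng.integers(6, 30))
            labels = (["cancer"] * (n // 2)
                      + ["control"] * (n - n // 2))
            stat = np.round(rng.normal(size=n), 1)  # provoke ties
            stat[:n // 2] += rng.uniform(0, 2)
            cohort = _cohort(labels, [0] * n, stat)
            curve = pc.roc_auc(cohort)
            assert curve.auc == pytest.approx(
                oracles["auc"](labels, stat), abs=1e-12)

    def test_auc_equals_mann_whitney_probability(self):
        rng = np.random.default_rng(2)
        labels = ["cancer"] * 30 + ["control"] * 40
        stat = np.r_[rng.normal(1, 1, 30), rng.normal(0, 1, 40)]
        curve = pc.roc_auc(_cohort(labels, [0] * 70, stat))
        u = stats.mannwhitneyu(stat[:30], stat[30:]).statistic
        assert curve.auc == pytest.approx(u / (30 * 40))

    def test_constant_statistic_degenerates_with_warning(self):
        labels = ["cancer"] * 3 + ["control"] * 3
        with pytest.warns(UserWarning, match="constant"):
            curve = pc.roc_auc(_cohort(labels, [0] * 6, np.ones(6)))
        assert curve.auc == 0.5


class TestOptimalCutoff:
    def test_perfect_separation_returns_separating_value(self):
        labels = ["cancer"] * 4 + ["control"] * 4
        stat = np.array([5.0, 6, 7, 8, 1, 2, 3, 4])
        curve = pc.roc_auc(_cohort(labels, [0] * 8, stat))
        cut = pc.optimal_cutoff(curve)
        assert 4 < cut <= 5

    def test_tie_broken_to_smaller_cutoff(self):
        curve = pc.RocCurve(cutoffs=np.array([3.0, 2.0, 1.0]),
                            tpr=np.array([0.6, 0.8, 1.0]),
                            fpr=np.array([0.1, 0.3, 0.5]),
                            auc=0.8)
        # J ties at 0.5 everywhere -> smallest cutoff wins
        assert pc.optimal_cutoff(curve) == 1.0


class TestFisherExact:
    def test_published_size_association(self):
        r = pc.fisher_exact_2x2([[32, 6], [17, 18]])
        assert r.or_cmle == pytest.approx(5.50, abs=0.01)
        assert r.ci95[0] == pytest.approx(1.70, abs=0.01)
        assert r.ci95[1] == pytest.approx(20.3, abs=0.05)
        assert r.p_two_sided == pytest.approx(0.002386, abs=1e-5)

    def test_symmetric_table_is_null(self):
        r = pc.fisher_exact_2x2([[5, 5], [5, 5]])
        assert r.or_cmle == pytest.approx(1.0)
        assert r.p_two_sided == pytest.approx(1.0)
        assert r.ci95[0] < 1 < r.ci95[1]

    def test_p_matches_enumeration_on_random_tables(self, oracles):
        rng = np.random.default_rng(4)
        for _ in range(60):
            while True:
                a, b, c, d = rng.integers(0, 9, 4)
                if a + b and c + d and a + c and b + d:
                    break
            table = [[int(a), int(b)], [int(c), int(d)]]
            r = pc.fisher_exact_2x2(table)
            assert r.p_two_sided == pytest.approx(
                oracles["fisher_p"](table), rel=1e-9)

    def test_zero_cell_yields_open_interval(self):
        r = pc.fisher_exact_2x2([[5, 0], [2, 6]])
        assert r.or_cmle == np.inf
        assert np.isinf(r.ci95[1])
        assert r.ci95[0] > 0

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            a, b, c, d = rng.integers(1, 12, 4)
            r = pc.fisher_exact_2x2([[int(a), int(b)], [int(c), int(d)]])
            assert r.ci95[0] <= r.or_cmle <= r.ci95[1]

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            pc.fisher_exact_2x2([[0, 0], [3, 4]])


class TestCrosstab:
    def _size_frame(self):
        counts = load_reported_cohorts()["size_crosstab"]["groups"]
        rows = []
        k = 0
        for group, cats in counts.items():
            for cat, n in cats.items():
                altered = {">=3": 3, "2": 2, "1": 1, "0": 0}[cat]
                for _ in range(n):
                    rows.append({"sample_id": f"v{k}", "size": group
                                 if group != "NA" else None,
                                 "altered_count": altered})
                    k += 1
        return pd.DataFrame(rows)

    def test_published_size_percentages(self):
        df = self._size_frame()
        tab = pc.crosstab_by_group(df, "size",
                                   groups=[">=5cm", "3-5cm", "<3cm"],
                                   test_groups=([">=5cm"], ["3-5cm", "<3cm"]))
        assert tab.loc[">=5cm", "pct_positive"] == pytest.approx(84.2, abs=0.05)
        assert tab.loc["3-5cm", "pct_positive"] == pytest.approx(52.9, abs=0.05)
        assert tab.loc["<3cm", "pct_positive"] == pytest.approx(44.4, abs=0.05)
        fisher = tab.attrs["fisher"]
        assert fisher.table == ((32, 6), (17, 18))
        assert fisher.or_cmle == pytest.approx(5.50, abs=0.01)

    def test_counts_partition_cohort_and_na_separate(self):
        df = self._size_frame()
        tab = pc.crosstab_by_group(df, "size")
        assert tab["n"].sum() == len(df)
        assert "NA" in tab.index
        assert tab.loc["NA", "n"] == 7

    def test_all_missing_covariate(self):
        df = pd.DataFrame({"sample_id": ["a", "b"], "size": [None, None],
                           "altered_count": [0, 2]})
        tab = pc.crosstab_by_group(df, "size")
        assert list(tab.index) == ["NA"]
        assert "fisher" not in tab.attrs


class TestCombineTests:
    @pytest.mark.parametrize("a,b,expected", [
        (False, False, False), (True, False, True),
        (False, True, True), (True, True, True),
    ])
    def test_logical_or(self, a, b, expected):
        assert bool(pc.combine_tests(a, b)) is expected

    def test_independent_tests_combined_sensitivity(self):
        rng = np.random.default_rng(6)
        n = 20_000
        a = rng.random(n) < 0.5
        b = rng.random(n) < 0.4
        combined = pc.combine_tests(a, b)
        expected = 1 - (1 - 0.5) * (1 - 0.4)
        assert combined.mean() == pytest.approx(expected, abs=0.01)


class TestReportedCohorts:
    def test_category_counts_consistency(self):
        data = load_reported_cohorts()
        disc = data["cohorts"]["discovery_cancer"]["counts"]
        assert sum(disc.values()) == 23
        ctrl = data["cohorts"]["discovery_control"]["counts"]
        assert sum(ctrl.values()) == 41
        val = data["cohorts"]["validation_presurgery"]["counts"]
        assert sum(val.values()) == 80
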