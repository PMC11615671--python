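import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sncfrag.diffexp import (
    AnalysisConfig,
    classify,
    compare_conditions,
    condition_means,
    exact_two_sided_test,
    summarize_classes,
)
from sncfrag.quant import ExpressionMatrix


def make_matrix(rpm: pd.DataFrame, classes: dict[str, str]) -> ExpressionMatrix:
    meta = pd.DataFrame(
        {
            "parent_id": [f.split(":")[0] for f in rpm.index],
            "class_label": [classes[f] for f in rpm.index],
            "start": 0, "end": 22, "feature_kind": "whole_parent",
        },
        index=rpm.index,
    )
    return ExpressionMatrix(
        counts=rpm.copy(), rpm=rpm, feature_meta=meta,
        denominators=pd.Series(1_000_000, index=rpm.columns),
        assigned_reads=pd.Series(0, index=rpm.columns),
    )


class TestConditionMeans:
    def setup_method(self):
        self.rpm = pd.DataFrame(
            {"w1": [10.0, 5.0], "w2": [30.0, 5.0], "k1": [100.0, 7.0]},
            index=pd.Index(["a:0-22", "b:0-22"], name="locus_id"),
        )
        self.matrix = make_matrix(self.rpm, {"a:0-22": "miRNA", "b:0-22": "tRNA"})

    def test_arithmetic_mean(self):
        means = condition_means(self.matrix, {"WT": ["w1", "w2"], "KO": ["k1"]})
        assert means.at["a:0-22", "WT"] == pytest.approx(20.0)
        assert means.at["a:0-22", "KO"] == pytest.approx(100.0)

    def test_permutation_invariance(self):
        m1 = condition_means(self.matrix, {"WT": ["w1", "w2"]})
        m2 = condition_means(self.matrix, {"WT": ["w2", "w1"]})
        pd.testing.assert_frame_equal(m1, m2)

    def test_unknown_library_rejected(self):
        with pytest.raises(ValueError, match="unknown library"):
            condition_means(self.matrix, {"WT": ["nope"]})
        with pytest.raises(ValueError, match="no libraries"):
            condition_means(self.matrix, {"WT": []})


class TestClassify:
    @pytest.mark.parametrize(
        "wt,ko,expressed,category",
        [
            (100.0, 150.0, True, "up"),        # boundary inclusive
            (100.0, 50.0, True, "down"),       # boundary inclusive
            (100.0, 100.0, True, "unchanged"),
            (100.0, 149.999, True, "unchanged"),
            (100.0, 50.001, True, "unchanged"),
            (19.0, 19.0, False, None),         # below the 20 RPM filter
            (20.0, 0.0, True, "down"),         # threshold itself retained
            (0.0, 20.0, True, "up"),           # undefined ratio, expressed KO
            (0.0, 5.0, False, None),
        ],
    )
    def test_boundaries(self, wt, ko, expressed, category):
        got_expressed, got_category, _ = classify(wt, ko)
        assert (got_expressed, got_category) == (expressed, category)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify(-1.0, 10.0)

    def test_monotone_in_ko(self):
        """Holding WT fixed, the category moves down->unchanged->up in KO."""
        order = {"down": 0, "unchanged": 1, "up": 2}
        last = -1
        for ko in np.linspace(20, 200, 181):
            _, category, _ = classify(100.0, float(ko))
            assert order[category] >= last
            last = order[category]


class TestExactTest:
    def test_balanced_table_is_one(self):
        assert exact_two_sided_test([[5, 5], [5, 5]]) == 1.0

    def test_separated_table_closed_form(self):
        assert exact_two_sided_test([[10, 0], [0, 10]]) == pytest.approx(
            2 / math.comb(20, 10), rel=1e-12
        )

    def test_against_enumeration_oracle(self):
        # independent oracle: exact rational hypergeometric enumeration
        def oracle(a, b, c, d):
            r1, r2, c1 = a + b, c + d, a + c
            n = r1 + r2

            def prob(k):
                return Fraction(
                    math.factorial(r1) * math.factorial(r2)
                    * math.factorial(c1) * math.factorial(n - c1),
                    math.factorial(k) * math.factorial(r1 - k)
                    * math.factorial(c1 - k) * math.factorial(r2 - c1 + k)
                    * math.factorial(n),
                )

            obs = prob(a)
            return float(sum(prob(k) for k in range(max(0, c1 - r2),
                                                    min(r1, c1) + 1)
                             if prob(k) <= obs))

        assert exact_two_sided_test([[8, 2], [2, 8]]) == pytest.approx(
            oracle(8, 2, 2, 8), rel=1e-12
        )
        rng = np.random.default_rng(7)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            assert exact_two_sided_test([[a, b], [c, d]]) == pytest.approx(
                oracle(a, b, c, d), rel=1e-9
            )

    def test_against_scipy_fisher(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 25, size=4))
            if (a + b) * (c + d) * (a + c) * (b + d) == 0:
                continue
            _, p_ref = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
            assert exact_two_sided_test([[a, b], [c, d]]) == pytest.approx(
                p_ref, rel=1e-6
            )

    def test_symmetry_under_row_and_column_swap(self):
        p = exact_two_sided_test([[8, 2], [3, 7]])
        assert exact_two_sided_test([[3, 7], [8, 2]]) == pytest.approx(p, rel=1e-12)
        assert exact_two_sided_test([[2, 8], [7, 3]]) == pytest.approx(p, rel=1e-12)

    def test_zero_margin_returns_one_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            assert exact_two_sided_test([[0, 0], [3, 4]]) == 1.0
        assert "degenerate" in caplog.text

    def test_negative_entry_rejected(self):
        with pytest.raises(ValueError):
            exact_two_sided_test([[-1, 2], [3, 4]])


def comparison_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["locus_id", "class_label", "wt_mean_rpm", "ko_mean_rpm",
                 "ratio", "expressed", "category"],
    ).set_index("locus_id")


class TestSummarizeClasses:
    def test_percentages_and_partition(self):
        rows = []
        # ysRNA-patterned class: 61 up, 0 down, 17 unchanged of 78 expressed
        for i in range(61):
            rows.append((f"y{i}", "yRNA", 100, 300, 3.0, True, "up"))
        for i in range(17):
            rows.append((f"yu{i}", "yRNA", 100, 100, 1.0, True, "unchanged"))
        for i in range(40):
            rows.append((f"m{i}", "miRNA", 100, 10, 0.1, True, "down"))
        for i in range(10):
            rows.append((f"mu{i}", "miRNA", 100, 100, 1.0, True, "unchanged"))
        rows.append(("mx", "miRNA", 5, 5, 1.0, False, ""))  # excluded
        summary = summarize_classes(comparison_frame(rows), "KO")
        y = summary.set_index("class_label").loc["yRNA"]
        assert y["n_expressed"] == 78
        assert y["pct_up"] == pytest.approx(100 * 61 / 78)  # 78.2%
        assert y["n_up"] + y["n_down"] + y["n_unchanged"] == y["n_expressed"]
        assert y["pct_up"] + y["pct_down"] + y["pct_unchanged"] == pytest.approx(100)
        m = summary.set_index("class_label").loc["miRNA"]
        assert m["n_expressed"] == 50  # the non-expressed feature is excluded
        assert m["p_down_vs_mirna"] == 1.0
        # yRNA 0/78 down vs miRNA 40/50 down
        expected = exact_two_sided_test([[0, 78], [40, 10]])
        assert y["p_down_vs_mirna"] == pytest.approx(expected, rel=1e-12)

    def test_all_unchanged_everywhere_gives_p_one(self):
        rows = [(f"m{i}", "miRNA", 100, 100, 1.0, True, "unchanged")
                for i in range(10)]
        rows += [(f"t{i}", "tRNA", 100, 100, 1.0, True, "unchanged")
                 for i in range(10)]
        summary = summarize_classes(comparison_frame(rows), "KO")
        assert (summary["p_down_vs_mirna"] == 1.0).all()

    def test_missing_mirna_class_warns_and_omits_p(self, caplog):
        rows = [(f"t{i}", "tRNA", 100, 300, 3.0, True, "up") for i in range(5)]
        with caplog.at_level("WARNING"):
            summary = summarize_classes(comparison_frame(rows), "KO")
        assert math.isnan(summary["p_down_vs_mirna"].iloc[0])
        assert "miRNA" in caplog.text

    def test_no_expressed_features_rejected(self):
        rows = [("a", "miRNA", 1, 1, 1.0, False, "")]
        with pytest.raises(ValueError, match="no expressed"):
            summarize_classes(comparison_frame(rows), "KO")


class TestCompareConditions:
    def test_per_feature_table_and_expression_filter(self):
        rpm = pd.DataFrame(
            {"w1": [100.0, 10.0, 0.0], "w2": [100.0, 10.0, 0.0],
             "k1": [50.0, 12.0, 30.0], "k2": [50.0, 12.0, 30.0]},
            index=pd.Index(["a:0-22", "b:0-22", "c:0-22"], name="locus_id"),
        )
        matrix = make_matrix(rpm, {"a:0-22": "miRNA", "b:0-22": "tRNA",
                                   "c:0-22": "tRNA"})
        comp = compare_conditions(
            matrix, {"WT": ["w1", "w2"], "KO": ["k1", "k2"]}, "WT", "KO"
        )
        assert comp.at["a:0-22", "category"] == "down"
        assert not comp.at["b:0-22", "expressed"]   # 10 vs 12: below filter
        assert comp.at["c:0-22", "category"] == "up"  # WT 0, KO expressed
        assert math.isinf(comp.at["c:0-22", "ratio"])

    def test_optional_replicate_test_column(self):
        rng = np.random.default_rng(5)
        rpm = pd.DataFrame(
            rng.normal(100, 5, size=(3, 6)).clip(0),
            index=pd.Index([f"f{i}:0-22" for i in range(3)], name="locus_id"),
            columns=["w1", "w2", "w3", "k1", "k2", "k3"],
        )
        matrix = make_matrix(rpm, {f"f{i}:0-22": "miRNA" for i in range(3)})
        groups = {"WT": ["w1", "w2", "w3"], "KO": ["k1", "k2", "k3"]}
        plain = compare_conditions(matrix, groups, "WT", "KO")
        assert "p_replicate" not in plain.columns
        config = AnalysisConfig(replicate_test=True)
        with_test = compare_conditions(matrix, groups, "WT", "KO", config)
        assert ((with_test["p_replicate"] >= 0) & (with_test["p_replicate"] <= 1)).all()


class TestAnalysisConfig:
    def test_defaults_are_study_conditions(self):
        config = AnalysisConfig()
        assert config.expression_threshold_rpm == 20.0
        assert (config.up_ratio, config.down_ratio) == (1.5, 0.5)
        assert (config.read_len_min, config.read_len_max) == (16, 32)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"down_ratio": 1.5, "up_ratio": 0.5},
            {"read_len_min": 33},
            {"read_len_min": 30, "read_len_max": 20},
            {"expression_threshold_rpm": -1},
            {"strand_policy": "minus"},
            {"multimap_policy": "best"},
        ],
    )
    def test_invalid_settings_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)
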