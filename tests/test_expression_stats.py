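import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirkit.expression_stats import (
    CtTable,
    assumption_checks,
    efficiency_percent,
    group_percent_change,
    one_way_anova,
    relative_expression,
    snk_posthoc,
)
from mirkit.synthetic_data import AssaySimConfig, simulate_assay


def ct_table(rows, efficiencies):
    return CtTable(pd.DataFrame(rows, columns=["sample_id", "group", "gene", "replicate", "ct"]),
                   efficiencies)


class TestRelativeExpression:
    def test_one_cycle_advantage_doubles(self):
        rows = [
            ("c1", "ctl", "tg", 1, 20.0), ("c1", "ctl", "ref", 1, 15.0),
            ("t1", "trt", "tg", 1, 19.0), ("t1", "trt", "ref", 1, 15.0),
        ]
        out = relative_expression(ct_table(rows, {"tg": 2.0, "ref": 2.0}), "tg", "ref", "ctl")
        assert out.loc[out.sample_id == "t1", "ratio"].item() == pytest.approx(2.0)

    def test_calibrator_mean_sample_is_unity(self):
        rows = [
            ("c1", "ctl", "tg", 1, 20.0), ("c1", "ctl", "ref", 1, 15.0),
        ]
        out = relative_expression(ct_table(rows, {"tg": 1.9, "ref": 2.1}), "tg", "ref", "ctl")
        assert out["ratio"].item() == pytest.approx(1.0)

    def test_efficiency_corrected_ratio(self):
        # E_t = 1.8 with dCt 2 against E_ref = 2.0 with dCt 0.5 -> 1.8^2 / 2^0.5
        rows = [
            ("c1", "ctl", "tg", 1, 20.0), ("c1", "ctl", "ref", 1, 15.0),
            ("c2", "ctl", "tg", 1, 20.0), ("c2", "ctl", "ref", 1, 15.0),
            ("t1", "trt", "tg", 1, 18.0), ("t1", "trt", "ref", 1, 14.5),
        ]
        out = relative_expression(ct_table(rows, {"tg": 1.8, "ref": 2.0}), "tg", "ref", "ctl")
        expected = 1.8**2 / 2**0.5
        assert out.loc[out.sample_id == "t1", "ratio"].item() == pytest.approx(expected)

    def test_technical_replicates_averaged_before_ratio(self):
        rows = [
            ("c1", "ctl", "tg", 1, 19.0), ("c1", "ctl", "tg", 2, 21.0),
            ("c1", "ctl", "ref", 1, 15.0), ("c1", "ctl", "ref", 2, 15.0),
            ("t1", "trt", "tg", 1, 19.0), ("t1", "trt", "ref", 1, 15.0),
        ]
        out = relative_expression(ct_table(rows, {"tg": 2.0, "ref": 2.0}), "tg", "ref", "ctl")
        assert out.loc[out.sample_id == "t1", "ratio"].item() == pytest.approx(2.0)

    def test_ddct_mode_forces_doubling(self):
        rows = [
            ("c1", "ctl", "tg", 1, 20.0), ("c1", "ctl", "ref", 1, 15.0),
            ("t1", "trt", "tg", 1, 19.0), ("t1", "trt", "ref", 1, 15.0),
        ]
        out = relative_expression(
            ct_table(rows, {"tg": 1.8, "ref": 1.8}), "tg", "ref", "ctl", mode="ddct"
        )
        assert out.loc[out.sample_id == "t1", "ratio"].item() == pytest.approx(2.0)

    def test_missing_reference_rows_rejected(self):
        rows = [("c1", "ctl", "tg", 1, 20.0)]
        with pytest.raises(ValueError, match="missing Ct"):
            relative_expression(ct_table(rows, {"tg": 2.0, "ref": 2.0}), "tg", "ref", "ctl")

    def test_invalid_efficiency_rejected(self):
        with pytest.raises(ValueError, match="amplification factor"):
            ct_table([("c1", "ctl", "tg", 1, 20.0)], {"tg": 0.9})

    def test_control_group_geometric_mean_is_one_on_simulated_assay(self):
        ct, _, _ = simulate_assay(AssaySimConfig(seed=5))
        table = CtTable(ct, {g: 2.0 for g in ct["gene"].unique()})
        out = relative_expression(table, "cyp2k5", "ef1a", "saline")
        control = out.loc[out.group == "saline", "ratio"]
        assert np.exp(np.log(control).mean()) == pytest.approx(1.0)


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        res = one_way_anova({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.F == 0 and (res.df_between, res.df_within) == (2, 6)

    def test_study_design_degrees_of_freedom(self):
        groups = {g: np.arange(6) + i for i, g in enumerate(["saline", "low", "high"])}
        res = one_way_anova(groups)
        assert (res.df_between, res.df_within) == (2, 15)

    def test_hand_computed_toy_decomposition(self):
        # groups {1,2},{2,3},{4,5}: grand mean 17/6, SSB = 28/3, SSW = 3/2
        res = one_way_anova({"a": [1, 2], "b": [2, 3], "c": [4, 5]})
        assert res.ss_between == pytest.approx(28 / 3)
        assert res.ss_within == pytest.approx(1.5)
        assert res.F == pytest.approx((28 / 3 / 2) / (1.5 / 3))

    def test_sum_of_squares_identity(self, rng):
        for _ in range(30):
            groups = {
                f"g{i}": rng.normal(rng.normal(), 1 + rng.random(), size=rng.integers(2, 12))
                for i in range(int(rng.integers(2, 6)))
            }
            res = one_way_anova(groups)
            assert res.ss_total == pytest.approx(res.ss_between + res.ss_within, rel=1e-10)

    def test_two_groups_f_equals_t_squared(self, rng):
        x, y = rng.normal(0, 1, 8), rng.normal(0.7, 1, 10)
        res = one_way_anova({"x": x, "y": y})
        t = stats.ttest_ind(x, y)
        assert res.F == pytest.approx(t.statistic**2)
        assert res.p == pytest.approx(t.pvalue)

    def test_degenerate_data_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            one_way_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestAssumptionChecks:
    def test_normal_data_passes(self, rng):
        groups = {g: rng.normal(0, 1, 18) for g in ("a", "b", "c")}
        report = assumption_checks(groups)
        assert report.passed and not report.recommend_log10

    def test_scaled_group_fails_levene(self, rng):
        groups = {"a": rng.normal(0, 1, 18), "b": rng.normal(0, 1, 18) * 10}
        report = assumption_checks(groups)
        assert report.levene_p < 0.05 and report.recommend_log10

    def test_lognormal_data_passes_after_log(self, rng):
        groups = {g: np.exp(rng.normal(0, 1.2, 20)) for g in ("a", "b", "c")}
        report = assumption_checks(groups)
        assert report.recommend_log10
        assert report.passed_after_log10

    def test_constant_group_flagged(self):
        report = assumption_checks({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        assert report.constant_groups == ("a",)
        assert not report.passed

    def test_too_small_groups_rejected(self):
        with pytest.raises(ValueError):
            assumption_checks({"a": [1.0, 2.0], "b": [1.0, 2.0, 3.0]})


class TestSnk:
    def test_two_separated_groups(self):
        grouping = snk_posthoc({"lo": [1, 2, 3], "hi": [11, 12, 13]})
        assert grouping.letters == {"hi": "a", "lo": "b"}
        assert grouping.different("hi", "lo")

    def test_identical_distributions_share_letter(self, rng):
        groups = {g: rng.normal(0, 1, 10) for g in ("a", "b", "c")}
        grouping = snk_posthoc(groups)
        assert set(grouping.letters.values()) == {"a"}

    def test_control_versus_two_equal_treatments(self, rng):
        # the recurring dose-independent signature: control distinct, doses alike
        groups = {
            "saline": 1.0 + rng.normal(0, 0.1, 6),
            "low-dose": 0.35 + rng.normal(0, 0.1, 6),
            "high-dose": 0.35 + rng.normal(0, 0.1, 6),
        }
        grouping = snk_posthoc(groups)
        assert grouping.letters["saline"] == "a"
        assert grouping.letters["low-dose"] == grouping.letters["high-dose"] == "b"

    def test_two_group_snk_matches_pooled_t(self, rng):
        # with two means the studentized range reduces to q = t * sqrt(2)
        for _ in range(20):
            x = rng.normal(0, 1, 6)
            y = rng.normal(rng.uniform(0, 2), 1, 6)
            grouping = snk_posthoc({"x": x, "y": y}, alpha=0.05)
            t_p = stats.ttest_ind(x, y).pvalue
            assert grouping.different("x", "y") == (t_p < 0.05)

    def test_letter_display_mirrors_rejection_relation(self, rng):
        for _ in range(15):
            k = int(rng.integers(2, 6))
            groups = {f"g{i}": rng.normal(rng.uniform(0, 3), 1, 8) for i in range(k)}
            grouping = snk_posthoc(groups)
            for a in groups:
                for b in groups:
                    if a >= b:
                        continue
                    share = set(grouping.letters[a]) & set(grouping.letters[b])
                    assert bool(share) == (not grouping.different(a, b))

    def test_snk_rejections_contain_tukey_rejections(self, rng):
        # SNK uses range-dependent (smaller) critical values, so it rejects
        # at least every pair Tukey's HSD rejects
        for _ in range(20):
            k = int(rng.integers(3, 6))
            groups = {f"g{i}": rng.normal(rng.uniform(0, 2), 1, 7) for i in range(k)}
            anova = one_way_anova(groups)
            grouping = snk_posthoc(groups)
            crit = stats.studentized_range.ppf(0.95, k, anova.df_within)
            tukey_rejected = set()
            names = list(groups)
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    n_h = 2 / (1 / anova.group_ns[a] + 1 / anova.group_ns[b])
                    q = abs(anova.group_means[a] - anova.group_means[b]) / np.sqrt(
                        anova.ms_within / n_h
                    )
                    if q > crit:
                        tukey_rejected.add(tuple(sorted((a, b))))
            assert tukey_rejected <= grouping.rejected

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            snk_posthoc({"only": [1.0, 2.0, 3.0]})


def test_group_percent_change():
    changes = group_percent_change({"ctl": [2.0, 2.0], "trt": [3.0, 3.2]}, "ctl")
    assert changes["trt"] == pytest.approx(55.0)
    assert changes["ctl"] == pytest.approx(0.0)


def test_efficiency_percent_conventions():
    assert efficiency_percent(1.8) == pytest.approx(90.0)
    assert efficiency_percent(2.2) == pytest.approx(110.0)
    assert efficiency_percent(2.0, convention="gain") == pytest.approx(100.0)
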