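"""Factorial statistics: closed-form oracles, gating and calibration."""

import numpy as np
import pandas as pd
import pytest

from pnnkit.geometry import ParameterError
from pnnkit.stats import (
    analyze_metric,
    kruskal_wallis_dunn,
    normality_gate,
    two_way_anova,
)

GROUPS = [("TnC+/+", "SE"), ("TnC+/+", "EE"), ("TnC-/-", "SE"),
          ("TnC-/-", "EE")]


def table(values_per_group):
    rows = []
    for (g, h), vals in zip(GROUPS, values_per_group):
        rows.extend({"genotype": g, "housing": h, "value": float(v)}
                    for v in vals)
    return pd.DataFrame(rows)


class TestNormalityGate:
    def test_normal_groups_usually_parametric(self):
        rng = np.random.default_rng(31)
        parametric = sum(
            normality_gate(table([rng.normal(0, 1, 20) for _ in range(4)]))
            ["choice"] == "parametric"
            for _ in range(50))
        assert parametric >= 45  # >= 90 % of replicates

    def test_constant_group_forces_nonparametric(self):
        t = table([[1.0] * 5, [1, 2, 3, 4, 5], [1, 2, 3, 4, 5],
                   [2, 3, 4, 5, 6]])
        assert normality_gate(t)["choice"] == "nonparametric"

    def test_tiny_group_forces_nonparametric_with_warning(self):
        t = table([[1, 2], [1, 2, 3], [1, 2, 3], [1, 2, 3]])
        with pytest.warns(UserWarning):
            assert normality_gate(t)["choice"] == "nonparametric"

    def test_force_override(self):
        t = table([[1.0] * 5] * 4)
        assert normality_gate(t, force="parametric")["choice"] == "parametric"
        with pytest.raises(ParameterError):
            normality_gate(t, force="bayesian")


class TestTwoWayAnova:
    def test_matches_hand_computed_sums_of_squares(self):
        t = table([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]])
        res = two_way_anova(t, posthoc=False)
        # balanced 3/cell: SS_A=108, SS_B=27, SS_AB=0, SS_E=8·1 -> F by hand
        assert res.statistics["genotype"][0] == pytest.approx(108.0, rel=1e-9)
        assert res.statistics["housing"][0] == pytest.approx(27.0, rel=1e-9)
        assert res.statistics["interaction"][0] == pytest.approx(0.0, abs=1e-9)

    def test_equal_cell_means_give_null_fs(self):
        rng = np.random.default_rng(5)
        base = rng.normal(0, 1, 8)
        t = table([base + 10, base + 10, base + 10, base + 10])
        res = two_way_anova(t, posthoc=False)
        for stat, p in res.statistics.values():
            assert stat == pytest.approx(0.0, abs=1e-9)

    def test_balanced_sum_of_squares_identity(self):
        rng = np.random.default_rng(6)
        vals = [rng.normal(0, 1, 6) for _ in range(4)]
        t = table(vals)
        all_v = t["value"].to_numpy()
        ss_total = ((all_v - all_v.mean()) ** 2).sum()
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        tab = sm.stats.anova_lm(
            ols("value ~ C(genotype) * C(housing)", data=t).fit(), typ=2)
        assert tab["sum_sq"].sum() == pytest.approx(ss_total, rel=1e-9)

    def test_empty_cell_named_in_error(self):
        t = table([[1, 2, 3], [4, 5, 6], [7, 8, 9], []])
        with pytest.raises(ParameterError, match="EE"):
            two_way_anova(t)

    def test_tukey_covers_all_six_pairs(self):
        rng = np.random.default_rng(7)
        t = table([rng.normal(i, 1, 5) for i in range(4)])
        res = two_way_anova(t)
        assert len(res.posthoc) == 6

    def test_null_interaction_rejection_rate(self):
        rng = np.random.default_rng(8)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = table([rng.normal(0, 1, 10) for _ in range(4)])
            p = two_way_anova(t, posthoc=False).statistics["interaction"][1]
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)


class TestKruskalWallis:
    def test_matches_hand_computed_rank_formula(self):
        t = table([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]])
        res = kruskal_wallis_dunn(t, posthoc=False)
        # ranks 1..12, mean ranks 2,5,8,11:
        # H = 12/(12·13)·3·(2²+5²+8²+11²)... centred: H = 10.384615...
        assert res.statistics["omnibus"][0] == pytest.approx(
            135 / 13, rel=1e-12)

    def test_identical_groups_h_zero(self):
        t = table([[5, 5, 5]] * 4)
        assert kruskal_wallis_dunn(t, posthoc=False).statistics["omnibus"] \
            == (0.0, 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        vals = [rng.normal(i * 0.3, 1, 12) for i in range(4)]
        t1 = table(vals)
        t2 = table([np.exp(v) for v in vals])  # strictly monotone map
        h1 = kruskal_wallis_dunn(t1, posthoc=False).statistics["omnibus"][0]
        h2 = kruskal_wallis_dunn(t2, posthoc=False).statistics["omnibus"][0]
        assert h1 == pytest.approx(h2, rel=1e-12)

    def test_empty_group_rejected(self):
        t = table([[1, 2], [3, 4], [5, 6], []])
        with pytest.raises(ParameterError):
            kruskal_wallis_dunn(t)

    def test_dunn_pairs_and_adjustment(self):
        rng = np.random.default_rng(10)
        t = table([rng.normal(i, 1, 8) for i in range(4)])
        res = kruskal_wallis_dunn(t, p_adjust="holm")
        assert len(res.posthoc) == 6
        assert np.all(res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15)
        none = kruskal_wallis_dunn(t, p_adjust="none").posthoc
        assert np.allclose(none["p_adj"], none["p_raw"])

    def test_dunn_z_hand_example_two_groups_dominance(self):
        # groups far apart -> largest |z| for the extreme pair
        t = table([[1, 2, 3], [4, 5, 6], [7, 8, 9], [10, 11, 12]])
        ph = kruskal_wallis_dunn(t).posthoc
        pair = ph.loc[ph["z"].abs().idxmax()]
        labels = {pair["group1"], pair["group2"]}
        assert labels == {"TnC+/+ / SE", "TnC-/- / EE"} or \
            labels == {"TnC+/+ / EE", "TnC-/- / SE"}

    def test_null_omnibus_rejection_rate(self):
        rng = np.random.default_rng(11)
        rejections = 0
        reps = 400
        for _ in range(reps):
            t = table([rng.normal(0, 1, 20) for _ in range(4)])
            p = kruskal_wallis_dunn(t, posthoc=False).statistics["omnibus"][1]
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.025)


class TestAnalyzeMetric:
    def test_gate_routes_to_anova_for_normal_data(self):
        rng = np.random.default_rng(12)
        t = table([rng.normal(0, 1, 15) for _ in range(4)])
        res = analyze_metric(t, "m")
        assert res.test in ("two-way ANOVA", "Kruskal-Wallis")
        assert res.gate["choice"] in ("parametric", "nonparametric")

    def test_force_nonparametric(self):
        rng = np.random.default_rng(13)
        t = table([rng.normal(0, 1, 15) for _ in range(4)])
        res = analyze_metric(t, "m", force="nonparametric")
        assert res.test == "Kruskal-Wallis"
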