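import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from synloc import (
    BehavioralCounts,
    GroupTable,
    dunn_posthoc,
    learning_index,
    reciprocal_average,
    significance_symbol,
    stats_decision_tree,
    two_way_interaction,
)


def _path_checks(result):
    return [name for name, _ in result.decision_path]


class TestDecisionTree:
    def test_identical_groups_not_significant(self):
        g = np.array([1.0, 1.1, 0.9, 1.05, 0.95, 1.02, 0.97, 1.2, 0.8, 1.0])
        res = stats_decision_tree([g, g.copy()], design="two_group")
        assert res.p_value > 0.05

    def test_normal_groups_route_to_student_t(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 10)
        b = rng.normal(1.5, 1.0, 10)
        res = stats_decision_tree([a, b], design="two_group")
        assert res.test_used == "student_t"
        checks = _path_checks(res)
        assert checks[:2] == ["shapiro_wilk[group0]", "shapiro_wilk[group1]"]
        assert checks[2] == "homoscedasticity[bartlett]"
        assert ("branch", "parametric") in res.decision_path
        # statistic agrees with a direct equal-variance t-test
        t_ref = sps.ttest_ind(a, b, equal_var=True)
        assert res.statistic == pytest.approx(t_ref.statistic)
        assert res.p_value == pytest.approx(t_ref.pvalue)

    def test_heavy_tailed_groups_route_to_mann_whitney(self):
        rng = np.random.default_rng(1)
        a = np.exp(rng.normal(0, 2.0, 15))  # strongly lognormal: fails Shapiro
        b = np.exp(rng.normal(1.0, 2.0, 15))
        res = stats_decision_tree([a, b], design="two_group")
        assert res.test_used == "mann_whitney_u"
        assert ("branch", "nonparametric") in res.decision_path

    def test_one_way_parametric_with_bonferroni_posthoc(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.0, 2.0)]
        res = stats_decision_tree(groups, design="one_way")
        assert res.test_used == "one_way_anova"
        assert res.adjusted == "bonferroni"
        assert len(res.posthoc) == 3
        assert np.all(res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-15)

    def test_one_way_dunnett_against_control(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(m, 1.0, 10) for m in (0.0, 0.1, 3.0)]
        res = stats_decision_tree(groups, design="one_way", post_hoc="dunnett")
        assert res.adjusted == "dunnett"
        assert list(res.posthoc["group"]) == [1, 2]

    def test_one_way_nonparametric_gets_dunn(self):
        rng = np.random.default_rng(4)
        groups = [np.exp(rng.normal(m, 2.0, 12)) for m in (0, 0, 1.5)]
        res = stats_decision_tree(groups, design="one_way")
        assert res.test_used == "kruskal_wallis"
        assert res.adjusted == "dunn_bonferroni"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="n=2"):
            stats_decision_tree([np.array([1.0, 2.0]), np.array([1.0, 2.0, 3.0])])

    def test_constant_group_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            stats_decision_tree([np.ones(5), np.array([1.0, 2.0, 3.0, 4.0, 5.0])])

    def test_two_group_design_needs_two_groups(self):
        rng = np.random.default_rng(5)
        with pytest.raises(ValueError, match="exactly 2"):
            stats_decision_tree([rng.normal(size=5)] * 3, design="two_group")

    def test_determinism(self):
        rng = np.random.default_rng(6)
        groups = [rng.normal(size=8), rng.normal(size=8)]
        a = stats_decision_tree(groups, design="two_group")
        b = stats_decision_tree([g.copy() for g in groups], design="two_group")
        assert a.decision_path == b.decision_path
        assert a.p_value == b.p_value

    def test_spearman_homoscedasticity_option(self):
        rng = np.random.default_rng(7)
        groups = [rng.normal(0, 1, 10), rng.normal(0.5, 1, 10)]
        res = stats_decision_tree(groups, design="two_group", homoscedasticity="spearman")
        assert "homoscedasticity[spearman]" in _path_checks(res)


class TestDunn:
    def test_two_groups_z_squared_equals_kruskal_h(self):
        # known identity: for k = 2 untied groups, Dunn's z^2 equals the
        # Kruskal-Wallis H statistic
        rng = np.random.default_rng(8)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 1, 12)
        df = dunn_posthoc([a, b])
        h = sps.kruskal(a, b).statistic
        assert df.loc[0, "z"] ** 2 == pytest.approx(h)

    def test_pairs_and_adjustment(self):
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, 1, 8) for m in (0, 0, 4)]
        df = dunn_posthoc(groups)
        assert len(df) == 3
        assert np.all(df["p_adj"] <= 1.0)
        # the clearly shifted group separates from both others
        strong = df[(df["group_j"] == 2)]
        assert (strong["p_adj"] < 0.05).all()


class TestTwoWayAnova:
    @staticmethod
    def _table(cell_values):
        rows = []
        for (geno, t), values in cell_values.items():
            for i, y in enumerate(values):
                rows.append(
                    {
                        "sample_id": f"{geno}{t}_{i}",
                        "genotype": geno,
                        "starvation_hours": t,
                        "region": "gamma5",
                        "measurement": y,
                    }
                )
        return GroupTable(pd.DataFrame(rows))

    def test_additive_means_zero_interaction(self):
        # cell mean = genotype effect + time effect, with identical
        # replicate offsets in every cell: SS_interaction = 0 exactly
        offsets = [-1.0, 0.0, 1.0]
        cells = {}
        for gi, geno in enumerate(["a", "b"]):
            for ti, t in enumerate([0, 24]):
                mean = 10 + 2 * gi + 3 * ti
                cells[(geno, t)] = [mean + o for o in offsets]
        res = two_way_interaction(self._table(cells))
        assert res.statistic == pytest.approx(0.0, abs=1e-10)

    def test_matches_hand_computed_sums_of_squares(self):
        # balanced 2x2 with integer values; the oracle is the textbook
        # cell/row/column-mean decomposition computed from scratch
        cells = {
            ("a", 0): [3.0, 5.0, 4.0],
            ("a", 24): [8.0, 6.0, 7.0],
            ("b", 0): [2.0, 4.0, 3.0],
            ("b", 24): [12.0, 10.0, 14.0],
        }
        res = two_way_interaction(self._table(cells))

        n = 3
        all_vals = np.concatenate([np.asarray(v) for v in cells.values()])
        grand = all_vals.mean()
        cell_means = {k: np.mean(v) for k, v in cells.items()}
        a_means = {g: np.mean([cell_means[(g, t)] for t in (0, 24)]) for g in "ab"}
        b_means = {t: np.mean([cell_means[(g, t)] for g in "ab"]) for t in (0, 24)}
        ss_inter = n * sum(
            (cell_means[(g, t)] - a_means[g] - b_means[t] + grand) ** 2
            for g in "ab"
            for t in (0, 24)
        )
        ss_err = sum(
            (y - cell_means[k]) ** 2 for k, v in cells.items() for y in v
        )
        df_err = len(all_vals) - 4
        f_oracle = (ss_inter / 1.0) / (ss_err / df_err)
        assert res.statistic == pytest.approx(f_oracle, rel=1e-10)
        p_oracle = sps.f.sf(f_oracle, 1, df_err)
        assert res.p_value == pytest.approx(p_oracle, rel=1e-10)

    def test_empty_cell_is_an_error(self):
        cells = {
            ("a", 0): [1.0, 2.0, 3.0],
            ("a", 24): [1.0, 2.0, 3.0],
            ("b", 0): [1.0, 2.0, 3.0],
        }
        with pytest.raises(ValueError, match="observations"):
            two_way_interaction(self._table(cells))

    def test_single_level_factor_rejected(self):
        cells = {("a", 0): [1.0, 2.0], ("a", 24): [3.0, 4.0]}
        with pytest.raises(ValueError, match="levels"):
            two_way_interaction(self._table(cells))

    def test_two_way_design_through_decision_tree(self):
        rng = np.random.default_rng(10)
        cells = {
            (g, t): list(rng.normal(m, 0.5, 6))
            for (g, t), m in {
                ("a", 0): 1.0, ("a", 24): 2.0, ("b", 0): 1.0, ("b", 24): 0.5,
            }.items()
        }
        res = stats_decision_tree(self._table(cells), design="two_way")
        assert res.test_used == "two_way_anova_interaction"
        assert any(name.startswith("shapiro") for name in _path_checks(res))


class TestLearningIndex:
    @staticmethod
    def _constant_counts(n_plus, n_minus, seconds=120):
        return BehavioralCounts(
            n_cs_plus=np.full(seconds, n_plus), n_cs_minus=np.full(seconds, n_minus)
        )

    @pytest.mark.parametrize(
        "n_plus,n_minus,expected",
        [(50, 50, 0.0), (25, 75, 0.5), (0, 80, 1.0), (80, 0, -1.0)],
    )
    def test_constant_split_values(self, n_plus, n_minus, expected):
        res = learning_index(self._constant_counts(n_plus, n_minus))
        assert res.value == pytest.approx(expected)
        assert res.n_seconds_used == 60

    def test_appetitive_sign_flip(self):
        counts = self._constant_counts(75, 25)
        assert learning_index(counts, sign="appetitive").value == pytest.approx(0.5)

    @given(
        n_plus=st.integers(0, 60),
        n_minus=st.integers(0, 60),
    )
    def test_bounded_and_antisymmetric(self, n_plus, n_minus):
        if n_plus + n_minus == 0:
            return
        fwd = learning_index(self._constant_counts(n_plus, n_minus)).value
        rev = learning_index(self._constant_counts(n_minus, n_plus)).value
        assert -1.0 <= fwd <= 1.0
        assert fwd == pytest.approx(-rev)

    def test_zero_second_excluded_with_flag(self):
        plus = np.full(120, 30)
        minus = np.full(120, 10)
        plus[100] = minus[100] = 0
        res = learning_index(BehavioralCounts(n_cs_plus=plus, n_cs_minus=minus))
        assert res.excluded_seconds == [100]
        assert res.n_seconds_used == 59
        assert res.value == pytest.approx(-0.5)

    def test_window_must_fit_session(self):
        with pytest.raises(ValueError, match="window"):
            learning_index(self._constant_counts(10, 10, seconds=30), window_seconds=60)

    def test_all_zero_window_is_an_error(self):
        counts = BehavioralCounts(
            n_cs_plus=np.zeros(120, int), n_cs_minus=np.zeros(120, int)
        )
        with pytest.raises(ValueError, match="zero flies"):
            learning_index(counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            BehavioralCounts(n_cs_plus=np.array([-1, 2]), n_cs_minus=np.array([1, 2]))


class TestHelpers:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.4, 0.6, 0.5), (0.7, 0.7, 0.7), (0.2, -0.1, 0.05)]
    )
    def test_reciprocal_average(self, a, b, expected):
        assert reciprocal_average(a, b) == pytest.approx(expected)

    def test_reciprocal_average_rejects_nan(self):
        with pytest.raises(ValueError):
            reciprocal_average(np.nan, 0.5)

    @pytest.mark.parametrize(
        "p,symbol",
        [(0.2, "ns"), (0.04, "*"), (0.005, "**"), (0.0005, "***")],
    )
    def test_significance_symbols(self, p, symbol):
        assert significance_symbol(p) == symbol
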