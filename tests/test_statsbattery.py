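"""Statistical battery: Type III ANOVA + eta^2, Sidak, Welch, chi-square,
Kruskal-Wallis + Dunn."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from sudephys.statsbattery import (
    DegenerateDataError, DesignError, chi_square, kruskal_dunn,
    normality_gate, sidak_adjust, two_way_anova, welch_t,
)


def balanced_2x2(rng, effect_a=0.0, effect_b=0.0, interaction=0.0, n_cell=6):
    rows = []
    for a in (-1, 1):
        for b in (-1, 1):
            mu = a * effect_a + b * effect_b + a * b * interaction
            for v in rng.normal(mu, 1.0, n_cell):
                rows.append({"value": v, "factor_a": f"a{a}", "factor_b": f"b{b}"})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_null_case_has_tiny_effect_sums(self, rng):
        df = balanced_2x2(rng, n_cell=200)
        eff = two_way_anova(df)
        for key in ("A", "B", "A:B"):
            assert eff[key].eta_sq < 0.02

    def test_balanced_design_matches_hand_ss_decomposition(self):
        # 2x2 with 2 obs/cell; hand decomposition from cell means
        data = {
            ("x", "u"): [1.0, 3.0],
            ("x", "v"): [2.0, 4.0],
            ("y", "u"): [5.0, 7.0],
            ("y", "v"): [10.0, 12.0],
        }
        rows = [
            {"value": v, "factor_a": a, "factor_b": b}
            for (a, b), vals in data.items()
            for v in vals
        ]
        df = pd.DataFrame(rows)
        # grand mean 5.5; A means: x=2.5, y=8.5; B means: u=4, v=7
        # SS_A = 8*(3^2) = 72; SS_B = 8*(1.5^2) = 18
        # cell means 2,3,6,11; interaction deviations +/-1 -> SS_AB = 8
        # residual: each cell two obs +/-1 around its mean -> SS_res = 8
        eff = two_way_anova(df)
        assert eff["A"].ss == pytest.approx(72.0, abs=1e-9)
        assert eff["B"].ss == pytest.approx(18.0, abs=1e-9)
        assert eff["A:B"].ss == pytest.approx(8.0, abs=1e-9)
        assert eff["residual"].ss == pytest.approx(8.0, abs=1e-9)
        total = sum(eff[k].ss for k in ("A", "B", "A:B", "residual"))
        assert total == pytest.approx(72 + 18 + 8 + 8, abs=1e-9)
        assert eff["A"].eta_sq == pytest.approx(72 / 106.0, abs=1e-12)

    def test_matches_statsmodels_type3_on_unbalanced_data(self, rng):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        rows = []
        for (a, b), k in zip(
            [("x", "u"), ("x", "v"), ("y", "u"), ("y", "v")], [7, 5, 6, 9]
        ):
            for v in rng.normal(1.0 * (a == "x") + 0.5 * (b == "u"), 1.0, k):
                rows.append({"value": v, "factor_a": a, "factor_b": b})
        df = pd.DataFrame(rows)
        eff = two_way_anova(df)
        fit = smf.ols("value ~ C(factor_a, Sum)*C(factor_b, Sum)", df).fit()
        tab = sm.stats.anova_lm(fit, typ=3)
        pairs = {
            "A": "C(factor_a, Sum)",
            "B": "C(factor_b, Sum)",
            "A:B": "C(factor_a, Sum):C(factor_b, Sum)",
        }
        for key, name in pairs.items():
            assert eff[key].ss == pytest.approx(tab.loc[name, "sum_sq"], abs=1e-9)
            assert eff[key].F == pytest.approx(tab.loc[name, "F"], abs=1e-9)
            assert eff[key].p == pytest.approx(tab.loc[name, "PR(>F)"], abs=1e-12)

    def test_eta_squared_partition(self, rng):
        df = balanced_2x2(rng, effect_a=1.0, effect_b=0.5, interaction=0.25)
        eff = two_way_anova(df)
        etas = [eff[k].eta_sq for k in ("A", "B", "A:B")]
        assert all(0 <= e <= 1 for e in etas)
        assert sum(etas) <= 1.0
        # balanced design: effects + residual partition SS_total exactly
        assert sum(etas) + eff["residual"].eta_sq == pytest.approx(1.0, abs=1e-9)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame(
            {"value": [1.0, 2.0, 3.0], "factor_a": "x", "factor_b": ["u", "v", "u"]}
        )
        with pytest.raises(DesignError):
            two_way_anova(df)


class TestSidak:
    @pytest.mark.parametrize(
        "p,m,expected",
        [(0.05, 1, 0.05), (0.01, 3, 0.029701), (1.0, 7, 1.0), (0.0, 5, 0.0)],
    )
    def test_adjustment_values(self, p, m, expected):
        assert sidak_adjust(p, m) == pytest.approx(expected, abs=1e-9)

    def test_monotone_in_p_and_m(self):
        assert sidak_adjust(0.02, 4) < sidak_adjust(0.03, 4)
        assert sidak_adjust(0.02, 4) < sidak_adjust(0.02, 5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.2, 3)
        with pytest.raises(ValueError):
            sidak_adjust(0.05, 0)


class TestWelch:
    def test_identical_samples(self):
        t, df, p = welch_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_textbook_case_against_hand_formula(self):
        x = np.array([27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1])
        y = np.array([27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0])
        t, df, p = welch_t(x, y)
        vx, vy = x.var(ddof=1) / len(x), y.var(ddof=1) / len(y)
        t_hand = (x.mean() - y.mean()) / np.sqrt(vx + vy)
        df_hand = (vx + vy) ** 2 / (
            vx**2 / (len(x) - 1) + vy**2 / (len(y) - 1)
        )
        assert t == pytest.approx(t_hand, abs=1e-12)
        assert df == pytest.approx(df_hand, abs=1e-9)
        assert p == pytest.approx(2 * stats.t.sf(abs(t_hand), df_hand), abs=1e-12)

    def test_antisymmetric_in_sample_order(self, rng):
        x, y = rng.normal(0, 1, 10), rng.normal(0.5, 2, 12)
        assert welch_t(x, y)[0] == pytest.approx(-welch_t(y, x)[0])

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateDataError):
            welch_t([1.0], [2.0, 3.0])
        with pytest.raises(DegenerateDataError):
            welch_t([1.0, 1.0], [2.0, 2.0])


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        chi2, df, p = chi_square([[10, 20, 30], [5, 10, 15]])
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert df == 2

    def test_diagonal_2x2_hand_value(self):
        chi2, df, p = chi_square([[10, 0], [0, 10]])
        assert chi2 == pytest.approx(20.0)
        assert df == 1

    def test_row_swap_invariance(self):
        a = chi_square([[8, 3], [2, 9]])[0]
        b = chi_square([[2, 9], [8, 3]])[0]
        assert a == pytest.approx(b)

    def test_zero_marginal_rejected(self):
        with pytest.raises(DegenerateDataError):
            chi_square([[0, 5], [0, 7]])


class TestKruskalDunn:
    def test_identical_groups_give_zero_h(self):
        g = {"a": np.array([1.0, 1.0]), "b": np.array([1.0, 1.0])}
        h, p, _ = kruskal_dunn(g)
        assert h == 0.0 and p == 1.0

    def test_three_group_hand_ranks(self):
        groups = {
            "a": np.array([1.0, 2.0, 3.0]),
            "b": np.array([4.0, 5.0, 6.0]),
            "c": np.array([7.0, 8.0, 9.0]),
        }
        h, p, comps = kruskal_dunn(groups, adjust="none")
        # mean ranks 2, 5, 8; H = 12/(9*10) * 3*((2-5)^2+(5-5)^2+(8-5)^2) = 7.2
        assert h == pytest.approx(7.2)
        by_pair = {(c.group_i, c.group_j): c for c in comps}
        # Dunn z for a vs c: (2-8)/sqrt((90/12)*(2/3)) = -6/sqrt(5)
        assert by_pair[("a", "c")].z == pytest.approx(-6 / np.sqrt(5), abs=1e-9)

    def test_h_invariant_under_monotone_transform(self, rng):
        groups = {k: rng.normal(i, 1, 10) for i, k in enumerate("abc")}
        h1, _, _ = kruskal_dunn(groups)
        h2, _, _ = kruskal_dunn({k: np.exp(v) for k, v in groups.items()})
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_sidak_adjustment_applied_to_pairs(self, rng):
        groups = {k: rng.normal(i, 1, 8) for i, k in enumerate("abc")}
        _, _, comps = kruskal_dunn(groups, adjust="sidak")
        for c in comps:
            assert c.p_adj == pytest.approx(sidak_adjust(c.p_raw, 3), abs=1e-12)


class TestTypeIErrorUnderNull:
    """Empirical size of each test at alpha = 0.05 over null simulations."""

    ALPHA = 0.05
    REPS = 2000

    def _ci(self, reps):
        return 3 * np.sqrt(self.ALPHA * (1 - self.ALPHA) / reps)

    def test_welch_kruskal_anova_sizes(self):
        rng = np.random.default_rng(77)
        rej_w = rej_k = rej_a = 0
        design_a = ["x", "y"] * 10
        design_b = (["u"] * 2 + ["v"] * 2) * 5
        for _ in range(self.REPS):
            if welch_t(rng.normal(0, 1, 10), rng.normal(0, 1, 10))[2] < self.ALPHA:
                rej_w += 1
            g = {k: rng.normal(0, 1, 8) for k in "abc"}
            if kruskal_dunn(g)[1] < self.ALPHA:
                rej_k += 1
            df = pd.DataFrame(
                {"value": rng.normal(0, 1, 20), "factor_a": design_a,
                 "factor_b": design_b}
            )
            if two_way_anova(df)["A"].p < self.ALPHA:
                rej_a += 1
        tol = self._ci(self.REPS)
        assert abs(rej_w / self.REPS - self.ALPHA) < tol
        assert abs(rej_k / self.REPS - self.ALPHA) < tol
        assert abs(rej_a / self.REPS - self.ALPHA) < tol


def test_normality_gate_routes_skewed_data():
    rng = np.random.default_rng(11)
    normal = [rng.normal(0, 1, 30) for _ in range(3)]
    skewed = [np.exp(rng.normal(0, 1.5, 300)) for _ in range(3)]
    assert normality_gate(normal) is True
    assert normality_gate(skewed) is False
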