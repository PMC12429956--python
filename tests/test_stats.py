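"""Chi-square, balanced three-way ANOVA, and Tukey HSD."""

import numpy as np
import pytest

from netdrugmap.stats import (
    chi_square_independence,
    significance_stars,
    three_way_anova,
    tukey_hsd,
)

from oracles import chi2_closed_form_2x2


class TestChiSquare:
    def test_known_2x2(self):
        stat, dof, p = chi_square_independence([[10, 20], [20, 10]])
        assert stat == pytest.approx(6.667, abs=5e-4)
        assert dof == 1

    def test_independent_table_gives_zero(self):
        stat, dof, p = chi_square_independence([[5, 5], [5, 5]])
        assert stat == 0.0
        assert p == pytest.approx(1.0)

    def test_matches_closed_form_on_random_tables(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            a, b, c, d = rng.integers(1, 100, size=4)
            stat, dof, _ = chi_square_independence([[a, b], [c, d]])
            assert stat == pytest.approx(chi2_closed_form_2x2(a, b, c, d), abs=1e-9)
            assert dof == 1

    def test_invariant_under_permutation(self):
        t = [[3, 9, 2], [8, 1, 7]]
        stat1, _, _ = chi_square_independence(t)
        stat2, _, _ = chi_square_independence([row[::-1] for row in t][::-1])
        assert stat1 == pytest.approx(stat2, abs=1e-12)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_square_independence([[0, 0], [3, 4]])

    def test_p_decreases_with_imbalance(self):
        """Fixed n: stronger off-diagonal imbalance → smaller p."""
        ps = []
        for shift in (0, 5, 10):
            _, _, p = chi_square_independence(
                [[15 + shift, 15 - shift], [15 - shift, 15 + shift]]
            )
            ps.append(p)
        assert ps[0] > ps[1] > ps[2]


class TestAnova:
    def test_pure_phase_effect(self):
        """μ + phase effect (0, 0, δ), no noise: PHASE F explodes, the
        other effects have zero SS, residual flagged as zero."""
        cells = np.zeros((4, 3, 3)) + 10.0
        cells[:, 2, :] += 5.0
        res = three_way_anova(cells)
        assert res.zero_residual
        assert res.f_stats["PHASE"] == np.inf
        for eff in ("DISEASE", "TARGET", "DISEASExTARGET"):
            assert res.ss[eff] == pytest.approx(0.0, abs=1e-9)

    def test_constant_cells(self):
        res = three_way_anova(np.full((2, 3, 4), 7.0))
        assert res.zero_residual
        assert all(f == 0.0 for f in res.f_stats.values())

    @pytest.mark.parametrize("seed", range(10))
    def test_ss_decomposition_conserves_total(self, seed):
        rng = np.random.default_rng(seed)
        cells = rng.normal(size=(3, 3, 3)) * 10
        res = three_way_anova(cells)
        ss_total = float(((cells - cells.mean()) ** 2).sum())
        assert sum(res.ss.values()) + res.residual_ss == pytest.approx(ss_total, abs=1e-9)

    def test_f_invariant_to_relabeling_other_factors(self):
        rng = np.random.default_rng(5)
        cells = rng.normal(size=(4, 3, 3))
        res1 = three_way_anova(cells)
        perm = cells[[2, 0, 3, 1], :, :][:, [1, 0, 2], :]
        res2 = three_way_anova(perm)
        assert res1.f_stats["TARGET"] == pytest.approx(res2.f_stats["TARGET"], abs=1e-9)

    def test_matches_statsmodels_on_random_design(self):
        """Independent oracle: OLS with all two-way interactions and the
        three-way term left out (so its SS is the residual)."""
        import pandas as pd
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(17)
        cells = rng.normal(size=(4, 3, 3)) * 5 + 50
        rows = [
            {"y": cells[i, j, k], "fa": f"a{i}", "fb": f"b{j}", "fc": f"c{k}"}
            for i in range(4) for j in range(3) for k in range(3)
        ]
        df = pd.DataFrame(rows)
        model = ols(
            "y ~ C(fa) + C(fb) + C(fc) + C(fa):C(fb) + C(fa):C(fc) + C(fb):C(fc)", df
        ).fit()
        table = sm.stats.anova_lm(model, typ=2)
        res = three_way_anova(cells, factors=("A", "B", "C"))
        mapping = {
            "A": "C(fa)", "B": "C(fb)", "C": "C(fc)",
            "AxB": "C(fa):C(fb)", "AxC": "C(fa):C(fc)", "BxC": "C(fb):C(fc)",
        }
        for eff, sm_name in mapping.items():
            assert res.ss[eff] == pytest.approx(table.loc[sm_name, "sum_sq"], rel=1e-8)
            assert res.f_stats[eff] == pytest.approx(table.loc[sm_name, "F"], rel=1e-8)
        assert res.residual_ss == pytest.approx(table.loc["Residual", "sum_sq"], rel=1e-8)

    def test_collapsing_a_factor_reduces_to_two_way(self):
        """Averaging over one factor, the remaining effects match a direct
        two-way decomposition of the collapsed table."""
        rng = np.random.default_rng(23)
        cells = rng.normal(size=(3, 4, 2))
        res3 = three_way_anova(cells)
        collapsed = cells.mean(axis=2)  # 3×4, average over C
        grand = collapsed.mean()
        ss_a = ((collapsed.mean(axis=1) - grand) ** 2).sum() * collapsed.shape[1]
        # per-observation weighting differs by the collapsed factor's size
        assert res3.ss["DISEASE"] == pytest.approx(ss_a * cells.shape[2], abs=1e-9)

    def test_missing_cell_named(self):
        cells = np.full((2, 3, 3), 1.0)
        cells[1, 2, 0] = np.nan
        with pytest.raises(ValueError, match="missing cell"):
            three_way_anova(cells)

    def test_single_level_factor_rejected(self):
        with pytest.raises(ValueError, match="at least 2 levels"):
            three_way_anova(np.ones((1, 3, 3)))


class TestTukey:
    def test_identical_means_give_p_one(self):
        table = tukey_hsd({"all": 5.0, "approved": 5.0}, ms_error=2.0,
                          df_error=10, group_size=6)
        row = table.rows[0]
        assert row["difference"] == 0.0
        assert row["p_adjusted"] == pytest.approx(1.0)

    def test_p_grows_as_difference_shrinks(self):
        ps = []
        for diff in (8.0, 4.0, 1.0):
            t = tukey_hsd({"a": 0.0, "b": diff}, ms_error=4.0, df_error=12, group_size=5)
            ps.append(t.rows[0]["p_adjusted"])
        assert ps[0] < ps[1] < ps[2]

    def test_pairwise_row_count(self):
        means = {f"l{i}": float(i) for i in range(5)}
        t = tukey_hsd(means, ms_error=1.0, df_error=20, group_size=4)
        assert len(t) == 5 * 4 // 2

    def test_agrees_with_scipy_reference(self):
        """Cross-check against scipy's own Tukey HSD on raw groups."""
        from scipy.stats import tukey_hsd as scipy_tukey

        rng = np.random.default_rng(3)
        groups = [rng.normal(loc=m, size=8) for m in (0.0, 1.0, 3.0)]
        ref = scipy_tukey(*groups)
        means = {f"g{i}": float(g.mean()) for i, g in enumerate(groups)}
        n = 8
        k = 3
        df_error = k * (n - 1)
        ms_error = float(np.mean([g.var(ddof=1) for g in groups]))
        mine = tukey_hsd(means, ms_error, df_error, n)
        got = {(r["level_a"], r["level_b"]): r["p_adjusted"] for r in mine}
        assert got[("g0", "g1")] == pytest.approx(ref.pvalue[0, 1], abs=1e-8)
        assert got[("g0", "g2")] == pytest.approx(ref.pvalue[0, 2], abs=1e-8)
        assert got[("g1", "g2")] == pytest.approx(ref.pvalue[1, 2], abs=1e-8)

    def test_invalid_df_rejected(self):
        with pytest.raises(ValueError):
            tukey_hsd({"a": 1.0, "b": 2.0}, 1.0, 0, 3)


def test_significance_star_convention():
    assert significance_stars(0.2) == ""
    assert significance_stars(0.03) == "*"
    assert significance_stars(0.004) == "**"
    assert significance_stars(5e-4) == "***"
    assert significance_stars(5e-5) == "****"
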