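"""Abundance and trend GLMs: recovery, invariances and multiplicity."""

import numpy as np
import pandas as pd
import pytest

from tecsuite.stats import (
    adjust_pvalues,
    age_expression_trend,
    nb_abundance_test,
    offset_selection_test,
    poisson_state_test,
)

AGES = np.array([1, 4, 16, 32, 52])


def nb_counts(rng, mu, alpha):
    if alpha <= 0:
        return rng.poisson(mu)
    size = 1.0 / alpha
    return rng.negative_binomial(size, size / (size + mu))


def abundance_table(rng, slopes, b0=np.log(500), alpha=0.1, n_rep=5, total=5000):
    rows = []
    for g, s in enumerate(slopes):
        for a in AGES:
            mu = np.exp(b0 + s * a)
            for r in range(n_rep):
                rows.append((f"g{g}", a, r, nb_counts(rng, mu, alpha), total))
    return pd.DataFrame(rows, columns=["group", "age", "replicate", "count", "total"])


class TestAdjustPvalues:
    def test_bh_step_up_hand_example(self):
        assert np.allclose(adjust_pvalues([0.01, 0.02, 0.03], "BH"), [0.03, 0.03, 0.03])

    def test_single_p_bonferroni_unchanged(self):
        assert adjust_pvalues([0.037], "bonferroni")[0] == pytest.approx(0.037)

    def test_all_ones_stay_ones(self):
        assert (adjust_pvalues([1.0, 1.0, 1.0], "BH") == 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.2])


class TestNbAbundance:
    def test_constant_counts_not_significant(self):
        rng = np.random.default_rng(0)
        tab = abundance_table(rng, [0.0, 0.0, 0.0])
        res = nb_abundance_test(tab)
        assert not res["significant"].any()
        assert np.allclose(res["coef_linear"], 0.0, atol=0.01)

    def test_planted_decline_recovered(self):
        rng = np.random.default_rng(1)
        tab = abundance_table(rng, [-0.1])
        res = nb_abundance_test(tab)
        assert res["significant"].iloc[0]
        assert abs(res["coef_linear"].iloc[0] + 0.1) <= 2 * res["se_linear"].iloc[0]

    def test_planted_effect_among_nulls_isolated(self):
        hits = 0
        for i in range(20):
            rng = np.random.default_rng(100 + i)
            tab = abundance_table(rng, [-0.1] + [0.0] * 9)
            res = nb_abundance_test(tab)
            if set(res.index[res["significant"]]) == {"g0"}:
                hits += 1
        assert hits >= 18

    def test_quadratic_terms_mode(self):
        rng = np.random.default_rng(2)
        tab = abundance_table(rng, [0.0])
        res = nb_abundance_test(tab, terms="linear+quadratic")
        assert not np.isnan(res["coef_quadratic"].iloc[0])

    def test_all_zero_group_excluded_with_warning(self):
        rng = np.random.default_rng(3)
        tab = abundance_table(rng, [0.0])
        zero = tab.copy()
        zero["group"] = "gz"
        zero["count"] = 0
        with pytest.warns(UserWarning, match="all-zero"):
            res = nb_abundance_test(pd.concat([tab, zero]))
        assert "gz" not in res.index

    def test_too_few_ages_rejected(self):
        tab = pd.DataFrame(
            {"group": "a", "age": [1, 1, 4, 4], "replicate": [1, 2, 1, 2],
             "count": [5, 6, 7, 8]}
        )
        with pytest.raises(ValueError, match="3 distinct ages"):
            nb_abundance_test(tab)


class TestPoissonStateTest:
    def test_planted_shifts_flagged(self):
        rng = np.random.default_rng(4)
        rows = []
        for state, slope in [(1, 0.04), (2, 0.0), (3, -0.04)]:
            for a in AGES:
                for r in range(3):
                    rows.append((state, a, r, rng.poisson(np.exp(4.5 + slope * a))))
        tab = pd.DataFrame(rows, columns=["state", "age", "replicate", "count"])
        res = poisson_state_test(tab)
        assert res.loc[1, "significant"] and res.loc[1, "coef_linear"] > 0
        assert res.loc[3, "significant"] and res.loc[3, "coef_linear"] < 0
        assert not res.loc[2, "significant"]

    def test_equal_counts_nothing_flagged(self):
        rows = [(s, a, r, 50) for s in (1, 2) for a in AGES for r in range(3)]
        tab = pd.DataFrame(rows, columns=["state", "age", "replicate", "count"])
        res = poisson_state_test(tab)
        assert not res["significant"].any()

    def test_single_state_bonferroni_is_identity(self):
        rng = np.random.default_rng(5)
        rows = [(1, a, r, rng.poisson(40)) for a in AGES for r in range(3)]
        tab = pd.DataFrame(rows, columns=["state", "age", "replicate", "count"])
        res = poisson_state_test(tab)
        assert res["p_adjusted"].iloc[0] == pytest.approx(res["pvalue"].iloc[0])


class TestOffsetSelection:
    @staticmethod
    def wave_table(rng, frac_slope, base_frac=0.1, parent_mu=5000, alpha=0.05):
        rows = []
        for a in AGES:
            for r in range(4):
                parent = rng.poisson(parent_mu)
                frac = base_frac * np.exp(frac_slope * a)
                wave = nb_counts(rng, parent * frac, alpha)
                rows.append(("w", a, r, wave, parent))
        return pd.DataFrame(rows, columns=["group", "age", "replicate", "count", "parent"])

    def test_constant_fraction_gives_null_coefficient(self):
        rng = np.random.default_rng(6)
        res = offset_selection_test(self.wave_table(rng, 0.0))
        assert abs(res["coef_linear"].iloc[0]) <= 2 * res["se_linear"].iloc[0] + 1e-3
        assert not res["significant"].any()

    def test_halving_fraction_per_10_weeks_recovered(self):
        slope = np.log(0.5) / 10  # ~ -0.0693 per week
        rng = np.random.default_rng(7)
        res = offset_selection_test(self.wave_table(rng, slope))
        assert res["significant"].iloc[0]
        assert abs(res["coef_linear"].iloc[0] - slope) <= 2 * res["se_linear"].iloc[0]

    def test_offset_absorbs_joint_rescaling(self):
        rng = np.random.default_rng(8)
        tab = self.wave_table(rng, 0.0)
        doubled = tab.copy()
        doubled["count"] *= 2
        doubled["parent"] *= 2
        r1 = offset_selection_test(tab)
        r2 = offset_selection_test(doubled)
        assert r1["coef_linear"].iloc[0] == pytest.approx(
            r2["coef_linear"].iloc[0], abs=0.02
        )

    def test_zero_parent_rows_excluded(self):
        rng = np.random.default_rng(9)
        tab = self.wave_table(rng, 0.0)
        tab.loc[0, "parent"] = 0
        with pytest.warns(UserWarning, match="non-positive parent"):
            offset_selection_test(tab)


class TestAgeExpressionTrend:
    def test_exact_log2_age_gene_has_unit_slope(self):
        ages = np.repeat(AGES, 10)
        sf = np.ones_like(ages, dtype=float)
        rng = np.random.default_rng(10)
        Y = np.column_stack([np.log2(ages), rng.normal(size=len(ages))])
        res = age_expression_trend(Y, ages, sf)
        assert res["slope"].iloc[0] == pytest.approx(1.0, abs=1e-9)
        assert res["pvalue"].iloc[0] < 1e-12

    def test_constant_gene_null(self):
        ages = np.repeat(AGES, 4)
        Y = np.column_stack([np.full(len(ages), 2.5)])
        res = age_expression_trend(Y, ages, np.ones(len(ages)))
        assert res["slope"].iloc[0] == 0.0
        assert res["pvalue"].iloc[0] == 1.0

    def test_null_genes_nominal_type_one_error(self):
        rng = np.random.default_rng(11)
        n_cells, n_genes = 100, 1000
        ages = rng.choice(AGES, size=n_cells)
        sf = rng.lognormal(0, 0.2, size=n_cells)
        Y = rng.normal(size=(n_cells, n_genes))
        res = age_expression_trend(Y, ages, sf)
        rate = (res["pvalue"] < 0.05).mean()
        assert rate == pytest.approx(0.05, abs=0.02)

    def test_depth_adjustment_removes_confounding(self):
        # expression tracks log(size factor) only; slope on log2(age) ~ 0
        rng = np.random.default_rng(12)
        n = 200
        ages = rng.choice(AGES, size=n)
        sf = rng.lognormal(0, 0.5, size=n)
        Y = np.column_stack([np.log(sf) * 2.0 + rng.normal(0, 0.01, n)])
        res = age_expression_trend(Y, ages, sf)
        assert abs(res["slope"].iloc[0]) < 0.01
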