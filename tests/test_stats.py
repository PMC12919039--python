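"""Group-statistics layer: ANOVA, t-tests, Kruskal–Wallis, Dunn, regressions."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from fbrquant.stats import (
    bonferroni,
    cross_section_regression,
    dunn_test,
    factorial_anova,
    kruskal_wallis,
    paired_ttest,
    posthoc_ttests,
    useful_fraction_trend,
)

from _oracles import dunn_z_oracle, kruskal_h_oracle


def two_group_table(a, b, factor="material", levels=("PI", "Si"), value="delta_neun"):
    return pd.DataFrame(
        {
            value: np.concatenate([a, b]),
            factor: [levels[0]] * len(a) + [levels[1]] * len(b),
        }
    )


class TestFactorialAnova:
    def test_two_groups_f_equals_t_squared(self):
        rng = np.random.default_rng(0)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        table = two_group_table(a, b)
        (res,) = factorial_anova(table, factors=("material",))
        t, p = sps.ttest_ind(a, b, equal_var=True)
        assert res.value == pytest.approx(t**2, rel=1e-9)
        assert res.p_raw == pytest.approx(p, rel=1e-9)

    def test_degenerate_identical_values_handled(self):
        table = two_group_table(np.ones(5), np.ones(5))
        (res,) = factorial_anova(table, factors=("material",))
        assert res.value == 0.0 and res.p_raw == 1.0

    def test_single_level_factor_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        table = two_group_table(rng.normal(size=8), rng.normal(size=8))
        table["tether"] = "T"
        with pytest.warns(UserWarning, match="dropped"):
            res = factorial_anova(table, factors=("material", "tether"))
        assert [r.comparison for r in res] == ["material"]

    def test_known_material_effect_detected(self):
        rng = np.random.default_rng(2)
        hits = 0
        for _ in range(100):
            a = rng.normal(0, 1, 20)
            b = rng.normal(1.5, 1, 20)  # Cohen's d = 1.5
            (res,) = factorial_anova(two_group_table(a, b), factors=("material",))
            hits += res.p_raw < 0.05
        assert hits >= 90


class TestPosthocTtests:
    def test_single_comparison_unadjusted(self):
        rng = np.random.default_rng(3)
        table = two_group_table(rng.normal(size=10), rng.normal(size=10))
        (res,) = posthoc_ttests(table, "delta_neun", "material")
        assert res.p_adj == res.p_raw

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.02, 4) == pytest.approx(0.08)
        assert bonferroni(0.5, 4) == 1.0

    def test_identical_groups_give_null_result(self):
        table = two_group_table(np.full(5, 3.0), np.full(5, 3.0))
        (res,) = posthoc_ttests(table, "delta_neun", "material")
        assert res.value == 0.0 and res.p_raw == 1.0


class TestKruskalWallis:
    def test_matches_hand_rank_oracle(self):
        groups = [np.array([1.0, 2, 3]), np.array([4.0, 5, 6])]
        res = kruskal_wallis(groups)
        assert res.value == pytest.approx(3.8571428, abs=1e-6)
        assert res.value == pytest.approx(kruskal_h_oracle([list(g) for g in groups]))

    def test_all_tied_is_null(self):
        res = kruskal_wallis([np.ones(4), np.ones(3)])
        assert res.value == 0.0 and res.p_raw == 1.0

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(4)
        groups = [rng.normal(size=8), rng.normal(1, 1, size=8), rng.normal(size=5)]
        r1 = kruskal_wallis(groups)
        r2 = kruskal_wallis([np.exp(g) for g in groups])
        assert r1.value == pytest.approx(r2.value)

    def test_agrees_with_oracle_on_small_tied_inputs(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            sizes = rng.integers(1, 4, size=rng.integers(2, 4))
            while sizes.sum() > 8:
                sizes = sizes[:-1]
            if len(sizes) < 2:
                continue
            groups = [list(rng.integers(0, 4, size=s).astype(float)) for s in sizes]
            pooled = [x for g in groups for x in g]
            if len(set(pooled)) == 1:
                continue
            res = kruskal_wallis([np.array(g) for g in groups])
            assert res.value == pytest.approx(kruskal_h_oracle(groups), abs=1e-9)


class TestDunn:
    def test_two_identical_groups_give_zero_z(self):
        (res,) = dunn_test([np.array([1.0, 2, 3]), np.array([1.0, 2, 3])])
        assert res.value == 0.0

    def test_three_separated_groups_match_hand_computation(self):
        groups = [
            np.array([1.0, 2, 3]),
            np.array([10.0, 11, 12]),
            np.array([20.0, 21, 22]),
        ]
        res = dunn_test(groups)
        extreme = [r for r in res if r.comparison == "g0 vs g2"][0]
        # mean ranks 2, 5, 8 over N=9, no ties: z = (2-8)/sqrt(7.5*(2/3))
        assert extreme.value == pytest.approx((2 - 8) / np.sqrt(7.5 * (2 / 3.0)))
        assert extreme.p_adj == pytest.approx(min(1.0, extreme.p_raw * 3))

    def test_swapping_groups_flips_sign(self):
        rng = np.random.default_rng(6)
        a, b = rng.normal(size=6), rng.normal(1, 1, size=6)
        (r1,) = dunn_test([a, b])
        (r2,) = dunn_test([b, a])
        assert r1.value == pytest.approx(-r2.value)

    def test_agrees_with_oracle_on_small_tied_inputs(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            n1, n2, n3 = rng.integers(1, 4, size=3)
            if n1 + n2 + n3 > 8:
                continue
            groups = [
                list(rng.integers(0, 3, size=n).astype(float)) for n in (n1, n2, n3)
            ]
            res = dunn_test([np.array(g) for g in groups])
            for r, (i, j) in zip(res, [(0, 1), (0, 2), (1, 2)]):
                assert r.value == pytest.approx(dunn_z_oracle(groups, i, j), abs=1e-9)

    def test_singleton_group_flagged(self):
        with pytest.warns(UserWarning, match="singleton"):
            dunn_test([np.array([1.0]), np.array([2.0, 3.0])])


class TestRegressions:
    def _table(self, idx):
        n = len(idx)
        rng = np.random.default_rng(8)
        return pd.DataFrame(
            {
                "idx_tissue_reaction": idx,
                "material": rng.choice(["PI", "Si"], size=n),
                "tether": rng.choice(["T", "U"], size=n),
                "region": rng.choice(["upper_cortex", "lower_cortex"], size=n),
                "cross_section_um2": rng.uniform(100, 5000, size=n),
            }
        )

    def test_constant_outcome_gives_zero_slopes(self):
        table = self._table(np.full(40, 0.3))
        results, _ = cross_section_regression(table)
        for r in results:
            assert r.value == pytest.approx(0.0, abs=1e-12)

    def test_exact_linear_relation_recovered(self):
        table = self._table(np.zeros(40))
        table["idx_tissue_reaction"] = 2.0 + 0.001 * table["cross_section_um2"]
        results, fit = cross_section_regression(table)
        slope = [r for r in results if r.comparison == "cross_section_um2"][0]
        assert slope.value == pytest.approx(0.001, rel=1e-9)

    def test_white_matter_rows_excluded(self):
        table = self._table(np.random.default_rng(9).uniform(0, 1, 40))
        extra = table.iloc[:5].copy()
        extra["region"] = "white_matter"
        _, fit = cross_section_regression(pd.concat([table, extra]))
        assert fit.nobs == 40

    def test_slope_estimate_unbiased(self):
        rng = np.random.default_rng(10)
        beta = 2e-4
        estimates = []
        for _ in range(300):
            x = rng.uniform(100, 5000, 30)
            y = 0.1 + beta * x + rng.normal(0, 0.05, 30)
            table = self._table(np.zeros(30))
            table["cross_section_um2"] = x
            table["idx_tissue_reaction"] = y
            results, _ = cross_section_regression(table)
            estimates.append(
                [r for r in results if r.comparison == "cross_section_um2"][0].value
            )
        bias = np.mean(estimates) - beta
        se = np.std(estimates, ddof=1) / np.sqrt(len(estimates))
        assert abs(bias) < 2 * se + 1e-12


class TestUsefulFractionTrend:
    def _weekly(self, values_by_material):
        rows = []
        for mat, vals in values_by_material.items():
            for w, v in enumerate(vals):
                rows.append({"material": mat, "week": w + 1, "pct_useful": v})
        return pd.DataFrame(rows)

    def test_constant_fraction_has_zero_slope(self):
        res = useful_fraction_trend(self._weekly({"PI": [50.0] * 6}))
        assert res["PI"].value == pytest.approx(0.0, abs=1e-12)

    def test_exact_line_recovered(self):
        weeks = np.arange(1, 25)
        res = useful_fraction_trend(self._weekly({"Si": list(80.0 - 2.0 * weeks)}))
        assert res["Si"].value == pytest.approx(-2.0, rel=1e-9)

    def test_too_few_time_points_rejected(self):
        with pytest.raises(ValueError):
            useful_fraction_trend(self._weekly({"PI": [50.0, 40.0]}))


class TestPairedTtest:
    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(11)
        a, b = rng.normal(size=12), rng.normal(size=12)
        res = paired_ttest(a, b)
        t, p = sps.ttest_rel(a, b)
        assert res.value == pytest.approx(t) and res.p_raw == pytest.approx(p)

    def test_identical_samples_are_null(self):
        a = np.arange(5.0)
        res = paired_ttest(a, a)
        assert res.value == 0.0 and res.p_raw == 1.0
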