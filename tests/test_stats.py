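"""Case aggregation, Grubbs, rank tests, ANOVA and adjustments."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from cordleak.stats import (aggregate_case, grubbs_critical, grubbs_outlier,
                            mann_whitney, pearson_linreg, sidak_adjust,
                            tukey_levels, two_way_anova, welch_t)
from oracles import grubbs_reference, mann_whitney_exact


class TestAggregateCase:
    def test_mean_and_bookkeeping(self):
        out = aggregate_case([1.0, 2.0, 6.0], case="c1", group="ALS",
                             level="thoracic")
        assert out.value == pytest.approx(3.0)
        assert out.n_sections == 3
        assert (out.case, out.group, out.level) == ("c1", "ALS", "thoracic")

    def test_order_invariant_and_nan_dropped(self):
        a = aggregate_case([3.0, float("nan"), 1.0])
        b = aggregate_case([1.0, 3.0])
        assert a.value == b.value and a.n_sections == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            aggregate_case([float("nan")])


class TestGrubbs:
    def test_matches_reference_formula(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            x = rng.normal(0, 1, size=rng.integers(4, 12))
            g, crit, idx = grubbs_reference(x, 0.2)
            expected = idx if g > crit else None
            assert grubbs_outlier(x, alpha=0.2) == expected

    def test_obvious_outlier_flagged(self):
        assert grubbs_outlier([10.0, 10.0, 10.0, 10.0, 100.0]) == 4

    def test_critical_value_example(self):
        # published two-sided critical value for n=10, alpha=0.05 is 2.290
        assert grubbs_critical(10, 0.05) == pytest.approx(2.290, abs=0.001)

    def test_all_equal_returns_none(self):
        assert grubbs_outlier([5.0, 5.0, 5.0, 5.0]) is None

    def test_single_pass_never_iterates(self):
        # after removing the flagged value the remainder may flag again;
        # one call never does that
        x = [1.0, 1.1, 0.9, 1.0, 6.0, 3.0]
        idx = grubbs_outlier(x, alpha=0.2)
        assert idx == 4  # only the single most extreme value

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            grubbs_outlier([1.0, 2.0])

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 1000), st.floats(0.1, 10.0), st.floats(-50.0, 50.0))
    def test_affine_invariance(self, seed, scale, shift):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, size=8)
        assert grubbs_outlier(x) == grubbs_outlier(scale * x + shift)


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        # n=3 vs n=3, complete separation: two-sided exact p = 2/20 = 0.1
        res = mann_whitney([1.0, 2.0, 3.0], [10.0, 11.0, 12.0])
        assert res.method == "exact"
        assert res.pvalue == pytest.approx(0.1)

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n1, n2 = rng.integers(3, 6, size=2)
            pooled = rng.permutation(np.arange(1.0, n1 + n2 + 1))
            a, b = pooled[:n1], pooled[n1:]
            _, p_oracle = mann_whitney_exact(a, b)
            res = mann_whitney(a, b)
            assert res.pvalue == pytest.approx(p_oracle, abs=1e-12)

    def test_identical_samples_p_one(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.5, 2.5, 4.5])
        assert res.pvalue > 0.5

    def test_ties_force_asymptotic(self):
        res = mann_whitney([1.0, 2.0, 2.0], [2.0, 3.0, 4.0])
        assert res.method == "normal approximation"

    def test_large_samples_asymptotic(self):
        rng = np.random.default_rng(1)
        res = mann_whitney(rng.normal(0, 1, 30), rng.normal(2, 1, 30))
        assert res.method == "normal approximation"
        assert res.pvalue < 1e-6
        assert res.extra["direction"] == "a<b"


class TestWelchAndPearson:
    def test_welch_known_example(self):
        a = [27.5, 21.0, 19.0, 23.6, 17.0, 17.9, 16.9, 20.1, 21.9, 22.6]
        b = [27.1, 22.0, 20.8, 23.4, 23.4, 23.5, 25.8, 22.0, 24.8, 20.2]
        res = welch_t(a, b)
        sp = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(float(sp.statistic))
        assert res.pvalue == pytest.approx(float(sp.pvalue))
        assert res.extra["direction"] == "a<b"

    def test_welch_needs_two_per_group(self):
        with pytest.raises(ValueError):
            welch_t([1.0], [2.0, 3.0])

    def test_pearson_perfect_line(self):
        x = np.arange(10.0)
        res = pearson_linreg(x, 3.0 * x + 1.0)
        assert res.extra["r"] == pytest.approx(1.0)
        assert res.extra["slope"] == pytest.approx(3.0)
        assert res.extra["intercept"] == pytest.approx(1.0)

    def test_pearson_degenerate_x_rejected(self):
        with pytest.raises(ValueError):
            pearson_linreg([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])


class TestSidak:
    def test_identity_at_m_one(self):
        assert sidak_adjust(0.04, 1) == pytest.approx(0.04)

    def test_known_value(self):
        assert sidak_adjust(0.02, 3) == pytest.approx(1 - 0.98 ** 3)

    @settings(deadline=None, max_examples=40, derandomize=True)
    @given(st.floats(0.0, 1.0), st.integers(1, 10))
    def test_properties(self, p, m):
        adj = sidak_adjust(p, m)
        assert 0.0 <= adj <= 1.0
        assert adj >= p - 1e-12           # never less significant raw
        assert adj <= min(1.0, m * p + 1e-12)  # never exceeds Bonferroni

    def test_invalid_rejected(self):
        with pytest.raises(ValueError):
            sidak_adjust(1.5, 2)
        with pytest.raises(ValueError):
            sidak_adjust(0.5, 0)


def _table(rng, n_per_cell, group_delta=0.0, level_deltas=(0.0, 0.0, 0.0),
           sigma=1.0):
    rows = []
    for gi, grp in enumerate(("control", "ALS")):
        for li, lev in enumerate(("cervical", "thoracic", "lumbar")):
            mu = (gi - 0.5) * group_delta + level_deltas[li]
            for s in range(n_per_cell):
                rows.append({"group": grp, "level": lev, "subject": f"{grp}{s}",
                             "value": float(rng.normal(mu, sigma))})
    return pd.DataFrame(rows)


class TestTwoWayAnova:
    def test_zero_group_effect_constructed(self):
        # identical group means cell by cell: the group F is exactly 0
        base = _table(np.random.default_rng(5), n_per_cell=4)
        mirrored = base.copy()
        half = base[base.group == "control"].copy()
        half["group"] = "ALS"
        df = pd.concat([base[base.group == "control"], half], ignore_index=True)
        res = two_way_anova(df, posthoc="none")
        assert res.statistic == pytest.approx(0.0, abs=1e-10)
        assert res.pvalue == pytest.approx(1.0)

    def test_type3_equals_type1_when_balanced(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols
        df = _table(np.random.default_rng(7), n_per_cell=5, group_delta=1.0,
                    level_deltas=(0.0, 0.5, 1.0))
        res = two_way_anova(df, posthoc="none")
        m1 = ols("value ~ C(group) * C(level)", data=df).fit()
        t1 = sm.stats.anova_lm(m1, typ=1)
        assert res.statistic == pytest.approx(float(t1.loc["C(group)", "F"]),
                                              rel=1e-8)

    def test_power_calibrated_against_noncentral_f(self):
        # empirical rejection rate of the group main effect vs the
        # noncentral-F prediction, within 5 percentage points
        n, delta, sigma, alpha = 5, 1.2, 1.0, 0.05
        lam = 2 * 3 * n * (delta / 2) ** 2 / sigma ** 2
        df2 = 2 * 3 * n - 6
        fcrit = sps.f.ppf(1 - alpha, 1, df2)
        predicted = float(sps.ncf.sf(fcrit, 1, df2, lam))
        rng = np.random.default_rng(11)
        hits = sum(two_way_anova(_table(rng, n, group_delta=delta),
                                 posthoc="none").pvalue < alpha
                   for _ in range(500))
        assert hits / 500 == pytest.approx(predicted, abs=0.05)

    def test_sidak_posthoc_rows(self):
        df = _table(np.random.default_rng(2), 4, group_delta=2.0)
        res = two_way_anova(df, posthoc="sidak")
        assert len(res.posthoc) == 3
        assert (res.posthoc["p_adj"] >= res.posthoc["p_raw"] - 1e-12).all()

    def test_tukey_posthoc_rows(self):
        df = _table(np.random.default_rng(2), 4, level_deltas=(0, 1, 3))
        res = two_way_anova(df, posthoc="tukey")
        assert len(res.posthoc) == 6  # 3 pairs x 2 groups
        assert set(res.posthoc["group"]) == {"control", "ALS"}

    def test_tukey_levels_single_group(self):
        df = _table(np.random.default_rng(4), 6, level_deltas=(0, 0, 5))
        sub = df[df.group == "ALS"].drop(columns=["group"])
        post = tukey_levels(sub)
        assert len(post) == 3
        hit = post[post.comparison.str.contains("lumbar")]
        assert (hit["p_adj"] < 0.01).all()

    def test_rm_requires_complete_design(self):
        df = _table(np.random.default_rng(3), 4, group_delta=1.0)
        # subjects are nested in group here, so the both-within design
        # is incomplete and must be refused
        with pytest.raises(ValueError, match="complete"):
            two_way_anova(df, repeated="both")

    def test_rm_complete_design_runs(self):
        rng = np.random.default_rng(8)
        rows = []
        for subj in range(6):
            for grp in ("pre", "post"):
                for lev in ("cervical", "thoracic", "lumbar"):
                    rows.append({"subject": f"s{subj}", "group": grp,
                                 "level": lev,
                                 "value": float(rng.normal(2.0 if grp == "post"
                                                           else 0.0, 1.0))})
        res = two_way_anova(pd.DataFrame(rows), repeated="both",
                            posthoc="sidak")
        assert res.method == "AnovaRM"
        assert res.pvalue < 0.05
        assert len(res.posthoc) == 3

    def test_bad_posthoc_rejected(self):
        with pytest.raises(ValueError):
            two_way_anova(_table(np.random.default_rng(0), 3),
                          posthoc="bonferroni")
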