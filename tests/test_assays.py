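"""Pooled luciferase assay model, group statistics, survival curves."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cloneburden.assays import (
    compare_groups,
    pairwise_posthoc,
    pool_homogenates,
    pooling_variance_profile,
    survival_curve,
)
from cloneburden.laws import LogNormalLaw
from cloneburden.presets import get_preset
from cloneburden.synth import sample_luciferase

# Tie-corrected Kruskal-Wallis H computed by hand (rank sums with average
# ranks for the tied 2.4 pair, H / tie-correction factor) for the toy groups
# below: H = 5.400560224089634.
KW_TOY_GROUPS = {
    "a": [1.2, 2.4, 3.6],
    "b": [2.4, 4.8, 6.0],
    "c": [5.1, 7.3, 8.8],
}
KW_TOY_H = 5.400560224089634


class TestPoolHomogenates:
    def test_k1_is_identity(self):
        values = [3.0, 1.0, 4.0, 1.5]
        pools = pool_homogenates(values, 1)
        assert pools["activity"].tolist() == values
        assert (pools["pool_size"] == 1).all()

    def test_constant_activities_pool_to_same_value(self):
        pools = pool_homogenates([7.0] * 10, 5)
        assert (pools["activity"] == 7.0).all()

    def test_arithmetic_mean_pooling(self):
        pools = pool_homogenates([10.0, 20.0, 30.0, 40.0], 2)
        assert pools["activity"].tolist() == [15.0, 35.0]
        assert not pools["is_remainder"].any()

    def test_remainder_forms_flagged_smaller_pool(self):
        pools = pool_homogenates([1.0, 2.0, 3.0, 4.0, 5.0], 2)
        assert len(pools) == 3
        assert pools.iloc[-1]["pool_size"] == 1
        assert bool(pools.iloc[-1]["is_remainder"])

    def test_invalid_pool_size(self):
        with pytest.raises(ValueError):
            pool_homogenates([1.0, 2.0], 0)

    @given(
        values=st.lists(st.floats(0.1, 1e5), min_size=2, max_size=60),
        k=st.integers(1, 10),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_grand_mean_preserved_when_divisible(self, values, k):
        """Pooling preserves the grand mean exactly when n is divisible by k."""
        n = (len(values) // k) * k
        if n == 0:
            return
        values = values[:n]
        pools = pool_homogenates(values, k)
        assert pools["activity"].mean() == pytest.approx(np.mean(values), rel=1e-9)


class TestPoolingVarianceProfile:
    def test_degenerate_law_has_zero_variance(self):
        profile = pooling_variance_profile(LogNormalLaw(1000.0, 0.0), [1, 2, 5], 100, seed=0)
        assert (profile["variance"] == 0.0).all()

    def test_variance_scales_as_one_over_k(self):
        """Pool-reading variance matches Var(per-fly)/k within 3 MC SEs."""
        law = LogNormalLaw(median=1000.0, sigma=0.8)
        n = 10_000
        profile = pooling_variance_profile(law, [1, 2, 5, 10], n, seed=3)
        for row in profile.itertuples():
            k = row.pool_size
            expected_var = law.var() / k
            # SE of a sample variance from the fourth moment of pool means,
            # estimated by an independent replicate draw
            rng = np.random.default_rng(1234 + k)
            pools = law.sample(rng, n * k).reshape(n, k).mean(axis=1)
            m4 = np.mean((pools - pools.mean()) ** 4)
            se_var = np.sqrt((m4 - pools.var(ddof=1) ** 2) / n)
            assert abs(row.variance - expected_var) < 3 * se_var

    def test_means_flat_across_pool_sizes(self):
        law = LogNormalLaw(median=1000.0, sigma=0.8)
        n = 10_000
        profile = pooling_variance_profile(law, [1, 2, 5, 10], n, seed=4)
        for row in profile.itertuples():
            se = np.sqrt(row.variance / n)
            assert abs(row.mean - law.mean()) < 3 * se

    def test_variance_strictly_decreasing_in_k(self):
        law = LogNormalLaw(median=1000.0, sigma=0.8)
        profile = pooling_variance_profile(law, [1, 2, 5, 10], 10_000, seed=5)
        variances = profile["variance"].tolist()
        assert all(a > b for a, b in zip(variances, variances[1:]))

    def test_argument_errors(self):
        law = LogNormalLaw(1000.0, 0.5)
        with pytest.raises(ValueError):
            pooling_variance_profile(law, [], 100, seed=0)
        with pytest.raises(ValueError):
            pooling_variance_profile(law, [1, 2], 1, seed=0)


class TestCompareGroups:
    def test_identical_groups_have_zero_h(self):
        result = compare_groups({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert result.statistic == pytest.approx(0.0, abs=1e-12)

    def test_kruskal_matches_hand_rank_sum_oracle(self):
        result = compare_groups(KW_TOY_GROUPS, test="kruskal_wallis")
        assert result.statistic == pytest.approx(KW_TOY_H, rel=1e-12)

    def test_kruskal_invariant_under_monotone_transform(self):
        base = compare_groups(KW_TOY_GROUPS)
        logged = compare_groups({k: np.log(v) for k, v in KW_TOY_GROUPS.items()})
        assert base.statistic == pytest.approx(logged.statistic, rel=1e-12)

    def test_anova_invariant_under_affine_transform(self):
        base = compare_groups(KW_TOY_GROUPS, test="one_way_anova")
        shifted = compare_groups(
            {k: 3.0 * np.asarray(v) + 7.0 for k, v in KW_TOY_GROUPS.items()},
            test="one_way_anova",
        )
        assert base.statistic == pytest.approx(shifted.statistic, rel=1e-9)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0], "b": [2.0, 3.0]})
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 2.0]})

    def test_week3_pooled_screen_power(self):
        """3 pools of 10 flies separate control from tumour arms in >= 90%
        of simulated screens at p <= 0.05 (Kruskal-Wallis)."""
        control = get_preset("control")
        apcras = get_preset("apcras")
        hits = 0
        n_repeats = 1000
        for rep in range(n_repeats):
            c = pool_homogenates(sample_luciferase(control, 3, 30, seed=50_000 + rep), 10)
            a = pool_homogenates(sample_luciferase(apcras, 3, 30, seed=90_000 + rep), 10)
            result = compare_groups(
                {"control": c["activity"], "apcras": a["activity"]}
            )
            hits += result.pvalue <= 0.05
        assert hits / n_repeats >= 0.90

    def test_week2_readings_overlap(self):
        """At week 2 the arms give comparable readings (no reliable separation)."""
        control = sample_luciferase(get_preset("control"), 2, 5000, seed=1)
        apcras = sample_luciferase(get_preset("apcras"), 2, 5000, seed=2)
        # large overlap: >25% of tumour-arm readings below the control median
        assert (apcras < np.median(control)).mean() > 0.25


class TestPairwisePosthoc:
    def test_holm_adjustment_is_monotone(self):
        groups = {
            "a": [1.0, 2.0, 3.0, 4.0],
            "b": [10.0, 11.0, 12.0, 13.0],
            "c": [1.5, 2.5, 3.5, 4.5],
        }
        table = pairwise_posthoc(groups)
        assert len(table) == 3
        assert (table["p_adjusted"] >= table["pvalue"] - 1e-12).all()
        assert table["p_adjusted"].between(0, 1).all()


class TestSurvivalCurve:
    def test_no_deaths_stays_at_hundred(self):
        events = pd.DataFrame(
            {"condition": ["c"] * 80, "day": [21] * 80, "died": [False] * 80}
        )
        curve = survival_curve(events, n_days=21)
        assert (curve["percent_survival"] == 100.0).all()
        assert len(curve) == 22  # day 0..21

    def test_all_die_day_one(self):
        events = pd.DataFrame({"condition": ["c"] * 5, "day": [1] * 5, "died": [True] * 5})
        curve = survival_curve(events, n_days=3)
        assert curve.loc[curve["day"] == 0, "percent_survival"].item() == 100.0
        assert (curve.loc[curve["day"] >= 1, "percent_survival"] == 0.0).all()

    def test_hand_counted_cohort(self):
        """5 flies, deaths on days {3, 3, 10}, 2 censored at 21."""
        events = pd.DataFrame(
            {
                "condition": ["c"] * 5,
                "day": [3, 3, 10, 21, 21],
                "died": [True, True, True, False, False],
            }
        )
        curve = survival_curve(events, n_days=21).set_index("day")
        assert curve.loc[2, "percent_survival"] == 100.0
        assert curve.loc[3, "percent_survival"] == 60.0
        assert curve.loc[10, "percent_survival"] == 40.0
        assert curve.loc[21, "percent_survival"] == 40.0

    def test_matches_kaplan_meier_without_interval_censoring(self):
        """With censoring only at the final day the curve equals Kaplan-Meier."""
        lifelines = pytest.importorskip("lifelines")
        from cloneburden.synth import sample_survival

        events = sample_survival(get_preset("apcras"), 200, 21, seed=9)
        curve = survival_curve(events, n_days=21).set_index("day")
        km = lifelines.KaplanMeierFitter()
        km.fit(events["day"], events["died"])
        for day in (1, 5, 10, 21):
            expected = 100.0 * float(km.predict(day))
            assert curve.loc[day, "percent_survival"] == pytest.approx(expected, abs=1e-9)

    def test_death_day_outside_window_rejected(self):
        events = pd.DataFrame({"condition": ["c"] * 2, "day": [25, 3], "died": [True, True]})
        with pytest.raises(ValueError):
            survival_curve(events, n_days=21)

    @given(
        days=st.lists(st.integers(1, 21), min_size=2, max_size=40),
    )
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_monotone_non_increasing_and_bounded(self, days):
        events = pd.DataFrame(
            {"condition": ["c"] * len(days), "day": days, "died": [True] * len(days)}
        )
        curve = survival_curve(events, n_days=21)
        values = curve["percent_survival"].to_numpy()
        assert values[0] == 100.0
        assert np.all(np.diff(values) <= 0)
        assert np.all((values >= 0) & (values <= 100))
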