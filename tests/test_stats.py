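import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from nirsvot import stats as stx


class TestRemoveOutliers:
    def test_single_extreme_removed(self):
        # mean 0.909, SD 3.015 -> upper bound 6.94: only the 10 falls out
        kept, removed = stx.remove_outliers([0] * 10 + [10])
        assert list(removed) == [10]
        assert len(kept) == 10

    def test_borderline_value_kept(self):
        # mean 2.8, SD 4.02 -> upper bound 10.85: the 10 stays
        kept, removed = stx.remove_outliers([1, 1, 1, 1, 10])
        assert removed.size == 0

    def test_all_equal_values_kept(self):
        kept, removed = stx.remove_outliers([5.0] * 8)
        assert removed.size == 0

    def test_small_sample_passthrough_with_warning(self):
        with pytest.warns(UserWarning):
            kept, removed = stx.remove_outliers([1.0, 100.0])
        assert len(kept) == 2

    def test_single_pass_no_iteration(self):
        # after removing 100, the value 10 would fall outside the recomputed
        # bounds; a single pass must keep it
        data = [0, 0, 0, 0, 0, 0, 0, 0, 10, 100]
        kept, removed = stx.remove_outliers(data)
        assert 10 in kept
        assert list(removed) == [9]


class TestRouteTest:
    def test_normal_samples_take_parametric_route(self):
        # stochastic fixture: a typical Normal draw at n=200 passes both
        # assumption checks
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 200) for _ in range(3)]
        assert stx.route_test(groups).route == "parametric"

    def test_heavily_skewed_group_takes_nonparametric_route(self):
        rng = np.random.default_rng(1)
        groups = [rng.normal(0, 1, 200), rng.exponential(1, 200),
                  rng.normal(0, 1, 200)]
        assert stx.route_test(groups).route == "nonparametric"

    def test_constant_group_forces_nonparametric_with_warning(self):
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="zero-variance"):
            decision = stx.route_test([np.full(10, 3.0), rng.normal(0, 1, 10)])
        assert decision.route == "nonparametric"
        assert decision.warning == "zero_variance_group"


class TestOmnibus:
    def test_identical_groups_give_f_zero_p_one(self):
        F, p = stx.one_way_anova([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
        assert F == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_null_type_one_error_near_alpha(self):
        rng = np.random.default_rng(10)
        hits = sum(
            stx.one_way_anova([rng.normal(0, 1, 12) for _ in range(3)])[1] < 0.05
            for _ in range(400)
        )
        assert 0.02 < hits / 400 < 0.08

    def test_kruskal_detects_shift(self):
        rng = np.random.default_rng(3)
        H, p = stx.kruskal_wallis([rng.normal(0, 1, 30),
                                   rng.normal(3, 1, 30)])
        assert p < 1e-4


class TestMixedAnova:
    def _table(self, means, n=12, sd=1.0, session_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for g, mu in means.items():
            for i in range(n):
                sid = f"{g}_{i}"
                base = rng.normal(mu, sd)
                for s, shift in [("S1", 0.0), ("S2", session_shift)]:
                    rows.append((sid, g, s, base + shift + rng.normal(0, 0.3)))
        return pd.DataFrame(rows, columns=["subject_id", "group", "session",
                                           "value"])

    def test_strong_group_separation_detected(self):
        # programmed separation of three pooled SDs
        hits = 0
        for seed in range(40):
            df = self._table({"G1": 0.0, "G2": 3.0}, seed=seed)
            aov = stx.mixed_anova(df)
            p = float(aov.loc[aov.Source == "group", "p_unc"].iloc[0])
            hits += p < 0.001
        assert hits >= 38

    def test_session_effect_without_group_effect(self):
        df = self._table({"G1": 0.0, "G2": 0.0}, session_shift=1.0, seed=5)
        aov = stx.mixed_anova(df)
        p_group = float(aov.loc[aov.Source == "group", "p_unc"].iloc[0])
        p_sess = float(aov.loc[aov.Source == "session", "p_unc"].iloc[0])
        assert p_group > 0.05
        assert p_sess < 0.01

    def test_incomplete_subject_dropped(self):
        df = self._table({"G1": 0.0, "G2": 1.0}, seed=7)
        df = df.drop(df[(df.subject_id == "G1_0") & (df.session == "S2")].index)
        aov = stx.mixed_anova(df)  # should not raise
        assert "group" in set(aov.Source)

    def test_two_within_levels_report_trivial_sphericity(self):
        df = self._table({"G1": 0.0, "G2": 1.0}, seed=8)
        aov = stx.mixed_anova(df)
        assert (aov.sphericity == "trivial (2 within levels)").all()


class TestPairwiseBonferroni:
    def test_identical_groups_corrected_p_is_one(self):
        g = {"A": np.arange(10.0), "B": np.arange(10.0), "C": np.arange(10.0)}
        for r in stx.pairwise_bonferroni(g, "parametric"):
            assert r.p_corrected == 1.0

    def test_two_groups_have_correction_factor_one(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 15), rng.normal(1, 1, 15)
        res = stx.pairwise_bonferroni({"A": a, "B": b}, "parametric")
        assert len(res) == 1
        assert res[0].p_corrected == pytest.approx(min(1.0, res[0].p_raw))

    def test_only_separated_pair_significant(self):
        hits = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            g = {"G1": rng.normal(-3, 1, 12), "G2": rng.normal(0, 1, 12),
                 "G3": rng.normal(0, 1, 12)}
            res = {(r.group_a, r.group_b): r.p_corrected
                   for r in stx.pairwise_bonferroni(g, "parametric")}
            hits += (res[("G1", "G2")] < 0.05 and res[("G1", "G3")] < 0.05
                     and res[("G2", "G3")] >= 0.05)
        assert hits >= 54

    def test_corrected_p_monotone_and_capped(self):
        rng = np.random.default_rng(6)
        g = {k: rng.normal(i * 0.5, 1, 10) for i, k in enumerate("ABCD")}
        res = stx.pairwise_bonferroni(g, "parametric")
        raw = [r.p_raw for r in res]
        corr = [r.p_corrected for r in res]
        order = np.argsort(raw)
        assert np.all(np.diff(np.array(corr)[order]) >= -1e-12)
        assert all(0 <= c <= 1 for c in corr)

    def test_nonparametric_route_uses_dunn_and_rank_biserial(self):
        rng = np.random.default_rng(8)
        g = {"G1": rng.exponential(1, 15), "G2": rng.exponential(1, 15) + 3,
             "G3": rng.exponential(1, 15)}
        res = stx.pairwise_bonferroni(g, "nonparametric")
        assert all(r.effect_kind == "rank_biserial" for r in res)
        assert all(abs(r.effect_size) <= 1 for r in res)


class TestEffectSizes:
    def test_cohen_d_sign_convention(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(0, 1, 500), rng.normal(1, 1, 500)
        assert stx.cohen_d(a, b) == pytest.approx(-1.0, abs=0.15)

    def test_cohen_d_identical_samples(self):
        x = np.arange(10.0)
        assert stx.cohen_d(x, x) == 0.0

    def test_cohen_d_hand_computed_pooled_sd(self):
        # pooled SD = sqrt(((3*(1/3)+3*(1/3))/6) = 0.577; (0.5-2.5)/0.577
        d = stx.cohen_d([0, 0, 1, 1], [2, 2, 3, 3])
        assert d == pytest.approx(-2.0 / math.sqrt(1.0 / 3.0), rel=1e-12)

    def test_cohen_d_zero_pooled_sd_flagged_nan(self):
        assert math.isnan(stx.cohen_d([1, 1], [1, 1]))

    def test_magnitude_labels(self):
        assert stx.d_magnitude(0.1) == "negligible"
        assert stx.d_magnitude(-0.3) == "small"
        assert stx.d_magnitude(0.6) == "medium"
        assert stx.d_magnitude(-2.5) == "large"

    def test_rank_biserial_complete_separation(self):
        assert stx.rank_biserial([1, 2, 3], [4, 5, 6]) == -1.0
        assert stx.rank_biserial([4, 5, 6], [1, 2, 3]) == 1.0

    def test_rank_biserial_interleaved_is_zero(self):
        # dominance: a wins 6 of 16 pairs, loses 10 -> (6-10)/16
        assert stx.rank_biserial([1, 3, 5, 7], [2, 4, 6, 8]) == pytest.approx(-0.25)
        assert stx.rank_biserial([1, 4], [2, 3]) == 0.0

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=8),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=8),
    )
    def test_rank_biserial_equals_dominance_enumeration(self, a, b):
        gt = sum(x > y for x in a for y in b)
        lt = sum(x < y for x in a for y in b)
        expected = (gt - lt) / (len(a) * len(b))
        assert stx.rank_biserial(a, b) == pytest.approx(expected, abs=1e-12)


class TestCompareGroups:
    def test_full_route_on_separated_cohort(self):
        rng = np.random.default_rng(12)
        g = {"G1": rng.normal(-5, 1, 12), "G2": rng.normal(0, 1, 12),
             "G3": rng.normal(0, 1, 12)}
        res = stx.compare_groups(g, parameter="tsi_auc", session="S1")
        assert res.omnibus_p < 0.001
        pw = {(r.group_a, r.group_b): r for r in res.pairwise}
        assert pw[("G1", "G2")].p_corrected < 0.05
        assert pw[("G2", "G3")].p_corrected > 0.05

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stx.compare_groups({"G1": np.arange(5.0)})
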