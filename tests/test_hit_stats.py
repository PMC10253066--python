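"""SSMD, Dunnett many-to-one test, hit classes, replication logic."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from nsepscreen.quantify import VariantPooled
from nsepscreen.stats import (
    VariantStats,
    classify_hits,
    combine_metric_calls,
    dunnett,
    dunnett_test,
    replication_concordance,
    screen_summary,
    ssmd,
)


def vp(mean, sem2, variant="KO1", metric="mean", n=3, values=()):
    return VariantPooled(
        variant=variant, metric=metric, mean=mean, sem2=sem2, n=n,
        values=tuple(values),
    )


def vs(variant, ssmd_value, p_adj, delta=None, metric="mean", hit_class="none"):
    if delta is None:
        delta = 100.0 + 20.0 * ssmd_value
    return VariantStats(
        variant=variant, metric=metric, delta_f_mean=delta, sem2=25.0, n=3,
        ssmd=ssmd_value, dunnett_t=ssmd_value, dunnett_p_adj=p_adj,
        hit_class=hit_class,
    )


class TestSSMD:
    def test_null_case_is_zero(self):
        assert ssmd(vp(100.0, 400.0), vp(100.0, 100.0)) == 0.0

    def test_direct_evaluation(self):
        value = ssmd(vp(140.0, 400.0), vp(100.0, 100.0))
        assert value == pytest.approx(40.0 / np.sqrt(500.0), abs=1e-12)

    def test_zero_variance_cases(self):
        assert ssmd(vp(100.0, 0.0), vp(100.0, 0.0)) == 0.0
        assert ssmd(vp(120.0, 0.0), vp(100.0, 0.0)) == np.inf
        assert ssmd(vp(80.0, 0.0), vp(100.0, 0.0)) == -np.inf

    @given(
        st.floats(min_value=-100, max_value=100),
        st.floats(min_value=0, max_value=1e4),
        st.floats(min_value=0.01, max_value=1e4),
    )
    def test_antisymmetry(self, diff, s2a, s2b):
        a, b = vp(100.0 + diff, s2a), vp(100.0, s2b)
        assert ssmd(a, b) == -ssmd(b, a)


class TestDunnett:
    def test_single_comparison_reduces_to_student_t(self, rng):
        g = rng.normal(110, 10, 4)
        c = rng.normal(100, 10, 6)
        res = dunnett_test([g], c)
        student = sps.ttest_ind(g, c, equal_var=True)
        assert res.statistic[0] == pytest.approx(student.statistic, abs=1e-10)
        assert res.pvalue[0] == pytest.approx(student.pvalue, abs=1e-8)

    def test_matches_scipy_reference(self, rng):
        """Independent cross-check against scipy's QMC-based Dunnett."""
        groups = [rng.normal(100, 12, 3) for _ in range(8)]
        control = rng.normal(100, 12, 9)
        ours = dunnett_test(groups, control)
        ref = sps.dunnett(*groups, control=control)
        np.testing.assert_allclose(ours.statistic, ref.statistic, atol=1e-10)
        np.testing.assert_allclose(ours.pvalue, ref.pvalue, atol=2e-3)

    def test_equal_means_give_t_zero_p_one(self):
        groups = [np.array([99.0, 100.0, 101.0]) + 0 for _ in range(5)]
        control = np.array([99.0, 100.0, 101.0])
        res = dunnett_test(groups, control)
        np.testing.assert_allclose(res.statistic, 0.0, atol=1e-12)
        np.testing.assert_allclose(res.pvalue, 1.0, atol=1e-9)

    def test_adjustment_only_inflates_p(self, rng):
        groups = [rng.normal(100 + 5 * k, 10, 3) for k in range(6)]
        control = rng.normal(100, 10, 6)
        res = dunnett_test(groups, control)
        nu, s2p = res.df, None
        # unadjusted p from the same pooled-variance t statistic
        unadj = 2 * sps.t.sf(np.abs(res.statistic), res.df)
        assert np.all(res.pvalue >= unadj - 1e-12)

    def test_family_size_inflates_p(self, rng):
        g = rng.normal(115, 10, 3)
        control = rng.normal(100, 10, 9)
        others = [rng.normal(100, 10, 3) for _ in range(18)]
        p_alone = dunnett_test([g], control).pvalue[0]
        p_family = dunnett_test([g] + others, control).pvalue[0]
        assert p_family > p_alone

    def test_input_validation(self):
        with pytest.raises(ValueError):
            dunnett_test([], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dunnett_test([np.array([1.0])], np.array([1.0, 2.0]))
        with pytest.raises(ValueError):
            dunnett_test([np.array([1.0, 2.0])], np.array([1.0]))

    def test_pooled_wrapper_uses_replicate_values(self, rng):
        values = [rng.normal(120, 8, 4) for _ in range(3)]
        kos = [
            vp(np.mean(v), np.var(v, ddof=1) / 4, variant=f"K{i}", n=4, values=v)
            for i, v in enumerate(values)
        ]
        scr = rng.normal(100, 8, 8)
        pairs = dunnett(kos, scr)
        ref = dunnett_test(values, scr)
        for (t, p), rt, rp in zip(pairs, ref.statistic, ref.pvalue):
            assert t == pytest.approx(rt) and p == pytest.approx(rp)


class TestClassification:
    @pytest.mark.parametrize(
        "ssmd_value, p_adj, expected",
        [
            (1.5, 0.01, "up_hit"),
            (1.5, 0.2, "possible_up"),
            (-1.2, 0.03, "down_hit"),
            (-1.1, 0.5, "possible_down"),
            (0.8, 0.001, "none"),  # significant but weak effect: not a hit
            (1.2, 0.05, "possible_up"),  # p exactly at alpha is not < alpha
            (0.0, 1.0, "none"),
        ],
    )
    def test_dual_criterion(self, ssmd_value, p_adj, expected):
        [out] = classify_hits([vs("KO1", ssmd_value, p_adj)])
        assert out.hit_class == expected

    def test_either_metric_qualifies_a_variant(self):
        stats = classify_hits(
            [
                vs("KO1", 0.5, 0.9, metric="mean"),
                vs("KO1", 1.3, 0.4, metric="median"),
                vs("KO2", 0.2, 0.9, metric="mean"),
                vs("KO2", 0.1, 0.8, metric="median"),
            ]
        )
        calls = combine_metric_calls(stats)
        assert calls["KO1"] == "possible_up"
        assert calls["KO2"] == "none"


class TestReplicationConcordance:
    def _series(self, *records):
        return [vs(*r[:-1], hit_class=r[-1]) for r in records]

    def test_hit_confirmed_by_strong_same_direction_ssmd(self):
        s1 = self._series(("KO1", 1.8, 0.01, 135.0, "up_hit"))
        s2 = self._series(("KO1", 1.1, 0.3, 118.0, "possible_up"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "up_hit"

    def test_hit_confirmed_by_delta_margin(self):
        s1 = self._series(("KO1", 1.8, 0.01, 140.0, "up_hit"))
        s2 = self._series(("KO1", 0.7, 0.5, 124.0, "none"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "up_hit"

    def test_opposite_direction_demotes(self):
        s1 = self._series(("KO1", 1.8, 0.01, 140.0, "up_hit"))
        s2 = self._series(("KO1", -0.9, 0.6, 91.0, "none"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "none"

    def test_significant_in_both_series(self):
        s1 = self._series(("KO1", 1.6, 0.02, 132.0, "up_hit"))
        s2 = self._series(("KO1", 1.4, 0.04, 128.0, "up_hit"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "up_hit"

    def test_significant_but_conflicting_directions(self):
        s1 = self._series(("KO1", 1.6, 0.02, 132.0, "up_hit"))
        s2 = self._series(("KO1", -1.6, 0.02, 70.0, "down_hit"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "none"

    def test_missing_variant_reported_untested(self):
        s1 = self._series(("KO1", 1.6, 0.02, 132.0, "up_hit"))
        out = replication_concordance(s1, []).set_index("variant")
        assert out.loc["KO1", "final"] == "untested"

    def test_down_direction_with_margin(self):
        s1 = self._series(("KO1", -1.7, 0.03, 72.0, "down_hit"))
        s2 = self._series(("KO1", -0.8, 0.4, 78.0, "none"))
        out = replication_concordance(s1, s2).set_index("variant")
        assert out.loc["KO1", "final"] == "down_hit"


class TestScreenSummary:
    def test_all_at_100_gives_zero_counts(self):
        pooled = [vp(100.0, 10.0, variant=f"K{i}") for i in range(5)]
        stats = [vs(f"K{i}", 0.0, 1.0, delta=100.0) for i in range(5)]
        summary = screen_summary(pooled, stats)
        assert all(v == 0 for v in summary.counts["mean"].values())

    def test_threshold_counting(self):
        values = [85.0, 95.0, 115.0, 125.0]
        pooled = [vp(x, 10.0, variant=f"K{i}") for i, x in enumerate(values)]
        stats = [vs(f"K{i}", 0.0, 1.0, delta=x) for i, x in enumerate(values)]
        counts = screen_summary(pooled, stats).counts["mean"]
        assert counts["above_110"] == 2
        assert counts["above_120"] == 1
        assert counts["below_90"] == 1
        assert counts["below_80"] == 0

    def test_infinite_ssmd_excluded_from_threshold_counts(self):
        pooled = [vp(130.0, 0.0, variant="K0", n=3)]
        stats = [vs("K0", np.inf, 0.0, delta=130.0)]
        counts = screen_summary(pooled, stats).counts["mean"]
        assert counts["ssmd_gt_1"] == 0 and counts["sig_up"] == 0
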