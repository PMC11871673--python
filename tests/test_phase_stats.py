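import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from teamsync.phase_stats import (
    bh_adjust,
    classify_effect,
    compare_phases,
    rank_biserial,
    wilcoxon_signed_rank,
)
from teamsync.types import ValidationError


def enumeration_p(d):
    """Two-sided signed-rank p by explicit enumeration of all sign assignments."""
    d = np.asarray(d, float)
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.sum([r for r, s in zip(ranks, signs) if s]) for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.asarray(ws)
    n = ws.size
    p_low = np.sum(ws <= w_obs + 1e-9) / n
    p_high = np.sum(ws >= w_obs - 1e-9) / n
    return min(1.0, 2.0 * min(p_low, p_high))


class TestWilcoxonSignedRank:
    def test_reference_example(self):
        res = wilcoxon_signed_rank([5.0, 3.0, -1.0, 2.0], [0.0, 0.0, 0.0, 0.0])
        assert res.w_plus == 9.0
        assert res.p == pytest.approx(0.25)
        assert res.method == "exact"

    def test_six_same_sign_differences(self):
        res = wilcoxon_signed_rank(np.arange(1.0, 7.0), np.zeros(6))
        assert res.p == pytest.approx(2.0 / 64.0)

    def test_identical_samples_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.method == "degenerate"
        assert res.p == 1.0 and res.w_plus == 0.0

    def test_missing_pairs_deleted(self):
        res = wilcoxon_signed_rank([5.0, np.nan, 3.0, -1.0, 2.0], [0.0, 1.0, 0.0, 0.0, 0.0])
        assert res.n == 4 and res.p == pytest.approx(0.25)

    @settings(max_examples=80, deadline=None)
    @given(d=st.lists(st.integers(min_value=-5, max_value=5), min_size=1, max_size=8))
    def test_exact_p_matches_full_enumeration(self, d):
        """Exact DP distribution agrees with brute-force sign enumeration, ties included."""
        if not any(x != 0 for x in d):
            return
        res = wilcoxon_signed_rank(np.asarray(d, float), np.zeros(len(d)))
        assert res.p == pytest.approx(enumeration_p(d))

    def test_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(2)
        from scipy.stats import wilcoxon as scipy_wilcoxon

        for _ in range(20):
            d = rng.normal(size=12)
            res = wilcoxon_signed_rank(d, np.zeros(12))
            ref = scipy_wilcoxon(d, mode="exact")
            assert res.p == pytest.approx(ref.pvalue)

    def test_normal_approximation_close_to_exact_at_n25(self):
        rng = np.random.default_rng(3)
        from teamsync.phase_stats import _approx_two_sided_p, _exact_two_sided_p

        for _ in range(10):
            d = rng.normal(scale=1.0, size=25)
            d = d[d != 0]
            ranks = rankdata(np.abs(d))
            w_plus = ranks[d > 0].sum()
            p_exact = _exact_two_sided_p(ranks, w_plus)
            p_approx = _approx_two_sided_p(ranks, w_plus, d)
            assert abs(p_exact - p_approx) < 0.01


class TestBenjaminiHochberg:
    def test_reference_example(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.04, 0.03]), [0.03, 0.04, 0.04])

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(bh_adjust([0.07, 0.07, 0.07]), [0.07, 0.07, 0.07])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.1, 1.4])

    @settings(max_examples=50, deadline=None)
    @given(p=st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=12))
    def test_monotone_and_order_preserving(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        # order statistics preserved: sorting inputs sorts outputs identically
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)


class TestRankBiserial:
    def test_reference_example(self):
        assert rank_biserial([5.0, 3.0, -1.0, 2.0], np.zeros(4)) == pytest.approx(0.8)

    def test_all_positive_is_one(self):
        assert rank_biserial([1.0, 2.0, 3.0], np.zeros(3)) == pytest.approx(1.0)

    def test_balanced_ranks_zero(self):
        # ranks {1,4,6,7} positive vs {2,3,5,8} negative: W+ = W- = 18
        d = [1.0, -2.0, -3.0, 4.0, -5.0, 6.0, 7.0, -8.0]
        assert rank_biserial(d, np.zeros(8)) == pytest.approx(0.0)

    def test_all_zero_differences_undefined(self):
        assert np.isnan(rank_biserial([1.0, 1.0], [1.0, 1.0]))


class TestClassifyEffect:
    @pytest.mark.parametrize("r, label", [
        (0.05, "negligible"), (-0.05, "negligible"),
        (0.1, "small"), (0.29, "small"),
        (0.3, "moderate"), (-0.45, "moderate"),
        (0.5, "large"), (0.8, "large"), (-1.0, "large"),
    ])
    def test_cohen_boundaries_lower_inclusive(self, r, label):
        assert classify_effect(r) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            classify_effect(1.2)


def _phase_avg_frame(rng, n_dyads, shift):
    """Phase-average table where 'street'/'tunnel' dtw sits `shift` below baseline."""
    rows = []
    for i in range(n_dyads):
        base = 5.0 + rng.normal(scale=0.5)
        for phase, delta in [("baseline", 0.0), ("pre_street", -shift / 2), ("pre_tunnel", -shift / 2),
                             ("street", -shift), ("tunnel", -shift)]:
            rows.append(("t" + str(i % 4), f"d{i}", "HR", 5, phase, base + delta + rng.normal(scale=0.05), 10))
    return pd.DataFrame(rows, columns=["team_id", "dyad", "metric", "delta_s", "phase",
                                       "mean_dtw_per_second", "n_intervals"])


class TestComparePhases:
    def test_lower_dtw_reported_as_higher_synchrony(self):
        rng = np.random.default_rng(1)
        table = _phase_avg_frame(rng, 12, shift=1.0)
        comps = compare_phases(table, [("baseline", "scenario"), ("baseline", "pre")])
        by_pair = {(c.phase_a, c.phase_b): c for c in comps}
        c = by_pair[("baseline", "scenario")]
        assert c.significant and c.r_rb > 0 and c.higher_ps_phase == "scenario"
        assert c.magnitude == "large"
        assert len(comps) == 2  # BH family of m = 2 within the metric

    def test_identical_phases_not_significant(self):
        rng = np.random.default_rng(2)
        table = _phase_avg_frame(rng, 12, shift=0.0)
        comps = compare_phases(table, [("baseline", "scenario")])
        assert not comps[0].significant
        assert abs(comps[0].r_rb) < 0.6

    def test_too_few_pairs_skipped(self, caplog):
        rng = np.random.default_rng(3)
        table = _phase_avg_frame(rng, 2, shift=1.0)
        comps = compare_phases(table, [("baseline", "scenario")])
        assert comps == []
        assert any("complete pairs" in r.message for r in caplog.records)

    def test_adjusted_p_not_below_raw(self):
        rng = np.random.default_rng(4)
        table = _phase_avg_frame(rng, 10, shift=0.3)
        for c in compare_phases(table, [("baseline", "pre"), ("baseline", "scenario"), ("pre", "scenario")]):
            assert c.p_adj >= c.p_raw - 1e-12
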