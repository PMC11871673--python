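import functools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from teamsync.dtw import (
    dtw_distance,
    dtw_path_length,
    dtw_per_second,
    dyad_sync_series,
    phase_average,
)
from teamsync.hrv import metric_series
from teamsync.types import (
    BeatSeries,
    MetricSeries,
    PhaseSpan,
    SyncRecord,
    ValidationError,
    enumerate_dyads,
    Dyad,
)


def brute_force_dtw(a, b):
    """Reference DTW by memoised recursion over all monotone warping paths."""

    @functools.lru_cache(maxsize=None)
    def rec(i, j):
        cost = abs(a[i] - b[j])
        if i == 0 and j == 0:
            return cost
        best = np.inf
        if i > 0 and j > 0:
            best = min(best, rec(i - 1, j - 1))
        if i > 0:
            best = min(best, rec(i - 1, j))
        if j > 0:
            best = min(best, rec(i, j - 1))
        return cost + best

    return rec(len(a) - 1, len(b) - 1)


class TestDtwDistance:
    def test_identical_sequences_cost_zero(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=20)
        assert dtw_distance(x, x) == 0.0

    def test_small_grid_example(self):
        assert dtw_distance([1, 2, 3], [2, 3, 4]) == pytest.approx(2.0)

    def test_single_cell_grid(self):
        assert dtw_distance([0.0], [5.0]) == pytest.approx(5.0)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            dtw_distance([], [1.0])

    def test_non_finite_rejected(self):
        with pytest.raises(ValidationError):
            dtw_distance([1.0, np.nan], [1.0, 2.0])

    @settings(max_examples=200, deadline=None)
    @given(
        a=st.lists(st.integers(min_value=-9, max_value=9), min_size=1, max_size=6),
        b=st.lists(st.integers(min_value=-9, max_value=9), min_size=1, max_size=6),
    )
    def test_matches_brute_force_oracle(self, a, b):
        assert dtw_distance(a, b) == pytest.approx(brute_force_dtw(tuple(a), tuple(b)))

    @settings(max_examples=100, deadline=None)
    @given(
        a=st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=12),
        b=st.lists(st.floats(min_value=-50, max_value=50), min_size=1, max_size=12),
    )
    def test_symmetry_and_nonnegativity(self, a, b):
        d = dtw_distance(a, b)
        assert d >= 0.0
        assert d == pytest.approx(dtw_distance(b, a))

    @settings(max_examples=100, deadline=None)
    @given(
        pair=st.lists(
            st.tuples(st.floats(min_value=-50, max_value=50), st.floats(min_value=-50, max_value=50)),
            min_size=1, max_size=15,
        )
    )
    def test_diagonal_path_is_upper_bound(self, pair):
        a = [p[0] for p in pair]
        b = [p[1] for p in pair]
        assert dtw_distance(a, b) <= sum(abs(x - y) for x, y in zip(a, b)) + 1e-9


class TestDtwPerSecond:
    def test_identical_windows_zero(self):
        assert dtw_per_second([1.0] * 5, [1.0] * 5, 5) == 0.0

    def test_seconds_normalisation(self):
        assert dtw_per_second([1, 2, 3], [2, 3, 4], 3) == pytest.approx(2.0 / 3.0)

    def test_path_normalisation_divides_by_path_length(self):
        a, b = [1, 2, 3], [2, 3, 4]
        assert dtw_per_second(a, b, 3, normalize="path") == pytest.approx(2.0 / dtw_path_length(a, b))

    def test_amplitude_homogeneity(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=10), rng.normal(size=10)
        assert dtw_per_second(2 * a, 2 * b, 10) == pytest.approx(2 * dtw_per_second(a, b, 10))


class TestDyadEnumeration:
    @pytest.mark.parametrize("n, expected", [(4, 6), (3, 3), (1, 0)])
    def test_pair_counts(self, n, expected):
        members = [f"p{i}" for i in range(n)]
        assert len(enumerate_dyads(members)) == expected

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValidationError):
            enumerate_dyads(["a", "a", "b"])

    def test_canonical_ordering(self):
        dyads = enumerate_dyads(["c", "a", "b"])
        assert all(d.member_a < d.member_b for d in dyads)


def _series(values, valid=None, pid="p", metric="HR", t0=0):
    values = np.asarray(values, dtype=float)
    valid = np.ones(values.size, bool) if valid is None else np.asarray(valid, bool)
    vals = values.copy()
    vals[~valid] = np.nan
    return MetricSeries(pid, metric, np.arange(t0, t0 + values.size), vals, valid)


class TestDyadSyncSeries:
    def test_scenario_tiling_counts(self, scenario_span):
        a = _series(np.full(480, 60.0), pid="a")
        b = _series(np.full(480, 60.0), pid="b")
        recs = dyad_sync_series(a, b, [scenario_span], 5)
        assert len(recs) == 96
        assert all(r.dtw_per_second == 0.0 for r in recs)

    def test_trailing_remainder_dropped(self):
        span = PhaseSpan("baseline", 0.0, 130.0)
        a = _series(np.full(130, 60.0), pid="a")
        b = _series(np.full(130, 62.0), pid="b")
        recs = dyad_sync_series(a, b, [span], 60)
        assert len(recs) == 2
        assert [r.interval_start_s for r in recs] == [0.0, 60.0]

    def test_delta_below_minimum_rejected(self, scenario_span):
        a = _series(np.full(480, 60.0), pid="a")
        with pytest.raises(ValidationError, match=">= 5"):
            dyad_sync_series(a, a, [scenario_span], 4)

    def test_delta_longer_than_phase_warns_no_records(self, caplog):
        span = PhaseSpan("baseline", 0.0, 100.0)
        a = _series(np.full(100, 60.0), pid="a")
        b = _series(np.full(100, 60.0), pid="b")
        assert dyad_sync_series(a, b, [span], 120) == []
        assert any("shorter than delta" in r.message for r in caplog.records)

    def test_joint_masking_and_coverage(self):
        span = PhaseSpan("baseline", 0.0, 10.0)
        ok = np.ones(10, bool)
        half = ok.copy(); half[:3] = False  # 2/5 valid in first interval
        a = _series(np.arange(10.0), valid=half, pid="a")
        b = _series(np.arange(10.0), pid="b")
        recs = dyad_sync_series(a, b, [span], 5)
        assert not recs[0].is_valid and recs[0].n_valid == 2
        assert recs[1].is_valid and recs[1].n_valid == 5

    def test_interval_value_matches_direct_dtw(self, beats_from_nn):
        rng = np.random.default_rng(7)
        nn = rng.uniform(700.0, 900.0, 700)
        beats_a = BeatSeries("a", np.concatenate(([0], np.cumsum(nn))))
        nn2 = rng.uniform(700.0, 900.0, 700)
        beats_b = BeatSeries("b", np.concatenate(([0], np.cumsum(nn2))))
        span = PhaseSpan("street", 100.0, 200.0, order=1)
        sa = metric_series(beats_a, "HR", (0.0, 250.0))
        sb = metric_series(beats_b, "HR", (0.0, 250.0))
        recs = dyad_sync_series(sa, sb, [span], 10)
        k = 3
        seg = slice(100 + 10 * k, 100 + 10 * (k + 1))
        expected = dtw_distance(sa.value[seg], sb.value[seg]) / 10.0
        assert recs[k].dtw_per_second == pytest.approx(expected)


class TestPhaseAverage:
    def _rec(self, value, k, phase="baseline"):
        return SyncRecord("t1", Dyad.of("a", "b", "t1"), "HR", phase, 5, k, 5.0 * k, value, 5)

    def test_mean_over_valid_intervals(self):
        out = phase_average([self._rec(0.2, 0), self._rec(0.4, 1)])
        assert out.loc[0, "mean_dtw_per_second"] == pytest.approx(0.3)
        assert out.loc[0, "n_intervals"] == 2

    def test_all_invalid_yields_missing(self):
        out = phase_average([self._rec(float("nan"), 0)])
        assert np.isnan(out.loc[0, "mean_dtw_per_second"])
        assert out.loc[0, "n_intervals"] == 0

    def test_single_record_is_its_own_mean(self):
        out = phase_average([self._rec(0.7, 0)])
        assert out.loc[0, "mean_dtw_per_second"] == pytest.approx(0.7)
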