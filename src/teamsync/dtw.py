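"""Dynamic-time-warping synchrony scoring for dyads.

Synchrony between two members' per-second metric series is the accumulated
DTW cost of aligning the two series within a sampling interval, divided by
the interval length in seconds ("dtw per second").  Lower values mean more
similar physiological patterns, i.e. higher synchrony.

The DTW variant is the simplest standard one: local cost |a_i - b_j| (L1, so
the score keeps the metric's units), symmetric unit-weight steps
{(1,1), (1,0), (0,1)}, no window constraint (sequences are at most 120
points).  An alternative normalisation by warping-path length is available
via ``normalize="path"``.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .types import (
    Dyad,
    MetricSeries,
    PhaseSpan,
    SyncRecord,
    ValidationError,
    enumerate_dyads,  # noqa: F401  (re-exported: dyad enumeration lives with the scorer)
    tile_span,
)

logger = logging.getLogger("teamsync")

MIN_DELTA_S = 5
COVERAGE_MIN_DEFAULT = 0.8


def _check_seq(x: np.ndarray, name: str) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size == 0:
        raise ValidationError(f"sequence {name} must be non-empty and one-dimensional")
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"sequence {name} contains non-finite values")
    return x


def dtw_distance(a, b) -> float:
    """Minimum accumulated |a_i - b_j| cost over monotone warping paths."""
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    n, m = a.size, b.size
    prev = np.empty(m)
    cur = np.empty(m)
    row0 = np.abs(a[0] - b)
    prev[:] = np.cumsum(row0)
    for i in range(1, n):
        cost = np.abs(a[i] - b)
        cur[0] = prev[0] + cost[0]
        for j in range(1, m):
            cur[j] = cost[j] + min(prev[j], prev[j - 1], cur[j - 1])
        prev, cur = cur, prev
    return float(prev[m - 1])


def dtw_path_length(a, b) -> int:
    """Number of steps (cells) on an optimal warping path (diagonal-preferring tie-break)."""
    a = _check_seq(a, "a")
    b = _check_seq(b, "b")
    n, m = a.size, b.size
    D = np.full((n + 1, m + 1), np.inf)
    D[0, 0] = 0.0
    for i in range(1, n + 1):
        cost = np.abs(a[i - 1] - b)
        for j in range(1, m + 1):
            D[i, j] = cost[j - 1] + min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
    i, j, steps = n, m, 1
    while (i, j) != (1, 1):
        moves = [(i - 1, j - 1), (i - 1, j), (i, j - 1)]
        i, j = min((mv for mv in moves if mv[0] >= 1 and mv[1] >= 1), key=lambda mv: D[mv])
        steps += 1
    return steps


def dtw_per_second(a, b, delta_s: float, *, normalize: str = "seconds") -> float:
    """DTW cost per second for one sampling interval.

    ``normalize="seconds"`` divides the accumulated cost by the interval
    length in seconds; ``"path"`` divides by the optimal warping-path length.
    """
    if normalize not in ("seconds", "path"):
        raise ValidationError(f"unknown normalization {normalize!r}")
    d = dtw_distance(a, b)
    if normalize == "path":
        return d / dtw_path_length(a, b)
    if delta_s <= 0:
        raise ValidationError("delta_s must be positive")
    return d / float(delta_s)


def dyad_sync_series(
    series_a: MetricSeries,
    series_b: MetricSeries,
    spans: list[PhaseSpan],
    delta_s: int,
    *,
    team_id: str = "",
    coverage_min: float = COVERAGE_MIN_DEFAULT,
    normalize: str = "seconds",
    standardize: bool = False,
) -> list[SyncRecord]:
    """Score one dyad over phase spans tiled into consecutive sampling intervals.

    Each phase is tiled with non-overlapping intervals of ``delta_s`` seconds
    anchored at the phase start (trailing remainder dropped).  Seconds where
    either member's metric is invalid are masked pairwise; an interval is
    scored only when the joint valid count reaches ``coverage_min * delta_s``,
    otherwise its record carries NaN.

    ``standardize=True`` z-scores each member's series (over the union of the
    spans, valid seconds only) before scoring, for cross-metric comparability.
    """
    if series_a.metric != series_b.metric:
        raise ValidationError("dyad series must share the metric")
    if delta_s < MIN_DELTA_S:
        raise ValidationError(f"delta_s must be >= {MIN_DELTA_S} s (too few samples for DTW below that)")
    dyad = Dyad.of(series_a.participant_id, series_b.participant_id, team_id)

    def grid_lookup(series: MetricSeries):
        t0 = int(series.t_s[0]) if series.t_s.size else 0
        return t0, series.value, series.valid

    a0, av, am = grid_lookup(series_a)
    b0, bv, bm = grid_lookup(series_b)

    if standardize:
        av, bv = av.copy(), bv.copy()
        for vals, msk in ((av, am), (bv, bm)):
            ok = vals[msk]
            if ok.size > 1 and np.std(ok) > 0:
                vals[msk] = (ok - np.mean(ok)) / np.std(ok)

    records: list[SyncRecord] = []
    for span in spans:
        tiles = tile_span(span, delta_s)
        if not tiles:
            logger.warning("phase %s shorter than delta_s=%d: no intervals", span.name, delta_s)
        for k, start in tiles:
            ts = np.arange(int(start), int(start) + delta_s)
            ia = ts - a0
            ib = ts - b0
            ok = (
                (ia >= 0) & (ia < av.size) & (ib >= 0) & (ib < bv.size)
            )
            ok[ok] &= am[ia[ok]] & bm[ib[ok]]
            n_valid = int(ok.sum())
            if n_valid >= coverage_min * delta_s:
                value = dtw_per_second(av[ia[ok]], bv[ib[ok]], delta_s, normalize=normalize)
            else:
                value = np.nan
            records.append(
                SyncRecord(team_id, dyad, series_a.metric, span.name,
                           int(delta_s), k, float(start), value, n_valid)
            )
    return records


def phase_average(records: list[SyncRecord]) -> pd.DataFrame:
    """Mean dtw/second per (team, dyad, metric, delta_s, phase) over valid intervals.

    Returns a tidy frame with the contributing-interval count; groups with no
    valid interval appear with NaN mean and n_intervals = 0.
    """
    if not records:
        return pd.DataFrame(columns=["team_id", "dyad", "metric", "delta_s", "phase", "mean_dtw_per_second", "n_intervals"])
    rows = [
        (r.team_id, r.dyad.label, r.metric, r.delta_s, r.phase, r.dtw_per_second)
        for r in records
    ]
    df = pd.DataFrame(rows, columns=["team_id", "dyad", "metric", "delta_s", "phase", "dtw_per_second"])
    out = (
        df.groupby(["team_id", "dyad", "metric", "delta_s", "phase"], sort=True)["dtw_per_second"]
        .agg(mean_dtw_per_second="mean", n_intervals="count")
        .reset_index()
    )
    empty = out["n_intervals"] == 0
    if empty.any():
        logger.warning("%d phase group(s) had no valid synchrony intervals", int(empty.sum()))
    return out
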