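"""Per-second cardiac metrics from beat series.

Heart rate (HR) uses a 30-s moving average; the ultra-short-term HRV indices
RMSSD and SDNN are computed over trailing 90-s windows.  All windows are
causal and half-open, (t - w, t], and an NN interval belongs to the window
that contains its *terminating* R peak.  Values are sampled on the 1-Hz
session grid.

A sample is valid only when the window does not extend before the start of
the recording (warm-up) and the NN intervals inside it cover at least
``coverage_min`` of the window width (dropout guard).  Passing
``coverage_min=0`` disables both guards and evaluates the raw formula on
whatever the window contains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .types import BeatSeries, MetricSeries, PhaseSpan, ValidationError, METRICS

logger = logging.getLogger("teamsync")

HR_WINDOW_S = 30.0
HRV_WINDOW_S = 90.0
COVERAGE_MIN_DEFAULT = 0.8
MIN_NN_FOR_HRV = 3


@dataclass(frozen=True)
class ArtifactFilter:
    """Optional NN-interval artefact filter (off by default).

    Drops NN intervals outside [nn_min_ms, nn_max_ms] or deviating more than
    ``max_rel_jump`` from the preceding interval.
    """

    nn_min_ms: float = 300.0
    nn_max_ms: float = 2000.0
    max_rel_jump: float = 0.2

    def mask(self, nn_ms: np.ndarray) -> np.ndarray:
        ok = (nn_ms >= self.nn_min_ms) & (nn_ms <= self.nn_max_ms)
        if nn_ms.size > 1:
            rel = np.abs(np.diff(nn_ms)) / nn_ms[:-1]
            ok[1:] &= rel <= self.max_rel_jump
        return ok


def window_nn(beats: BeatSeries, t_s: float, width_s: float) -> np.ndarray:
    """NN intervals whose terminating R peak lies in (t_s - width_s, t_s] (ms)."""
    if width_s <= 0:
        raise ValidationError("width_s must be positive")
    peaks = beats.peak_times_ms
    lo = np.searchsorted(peaks, (t_s - width_s) * 1000.0, side="right")
    hi = np.searchsorted(peaks, t_s * 1000.0, side="right")
    lo = max(lo, 1)  # the terminating peak needs a predecessor
    if hi <= lo:
        return np.empty(0)
    return beats.nn_ms[lo - 1:hi - 1]


#: NN intervals longer than this are treated as dropout gaps, not beats,
#: when judging window coverage
NN_PLAUSIBLE_MAX_MS = 2000.0


def _coverage_ok(nn: np.ndarray, width_s: float, coverage_min: float) -> bool:
    covered = nn[nn <= NN_PLAUSIBLE_MAX_MS].sum()
    return covered >= coverage_min * width_s * 1000.0


def _warmed_up(beats: BeatSeries, t_s: float, width_s: float) -> bool:
    return beats.n_beats > 0 and (t_s - width_s) * 1000.0 >= beats.peak_times_ms[0]


def hr_at(beats: BeatSeries, t_s: float, *, coverage_min: float = COVERAGE_MIN_DEFAULT) -> float:
    """Moving-average heart rate at t_s: 60000 / mean(NN over trailing 30 s), bpm.

    Defined as beats-per-minute over the window (reciprocal of the mean NN),
    not the mean of instantaneous rates.  NaN when the window extends before
    the recording or covers less than ``coverage_min`` of its width.
    """
    nn = window_nn(beats, t_s, HR_WINDOW_S)
    if nn.size == 0:
        return np.nan
    if coverage_min > 0 and (
        not _warmed_up(beats, t_s, HR_WINDOW_S) or not _coverage_ok(nn, HR_WINDOW_S, coverage_min)
    ):
        return np.nan
    return 60000.0 / float(np.mean(nn))


def rmssd_at(beats: BeatSeries, t_s: float, *, coverage_min: float = COVERAGE_MIN_DEFAULT) -> float:
    """RMSSD over the trailing 90-s window (ms): sqrt(mean squared successive NN differences)."""
    nn = window_nn(beats, t_s, HRV_WINDOW_S)
    if nn.size < MIN_NN_FOR_HRV:
        return np.nan
    if coverage_min > 0 and (
        not _warmed_up(beats, t_s, HRV_WINDOW_S) or not _coverage_ok(nn, HRV_WINDOW_S, coverage_min)
    ):
        return np.nan
    return float(np.sqrt(np.mean(np.diff(nn) ** 2)))


def sdnn_at(beats: BeatSeries, t_s: float, *, coverage_min: float = COVERAGE_MIN_DEFAULT) -> float:
    """SDNN over the trailing 90-s window (ms): sample SD (n-1 denominator) of NN intervals."""
    nn = window_nn(beats, t_s, HRV_WINDOW_S)
    if nn.size < MIN_NN_FOR_HRV:
        return np.nan
    if coverage_min > 0 and (
        not _warmed_up(beats, t_s, HRV_WINDOW_S) or not _coverage_ok(nn, HRV_WINDOW_S, coverage_min)
    ):
        return np.nan
    return float(np.std(nn, ddof=1))


_METRIC_FN = {"HR": hr_at, "RMSSD": rmssd_at, "SDNN": sdnn_at}
_METRIC_WINDOW = {"HR": HR_WINDOW_S, "RMSSD": HRV_WINDOW_S, "SDNN": HRV_WINDOW_S}


def metric_series(
    beats: BeatSeries,
    metric: str,
    span: PhaseSpan | tuple[float, float],
    *,
    coverage_min: float = COVERAGE_MIN_DEFAULT,
    artifact_filter: ArtifactFilter | None = None,
) -> MetricSeries:
    """Evaluate one metric on the 1-Hz grid over a span.

    Warm-up seconds (window reaching before the first beat) and low-coverage
    seconds are marked invalid.  A span entirely outside the data range yields
    an all-invalid series with a warning.
    """
    if metric not in METRICS:
        raise ValidationError(f"unknown metric {metric!r}; expected one of {METRICS}")
    if isinstance(span, PhaseSpan):
        start_s, end_s = span.start_s, span.end_s
    else:
        start_s, end_s = span
    t_grid = np.arange(int(np.ceil(start_s)), int(np.ceil(end_s)))

    if artifact_filter is not None and beats.n_beats > 1:
        keep = artifact_filter.mask(beats.nn_ms)
        # rebuild peak times from the retained intervals, preserving onset
        nn = beats.nn_ms[keep]
        peaks = np.concatenate(([beats.peak_times_ms[0]], beats.peak_times_ms[0] + np.cumsum(nn)))
        beats = BeatSeries(beats.participant_id, peaks)

    fn = _METRIC_FN[metric]
    values = np.array([fn(beats, float(t), coverage_min=coverage_min) for t in t_grid])
    valid = np.isfinite(values)
    if t_grid.size and not valid.any():
        logger.warning(
            "participant %s: %s series over [%s, %s) has no valid samples",
            beats.participant_id, metric, start_s, end_s,
        )
    return MetricSeries(beats.participant_id, metric, t_grid, values, valid)
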