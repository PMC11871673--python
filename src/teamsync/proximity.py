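"""Dyadic proximity from position trajectories.

Proximity is the Euclidean floor-plane distance between two team members,
resampled to the 1-Hz session grid by linear interpolation and averaged over
the same sampling-interval tiling used for synchrony, so proximity and
synchrony tables join one-to-one on (dyad, delta_s, interval_index).
Higher values indicate a larger distance between trainees.
"""

from __future__ import annotations

import logging

import numpy as np

from .types import (
    Dyad,
    PhaseSpan,
    ProximityRecord,
    TrajectorySeries,
    ValidationError,
    tile_span,
)

logger = logging.getLogger("teamsync")

COVERAGE_MIN_DEFAULT = 0.8


def resample_positions(traj: TrajectorySeries, t_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Linear interpolation of (x, y) onto t_grid; NaN outside the track's range."""
    t_grid = np.asarray(t_grid, dtype=float)
    x = np.interp(t_grid, traj.t_s, traj.x_m)
    y = np.interp(t_grid, traj.t_s, traj.y_m)
    outside = (t_grid < traj.t_s[0]) | (t_grid > traj.t_s[-1])
    x[outside] = np.nan
    y[outside] = np.nan
    return x, y


def pair_distance(at_s: float, traj_a: TrajectorySeries, traj_b: TrajectorySeries) -> float:
    """Euclidean distance (m) between two members at one timestamp.

    NaN when the timestamp falls outside either trajectory's range.
    """
    d = distance_series(traj_a, traj_b, np.array([at_s]))
    return float(d[0])


def distance_series(traj_a: TrajectorySeries, traj_b: TrajectorySeries, t_grid: np.ndarray) -> np.ndarray:
    xa, ya = resample_positions(traj_a, t_grid)
    xb, yb = resample_positions(traj_b, t_grid)
    return np.hypot(xa - xb, ya - yb)


def interval_mean_distance(
    traj_a: TrajectorySeries,
    traj_b: TrajectorySeries,
    spans: list[PhaseSpan],
    delta_s: int,
    *,
    team_id: str = "",
    coverage_min: float = COVERAGE_MIN_DEFAULT,
) -> list[ProximityRecord]:
    """Mean 1-Hz pair distance per sampling interval, tiled exactly as synchrony.

    An interval with fewer than ``coverage_min * delta_s`` overlapping samples
    is recorded as invalid (NaN mean).
    """
    if delta_s <= 0:
        raise ValidationError("delta_s must be positive")
    dyad = Dyad.of(traj_a.participant_id, traj_b.participant_id, team_id)
    records: list[ProximityRecord] = []
    for span in spans:
        for k, start in tile_span(span, delta_s):
            ts = np.arange(int(start), int(start) + delta_s, dtype=float)
            d = distance_series(traj_a, traj_b, ts)
            ok = np.isfinite(d)
            n = int(ok.sum())
            value = float(np.mean(d[ok])) if n >= coverage_min * delta_s else np.nan
            records.append(
                ProximityRecord(team_id, dyad, span.name, int(delta_s), k, float(start), value, n)
            )
    n_bad = sum(1 for r in records if not r.is_valid)
    if n_bad:
        logger.warning("dyad %s: %d proximity interval(s) invalid (insufficient overlap)", dyad.label, n_bad)
    return records
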