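"""Readers and writers for the pipeline's plain-text formats.

Inputs
------
* beats CSV         columns ``participant_id, peak_time_ms`` (one participant per file)
* positions CSV     columns ``participant_id, t_s, x_m, y_m`` (one participant per file)
* annotation YAML   session/team ids, roster, phase table
* events CSV        columns ``t_s, label``

Outputs are tidy CSVs with a stable, documented column order so that
write -> read round-trips losslessly.
"""

from __future__ import annotations

import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .types import (
    BeatSeries,
    Dyad,
    EventAnnotation,
    PhaseSpan,
    ProximityRecord,
    SessionAnnotation,
    SyncRecord,
    TrajectorySeries,
    ValidationError,
)

logger = logging.getLogger("teamsync")

SYNC_COLUMNS = [
    "team_id", "member_a", "member_b", "metric", "phase",
    "delta_s", "interval_index", "interval_start_s", "dtw_per_second", "n_valid",
]
PROXIMITY_COLUMNS = [
    "team_id", "member_a", "member_b", "phase",
    "delta_s", "interval_index", "interval_start_s", "mean_distance_m", "n_samples",
]
METRIC_COLUMNS = ["participant_id", "metric", "t_s", "value", "valid"]


def read_beats(path: str | Path) -> BeatSeries:
    """Read one participant's R-peak times; NN intervals are derived, never read.

    Peak times must appear in strictly increasing order; a non-monotone time is
    a hard error naming the first offending data row (1-based).
    """
    df = pd.read_csv(path)
    missing = {"participant_id", "peak_time_ms"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    if df.empty:
        raise ValidationError(f"{path}: no beat rows")
    pids = df["participant_id"].unique()
    if len(pids) != 1:
        raise ValidationError(f"{path}: expected a single participant, found {list(pids)}")
    peaks = df["peak_time_ms"].to_numpy(dtype=float)
    d = np.diff(peaks)
    if d.size and not np.all(d > 0):
        row = int(np.argmin(d > 0)) + 2
        raise ValidationError(f"{path}: non-monotone peak time at row {row}")
    return BeatSeries(str(pids[0]), peaks)


def read_positions(path: str | Path) -> TrajectorySeries:
    """Read one participant's position track.

    Rows with a NaN coordinate are dropped with a warning; among duplicate
    timestamps the first row is kept (warned).  All rows dropped is an error.
    """
    df = pd.read_csv(path)
    missing = {"participant_id", "t_s", "x_m", "y_m"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    pids = df["participant_id"].dropna().unique()
    if len(pids) > 1:
        raise ValidationError(f"{path}: expected a single participant, found {list(pids)}")
    n0 = len(df)
    df = df.dropna(subset=["t_s", "x_m", "y_m"])
    if len(df) < n0:
        logger.warning("%s: dropped %d row(s) with NaN coordinates", path, n0 - len(df))
    df = df.sort_values("t_s", kind="stable")
    dup = df["t_s"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: dropped %d duplicate timestamp row(s), keeping first", path, int(dup.sum()))
        df = df[~dup]
    if df.empty:
        raise ValidationError(f"{path}: no valid position rows")
    return TrajectorySeries(
        str(pids[0]),
        df["t_s"].to_numpy(float),
        df["x_m"].to_numpy(float),
        df["y_m"].to_numpy(float),
    )


def read_annotation(path: str | Path) -> SessionAnnotation:
    """Read a session annotation (YAML).

    Scenario order is taken from the file when present, otherwise inferred from
    phase start times.  Overlapping phases or a missing/duplicated baseline are
    errors (enforced by :class:`SessionAnnotation`).
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    try:
        phases = [
            PhaseSpan(p["name"], float(p["start_s"]), float(p["end_s"]),
                      int(p["order"]) if p.get("order") is not None else None)
            for p in doc["phases"]
        ]
        return SessionAnnotation(
            session_id=str(doc["session_id"]),
            team_id=str(doc["team_id"]),
            members=[str(m) for m in doc["members"]],
            phases=phases,
        )
    except KeyError as exc:
        raise ValidationError(f"{path}: missing annotation field {exc}") from exc


def write_annotation(annotation: SessionAnnotation, path: str | Path) -> None:
    doc = {
        "session_id": annotation.session_id,
        "team_id": annotation.team_id,
        "members": list(annotation.members),
        "phases": [
            {"name": p.name, "start_s": float(p.start_s), "end_s": float(p.end_s),
             **({"order": int(p.order)} if p.order is not None else {})}
            for p in annotation.phases
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_events(path: str | Path) -> list[EventAnnotation]:
    df = pd.read_csv(path)
    missing = {"t_s", "label"} - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return [EventAnnotation(float(r.t_s), str(r.label)) for r in df.itertuples()]


def _record_kind(rec) -> str:
    if isinstance(rec, SyncRecord):
        return "sync"
    if isinstance(rec, ProximityRecord):
        return "proximity"
    raise ValidationError(f"unsupported record type {type(rec).__name__}")


def records_to_frame(records: list[SyncRecord] | list[ProximityRecord]) -> pd.DataFrame:
    """Tidy DataFrame for a homogeneous record list (empty list -> sync layout)."""
    kinds = {_record_kind(r) for r in records}
    if len(kinds) > 1:
        raise ValidationError(f"mixed record kinds: {sorted(kinds)}")
    kind = kinds.pop() if kinds else "sync"
    if kind == "sync":
        rows = [
            (r.team_id, r.dyad.member_a, r.dyad.member_b, r.metric, r.phase,
             r.delta_s, r.interval_index, r.interval_start_s, r.dtw_per_second, r.n_valid)
            for r in records
        ]
        return pd.DataFrame(rows, columns=SYNC_COLUMNS)
    rows = [
        (r.team_id, r.dyad.member_a, r.dyad.member_b, r.phase,
         r.delta_s, r.interval_index, r.interval_start_s, r.mean_distance_m, r.n_samples)
        for r in records
    ]
    return pd.DataFrame(rows, columns=PROXIMITY_COLUMNS)


def write_tidy(records: list, path: str | Path) -> None:
    """Write a homogeneous record list as tidy CSV (header-only when empty)."""
    records_to_frame(records).to_csv(path, index=False)


def read_tidy(path: str | Path) -> list:
    """Read a tidy CSV back into SyncRecord/ProximityRecord objects."""
    df = pd.read_csv(path)
    cols = list(df.columns)
    if cols == SYNC_COLUMNS:
        return [
            SyncRecord(str(r.team_id), Dyad.of(str(r.member_a), str(r.member_b), str(r.team_id)),
                       str(r.metric), str(r.phase), int(r.delta_s), int(r.interval_index),
                       float(r.interval_start_s), float(r.dtw_per_second), int(r.n_valid))
            for r in df.itertuples()
        ]
    if cols == PROXIMITY_COLUMNS:
        return [
            ProximityRecord(str(r.team_id), Dyad.of(str(r.member_a), str(r.member_b), str(r.team_id)),
                            str(r.phase), int(r.delta_s), int(r.interval_index),
                            float(r.interval_start_s), float(r.mean_distance_m), int(r.n_samples))
            for r in df.itertuples()
        ]
    raise ValidationError(f"{path}: unrecognised tidy layout {cols}")


def write_beats(beats: BeatSeries, path: str | Path) -> None:
    pd.DataFrame({
        "participant_id": beats.participant_id,
        "peak_time_ms": beats.peak_times_ms,
    }).to_csv(path, index=False)


def write_positions(traj: TrajectorySeries, path: str | Path) -> None:
    pd.DataFrame({
        "participant_id": traj.participant_id,
        "t_s": traj.t_s, "x_m": traj.x_m, "y_m": traj.y_m,
    }).to_csv(path, index=False)


def write_events(events: list[EventAnnotation], path: str | Path) -> None:
    pd.DataFrame({"t_s": [e.t_s for e in events], "label": [e.label for e in events]}).to_csv(path, index=False)
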