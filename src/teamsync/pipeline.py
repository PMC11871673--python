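"""Pipeline orchestration: config, stages, and report outputs.

A single YAML config drives the whole analysis.  Inputs are either synthetic
(a ``synthesis`` block) or file-based (an ``inputs`` block listing per-team
annotation/beats/positions files).  Stages run in order

    metrics -> synchrony -> proximity -> phase statistics -> influence models

and write ``metrics.csv``, ``sync.csv``, ``proximity.csv``,
``phase_stats.json``, ``influence.json``, ``stability.csv`` and an optional
synchrony time-series plot into the output directory.  With a fixed seed the
whole run is deterministic (bit-identical outputs across repeated runs on the
same platform).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as tio
from .dtw import dyad_sync_series, phase_average
from .hrv import ArtifactFilter, metric_series
from .influence import build_design, fit_lme, select_model, stability_frame, stability_sweep
from .phase_stats import compare_phases
from .proximity import interval_mean_distance
from .simulate import SimulationConfig, simulate_session
from .types import METRICS, SessionAnnotation, ValidationError, enumerate_dyads

logger = logging.getLogger("teamsync")

DEFAULT_PHASE_PAIRS = [["baseline", "pre"], ["baseline", "scenario"], ["pre", "scenario"]]


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "teamsync-out"
    metrics: list[str] = field(default_factory=lambda: list(METRICS))
    intervals: list[int] = field(default_factory=lambda: [5, 10, 15, 30, 60, 90, 120])
    coverage_min: float = 0.8
    normalize: str = "seconds"           # dtw normalisation: seconds | path
    standardize: bool = False            # z-score series before DTW
    artifact_filter: bool = False
    phase_pairs: list[list[str]] = field(default_factory=lambda: [list(p) for p in DEFAULT_PHASE_PAIRS])
    bh_family: str = "metric"
    synthesis: dict | None = None        # SimulationConfig overrides
    inputs: list[dict] | None = None     # per-team file listings
    influence_delta_s: int = 5
    influence_metrics: list[str] | None = None
    run_selection: bool = True
    stability_intervals: list[int] | None = None
    plot: bool = False
    plot_delta_s: int = 5

    def __post_init__(self) -> None:
        unknown = [m for m in self.metrics if m not in METRICS]
        if unknown:
            raise ValidationError(f"unknown metric name(s) {unknown}; expected subset of {list(METRICS)}")
        if self.normalize not in ("seconds", "path"):
            raise ValidationError(f"unknown dtw normalization {self.normalize!r}")
        if self.synthesis is None and self.inputs is None:
            raise ValidationError("config needs either a 'synthesis' block or an 'inputs' block")
        if self.influence_delta_s not in self.intervals:
            raise ValidationError("influence_delta_s must be one of the configured intervals")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in cls.__dataclass_fields__.values()}
        bad = set(doc) - known
        if bad:
            raise ValidationError(f"unknown config key(s): {sorted(bad)}")
        return cls(**doc)


@dataclass
class SessionData:
    annotation: SessionAnnotation
    beats: dict
    trajectories: dict
    events: list


def _load_inputs(cfg: PipelineConfig) -> list[SessionData]:
    if cfg.synthesis is not None:
        sim = SimulationConfig(**cfg.synthesis)
        bundle = simulate_session(sim, cfg.seed)
        return [SessionData(t.annotation, t.beats, t.trajectories, t.events) for t in bundle.teams]
    sessions = []
    for entry in cfg.inputs:
        ann = tio.read_annotation(entry["annotation"])
        beats = {}
        for p in entry["beats"]:
            bs = tio.read_beats(p)
            beats[bs.participant_id] = bs
        trajs = {}
        for p in entry.get("positions", []):
            tr = tio.read_positions(p)
            trajs[tr.participant_id] = tr
        events = tio.read_events(entry["events"]) if entry.get("events") else []
        sessions.append(SessionData(ann, beats, trajs, events))
    return sessions


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@_stage("metrics")
def stage_metrics(sessions: list[SessionData], cfg: PipelineConfig) -> dict:
    """Per-second metric series per participant over the whole session."""
    filt = ArtifactFilter() if cfg.artifact_filter else None
    out = {}
    for ses in sessions:
        end = max(p.end_s for p in ses.annotation.phases)
        for pid, bs in ses.beats.items():
            for metric in cfg.metrics:
                out[(pid, metric)] = metric_series(
                    bs, metric, (0.0, end), coverage_min=cfg.coverage_min, artifact_filter=filt
                )
    return out


@_stage("sync")
def stage_sync(sessions, metric_map, cfg: PipelineConfig) -> list:
    records = []
    for ses in sessions:
        ann = ses.annotation
        for dyad in enumerate_dyads(ann.members, ann.team_id):
            for metric in cfg.metrics:
                sa = metric_map.get((dyad.member_a, metric))
                sb = metric_map.get((dyad.member_b, metric))
                if sa is None or sb is None:
                    continue  # excluded recording: dyad absent, as in lost ECGs
                for delta in cfg.intervals:
                    records.extend(dyad_sync_series(
                        sa, sb, ann.phases, delta,
                        team_id=ann.team_id, coverage_min=cfg.coverage_min,
                        normalize=cfg.normalize, standardize=cfg.standardize,
                    ))
    return records


@_stage("proximity")
def stage_proximity(sessions, cfg: PipelineConfig) -> list:
    records = []
    for ses in sessions:
        ann = ses.annotation
        for dyad in enumerate_dyads(ann.members, ann.team_id):
            ta = ses.trajectories.get(dyad.member_a)
            tb = ses.trajectories.get(dyad.member_b)
            if ta is None or tb is None:
                continue  # missing position data: records absent
            for delta in cfg.intervals:
                records.extend(interval_mean_distance(
                    ta, tb, ann.phases, delta,
                    team_id=ann.team_id, coverage_min=cfg.coverage_min,
                ))
    return records


@_stage("phases")
def stage_phases(sync_records, cfg: PipelineConfig) -> dict:
    avg = phase_average([r for r in sync_records if r.delta_s == cfg.influence_delta_s])
    comparisons = compare_phases(
        avg, [tuple(p) for p in cfg.phase_pairs], metrics=cfg.metrics, family=cfg.bh_family,
    )
    return {
        "delta_s": cfg.influence_delta_s,
        "note": "dyads are the paired unit; within-team dependence is not corrected for",
        "comparisons": [c.to_dict() for c in comparisons],
    }


@_stage("influence")
def stage_influence(sync_df, prox_df, annotations, cfg: PipelineConfig) -> tuple[dict, pd.DataFrame]:
    design = build_design(sync_df, prox_df, annotations)
    metrics = cfg.influence_metrics or cfg.metrics
    results = {"delta_s": cfg.influence_delta_s, "models": [], "selection": {}}
    tier_by_metric = {}
    for metric in metrics:
        sub = design[(design["metric"] == metric) & (design["delta_s"] == cfg.influence_delta_s)]
        if sub.empty:
            logger.warning("influence: no design rows for %s", metric)
            continue
        if cfg.run_selection:
            sel = select_model(sub)
            results["selection"][metric] = sel.to_dict()
            tier = sel.best_tier
        else:
            tier = 4
        tier_by_metric[metric] = tier
        res = fit_lme(sub, tier, reml=True)
        results["models"].append(res.to_dict())
    if not results["models"]:
        raise ValidationError(f"no influence model could be fitted for metrics {metrics}")
    sweep_intervals = cfg.stability_intervals or [d for d in cfg.intervals if d != cfg.influence_delta_s]
    rows = []
    for metric, tier in tier_by_metric.items():
        rows.extend(stability_sweep(design, sweep_intervals, metrics=[metric], tier=max(tier, 1)))
    return results, stability_frame(rows)


def bundle_sync_records(
    bundle,
    metric: str = "HR",
    delta_s: int = 5,
    *,
    scenario_only: bool = True,
    coverage_min: float = 0.8,
) -> list:
    """Synchrony records for every dyad of a synthetic session bundle."""
    records = []
    for team in bundle.teams:
        ann = team.annotation
        end = max(p.end_s for p in ann.phases)
        series = {pid: metric_series(bs, metric, (0.0, end), coverage_min=coverage_min)
                  for pid, bs in team.beats.items()}
        spans = ann.scenario_phases if scenario_only else ann.phases
        for dyad in enumerate_dyads(ann.members, ann.team_id):
            records.extend(dyad_sync_series(
                series[dyad.member_a], series[dyad.member_b], spans, delta_s,
                team_id=ann.team_id, coverage_min=coverage_min,
            ))
    return records


def scenario_design(bundle, metric: str = "HR", deltas: tuple[int, ...] = (5,)) -> pd.DataFrame:
    """Influence-model design table (scenario phases) for a synthetic bundle."""
    sync, prox = [], []
    for team in bundle.teams:
        ann = team.annotation
        end = max(p.end_s for p in ann.phases)
        series = {pid: metric_series(bs, metric, (0.0, end)) for pid, bs in team.beats.items()}
        for dyad in enumerate_dyads(ann.members, ann.team_id):
            for delta in deltas:
                sync.extend(dyad_sync_series(
                    series[dyad.member_a], series[dyad.member_b], ann.scenario_phases,
                    delta, team_id=ann.team_id,
                ))
                prox.extend(interval_mean_distance(
                    team.trajectories[dyad.member_a], team.trajectories[dyad.member_b],
                    ann.scenario_phases, delta, team_id=ann.team_id,
                ))
    annotations = {t.annotation.team_id: t.annotation for t in bundle.teams}
    return build_design(tio.records_to_frame(sync), tio.records_to_frame(prox), annotations)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.bool_):
        return bool(o)
    raise TypeError(f"not JSON serialisable: {type(o)}")


def run_pipeline(config: PipelineConfig | str | Path) -> dict:
    """Execute all stages and write the report bundle to the output directory."""
    cfg = PipelineConfig.from_yaml(config) if not isinstance(config, PipelineConfig) else config
    outdir = Path(cfg.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    sessions = _load_inputs(cfg)
    annotations = {s.annotation.team_id: s.annotation for s in sessions}

    metric_map = stage_metrics(sessions, cfg)
    metric_frames = [
        pd.DataFrame({"participant_id": ms.participant_id, "metric": ms.metric,
                      "t_s": ms.t_s, "value": ms.value, "valid": ms.valid})
        for ms in metric_map.values()
    ]
    pd.concat(metric_frames, ignore_index=True).to_csv(outdir / "metrics.csv", index=False)

    sync_records = stage_sync(sessions, metric_map, cfg)
    tio.write_tidy(sync_records, outdir / "sync.csv")
    prox_records = stage_proximity(sessions, cfg)
    tio.write_tidy(prox_records, outdir / "proximity.csv")

    phase_stats = stage_phases(sync_records, cfg)
    with open(outdir / "phase_stats.json", "w") as fh:
        json.dump(phase_stats, fh, indent=2, sort_keys=True, default=_json_default)

    sync_df = tio.records_to_frame(sync_records)
    prox_df = tio.records_to_frame(prox_records)
    influence, stability = stage_influence(sync_df, prox_df, annotations, cfg)
    with open(outdir / "influence.json", "w") as fh:
        json.dump(influence, fh, indent=2, sort_keys=True, default=_json_default)
    stability.to_csv(outdir / "stability.csv", index=False)

    if cfg.plot:
        from .plotting import plot_sync_timeseries
        team0 = sessions[0]
        plot_sync_timeseries(
            sync_df[sync_df["team_id"] == team0.annotation.team_id],
            team0.events, outdir / "sync_timeseries.svg", delta_s=cfg.plot_delta_s,
        )

    return {
        "sessions": sessions,
        "sync": sync_df,
        "proximity": prox_df,
        "phase_stats": phase_stats,
        "influence": influence,
        "stability": stability,
        "output_dir": outdir,
    }
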