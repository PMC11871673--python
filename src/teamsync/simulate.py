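"""Synthetic team-training sessions with known ground truth.

Emulates the study conditions of a mixed-reality mass-casualty team training:
teams of 3-4 medical first responders, a 2-min standing baseline, two 2-min
preparation phases and two ~8-min scenarios (street / tunnel) in random
order, beat-by-beat ECG R-peak streams, and 2-D position tracks in a
10 x 10 m arena.

Cardiac model
-------------
Each participant's instantaneous mean RR interval is modulated around a
personal base value::

    RR_i(t) = base_i * (1 + a * m_i(t)),   m_i(t) = k_i(t) * s(t) + (1 - k_i(t)) * u_i(t)

where ``s`` is a team-shared driver (sum of sinusoids at a Mayer-wave-like
0.1 Hz and a slow 0.02 Hz task drift, unit variance) and ``u_i`` an
independent process: an oscillation with the same spectrum (random phases per
participant) plus a personal tonic arousal offset.  The offset makes coupling
act on heart-rate *levels* as well as fluctuations — uncoupled members sit at
individually different arousal levels, coupled members are pulled onto the
shared driver — which is what lets dyad-level DTW distances respond strongly
to the coupling.  The coupling ``k`` is set per phase and, when the proximity
link is enabled,
attenuated with the participant's distance from the team centroid::

    k_eff_i(t) = k_phase(t) * exp(-d_i(t) / length_scale_m)

so that spatially dispersed teams are less physiologically coupled — the
injected ground truth for proximity-effect recovery.  Beat times follow by
cumulative summation of RR plus white beat-to-beat noise whose amplitude is
itself modulated by ``m`` (so RMSSD/SDNN track the coupling too, not just HR).

Movement model
--------------
A team centroid performs a mean-reverting random walk around the arena
centre; each member performs a mean-reverting walk attracted to the centroid,
reflected at the arena bounds.  The attraction parameter sets the stationary
team spread; with attraction 0 positions are uniform over the arena.

All randomness derives from one seeded generator per session; outputs are
byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as tio
from .types import (
    BeatSeries,
    EventAnnotation,
    PhaseSpan,
    SessionAnnotation,
    TrajectorySeries,
    ValidationError,
)

logger = logging.getLogger("teamsync")

DEFAULT_KAPPA = {
    "baseline": 0.1,
    "pre_street": 0.4,
    "pre_tunnel": 0.4,
    "street": 0.85,
    "tunnel": 0.85,
}

#: within-scenario events shared by all teams (offsets from scenario start, s)
SCENARIO_EVENTS = [
    (20.0, "briefing"),
    (150.0, "danger called out"),
    (360.0, "triage count"),
    (430.0, "final discussion"),
]


@dataclass
class SimulationConfig:
    """Generator parameters; defaults emulate the training protocol."""

    n_teams: int = 6
    team_size: int | str = "mixed"            # 3, 4 or "mixed" (random 3/4)
    # cardiac model
    base_rr_mean_ms: float = 850.0            # ~71 bpm resting mean across participants
    base_rr_sd_ms: float = 30.0               # between-participant spread
    rr_mod_amp: float = 0.12                  # a: modulation-to-RR gain
    hrv_mod_amp: float = 0.3                  # b: modulation of beat-to-beat noise SD
    rr_noise_ms: float = 10.0                 # white beat-to-beat noise SD
    driver_freqs_hz: tuple = (0.1, 0.02)      # Mayer wave + slow task drift
    driver_amps: tuple = (1.0, 1.5)
    indiv_osc_amp: float = 0.35                # oscillatory amplitude of the individual process
    indiv_bias_sd: float = 3.5                # SD of the personal tonic arousal offset
    kappa_by_phase: dict = field(default_factory=lambda: dict(DEFAULT_KAPPA))
    kappa_gap: float = 0.1                    # coupling during unannotated time
    tunnel_kappa_boost: float = 0.0           # transient extra coupling in the tunnel scenario
    tunnel_boost_duration_s: float = 60.0
    tunnel_lag_s: float = 0.0                 # max per-member reaction latency to the shared
                                              # driver in the tunnel scenario (transient
                                              # desynchronisation that short DTW windows see
                                              # but long windows warp away)
    tunnel_lag_second_only: bool = False      # apply the lag only when tunnel comes second
                                              # (a scenario x order interaction)
    kappa_order_delta: float = 0.0            # coupling change in the second scenario
                                              # (familiarity / carry-over order effect)
    # proximity link (injected proximity -> coupling ground truth)
    proximity_link: bool = True
    length_scale_m: float = 2.0
    # movement model
    arena_m: tuple = (10.0, 10.0)
    attraction: float = 0.8                   # member pull toward the team centroid, per s
    step_sd_m: float = 1.7                    # member random-walk step SD, m/s
    centroid_attraction: float = 0.3
    centroid_step_sd_m: float = 0.15
    # timeline (s)
    baseline_s: float = 120.0
    pre_s: float = 120.0
    scenario_s: float = 480.0
    lead_in_s: float = 120.0                  # recording before the baseline (sensor fitting)
    gap_s: float = 60.0                       # hot wash / breaks between phases
    tail_s: float = 30.0

    def __post_init__(self) -> None:
        for name, k in {**self.kappa_by_phase, "gap": self.kappa_gap}.items():
            if not 0.0 <= k <= 1.0:
                raise ValidationError(f"coupling for {name!r} must lie in [0, 1], got {k}")
        for name in ("base_rr_sd_ms", "rr_noise_ms", "step_sd_m", "centroid_step_sd_m"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.team_size not in (3, 4, "mixed"):
            raise ValidationError("team_size must be 3, 4 or 'mixed'")


@dataclass
class GroundTruth:
    """Generator truth stored alongside outputs for recovery tests."""

    kappa_by_phase: dict
    proximity_link: bool
    length_scale_m: float
    tunnel_kappa_boost: float
    tunnel_boost_duration_s: float
    tunnel_lag_s: float
    base_rr_ms: dict[str, float]
    scenario_order: dict[str, int]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class TeamSession:
    annotation: SessionAnnotation
    beats: dict[str, BeatSeries]
    trajectories: dict[str, TrajectorySeries]
    events: list[EventAnnotation]
    ground_truth: GroundTruth


@dataclass
class SessionBundle:
    config: SimulationConfig
    seed: int
    teams: list[TeamSession]


def build_timeline(config: SimulationConfig, first_scenario: str) -> list[PhaseSpan]:
    """Phase spans for one session; scenario order given by ``first_scenario``."""
    if first_scenario not in ("street", "tunnel"):
        raise ValidationError(f"first_scenario must be street or tunnel, got {first_scenario!r}")
    second = "tunnel" if first_scenario == "street" else "street"
    t = config.lead_in_s
    phases = [PhaseSpan("baseline", t, t + config.baseline_s)]
    t += config.baseline_s + config.gap_s
    for order, scen in enumerate((first_scenario, second), start=1):
        phases.append(PhaseSpan(f"pre_{scen}", t, t + config.pre_s))
        t += config.pre_s
        phases.append(PhaseSpan(scen, t, t + config.scenario_s, order=order))
        t += config.scenario_s + config.gap_s
    return phases


def session_end_s(config: SimulationConfig, phases: list[PhaseSpan]) -> int:
    return int(np.ceil(phases[-1].end_s + config.tail_s))


def _oscillator(t: np.ndarray, freqs, amps, phases) -> np.ndarray:
    """Unit-variance sum of sinusoids."""
    out = np.zeros_like(t, dtype=float)
    for f, a, ph in zip(freqs, amps, phases):
        out += a * np.sin(2 * np.pi * f * t + ph)
    norm = np.sqrt(0.5 * np.sum(np.square(amps)))
    return out / norm if norm > 0 else out


def _reflect(v: np.ndarray, hi: float) -> np.ndarray:
    v = np.abs(v)
    v = np.where(v > hi, 2 * hi - v, v)
    return np.clip(v, 0.0, hi)  # guard huge excursions


def simulate_trajectories(
    config: SimulationConfig,
    members: list[str],
    end_s: int,
    rng: np.random.Generator,
) -> dict[str, TrajectorySeries]:
    """1-Hz mean-reverting walks attracted to a moving team centroid.

    With ``attraction == 0`` members start uniform over the arena and perform
    reflected random walks (uniform stationary distribution).
    """
    W, H = config.arena_m
    T = end_s + 1
    t_grid = np.arange(T, dtype=float)
    centre = np.array([W / 2, H / 2])
    c_steps = rng.normal(0.0, config.centroid_step_sd_m, size=(T, 2))
    c = np.empty((T, 2))
    c[0] = centre
    for t in range(1, T):
        c[t] = c[t - 1] + config.centroid_attraction * (centre - c[t - 1]) + c_steps[t]
        c[t, 0] = _reflect(np.atleast_1d(c[t, 0]), W)[0]
        c[t, 1] = _reflect(np.atleast_1d(c[t, 1]), H)[0]

    out: dict[str, TrajectorySeries] = {}
    for pid in members:
        steps = rng.normal(0.0, config.step_sd_m, size=(T, 2))
        x = np.empty((T, 2))
        if config.attraction > 0:
            x[0] = c[0] + rng.normal(0.0, 1.0, size=2)
        else:
            x[0] = rng.uniform([0, 0], [W, H])
        x[0, 0] = min(max(x[0, 0], 0.0), W)
        x[0, 1] = min(max(x[0, 1], 0.0), H)
        for t in range(1, T):
            x[t] = x[t - 1] + config.attraction * (c[t - 1] - x[t - 1]) + steps[t]
            x[t, 0] = _reflect(np.atleast_1d(x[t, 0]), W)[0]
            x[t, 1] = _reflect(np.atleast_1d(x[t, 1]), H)[0]
        out[pid] = TrajectorySeries(pid, t_grid, x[:, 0], x[:, 1])
    return out


def _kappa_series(
    config: SimulationConfig,
    phases: list[PhaseSpan],
    end_s: int,
    centroid_dist: np.ndarray | None,
) -> np.ndarray:
    """Per-second effective coupling for one participant."""
    t = np.arange(end_s + 1, dtype=float)
    kappa = np.full(t.size, config.kappa_gap)
    for p in phases:
        sel = (t >= p.start_s) & (t < p.end_s)
        kappa[sel] = config.kappa_by_phase[p.name]
        if p.name == "tunnel" and config.tunnel_kappa_boost:
            boost = sel & (t < p.start_s + config.tunnel_boost_duration_s)
            kappa[boost] = kappa[boost] + config.tunnel_kappa_boost
        if p.is_scenario and p.order == 2 and config.kappa_order_delta:
            kappa[sel] = kappa[sel] + config.kappa_order_delta
    if config.proximity_link and centroid_dist is not None:
        kappa = kappa * np.exp(-centroid_dist / config.length_scale_m)
    return np.clip(kappa, 0.0, 1.0)


def simulate_beats(
    config: SimulationConfig,
    participant_id: str,
    base_rr_ms: float,
    modulation: np.ndarray,
    rng: np.random.Generator,
    end_s: int,
) -> BeatSeries:
    """Beat times by cumulative summation of modulated RR plus white noise.

    ``modulation`` is the participant's per-second m(t); beat-to-beat noise SD
    is ``rr_noise_ms * (1 + hrv_mod_amp * m)``, floored at zero.  NN intervals
    are floored at 300 ms to stay physiological.
    """
    total_ms = end_s * 1000.0
    # pre-drawn noise: the draw sequence is independent of coupling parameters
    max_beats = int(np.ceil(total_ms / 300.0)) + 4
    noise = rng.standard_normal(max_beats)
    peaks = [0.0]
    t = 0.0
    i = 0
    while True:
        sec = min(int(t / 1000.0), end_s)
        m = modulation[sec]
        rr = base_rr_ms * (1.0 + config.rr_mod_amp * m)
        sd = max(config.rr_noise_ms * (1.0 + config.hrv_mod_amp * m), 0.0)
        nn = max(rr + sd * noise[i], 300.0)
        i += 1
        t += nn
        if t > total_ms:
            break
        peaks.append(t)
    return BeatSeries(participant_id, np.asarray(peaks))


def simulate_team(
    config: SimulationConfig,
    team_index: int,
    rng: np.random.Generator,
) -> TeamSession:
    team_id = f"team{team_index + 1:02d}"
    if config.team_size == "mixed":
        size = int(rng.choice([3, 4]))
    else:
        size = int(config.team_size)
    members = [f"{team_id}p{j + 1}" for j in range(size)]
    first = "street" if rng.random() < 0.5 else "tunnel"
    phases = build_timeline(config, first)
    end_s = session_end_s(config, phases)
    annotation = SessionAnnotation(f"session-{team_id}", team_id, members, phases)

    trajectories = simulate_trajectories(config, members, end_s, rng)
    centroid = np.mean(
        [np.column_stack([trajectories[m].x_m, trajectories[m].y_m]) for m in members], axis=0
    )

    t_grid = np.arange(end_s + 1, dtype=float)
    driver_phases = rng.uniform(0, 2 * np.pi, size=len(config.driver_freqs_hz))
    s = _oscillator(t_grid, config.driver_freqs_hz, config.driver_amps, driver_phases)

    base_rr = {
        m: float(config.base_rr_mean_ms + config.base_rr_sd_ms * rng.standard_normal())
        for m in members
    }
    beats: dict[str, BeatSeries] = {}
    for m in members:
        u_phases = rng.uniform(0, 2 * np.pi, size=len(config.driver_freqs_hz))
        bias = config.indiv_bias_sd * rng.standard_normal()
        lag = rng.uniform(-config.tunnel_lag_s, config.tunnel_lag_s)
        u = config.indiv_osc_amp * _oscillator(
            t_grid, config.driver_freqs_hz, config.driver_amps, u_phases
        ) + bias
        s_member = s
        if config.tunnel_lag_s > 0:
            # individual reaction latency to the shared driver, tunnel scenario only
            s_lagged = _oscillator(t_grid - lag, config.driver_freqs_hz, config.driver_amps, driver_phases)
            tunnel = next((p for p in phases if p.name == "tunnel"), None)
            applies = tunnel is not None and (
                not config.tunnel_lag_second_only or tunnel.order == 2
            )
            if applies:
                in_tunnel = (t_grid >= tunnel.start_s) & (t_grid < tunnel.end_s)
                s_member = np.where(in_tunnel, s_lagged, s)
        pos = np.column_stack([trajectories[m].x_m, trajectories[m].y_m])
        dist = np.hypot(*(pos - centroid).T)
        kappa = _kappa_series(config, phases, end_s, dist if config.proximity_link else None)
        mod = kappa * s_member + (1.0 - kappa) * u
        beats[m] = simulate_beats(config, m, base_rr[m], mod, rng, end_s)

    events = [
        EventAnnotation(p.start_s + off, f"{p.name}: {label}")
        for p in annotation.scenario_phases
        for off, label in SCENARIO_EVENTS
        if p.start_s + off < p.end_s
    ]
    truth = GroundTruth(
        kappa_by_phase=dict(config.kappa_by_phase),
        proximity_link=config.proximity_link,
        length_scale_m=config.length_scale_m,
        tunnel_kappa_boost=config.tunnel_kappa_boost,
        tunnel_boost_duration_s=config.tunnel_boost_duration_s,
        tunnel_lag_s=config.tunnel_lag_s,
        base_rr_ms=base_rr,
        scenario_order=annotation.scenario_order(),
    )
    return TeamSession(annotation, beats, trajectories, events, truth)


def simulate_session(
    config: SimulationConfig,
    seed: int,
    outdir: str | Path | None = None,
) -> SessionBundle:
    """Generate ``n_teams`` complete sessions; optionally write all input files.

    With ``outdir`` set, one directory per team is written containing
    ``annotation.yaml``, ``beats_<pid>.csv``, ``positions_<pid>.csv``,
    ``events.csv`` and ``ground_truth.json`` — exactly the dialects the
    pipeline readers consume.
    """
    rng = np.random.default_rng(seed)
    teams = [simulate_team(config, i, rng) for i in range(config.n_teams)]
    bundle = SessionBundle(config, seed, teams)
    if outdir is not None:
        write_session_bundle(bundle, outdir)
    return bundle


def write_session_bundle(bundle: SessionBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    for team in bundle.teams:
        tdir = outdir / team.annotation.team_id
        tdir.mkdir(parents=True, exist_ok=True)
        tio.write_annotation(team.annotation, tdir / "annotation.yaml")
        for pid, bs in team.beats.items():
            tio.write_beats(bs, tdir / f"beats_{pid}.csv")
        for pid, traj in team.trajectories.items():
            tio.write_positions(traj, tdir / f"positions_{pid}.csv")
        tio.write_events(team.events, tdir / "events.csv")
        with open(tdir / "ground_truth.json", "w") as fh:
            json.dump(team.ground_truth.to_dict(), fh, indent=2, sort_keys=True)
    logger.info("wrote %d team session(s) under %s", len(bundle.teams), outdir)


def protocol_default_config(**overrides) -> SimulationConfig:
    """The default training-protocol preset (mixed 3-4-member teams, full timeline)."""
    return SimulationConfig(**overrides)
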