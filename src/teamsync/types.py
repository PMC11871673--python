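"""Domain types for team physiological synchrony analysis.

All time streams live on a single per-session clock in seconds with t = 0 at
session start.  Phase spans are half-open intervals [start_s, end_s).  Beat
times are absolute R-peak times in milliseconds on the same clock; NN (normal-
to-normal) intervals are always derived from peak times, never stored, so the
two can never disagree.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger("teamsync")

PHASE_NAMES = ("baseline", "pre_street", "pre_tunnel", "street", "tunnel")
SCENARIO_PHASES = ("street", "tunnel")
PRE_PHASES = ("pre_street", "pre_tunnel")
METRICS = ("HR", "RMSSD", "SDNN")

#: phase categories used when averaging synchrony "per phase" for the
#: task-dependence comparisons: the baseline, the pre-scenario phases pooled,
#: and the scenario phases pooled.
PHASE_CATEGORIES = {
    "baseline": ("baseline",),
    "pre": PRE_PHASES,
    "scenario": SCENARIO_PHASES,
}


class ValidationError(ValueError):
    """An input violates a domain-type invariant."""


@dataclass(frozen=True)
class PhaseSpan:
    """One annotated phase of a training session, half-open [start_s, end_s)."""

    name: str
    start_s: float
    end_s: float
    order: int | None = None  # 1 or 2, scenario phases only

    #: nominal durations (s); deviations are warned about, never rejected
    NOMINAL = {"baseline": (120.0, 120.0), "pre": (120.0, 120.0), "scenario": (480.0, 540.0)}

    def __post_init__(self) -> None:
        if self.name not in PHASE_NAMES:
            raise ValidationError(f"unknown phase name {self.name!r}; expected one of {PHASE_NAMES}")
        if not (self.end_s > self.start_s):
            raise ValidationError(f"phase {self.name!r}: end_s ({self.end_s}) must exceed start_s ({self.start_s})")
        if self.order is not None and self.order not in (1, 2):
            raise ValidationError(f"phase {self.name!r}: order must be 1 or 2, got {self.order}")
        kind = "baseline" if self.name == "baseline" else ("pre" if self.name in PRE_PHASES else "scenario")
        lo, hi = self.NOMINAL[kind]
        dur = self.duration_s
        if not (0.5 * lo <= dur <= 1.5 * hi):
            logger.warning("phase %s duration %.0f s far from nominal %s s", self.name, dur, (lo, hi))

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def is_scenario(self) -> bool:
        return self.name in SCENARIO_PHASES

    def contains(self, t_s: float) -> bool:
        return self.start_s <= t_s < self.end_s


@dataclass
class SessionAnnotation:
    """Team roster and phase timeline for one training session."""

    session_id: str
    team_id: str
    members: list[str]
    phases: list[PhaseSpan]

    def __post_init__(self) -> None:
        if len(set(self.members)) != len(self.members):
            raise ValidationError(f"duplicate participant ids in roster: {self.members}")
        if not 3 <= len(self.members) <= 4:
            logger.warning("team %s has %d members (teams normally have 3-4)", self.team_id, len(self.members))
        self.phases = sorted(self.phases, key=lambda p: p.start_s)
        for a, b in zip(self.phases, self.phases[1:]):
            if b.start_s < a.end_s:
                raise ValidationError(f"phases {a.name!r} and {b.name!r} overlap ([{a.start_s},{a.end_s}) vs [{b.start_s},{b.end_s}))")
        n_base = sum(1 for p in self.phases if p.name == "baseline")
        if n_base != 1:
            raise ValidationError(f"session {self.session_id!r}: expected exactly one baseline phase, found {n_base}")
        self._infer_scenario_order()

    def _infer_scenario_order(self) -> None:
        scen = [p for p in self.phases if p.is_scenario]
        if any(p.order is None for p in scen):
            by_time = sorted(scen, key=lambda p: p.start_s)
            ordered = {p.name: i + 1 for i, p in enumerate(by_time)}
            self.phases = [
                PhaseSpan(p.name, p.start_s, p.end_s, ordered[p.name]) if p.is_scenario else p
                for p in self.phases
            ]

    def phase(self, name: str) -> PhaseSpan:
        for p in self.phases:
            if p.name == name:
                return p
        raise KeyError(f"session {self.session_id!r} has no phase {name!r}")

    @property
    def scenario_phases(self) -> list[PhaseSpan]:
        return [p for p in self.phases if p.is_scenario]

    def scenario_order(self) -> dict[str, int]:
        """Map scenario name -> presentation order (1 = first)."""
        return {p.name: int(p.order) for p in self.scenario_phases}

    def phase_at(self, t_s: float) -> PhaseSpan | None:
        for p in self.phases:
            if p.contains(t_s):
                return p
        return None


@dataclass
class BeatSeries:
    """One participant's R-peak times (ms, session clock), strictly increasing."""

    participant_id: str
    peak_times_ms: np.ndarray

    def __post_init__(self) -> None:
        self.peak_times_ms = np.asarray(self.peak_times_ms, dtype=float)
        if self.peak_times_ms.ndim != 1:
            raise ValidationError("peak_times_ms must be one-dimensional")
        if not np.all(np.isfinite(self.peak_times_ms)):
            raise ValidationError(f"participant {self.participant_id!r}: non-finite peak time")
        d = np.diff(self.peak_times_ms)
        if d.size and not np.all(d > 0):
            row = int(np.argmin(d > 0)) + 2  # 1-based data row of the offending peak
            raise ValidationError(
                f"participant {self.participant_id!r}: non-monotone peak time at row {row}"
            )

    @property
    def nn_ms(self) -> np.ndarray:
        """Successive NN intervals (ms); length = number of peaks - 1."""
        return np.diff(self.peak_times_ms)

    @property
    def n_beats(self) -> int:
        return int(self.peak_times_ms.size)


@dataclass
class TrajectorySeries:
    """One participant's 2-D position track (metres) on the session clock."""

    participant_id: str
    t_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_m = np.asarray(self.x_m, dtype=float)
        self.y_m = np.asarray(self.y_m, dtype=float)
        if not (self.t_s.size == self.x_m.size == self.y_m.size):
            raise ValidationError("trajectory arrays must have equal length")
        if self.t_s.size and not np.all(np.diff(self.t_s) > 0):
            raise ValidationError(f"participant {self.participant_id!r}: trajectory timestamps not strictly increasing")
        if not (np.all(np.isfinite(self.x_m)) and np.all(np.isfinite(self.y_m))):
            raise ValidationError(f"participant {self.participant_id!r}: non-finite coordinate")


@dataclass(frozen=True)
class EventAnnotation:
    """A labelled instant (e.g. 'danger called out') used only for plotting."""

    t_s: float
    label: str


@dataclass(frozen=True, order=True)
class Dyad:
    """Unordered pair of team members, canonically ordered member_a < member_b."""

    member_a: str
    member_b: str
    team_id: str = ""

    def __post_init__(self) -> None:
        if self.member_a == self.member_b:
            raise ValidationError(f"dyad members must differ, got {self.member_a!r} twice")
        if self.member_a > self.member_b:
            raise ValidationError("dyad members must be lexicographically ordered; use Dyad.of()")

    @classmethod
    def of(cls, a: str, b: str, team_id: str = "") -> "Dyad":
        lo, hi = sorted((a, b))
        return cls(lo, hi, team_id)

    @property
    def label(self) -> str:
        return f"{self.member_a}--{self.member_b}"


def enumerate_dyads(members: list[str], team_id: str = "") -> list[Dyad]:
    """All unordered pairs of a roster: n(n-1)/2 dyads, canonically ordered.

    A 3-member team yields 3 dyads, a 4-member team 6.
    """
    if len(set(members)) != len(members):
        raise ValidationError(f"duplicate participant ids: {members}")
    return [Dyad.of(a, b, team_id) for a, b in itertools.combinations(sorted(members), 2)]


@dataclass
class MetricSeries:
    """Per-second samples of one cardiac metric on a contiguous 1-Hz grid."""

    participant_id: str
    metric: str
    t_s: np.ndarray      # integer seconds, contiguous
    value: np.ndarray    # HR in bpm, RMSSD/SDNN in ms; NaN where invalid
    valid: np.ndarray    # bool per sample

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=int)
        self.value = np.asarray(self.value, dtype=float)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}; expected one of {METRICS}")
        if self.t_s.size > 1 and not np.all(np.diff(self.t_s) == 1):
            raise ValidationError("t_s must be a contiguous 1-Hz grid")
        ok = self.value[self.valid]
        if ok.size and (not np.all(np.isfinite(ok)) or np.any(ok < 0)):
            raise ValidationError("valid samples must be finite and non-negative")
        if self.metric == "HR" and ok.size and (ok.min() < 20 or ok.max() > 250):
            logger.warning("participant %s: HR outside plausible 20-250 bpm range", self.participant_id)


@dataclass(frozen=True)
class SyncRecord:
    """Synchrony for one dyad x metric x sampling interval: DTW cost per second.

    ``dtw_per_second`` is NaN when the interval had insufficient jointly valid
    samples.  Lower values mean more similar physiological patterns, i.e.
    higher synchrony.
    """

    team_id: str
    dyad: Dyad
    metric: str
    phase: str
    delta_s: int
    interval_index: int
    interval_start_s: float
    dtw_per_second: float
    n_valid: int

    @property
    def is_valid(self) -> bool:
        return np.isfinite(self.dtw_per_second)


@dataclass(frozen=True)
class ProximityRecord:
    """Mean pairwise Euclidean distance (m) of a dyad over one sampling interval."""

    team_id: str
    dyad: Dyad
    phase: str
    delta_s: int
    interval_index: int
    interval_start_s: float
    mean_distance_m: float
    n_samples: int

    @property
    def is_valid(self) -> bool:
        return np.isfinite(self.mean_distance_m)


def tile_span(span: PhaseSpan, delta_s: int) -> list[tuple[int, float]]:
    """Tile a phase with consecutive non-overlapping sampling intervals.

    Intervals are anchored at the phase start; the trailing remainder shorter
    than ``delta_s`` is dropped.  Returns (interval_index, interval_start_s)
    pairs, indices starting at 0 within the phase.
    """
    if delta_s <= 0:
        raise ValidationError("delta_s must be positive")
    n = int(span.duration_s // delta_s)
    return [(k, span.start_s + k * delta_s) for k in range(n)]
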