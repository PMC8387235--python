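"""Behavioural scoring of cage sessions.

Scores nest crossings, dam->virgin chases, shepherding (a chase in which the
virgin ends nearer the nest than she started), nest dwell time, pup-retrieval
learning outcomes, and ultrasonic-vocalization bout classes from centroid
trajectories and event logs.

Conventions: positions in cm with the origin at the bottom-left corner of the
cage; times in seconds from session start; intervals are half-open
``[t_start, t_end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Controlled vocabulary for ethogram behaviour labels.
BEHAVIOURS = frozenset(
    {
        "nest_entry",
        "nest_exit",
        "chase",
        "shepherding",
        "dam_retrieval",
        "pup_drop",
        "pup_call",
        "pup_call_bout",
        "retrieval",
    }
)


@dataclass(frozen=True)
class NestRegion:
    """Circular nest area inside the cage."""

    center: tuple[float, float]
    radius_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("nest radius must be positive")

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        cx, cy = self.center
        return np.hypot(np.asarray(x) - cx, np.asarray(y) - cy) <= self.radius_cm


@dataclass
class EthogramEvent:
    """A labelled behavioural interval performed by one animal."""

    actor: str
    behaviour: str
    t_start_s: float
    t_end_s: float
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.t_end_s < self.t_start_s:
            raise ValueError(
                f"event end {self.t_end_s} precedes start {self.t_start_s}"
            )
        if self.behaviour not in BEHAVIOURS:
            raise ValueError(f"unknown behaviour label {self.behaviour!r}")

    @property
    def duration_s(self) -> float:
        return self.t_end_s - self.t_start_s


@dataclass
class ShepherdingEvent:
    """A dam->virgin chase that ends nearer the nest than it starts."""

    t_start_s: float
    t_end_s: float
    d_start_cm: float
    d_end_cm: float

    def __post_init__(self) -> None:
        if not self.d_start_cm > self.d_end_cm:
            raise ValueError("shepherding requires d_start > d_end")


@dataclass
class RetrievalSession:
    """One daily 10-trial pup-retrieval test for one subject.

    ``successes[i]`` flags trial i; latencies (s) are recorded only for
    successful trials and are capped by the 120-s trial limit.
    """

    subject: str
    condition: str
    day: int
    successes: list[bool]
    latencies_s: list[float]

    def __post_init__(self) -> None:
        if len(self.latencies_s) != sum(self.successes):
            raise ValueError("one latency per successful trial required")
        if any(lat > 120.0 or lat < 0 for lat in self.latencies_s):
            raise ValueError("latencies must lie in [0, 120] s")

    @property
    def n_success(self) -> int:
        return int(sum(self.successes))

    @property
    def n_trials(self) -> int:
        return len(self.successes)


class Trajectory:
    """Centroid positional time series for one animal."""

    def __init__(self, animal: str, t_s, x_cm, y_cm):
        self.animal = animal
        self.t_s = np.asarray(t_s, dtype=float)
        self.x_cm = np.asarray(x_cm, dtype=float)
        self.y_cm = np.asarray(y_cm, dtype=float)
        if not (self.t_s.shape == self.x_cm.shape == self.y_cm.shape):
            raise ValueError("t, x, y must have equal length")
        if self.t_s.size > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("time stamps must be strictly increasing")

    def __len__(self) -> int:
        return self.t_s.size

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t_s[0]), float(self.t_s[-1])

    def position(self, t) -> np.ndarray:
        """Linearly interpolated (x, y) at time(s) ``t`` (must be in span)."""
        t = np.asarray(t, dtype=float)
        lo, hi = self.span
        if np.any(t < lo) or np.any(t > hi):
            raise ValueError("query time outside trajectory span")
        x = np.interp(t, self.t_s, self.x_cm)
        y = np.interp(t, self.t_s, self.y_cm)
        return np.stack([x, y], axis=-1)

    def velocity(self) -> np.ndarray:
        """Per-sample velocity (cm/s) by central differences."""
        vx = np.gradient(self.x_cm, self.t_s)
        vy = np.gradient(self.y_cm, self.t_s)
        return np.stack([vx, vy], axis=-1)

    def speed(self) -> np.ndarray:
        v = self.velocity()
        return np.hypot(v[:, 0], v[:, 1])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_s": self.t_s, "animal": self.animal, "x_cm": self.x_cm, "y_cm": self.y_cm}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, animal: str) -> "Trajectory":
        sub = df[df["animal"] == animal].sort_values("t_s")
        return cls(animal, sub["t_s"].to_numpy(), sub["x_cm"].to_numpy(), sub["y_cm"].to_numpy())


def distance_to_nest(trajectory: Trajectory, nest: NestRegion, t) -> np.ndarray | float:
    """Euclidean distance (cm) from the animal's interpolated position to the
    nest center at time(s) ``t``."""
    pos = trajectory.position(t)
    cx, cy = nest.center
    d = np.hypot(pos[..., 0] - cx, pos[..., 1] - cy)
    return float(d) if np.isscalar(t) or np.ndim(t) == 0 else d


def nest_crossings(trajectory: Trajectory, nest: NestRegion) -> list[EthogramEvent]:
    """Entry/exit events from centroid crossings of the nest circle.

    An entry is stamped at the first sample inside the circle after being
    outside; an exit at the first sample outside after inside.  Entries and
    exits strictly alternate.
    """
    if len(trajectory) == 0:
        return []
    inside = nest.contains(trajectory.x_cm, trajectory.y_cm)
    events: list[EthogramEvent] = []
    flips = np.flatnonzero(np.diff(inside.astype(int)) != 0) + 1
    for i in flips:
        kind = "nest_entry" if inside[i] else "nest_exit"
        t = float(trajectory.t_s[i])
        events.append(EthogramEvent(trajectory.animal, kind, t, t))
    return events


@dataclass(frozen=True)
class ChaseParams:
    """Thresholds for automatic chase detection.

    A chase is a maximal interval in which the dam is within ``proximity_cm``
    of the virgin, both animals move at >= ``speed_min_cm_s``, and the dam is
    behind the virgin's heading.  Runs separated by gaps <= ``merge_gap_s``
    are merged; runs shorter than ``min_duration_s`` are dropped.
    """

    proximity_cm: float = 10.0
    speed_min_cm_s: float = 10.0
    min_duration_s: float = 0.6
    merge_gap_s: float = 0.4


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal [i0, i1] index runs where mask is True."""
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    ends = np.concatenate([idx[breaks], [idx[-1]]])
    return list(zip(starts.tolist(), ends.tolist()))


def detect_chases(
    traj_dam: Trajectory,
    traj_virgin: Trajectory,
    params: ChaseParams | None = None,
) -> list[EthogramEvent]:
    """Detect dam->virgin chases from two trajectories on a common clock."""
    params = params or ChaseParams()
    if not np.array_equal(traj_dam.t_s, traj_virgin.t_s):
        raise ValueError("trajectories must share a common clock")
    t = traj_dam.t_s
    if t.size < 3:
        return []
    dx = traj_dam.x_cm - traj_virgin.x_cm
    dy = traj_dam.y_cm - traj_virgin.y_cm
    dist = np.hypot(dx, dy)
    sp_d = traj_dam.speed()
    sp_v = traj_virgin.speed()
    v_v = traj_virgin.velocity()
    # dam behind the virgin's heading: relative vector dam-virgin opposes motion
    behind = dx * v_v[:, 0] + dy * v_v[:, 1] < 0.0
    ok = (
        (dist <= params.proximity_cm)
        & (sp_d >= params.speed_min_cm_s)
        & (sp_v >= params.speed_min_cm_s)
        & behind
    )
    runs = _runs(ok)
    # merge runs separated by short gaps
    merged: list[list[int]] = []
    for i0, i1 in runs:
        if merged and t[i0] - t[merged[-1][1]] <= params.merge_gap_s:
            merged[-1][1] = i1
        else:
            merged.append([i0, i1])
    events = []
    for i0, i1 in merged:
        if t[i1] - t[i0] >= params.min_duration_s:
            events.append(EthogramEvent("dam", "chase", float(t[i0]), float(t[i1])))
    return events


def classify_shepherding(
    chase: EthogramEvent, traj_virgin: Trajectory, nest: NestRegion
) -> ShepherdingEvent | None:
    """Return a ShepherdingEvent iff the virgin ends the chase nearer the
    nest than she started; ``None`` otherwise."""
    d0 = float(distance_to_nest(traj_virgin, nest, chase.t_start_s))
    d1 = float(distance_to_nest(traj_virgin, nest, chase.t_end_s))
    if d0 > d1:
        return ShepherdingEvent(chase.t_start_s, chase.t_end_s, d0, d1)
    return None


def shepherding_rate(n_events: int, observation_hours: float) -> float:
    """Shepherding events per hour of observation."""
    if observation_hours <= 0:
        raise ValueError("observation time must be positive")
    return n_events / observation_hours


@dataclass
class RateTest:
    rates_per_h: list[float]
    reference: float
    t: float
    p_two_sided: float
    p_one_sided: float


def shepherding_rate_test(rates_per_h: Sequence[float], reference: float = 0.2) -> RateTest:
    """One-sample t test of per-cage shepherding rates against a reference
    rate (default 0.2 events/h, the dam->virgin chase rate without pups).

    The directional p (rate > reference) is the halved two-sided p when the
    sample mean exceeds the reference, else its complement.
    """
    rates = np.asarray(rates_per_h, dtype=float)
    if np.allclose(rates, reference):  # degenerate: no deviation to test
        t, p2 = 0.0, 1.0
    else:
        t, p2 = stats.ttest_1samp(rates, popmean=reference)
        t, p2 = float(t), float(p2)
        if np.isnan(t):
            t, p2 = 0.0, 1.0
    p1 = p2 / 2.0 if np.mean(rates) > reference else 1.0 - p2 / 2.0
    return RateTest(list(map(float, rates)), reference, t, p2, p1)


def dwell_intervals(
    events: Iterable[EthogramEvent], session_end_s: float | None = None
) -> list[tuple[float, float]]:
    """Pair alternating nest_entry/nest_exit events into dwell intervals.

    An open dwell at the end of the log is closed at ``session_end_s`` when
    given (otherwise dropped).  An exit before any entry is a malformed log.
    """
    t_in: float | None = None
    out: list[tuple[float, float]] = []
    for ev in sorted(events, key=lambda e: e.t_start_s):
        if ev.behaviour == "nest_entry":
            if t_in is not None:
                raise ValueError("two entries without an intervening exit")
            t_in = ev.t_start_s
        elif ev.behaviour == "nest_exit":
            if t_in is None:
                raise ValueError("nest exit before any entry")
            out.append((t_in, ev.t_start_s))
            t_in = None
    if t_in is not None and session_end_s is not None:
        out.append((t_in, session_end_s))
    return out


def time_in_nest(
    events: Iterable[EthogramEvent],
    session_end_s: float,
    day_length_s: float = 86400.0,
) -> dict[int, float]:
    """Minutes in the nest per day (day index 1-based) for one animal's
    alternating entry/exit log."""
    minutes: dict[int, float] = {}
    for t0, t1 in dwell_intervals(events, session_end_s):
        d0 = int(t0 // day_length_s)
        d1 = int(np.ceil(t1 / day_length_s))
        for d in range(d0, max(d1, d0 + 1)):
            lo = max(t0, d * day_length_s)
            hi = min(t1, (d + 1) * day_length_s)
            if hi > lo:
                minutes[d + 1] = minutes.get(d + 1, 0.0) + (hi - lo) / 60.0
    return minutes


def retrieval_onset(
    sessions: Sequence[RetrievalSession], rule: str = "cohoused"
) -> tuple[int | None, bool]:
    """First day a subject meets the retrieval criterion.

    rule='cohoused': reliable retrieval is >=2 of 10 successful trials;
    rule='observation': a single success counts (observer cohorts).
    Returns (onset_day, censored); censored subjects never meet the rule.
    """
    if rule not in {"cohoused", "observation"}:
        raise ValueError(f"unknown rule {rule!r}")
    need = 2 if rule == "cohoused" else 1
    ordered = sorted(sessions, key=lambda s: s.day)
    days = [s.day for s in ordered]
    if days != list(range(days[0], days[0] + len(days))):
        raise ValueError("sessions must cover consecutive days")
    for s in ordered:
        if s.n_success >= need:
            return s.day, False
    return None, True


def day1_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between paired per-cage day-1
    measures, e.g. nest-entry counts vs retrieval probability."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired samples with n >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def classify_usv_bout(
    onsets_s: Sequence[float], peak_freq_khz: Sequence[float]
) -> str:
    """Classify a syllable bout as pup distress calling or other.

    Distress (isolation) calls show a syllable bout rate of 4-8 Hz with peak
    frequencies of 40-90 kHz; the medians of both statistics must fall in
    range.  A single syllable is indeterminate.
    """
    onsets = np.sort(np.asarray(onsets_s, dtype=float))
    freqs = np.asarray(peak_freq_khz, dtype=float)
    if onsets.size < 2:
        raise ValueError("at least two syllables needed to estimate bout rate")
    rate_hz = 1.0 / float(np.median(np.diff(onsets)))
    f_khz = float(np.median(freqs))
    if 4.0 <= rate_hz <= 8.0 and 40.0 <= f_khz <= 90.0:
        return "distress"
    return "other"
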