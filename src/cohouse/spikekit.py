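"""Event-aligned spike-train statistics.

Implements the core single-unit pipeline: quality control (refractory and
cross-channel coincidence rules), photo-tagging identification, the signed
percent modulation index

    M = (rate_behaviour - rate_baseline) * 100 / (rate_behaviour + rate_baseline),

its shift-permutation null (behaviour intervals shifted by a common random
offset in [-500, 500] s, 1000 shuffles, add-one p estimator), per-family
Benjamini-Hochberg FDR flags, z-scored peri-event time histograms, pairwise
zero-lag spike-count synchrony, pup-call playback responses, and per-trial
population modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

from .ethogram import EthogramEvent

NEST_ENTRY_CAP_S = 40.0  # analysis cut-off for long nest dwells

#: baseline rule per behaviour: equal-duration window immediately before the
#: event (nest entry) or a fixed 10-s pre-window (shepherding, dam retrieval).
BASELINE_RULES = {
    "nest_entry": "equal_preceding",
    "shepherding": "fixed_10s",
    "dam_retrieval": "fixed_10s",
}

#: peri-event window per behaviour for PSTHs (s relative to onset)
PSTH_WINDOWS = {
    "nest_entry": (-20.0, 40.0),
    "dam_retrieval": (-20.0, 40.0),
    "shepherding": (-10.0, 20.0),
}


@dataclass
class SpikeTrain:
    """Sorted spike times (s) of one unit."""

    unit_id: str
    spike_times_s: np.ndarray
    channel_group: str = ""
    class_label: str = "unclassified"  # PVN | OT-PVN | unclassified

    def __post_init__(self) -> None:
        t = np.asarray(self.spike_times_s, dtype=float)
        if t.size and (np.any(np.diff(t) <= 0) or t[0] < 0):
            raise ValueError("spike times must be strictly sorted and non-negative")
        self.spike_times_s = t

    def __len__(self) -> int:
        return self.spike_times_s.size


@dataclass
class QCReport:
    n_refractory_removed: dict[str, int]
    n_coincident_removed: dict[str, int]


def qc_spike_trains(
    trains: Sequence[SpikeTrain],
    coincidence_channels: int = 10,
    coincidence_window_ms: float = 0.5,
    refractory_ms: float = 2.0,
) -> tuple[list[SpikeTrain], QCReport]:
    """Remove artifact and refractory-violating spikes.

    Spikes coincident (within ``coincidence_window_ms``) across
    ``coincidence_channels`` or more distinct channels are removed as
    electrical artifacts; then, within each unit, the later spike of any pair
    closer than ``refractory_ms`` is removed.
    """
    if not 2.0 <= refractory_ms <= 3.0:
        warnings.warn("refractory setting outside the usual 2-3 ms range")
    win = coincidence_window_ms / 1000.0
    have_channels = all(tr.channel_group for tr in trains)
    if not have_channels and trains:
        warnings.warn("channel map missing; coincidence rule skipped")

    coinc_bad: dict[str, np.ndarray] = {tr.unit_id: np.zeros(len(tr), bool) for tr in trains}
    if have_channels and trains:
        all_t = np.concatenate([tr.spike_times_s for tr in trains])
        all_ch = np.concatenate(
            [np.full(len(tr), i) for i, tr in enumerate(trains)]
        )
        all_unit = np.concatenate([np.full(len(tr), i) for i, tr in enumerate(trains)])
        all_idx = np.concatenate([np.arange(len(tr)) for tr in trains])
        order = np.argsort(all_t, kind="stable")
        t, ch, ui, ix = all_t[order], all_ch[order], all_unit[order], all_idx[order]
        chans = [tr.channel_group for tr in trains]
        # cluster sorted spikes whose neighbours are within the window
        n = t.size
        i = 0
        while i < n:
            j = i + 1
            while j < n and t[j] - t[j - 1] <= win:
                j += 1
            if j - i >= coincidence_channels:
                uniq = {chans[c] for c in ch[i:j]}
                if len(uniq) >= coincidence_channels:
                    for k in range(i, j):
                        coinc_bad[trains[ui[k]].unit_id][ix[k]] = True
            i = j

    out: list[SpikeTrain] = []
    n_ref: dict[str, int] = {}
    n_co: dict[str, int] = {}
    for tr in trains:
        keep = ~coinc_bad[tr.unit_id]
        n_co[tr.unit_id] = int((~keep).sum())
        t = tr.spike_times_s[keep]
        # drop the later spike of each too-close pair, sequentially
        kept: list[float] = []
        last = -np.inf
        removed = 0
        for s in t:
            if s - last < refractory_ms / 1000.0:
                removed += 1
            else:
                kept.append(s)
                last = s
        n_ref[tr.unit_id] = removed
        out.append(
            SpikeTrain(tr.unit_id, np.asarray(kept), tr.channel_group, tr.class_label)
        )
    return out, QCReport(n_ref, n_co)


@dataclass
class TagResult:
    unit_id: str
    reliability: float
    median_latency_ms: float
    is_tagged: bool
    n_pulses: int


def tag_unit(
    train: SpikeTrain,
    pulses: Sequence[float],
    latency_max_ms: float = 4.0,
    reliability_min: float = 0.7,
    min_pulses: int = 20,
) -> TagResult:
    """Photo-tagging classification.

    A unit is tagged when it spikes within ``latency_max_ms`` after at least
    ``reliability_min`` of the light pulses (>=70% of trials at <=4 ms
    latency by default).  Reliability is the fraction of pulses with at least
    one spike in the (0, latency_max] window; the median first-spike latency
    over responsive pulses is reported.
    """
    pulses = np.asarray(pulses, dtype=float)
    if pulses.size == 0:
        raise ValueError("at least one light pulse required")
    if pulses.size < min_pulses:
        warnings.warn(f"only {pulses.size} pulses; tagging estimate is coarse")
    t = train.spike_times_s
    win = latency_max_ms / 1000.0
    i0 = np.searchsorted(t, pulses, side="right")
    i1 = np.searchsorted(t, pulses + win, side="right")
    hit = i1 > i0
    reliability = float(hit.mean())
    if hit.any():
        lat = (t[i0[hit]] - pulses[hit]) * 1000.0
        med = float(np.median(lat))
    else:
        med = float("nan")
    tagged = reliability >= reliability_min and (hit.any() and med <= latency_max_ms)
    return TagResult(train.unit_id, reliability, med, bool(tagged), int(pulses.size))


@dataclass
class AlignedRates:
    rate_behaviour_hz: float
    rate_baseline_hz: float
    t_start_s: float
    duration_s: float
    baseline_rule: str
    in_span: bool = True


def _count(t: np.ndarray, a: float, b: float) -> int:
    return int(np.searchsorted(t, b) - np.searchsorted(t, a))


def event_aligned_rates(
    train: SpikeTrain,
    event: EthogramEvent,
    baseline_rule: str | None = None,
    cap_s: float | None = None,
    span: tuple[float, float] | None = None,
) -> AlignedRates:
    """Firing rate during one behavioural episode and its baseline.

    The analysis window runs from event onset for the duration of the
    behaviour, capped at 40 s for nest entries.  The baseline is either an
    equal-duration window immediately preceding onset (nest entry) or the
    fixed 10 s before onset (shepherding, dam retrieval).
    """
    if baseline_rule is None:
        baseline_rule = BASELINE_RULES.get(event.behaviour, "fixed_10s")
    if cap_s is None and event.behaviour == "nest_entry":
        cap_s = NEST_ENTRY_CAP_S
    dur = event.duration_s if cap_s is None else min(event.duration_s, cap_s)
    if dur <= 0:
        raise ValueError("zero-duration analysis window")
    base_dur = dur if baseline_rule == "equal_preceding" else 10.0
    a = event.t_start_s
    t = train.spike_times_s
    in_span = True
    if span is not None and (a - base_dur < span[0] or a + dur > span[1]):
        in_span = False
    rb = _count(t, a, a + dur) / dur
    r0 = _count(t, a - base_dur, a) / base_dur
    return AlignedRates(rb, r0, a, dur, baseline_rule, in_span)


def modulation_index(rates: AlignedRates | tuple[float, float]) -> float:
    """Signed percent change of event vs baseline firing, bounded in
    [-100, 100]; defined as 0 when both rates are 0."""
    if isinstance(rates, AlignedRates):
        b, base = rates.rate_behaviour_hz, rates.rate_baseline_hz
    else:
        b, base = rates
    if b < 0 or base < 0:
        raise ValueError("rates must be non-negative")
    if b + base == 0:
        return 0.0
    return float(np.clip((b - base) * 100.0 / (b + base), -100.0, 100.0))


def _window_durations(
    events: Sequence[EthogramEvent], baseline_rule: str | None, cap_s: float | None
):
    starts = np.array([ev.t_start_s for ev in events], dtype=float)
    durs = np.array([ev.duration_s for ev in events], dtype=float)
    behaviour = events[0].behaviour
    if cap_s is None and behaviour == "nest_entry":
        cap_s = NEST_ENTRY_CAP_S
    if cap_s is not None:
        durs = np.minimum(durs, cap_s)
    if baseline_rule is None:
        baseline_rule = BASELINE_RULES.get(behaviour, "fixed_10s")
    base_durs = durs.copy() if baseline_rule == "equal_preceding" else np.full_like(durs, 10.0)
    return starts, durs, base_durs


def _circular_counts(t: np.ndarray, start: np.ndarray, dur: np.ndarray, T: float) -> np.ndarray:
    """Spike counts in windows [start, start+dur) wrapped circularly on [0, T)."""
    a = np.mod(start, T)
    b = a + dur
    hi = np.minimum(b, T)
    n = np.searchsorted(t, hi) - np.searchsorted(t, a)
    over = b - T
    extra = np.where(over > 0, np.searchsorted(t, np.maximum(over, 0.0)), 0)
    return n + extra


@dataclass
class ModulationResult:
    unit_id: str
    behaviour: str
    M: float
    p_act: float
    p_sup: float
    n_events: int
    family: str = ""
    p_two_sided: float = float("nan")
    q: float = float("nan")
    direction: str = "ns"


def shuffle_null_test(
    train: SpikeTrain,
    events: Sequence[EthogramEvent],
    baseline_rule: str | None = None,
    cap_s: float | None = None,
    n_shuffles: int = 1000,
    shift_range_s: tuple[float, float] = (-500.0, 500.0),
    span: tuple[float, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> ModulationResult:
    """Shift-permutation test of event-aligned modulation for one unit.

    The observed statistic is the across-event mean of the per-event
    modulation index.  Each shuffle shifts all behaviour intervals (and their
    baselines) by one common draw uniform in ``shift_range_s``, wrapping
    circularly around the recording, and recomputes the mean index.  One-sided
    p values use the add-one estimator p = (1 + #{null >= obs}) / (n + 1);
    the "greater than 950 of 1000 shuffles" criterion corresponds to
    p_act <= 51/1001 ~ 0.051 under this estimator.
    """
    if len(events) == 0:
        raise ValueError("no events to test")
    rng = np.random.default_rng(rng)
    t = train.spike_times_s
    if span is None:
        hi = max(
            float(t[-1]) if t.size else 0.0, max(ev.t_end_s for ev in events)
        )
        span = (0.0, hi)
    t0, t1 = span
    T = t1 - t0
    ts = t - t0

    starts, durs, base_durs = _window_durations(events, baseline_rule, cap_s)
    starts = starts - t0

    def mean_m(start_mat: np.ndarray) -> np.ndarray:
        nb = _circular_counts(ts, start_mat, np.broadcast_to(durs, start_mat.shape), T)
        n0 = _circular_counts(
            ts,
            start_mat - base_durs,
            np.broadcast_to(base_durs, start_mat.shape),
            T,
        )
        rb = nb / durs
        r0 = n0 / base_durs
        denom = rb + r0
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(denom > 0, (rb - r0) * 100.0 / denom, 0.0)
        return m.mean(axis=-1)

    m_obs = float(mean_m(starts[None, :])[0])
    shifts = rng.uniform(shift_range_s[0], shift_range_s[1], size=n_shuffles)
    m_null = mean_m(starts[None, :] + shifts[:, None])
    p_act = (1.0 + np.sum(m_null >= m_obs)) / (n_shuffles + 1.0)
    p_sup = (1.0 + np.sum(m_null <= m_obs)) / (n_shuffles + 1.0)
    return ModulationResult(
        train.unit_id,
        events[0].behaviour,
        m_obs,
        float(p_act),
        float(p_sup),
        len(events),
    )


def fdr_flags(results: Iterable[ModulationResult], q: float = 0.05) -> list[ModulationResult]:
    """Benjamini-Hochberg FDR within each family (e.g. all PVN units of one
    recording day), at accepted FDR ``q``.

    Each unit's two-sided p is 2 * min(p_act, p_sup) capped at 1; significant
    units are labelled by the direction of the smaller one-sided p.
    """
    results = list(results)
    for r in results:
        r.p_two_sided = min(1.0, 2.0 * min(r.p_act, r.p_sup))
    by_family: dict[str, list[ModulationResult]] = {}
    for r in results:
        by_family.setdefault(r.family, []).append(r)
    for fam in by_family.values():
        ps = [r.p_two_sided for r in fam]
        reject, qvals, _, _ = multipletests(ps, alpha=q, method="fdr_bh")
        for r, rej, qv in zip(fam, reject, qvals):
            r.q = float(qv)
            if rej:
                r.direction = "activated" if r.p_act <= r.p_sup else "suppressed"
            else:
                r.direction = "ns"
    return results


@dataclass
class PSTH:
    behaviour: str
    bin_edges_s: np.ndarray
    z: np.ndarray          # raw z per bin (nan where undefined)
    mean_count: np.ndarray  # event-averaged spike count per bin
    n_events: int

    @property
    def display_z(self) -> np.ndarray:
        """z clipped to the +/-3 display bounds (raw values retained)."""
        return np.clip(self.z, -3.0, 3.0)


def psth_zscore(
    train: SpikeTrain,
    events: Sequence[EthogramEvent],
    window: tuple[float, float] | None = None,
    bin_s: float = 0.25,
) -> PSTH:
    """Event-aligned z-scored PSTH in 250-ms bins.

    Counts are averaged across events per bin; z references the mean and SD
    of the pre-onset bins of the same histogram.  Windows default to
    -20..+40 s (-10..+20 s for shepherding).
    """
    if len(events) < 2:
        raise ValueError("at least two events required for a PSTH")
    behaviour = events[0].behaviour
    if window is None:
        window = PSTH_WINDOWS.get(behaviour, (-20.0, 40.0))
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    t = train.spike_times_s
    counts = np.empty((len(events), n_bins))
    for i, ev in enumerate(events):
        counts[i] = np.diff(np.searchsorted(t, ev.t_start_s + edges))
    mean_count = counts.mean(axis=0)
    pre = mean_count[edges[1:] <= 0]
    mu, sd = pre.mean(), pre.std(ddof=1)
    if sd == 0:
        z = np.full(n_bins, np.nan)
    else:
        z = (mean_count - mu) / sd
    return PSTH(behaviour, edges, z, mean_count, len(events))


@dataclass
class PairSync:
    unit_a: str
    unit_b: str
    behaviour: str
    per_event_r: list[float]
    mean_z: float
    r_combined: float
    n_skipped: int


def pair_zero_lag_sync(
    train_a: SpikeTrain,
    train_b: SpikeTrain,
    events: Sequence[EthogramEvent],
    bin_s: float = 0.01,
    r_cap: float = 0.9999,
) -> PairSync:
    """Zero-lag correlation of 10-ms spike counts within behavioural events.

    Per event, Pearson r of the two binned count vectors; events where either
    vector has zero variance are skipped.  r values are Fisher z-transformed
    (|r| capped below 1), averaged across events, and back-transformed.
    """
    rs: list[float] = []
    skipped = 0
    for ev in events:
        n_bins = int(np.floor(ev.duration_s / bin_s))
        if n_bins < 2:
            skipped += 1
            continue
        edges = ev.t_start_s + bin_s * np.arange(n_bins + 1)
        ca = np.diff(np.searchsorted(train_a.spike_times_s, edges))
        cb = np.diff(np.searchsorted(train_b.spike_times_s, edges))
        if ca.std() == 0 or cb.std() == 0:
            skipped += 1
            continue
        r = float(np.corrcoef(ca, cb)[0, 1])
        rs.append(r)
    behaviour = events[0].behaviour if events else ""
    if not rs:
        return PairSync(train_a.unit_id, train_b.unit_id, behaviour, [], float("nan"), float("nan"), skipped)
    z = np.arctanh(np.clip(rs, -r_cap, r_cap))
    mean_z = float(z.mean())
    return PairSync(
        train_a.unit_id, train_b.unit_id, behaviour, rs, mean_z, float(np.tanh(mean_z)), skipped
    )


@dataclass
class PlaybackResponse:
    unit_id: str
    per_call: list[float]
    mean: float
    n_skipped: int


def playback_response(
    train: SpikeTrain,
    call_onsets: Sequence[float],
    call_s: float = 1.0,
    baseline_s: float = 1.0,
) -> PlaybackResponse:
    """Per-call firing rate in the 1-s call window normalized to the 1-s
    pre-call baseline; calls with a silent baseline are skipped (counted)."""
    t = train.spike_times_s
    ratios: list[float] = []
    skipped = 0
    for c in call_onsets:
        n_call = _count(t, c, c + call_s) / call_s
        n_base = _count(t, c - baseline_s, c) / baseline_s
        if n_base == 0:
            skipped += 1
            continue
        ratios.append(n_call / n_base)
    mean = float(np.mean(ratios)) if ratios else float("nan")
    return PlaybackResponse(train.unit_id, ratios, mean, skipped)


def population_trial_modulation(
    trains: Sequence[SpikeTrain],
    trial_events: Sequence[EthogramEvent],
    baseline_rule: str = "fixed_10s",
) -> np.ndarray:
    """Population-average modulation per trial: for each trial event, the
    mean across units of the per-unit modulation index."""
    if not trains:
        raise ValueError("at least one unit required")
    if not trial_events:
        raise ValueError("no trials")
    out = np.empty(len(trial_events))
    for j, ev in enumerate(trial_events):
        ms = [
            modulation_index(event_aligned_rates(tr, ev, baseline_rule=baseline_rule))
            for tr in trains
        ]
        out[j] = float(np.mean(ms))
    return out
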