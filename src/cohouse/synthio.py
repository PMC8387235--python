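"""Synthetic cage-session generator with known ground truth.

Emulates a continuous co-housing recording in an 80 x 40 cm home cage with a
~10 cm-radius nest: dam and virgin centroid trajectories (mean-reverting
random walks with scripted chase, nest-visit and spontaneous-retrieval
episodes), inhomogeneous-Poisson spike populations with labelled modulated
and light-tagged units, optical-tagging sessions, photometry traces with
call-evoked calcium transients, and multi-day retrieval-learning cohorts
with censoring.  Every generator is deterministic given the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .ethogram import EthogramEvent, NestRegion, RetrievalSession, ShepherdingEvent, Trajectory
from .photom import PhotometryTrace, calcium_kernel
from .spikekit import SpikeTrain


def _default_event_rates() -> dict[str, float]:
    # chases a few times per hour (shepherding occurs hundreds of times over
    # days of co-housing); dams drop-and-retrieve pups about once every two
    # hours; virgins visit the nest several times per hour
    return {"chase": 3.0, "nest_visit": 6.0, "dam_retrieval": 0.5}


def _default_cohort() -> dict[str, tuple[int, float]]:
    # observer cohorts sized like the four observation conditions, with
    # per-day learning hazards solved from the fraction ever retrieving
    # across four daily sessions: 11/15, 12/19, 2/18 and 3/10
    return {
        "no_barrier": (15, 0.2813),
        "transparent": (19, 0.2208),
        "opaque": (18, 0.0290),
        "oxtr_ko": (10, 0.0853),
    }


@dataclass
class SimConfig:
    """Study-condition parameters for all synthetic generators."""

    seed: int = 0
    cage_size_cm: tuple[float, float] = (80.0, 40.0)
    nest_center_cm: tuple[float, float] = (15.0, 15.0)
    nest_radius_cm: float = 10.0
    session_hours: float = 2.0
    traj_fs_hz: float = 5.0
    event_rates_per_h: dict[str, float] = field(default_factory=_default_event_rates)
    frac_nest_directed_chases: float = 0.8
    chase_speed_cm_s: tuple[float, float] = (20.0, 30.0)

    n_units: int = 20
    frac_modulated: float = 0.3
    frac_suppressed: float = 0.25  # fraction of modulated units suppressed
    frac_tagged: float = 0.1
    baseline_rate_range_hz: tuple[float, float] = (1.0, 10.0)  # log-uniform
    modulation_gain: float = 3.0

    tag_reliability: float = 0.9
    tag_latency_ms: float = 2.0
    tag_pulse_hz: float = 2.0  # 5-ms pulses at 2 (or 5) Hz
    tag_n_pulses: int = 100

    calcium_tau_rise_s: float = 0.2
    calcium_tau_decay_s: float = 1.5
    transient_amplitude: float = 0.5
    photometry_f0: float = 1.0
    drift_amplitude: float = 0.02
    noise_sd: float = 0.02
    carrier_hz: float = 400.0
    lowpass_hz: float = 20.0

    n_days: int = 4
    n_trials: int = 10
    cohort: dict[str, tuple[int, float]] = field(default_factory=_default_cohort)

    def __post_init__(self) -> None:
        w, h = self.cage_size_cm
        cx, cy = self.nest_center_cm
        r = self.nest_radius_cm
        if r <= 0 or w <= 0 or h <= 0:
            raise ValueError("cage and nest dimensions must be positive")
        if not (r <= cx <= w - r and r <= cy <= h - r):
            raise ValueError("nest circle must lie inside the cage")
        if any(v < 0 for v in self.event_rates_per_h.values()):
            raise ValueError("event rates must be non-negative")
        for name in ("frac_nest_directed_chases", "frac_modulated", "frac_suppressed",
                     "frac_tagged", "tag_reliability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.baseline_rate_range_hz[0] <= 0:
            raise ValueError("baseline rates must be positive")

    @property
    def session_s(self) -> float:
        return self.session_hours * 3600.0

    @property
    def nest(self) -> NestRegion:
        return NestRegion(self.nest_center_cm, self.nest_radius_cm)


@dataclass
class GroundTruthUnits:
    """Per-unit generating parameters persisted with the dataset."""

    table: pd.DataFrame  # unit_id, baseline_hz, behaviour, gain, direction, is_tagged

    def modulated(self, behaviour: str | None = None, direction: str | None = None) -> list[str]:
        df = self.table[self.table["gain"] != 1.0]
        if behaviour is not None:
            df = df[df["behaviour"] == behaviour]
        if direction is not None:
            df = df[df["direction"] == direction]
        return df["unit_id"].tolist()

    def tagged(self) -> list[str]:
        return self.table[self.table["is_tagged"]]["unit_id"].tolist()


@dataclass
class CageSession:
    trajectories: dict[str, Trajectory]
    nest: NestRegion
    events: list[EthogramEvent]
    truth: dict


def _ou_walk(rng, n: int, fs: float, mean_xy, bounds, theta=0.25, sigma=2.0):
    """Mean-reverting random walk clipped to cage bounds (exact AR(1))."""
    dt = 1.0 / fs
    a = np.exp(-theta * dt)
    sd_eq = sigma / np.sqrt(2.0 * theta)
    out = np.empty((n, 2))
    for d in range(2):
        eps = rng.normal(0.0, sd_eq * np.sqrt(1.0 - a * a), size=n)
        x = lfilter([1.0], [1.0, -a], eps, zi=[a * rng.normal(0.0, sd_eq)])[0]
        out[:, d] = mean_xy[d] + x
    np.clip(out[:, 0], bounds[0][0], bounds[0][1], out=out[:, 0])
    np.clip(out[:, 1], bounds[1][0], bounds[1][1], out=out[:, 1])
    return out


def _point_at_distance(rng, center, dist, w, h, margin=2.0, max_tries=200):
    """Random point at a given distance from ``center`` inside the cage."""
    for _ in range(max_tries):
        ang = rng.uniform(0.0, 2.0 * np.pi)
        p = np.array([center[0] + dist * np.cos(ang), center[1] + dist * np.sin(ang)])
        if margin <= p[0] <= w - margin and margin <= p[1] <= h - margin:
            return p
    raise RuntimeError("could not place point inside cage")


def gen_cage_session(config: SimConfig) -> CageSession:
    """Simulate one co-housing session.

    Returns dam and virgin trajectories, the nest region, the ground-truth
    event log (chases with nest-directed flags, shepherding, nest entries,
    pup drops, dam retrievals, pup-call bouts), and a truth record holding
    the scripted shepherding geometry.
    """
    rng = np.random.default_rng([config.seed, 0])
    fs = config.traj_fs_hz
    T = config.session_s
    n = int(round(T * fs)) + 1
    t = np.arange(n) / fs
    w, h = config.cage_size_cm
    nest = config.nest
    nc = np.asarray(config.nest_center_cm)
    # farthest reachable distance from the nest center inside the cage
    max_d = max(
        np.hypot(*(np.array([w, h]) - nc)), np.hypot(*nc), np.hypot(w - nc[0], nc[1]),
        np.hypot(nc[0], h - nc[1]),
    )

    # ---- schedule scripted episodes ---------------------------------------
    rates = config.event_rates_per_h
    proposals: list[tuple[float, float, str, dict]] = []

    n_chase = rng.poisson(rates.get("chase", 0.0) * config.session_hours)
    for _ in range(n_chase):
        t0 = rng.uniform(60.0, max(T - 60.0, 61.0))
        nest_directed = rng.random() < config.frac_nest_directed_chases
        d_start = rng.uniform(*sorted((20.0, max(21.0, min(35.0, max_d - 4.0)))))
        if nest_directed:
            d_end = rng.uniform(2.0, d_start - 10.0)
        else:
            d_end = rng.uniform(d_start + 5.0, d_start + 15.0)
        speed = rng.uniform(*config.chase_speed_cm_s)
        start = _point_at_distance(rng, nc, d_start, w, h)
        # chases cover ground: resample the end point until the run is long
        # enough to span several trajectory samples
        for _ in range(100):
            end = _point_at_distance(rng, nc, min(d_end, max_d - 4.0), w, h)
            if np.hypot(*(end - start)) >= 25.0:
                break
        # at least ~6 trajectory samples so the run is resolvable at traj_fs
        dur = float(max(np.hypot(*(end - start)) / speed, 1.2))
        proposals.append((t0, dur, "chase", {
            "start": start, "end": end, "nest_directed": nest_directed,
        }))

    n_visit = rng.poisson(rates.get("nest_visit", 0.0) * config.session_hours)
    for _ in range(n_visit):
        t0 = rng.uniform(60.0, max(T - 120.0, 61.0))
        dwell = rng.uniform(10.0, 40.0)
        a_in = rng.uniform(0, 2 * np.pi)
        a_out = rng.uniform(0, 2 * np.pi)
        proposals.append((t0, 2.0 + dwell + 2.0, "nest_visit", {
            "dwell": dwell, "angle_in": a_in, "angle_out": a_out,
        }))

    n_retr = rng.poisson(rates.get("dam_retrieval", 0.0) * config.session_hours)
    for _ in range(n_retr):
        t0 = rng.uniform(60.0, max(T - 120.0, 61.0))
        dist = rng.uniform(15.0, min(30.0, max_d - 4.0))
        drop = _point_at_distance(rng, nc, dist, w, h)
        out_dur = dist / 15.0
        back_dur = dist / 12.0
        proposals.append((t0, out_dur + 1.0 + back_dur, "dam_retrieval", {
            "drop": drop, "out_dur": out_dur, "back_dur": back_dur,
        }))

    # greedy non-overlap with a 15-s guard band (room for 10-s baselines)
    proposals.sort(key=lambda p: p[0])
    scripted: list[tuple[float, float, str, dict]] = []
    prev_end = 0.0
    for t0, dur, kind, info in proposals:
        if t0 >= prev_end + 15.0 and t0 + dur <= T - 10.0:
            scripted.append((t0, dur, kind, info))
            prev_end = t0 + dur

    # ---- trajectories ------------------------------------------------------
    bounds = ((1.0, w - 1.0), (1.0, h - 1.0))
    center = (w / 2.0, h / 2.0)
    free = {
        "dam": _ou_walk(rng, n, fs, center, bounds),
        "virgin": _ou_walk(rng, n, fs, center, bounds),
    }
    overrides: dict[str, list[tuple[int, int, np.ndarray]]] = {"dam": [], "virgin": []}
    events: list[EthogramEvent] = []
    shepherding: list[ShepherdingEvent] = []

    r = config.nest_radius_cm
    for t0, dur, kind, info in scripted:
        i0 = int(round(t0 * fs))
        if kind == "chase":
            n_seg = max(int(round(dur * fs)), 3)
            i1 = i0 + n_seg
            u = np.linspace(0.0, 1.0, n_seg + 1)[:, None]
            v_path = info["start"][None, :] * (1 - u) + info["end"][None, :] * u
            dirv = info["end"] - info["start"]
            dirv = dirv / np.hypot(*dirv)
            d_path = np.clip(v_path - 4.0 * dirv[None, :], [1.0, 1.0], [w - 1.0, h - 1.0])
            overrides["virgin"].append((i0, i1, v_path))
            overrides["dam"].append((i0, i1, d_path))
            ta, tb = i0 / fs, i1 / fs
            d0 = float(np.hypot(*(v_path[0] - nc)))
            d1 = float(np.hypot(*(v_path[-1] - nc)))
            events.append(EthogramEvent("dam", "chase", ta, tb, {
                "nest_directed": bool(info["nest_directed"]),
                "d_start_cm": d0, "d_end_cm": d1,
            }))
            if d0 > d1:
                events.append(EthogramEvent("dam", "shepherding", ta, tb))
                shepherding.append(ShepherdingEvent(ta, tb, d0, d1))
        elif kind == "nest_visit":
            p_in = nc + (r + 4.0) * np.array([np.cos(info["angle_in"]), np.sin(info["angle_in"])])
            p_out = nc + (r + 4.0) * np.array([np.cos(info["angle_out"]), np.sin(info["angle_out"])])
            p_in = np.clip(p_in, [1.0, 1.0], [w - 1.0, h - 1.0])
            p_out = np.clip(p_out, [1.0, 1.0], [w - 1.0, h - 1.0])
            n_ramp = max(int(round(2.0 * fs)), 2)
            n_dwell = max(int(round(info["dwell"] * fs)), 1)
            u = np.linspace(0.0, 1.0, n_ramp + 1)[:, None]
            seg_in = p_in[None, :] * (1 - u) + nc[None, :] * u
            jitter = rng.normal(0.0, 0.3, size=(n_dwell, 2))
            seg_dwell = nc[None, :] + np.clip(jitter, -r / 2, r / 2)
            seg_out = nc[None, :] * (1 - u) + p_out[None, :] * u
            path = np.vstack([seg_in, seg_dwell, seg_out[1:]])
            i1 = i0 + path.shape[0] - 1
            overrides["virgin"].append((i0, i1, path))
            # radial crossings of the entry/exit ramps (distance linear in u)
            din = float(np.hypot(*(p_in - nc)))
            dout = float(np.hypot(*(p_out - nc)))
            tc_in = i0 / fs + 2.0 * (din - r) / din
            t_exit0 = (i0 + n_ramp + n_dwell) / fs
            tc_out = t_exit0 + 2.0 * (r / dout)
            events.append(EthogramEvent("virgin", "nest_entry", tc_in, tc_out))
        elif kind == "dam_retrieval":
            n_out = max(int(round(info["out_dur"] * fs)), 2)
            n_pause = max(int(round(1.0 * fs)), 1)
            n_back = max(int(round(info["back_dur"] * fs)), 2)
            u1 = np.linspace(0.0, 1.0, n_out + 1)[:, None]
            u2 = np.linspace(0.0, 1.0, n_back + 1)[:, None]
            drop = info["drop"]
            seg_out = nc[None, :] * (1 - u1) + drop[None, :] * u1
            seg_pause = np.repeat(drop[None, :], n_pause, axis=0)
            seg_back = drop[None, :] * (1 - u2) + nc[None, :] * u2
            path = np.vstack([seg_out, seg_pause, seg_back[1:]])
            i1 = i0 + path.shape[0] - 1
            overrides["dam"].append((i0, i1, path))
            t_drop = (i0 + n_out) / fs
            t_pick = (i0 + n_out + n_pause) / fs
            t_done = i1 / fs
            events.append(EthogramEvent("dam", "pup_drop", t_drop, t_drop))
            events.append(EthogramEvent("dam", "dam_retrieval", t_pick, t_done))
            events.append(EthogramEvent("pup", "pup_call_bout", t_drop, t_done))

    trajectories: dict[str, Trajectory] = {}
    for animal in ("dam", "virgin"):
        base = free[animal]
        xy = base.copy()
        segs = sorted(overrides[animal], key=lambda s: s[0])
        # paste scripted paths, then bridge the free walk between fixed points
        anchors: list[tuple[int, np.ndarray]] = []
        for i0, i1, path in segs:
            i1 = min(i1, n - 1)
            xy[i0 : i0 + path.shape[0]] = path[: max(0, n - i0)]
            anchors.append((i0, path[0]))
            anchors.append((i1, path[min(path.shape[0], n - i0) - 1]))
        # bridge each gap so the free walk meets the scripted endpoints; the
        # linear correction adds only a slow drift over multi-second gaps
        fixed = [(0, None)] + [(i, p) for i, p in anchors] + [(n - 1, None)]
        for k in range(0, len(fixed) - 1, 2):
            g0, p0 = fixed[k]
            g1, p1 = fixed[k + 1]
            if g1 <= g0 + 1:
                continue
            i = np.arange(g0 + 1, g1)
            uu = (i - g0) / (g1 - g0)
            corr0 = (p0 - base[g0]) if p0 is not None else np.zeros(2)
            corr1 = (p1 - base[g1]) if p1 is not None else np.zeros(2)
            xy[i] = base[i] + np.outer(1 - uu, corr0) + np.outer(uu, corr1)
        np.clip(xy[:, 0], 0.0, w, out=xy[:, 0])
        np.clip(xy[:, 1], 0.0, h, out=xy[:, 1])
        trajectories[animal] = Trajectory(animal, t, xy[:, 0], xy[:, 1])

    events.sort(key=lambda e: e.t_start_s)
    truth = {
        "shepherding": shepherding,
        "n_chases": sum(1 for e in events if e.behaviour == "chase"),
        "session_s": T,
    }
    return CageSession(trajectories, nest, events, truth)


def gen_spike_population(
    config: SimConfig,
    events: Sequence[EthogramEvent],
    span: tuple[float, float] | None = None,
    behaviours: Sequence[str] = ("shepherding", "nest_entry", "dam_retrieval"),
) -> tuple[list[SpikeTrain], GroundTruthUnits]:
    """Simulate an inhomogeneous-Poisson unit population.

    Each unit fires at a log-uniform baseline rate; modulated units multiply
    their rate by the configured gain (activated) or its inverse
    (suppressed) inside the events of their assigned behaviour.
    """
    rng = np.random.default_rng([config.seed, 1])
    if span is None:
        hi = max((ev.t_end_s for ev in events), default=0.0)
        span = (0.0, max(config.session_s, hi))
    t0, t1 = span
    T = t1 - t0
    if T <= 0:
        raise ValueError("empty recording span")
    for ev in events:
        if ev.t_start_s < t0 or ev.t_end_s > t1:
            raise ValueError("event outside recording span")

    present = [b for b in behaviours if any(ev.behaviour == b for ev in events)]
    lo, hi_r = config.baseline_rate_range_hz
    n_mod = int(round(config.frac_modulated * config.n_units))
    rows = []
    trains: list[SpikeTrain] = []
    for i in range(config.n_units):
        lam = float(np.exp(rng.uniform(np.log(lo), np.log(hi_r))))
        behaviour, gain, direction = "", 1.0, "null"
        if i < n_mod and present:
            behaviour = present[i % len(present)]
            if rng.random() < config.frac_suppressed:
                gain, direction = 1.0 / config.modulation_gain, "suppressed"
            else:
                gain, direction = config.modulation_gain, "activated"
        windows = [
            (ev.t_start_s, ev.t_end_s)
            for ev in events
            if behaviour and ev.behaviour == behaviour and ev.duration_s > 0
        ]
        n_base = rng.poisson(lam * T)
        times = rng.uniform(t0, t1, size=n_base)
        if gain > 1.0:
            extra = []
            for a, b in windows:
                k = rng.poisson((gain - 1.0) * lam * (b - a))
                extra.append(rng.uniform(a, b, size=k))
            if extra:
                times = np.concatenate([times] + extra)
        elif gain < 1.0 and windows:
            ws = np.array([wdw[0] for wdw in windows])
            we = np.array([wdw[1] for wdw in windows])
            idx = np.searchsorted(ws, times, side="right") - 1
            inside = (idx >= 0) & (times < we[np.clip(idx, 0, len(we) - 1)])
            keep = ~inside | (rng.random(times.size) < gain)
            times = times[keep]
        times = np.unique(np.sort(times))
        trains.append(SpikeTrain(f"u{i:03d}", times, channel_group=f"ch{i:02d}", class_label="PVN"))
        rows.append({
            "unit_id": f"u{i:03d}", "baseline_hz": lam, "behaviour": behaviour,
            "gain": gain, "direction": direction, "is_tagged": False,
        })

    truth = pd.DataFrame(rows)
    n_tag = int(round(config.frac_tagged * config.n_units))
    tag_ids = rng.choice(config.n_units, size=n_tag, replace=False) if n_tag else []
    truth.loc[list(tag_ids), "is_tagged"] = True
    for i in tag_ids:
        trains[i].class_label = "OT-PVN"
    return trains, GroundTruthUnits(truth)


def gen_tagging_session(
    config: SimConfig, truth: GroundTruthUnits
) -> tuple[np.ndarray, list[SpikeTrain]]:
    """Simulate an optical-tagging block: 5-ms pulses at the configured rate;
    tagged units spike after each pulse with probability ``tag_reliability``
    at ~``tag_latency_ms`` latency; untagged units are unaffected."""
    rng = np.random.default_rng([config.seed, 2])
    pulses = 1.0 + np.arange(config.tag_n_pulses) / config.tag_pulse_hz
    T = float(pulses[-1]) + 1.0
    trains: list[SpikeTrain] = []
    for _, row in truth.table.iterrows():
        lam = row["baseline_hz"]
        times = rng.uniform(0.0, T, size=rng.poisson(lam * T))
        if row["is_tagged"]:
            evoked = pulses[rng.random(pulses.size) < config.tag_reliability]
            lat = np.clip(
                rng.normal(config.tag_latency_ms, 0.5, size=evoked.size), 0.2, 3.9
            )
            times = np.concatenate([times, evoked + lat / 1000.0])
        label = "OT-PVN" if row["is_tagged"] else "PVN"
        trains.append(SpikeTrain(row["unit_id"], np.unique(times), class_label=label))
    return pulses, trains


def gen_photometry(
    config: SimConfig,
    call_events: Sequence[float] | Sequence[EthogramEvent],
    duration_s: float | None = None,
    fs_hz: float | None = None,
    raw: bool = False,
    amplitudes: Sequence[float] | None = None,
    noise_sd: float | None = None,
) -> tuple[PhotometryTrace, pd.DataFrame]:
    """Simulate a fluorescence trace with call-evoked calcium transients.

    The envelope is F0 + sum_i A_i * k(t - t_i) + slow drift + Gaussian
    noise, with k a difference-of-exponentials kernel.  With ``raw=True``
    the envelope amplitude-modulates a 400-Hz sinusoidal carrier (sampling
    must exceed twice the carrier)."""
    rng = np.random.default_rng([config.seed, 3])
    onsets = np.array(
        [ev.t_start_s if isinstance(ev, EthogramEvent) else float(ev) for ev in call_events]
    )
    if fs_hz is None:
        fs_hz = 2000.0 if raw else 200.0
    if fs_hz <= 0:
        raise ValueError("sampling rate must be positive")
    if raw and fs_hz <= 2 * config.carrier_hz:
        raise ValueError("sampling must exceed twice the carrier frequency")
    if duration_s is None:
        duration_s = (float(onsets.max()) + 10.0) if onsets.size else 10.0
    nsd = config.noise_sd if noise_sd is None else noise_sd
    t = np.arange(int(round(duration_s * fs_hz))) / fs_hz
    amps = (
        np.full(onsets.size, config.transient_amplitude)
        if amplitudes is None
        else np.asarray(amplitudes, dtype=float)
    )
    env = np.full(t.size, config.photometry_f0)
    for t_i, a_i in zip(onsets, amps):
        env += a_i * calcium_kernel(t - t_i, config.calcium_tau_rise_s, config.calcium_tau_decay_s)
    if config.drift_amplitude:
        env += config.drift_amplitude * np.sin(2 * np.pi * t / 300.0)  # slow drift
    if nsd > 0:
        env += rng.normal(0.0, nsd, size=t.size)
    if raw:
        sig = env * np.sin(2 * np.pi * config.carrier_hz * t)
        trace = PhotometryTrace(t, sig, fs_hz, stage="raw_modulated")
    else:
        trace = PhotometryTrace(t, env, fs_hz, stage="demodulated")
    truth = pd.DataFrame({"t_s": onsets, "amplitude": amps})
    return trace, truth


def gen_learning_cohort(config: SimConfig) -> list[RetrievalSession]:
    """Simulate multi-day retrieval-learning cohorts with censoring.

    Each subject draws a latent learning day from its condition's per-day
    hazard; sessions before it score 0/10 (naive virgins ignore isolated
    pups), while sessions from the learning day on succeed on most trials
    (at least two, so the onset rules recover the latent day exactly).
    Subjects that never learn within the observation window are censored.
    """
    rng = np.random.default_rng([config.seed, 4])
    sessions: list[RetrievalSession] = []
    for condition, (n_subj, hazard) in config.cohort.items():
        hazards = [hazard] * config.n_days if np.isscalar(hazard) else list(hazard)
        if any(not 0.0 <= hz <= 1.0 for hz in hazards):
            raise ValueError("per-day hazards must lie in [0, 1]")
        for s in range(n_subj):
            subject = f"{condition}_{s:02d}"
            learn_day: int | None = None
            for d, hz in enumerate(hazards, start=1):
                if rng.random() < hz:
                    learn_day = d
                    break
            for d in range(1, config.n_days + 1):
                if learn_day is None or d < learn_day:
                    succ = [False] * config.n_trials
                else:
                    k = 2 + int(rng.binomial(config.n_trials - 2, 0.75))
                    pos = rng.choice(config.n_trials, size=k, replace=False)
                    succ = [i in set(pos.tolist()) for i in range(config.n_trials)]
                lats = [float(l) for l in rng.uniform(5.0, 110.0, size=sum(succ))]
                sessions.append(RetrievalSession(subject, condition, d, succ, lats))
    return sessions
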