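"""Fibre-photometry processing and joint spike-photometry analysis.

The raw signal is a 400-Hz amplitude-modulated carrier (sinusoidal
excitation); lock-in (quadrature) demodulation followed by a zero-phase
20-Hz low-pass recovers the fluorescence envelope.  Trial responses are
dF/F relative to the median of a 1-s pre-interval baseline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .ethogram import EthogramEvent


@dataclass
class PhotometryTrace:
    """Uniformly sampled fluorescence trace."""

    t_s: np.ndarray
    signal: np.ndarray
    fs_hz: float
    stage: str = "demodulated"  # raw_modulated | demodulated | dff

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.t_s.shape != self.signal.shape:
            raise ValueError("t and signal must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def span(self) -> tuple[float, float]:
        return float(self.t_s[0]), float(self.t_s[-1])


@dataclass
class TrialResponse:
    trial: int
    interval: tuple[float, float]
    dff_mean: float
    ok: bool = True


def demodulate_lockin(
    raw: PhotometryTrace, f_ref_hz: float = 400.0, cutoff_hz: float = 20.0
) -> PhotometryTrace:
    """Quadrature demodulation at the excitation frequency followed by a
    zero-phase low-pass at ``cutoff_hz``; returns the recovered envelope."""
    if raw.stage != "raw_modulated":
        raise ValueError("input must be a raw modulated trace")
    if raw.fs_hz <= 2.0 * f_ref_hz:
        raise ValueError("sampling rate must exceed twice the carrier frequency")
    w = 2.0 * np.pi * f_ref_hz * raw.t_s
    i = 2.0 * raw.signal * np.sin(w)
    q = 2.0 * raw.signal * np.cos(w)
    b, a = signal.butter(4, cutoff_hz / (raw.fs_hz / 2.0))
    i_f = signal.filtfilt(b, a, i)
    q_f = signal.filtfilt(b, a, q)
    env = np.hypot(i_f, q_f)
    return PhotometryTrace(raw.t_s, env, raw.fs_hz, stage="demodulated")


def dff(
    trace: PhotometryTrace,
    interval: tuple[float, float],
    baseline_s: float = 1.0,
    trial: int = 0,
) -> TrialResponse:
    """Mean dF/F over an interval, with F0 the median of the ``baseline_s``
    window immediately preceding it; flagged not-ok when F0 <= 0."""
    lo, hi = trace.span
    a, b = interval
    if not (lo <= a - baseline_s and b <= hi and b > a):
        raise ValueError("interval/baseline outside trace span")
    t = trace.t_s
    base = trace.signal[(t >= a - baseline_s) & (t < a)]
    seg = trace.signal[(t >= a) & (t < b)]
    f0 = float(np.median(base))
    if f0 <= 0 or seg.size == 0:
        return TrialResponse(trial, interval, float("nan"), ok=False)
    return TrialResponse(trial, interval, float(np.mean((seg - f0) / f0)), ok=True)


def call_responses(
    trace: PhotometryTrace,
    call_events: Sequence[EthogramEvent],
    day_length_s: float = 86400.0,
) -> tuple[list[TrialResponse], pd.DataFrame]:
    """Per-call dF/F plus daily means (day index from event onset)."""
    out: list[TrialResponse] = []
    rows = []
    for i, ev in enumerate(sorted(call_events, key=lambda e: e.t_start_s)):
        tr = dff(trace, (ev.t_start_s, ev.t_end_s), trial=i)
        out.append(tr)
        rows.append(
            {"trial": i, "day": int(ev.t_start_s // day_length_s) + 1, "dff": tr.dff_mean, "ok": tr.ok}
        )
    df = pd.DataFrame(rows)
    daily = (
        df[df["ok"]].groupby("day")["dff"].mean().rename("dff_mean").reset_index()
        if len(df)
        else pd.DataFrame(columns=["day", "dff_mean"])
    )
    return out, daily


def align_daily_to_onset(daily: pd.DataFrame, onset_day: int) -> pd.DataFrame:
    """Re-index daily means relative to a subject's retrieval-onset day
    (rel_day 0 = onset)."""
    out = daily.copy()
    out["rel_day"] = out["day"] - onset_day
    return out


def joint_trial_correlation(
    pvn_trial_mod: Sequence[float], cortex_trial_dff: Sequence[float]
) -> tuple[float, float]:
    """Pearson correlation (r, two-sided p) between single-trial population
    spike modulation and single-trial cortical dF/F across paired trials."""
    x = np.asarray(pvn_trial_mod, dtype=float)
    y = np.asarray(cortex_trial_dff, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("paired trials with n >= 3 required")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def calcium_kernel(
    t: np.ndarray, tau_rise_s: float = 0.2, tau_decay_s: float = 1.5
) -> np.ndarray:
    """Difference-of-exponentials calcium kernel, normalized to unit peak
    (GCaMP6s-like: 0.2-s rise, 1.5-s decay)."""
    t = np.asarray(t, dtype=float)
    tp = np.where(t >= 0, t, 0.0)
    k = np.where(t >= 0, np.exp(-tp / tau_decay_s) - np.exp(-tp / tau_rise_s), 0.0)
    t_peak = (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s) * np.log(tau_decay_s / tau_rise_s)
    )
    peak = np.exp(-t_peak / tau_decay_s) - np.exp(-t_peak / tau_rise_s)
    return k / peak
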