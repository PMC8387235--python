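import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from cohouse.ethogram import EthogramEvent
from cohouse.spikekit import SpikeTrain


@pytest.fixture
def rng():
    return np.random.default_rng(123)


def make_events(n, dur_s=5.0, gap_s=55.0, behaviour="shepherding", t0=60.0, actor="dam"):
    """Regularly spaced behavioural events for alignment tests."""
    out = []
    t = t0
    for _ in range(n):
        out.append(EthogramEvent(actor, behaviour, t, t + dur_s))
        t += dur_s + gap_s
    return out


def poisson_train(rng, rate_hz, duration_s, unit_id="u", events=None, gain=1.0):
    """Homogeneous Poisson train, optionally rate-modulated inside events."""
    n = rng.poisson(rate_hz * duration_s)
    t = rng.uniform(0.0, duration_s, size=n)
    if events is not None and gain > 1.0:
        extra = [
            rng.uniform(ev.t_start_s, ev.t_end_s, size=rng.poisson((gain - 1.0) * rate_hz * ev.duration_s))
            for ev in events
        ]
        t = np.concatenate([t] + extra)
    elif events is not None and gain < 1.0:
        keep = np.ones(t.size, bool)
        for ev in events:
            inside = (t >= ev.t_start_s) & (t < ev.t_end_s)
            keep &= ~inside | (rng.random(t.size) < gain)
        t = t[keep]
    return SpikeTrain(unit_id, np.unique(t))
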