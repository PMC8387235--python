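"""Spike-train statistics: QC, tagging, modulation, PSTH, synchrony."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cohouse import spikekit
from cohouse.ethogram import EthogramEvent
from cohouse.spikekit import (
    AlignedRates,
    ModulationResult,
    SpikeTrain,
    event_aligned_rates,
    fdr_flags,
    modulation_index,
    pair_zero_lag_sync,
    playback_response,
    population_trial_modulation,
    psth_zscore,
    qc_spike_trains,
    shuffle_null_test,
    tag_unit,
)

from conftest import make_events, poisson_train


class TestQC:
    def test_refractory_pair_drops_later_spike(self):
        tr = SpikeTrain("u", np.array([1.000, 1.001, 1.006]), channel_group="ch0")
        out, rep = qc_spike_trains([tr], refractory_ms=2.0)
        assert len(out[0]) == 2
        assert rep.n_refractory_removed["u"] == 1

    def test_coincident_artifact_across_channels_removed(self):
        trains = [
            SpikeTrain(f"u{i}", np.array([5.0, 10.0 + i]), channel_group=f"ch{i}")
            for i in range(12)
        ]
        out, rep = qc_spike_trains(trains)
        for tr in out:
            assert 5.0 not in tr.spike_times_s
        assert sum(rep.n_coincident_removed.values()) == 12

    def test_clean_poisson_removal_rate_matches_expectation(self, rng):
        lam, T = 5.0, 2000.0
        tr = poisson_train(rng, lam, T, unit_id="u")
        tr.channel_group = "ch0"
        out, rep = qc_spike_trains([tr], refractory_ms=2.0)
        n = len(tr)
        expected = n * lam * 0.002  # P(next spike within 2 ms) ~ lam*dt
        removed = rep.n_refractory_removed["u"]
        assert abs(removed - expected) < 4 * np.sqrt(expected)


class TestTagging:
    def test_perfect_unit_tagged(self):
        pulses = np.arange(50) * 0.5 + 1.0
        tr = SpikeTrain("u", pulses + 0.002)
        res = tag_unit(tr, pulses)
        assert res.reliability == 1.0
        assert res.is_tagged
        assert res.median_latency_ms == pytest.approx(2.0)

    def test_sixty_percent_not_tagged(self):
        pulses = np.arange(50) * 0.5 + 1.0
        tr = SpikeTrain("u", pulses[:30] + 0.002)
        res = tag_unit(tr, pulses)
        assert res.reliability == pytest.approx(0.6)
        assert not res.is_tagged

    def test_boundary_reliability_and_latency(self):
        pulses = np.arange(20, dtype=float)
        # exactly 70% of pulses answered, at exactly 4 ms: both thresholds inclusive
        tr = SpikeTrain("u", pulses[:14] + 0.004)
        res = tag_unit(tr, pulses)
        assert res.reliability == pytest.approx(0.7)
        assert res.is_tagged
        just_under = SpikeTrain("u", pulses[:13] + 0.004)
        assert not tag_unit(just_under, pulses).is_tagged

    def test_untagged_poisson_reliability_near_closed_form(self, rng):
        lam = 5.0
        pulses = np.arange(100) * 0.5 + 1.0
        tr = poisson_train(rng, lam, 60.0)
        res = tag_unit(tr, pulses)
        # P(spike in 4 ms) = 1 - exp(-lam * 0.004) ~ 0.02
        assert res.reliability < 0.15
        assert not res.is_tagged

    def test_zero_pulses_error(self):
        with pytest.raises(ValueError):
            tag_unit(SpikeTrain("u", np.array([1.0])), [])

    def test_threshold_monotone(self, rng):
        pulses = np.arange(40) * 0.5 + 1.0
        tr = SpikeTrain("u", pulses[::2] + 0.003)  # 50% reliability
        for lo, hi in [(0.3, 0.5), (0.5, 0.7), (0.4, 0.9)]:
            tagged_hi = tag_unit(tr, pulses, reliability_min=hi).is_tagged
            tagged_lo = tag_unit(tr, pulses, reliability_min=lo).is_tagged
            assert not (tagged_hi and not tagged_lo)


class TestAlignedRates:
    def test_rate_arithmetic(self):
        t = np.linspace(10.01, 14.99, 10)
        tr = SpikeTrain("u", t)
        ev = EthogramEvent("dam", "shepherding", 10.0, 15.0)
        rates = event_aligned_rates(tr, ev)
        assert rates.rate_behaviour_hz == pytest.approx(2.0)
        assert rates.baseline_rule == "fixed_10s"

    def test_nest_entry_capped_at_forty_seconds(self):
        tr = SpikeTrain("u", np.array([50.0]))
        ev = EthogramEvent("virgin", "nest_entry", 10.0, 110.0)
        rates = event_aligned_rates(tr, ev)
        assert rates.duration_s == 40.0
        assert rates.baseline_rule == "equal_preceding"

    def test_empty_train_zero_rates(self):
        tr = SpikeTrain("u", np.array([]))
        ev = EthogramEvent("dam", "shepherding", 20.0, 25.0)
        rates = event_aligned_rates(tr, ev)
        assert rates.rate_behaviour_hz == 0.0
        assert modulation_index(rates) == 0.0


class TestModulationIndex:
    def test_known_values(self):
        assert modulation_index((10.0, 5.0)) == pytest.approx(100.0 / 3.0)
        assert modulation_index((3.0, 3.0)) == 0.0
        assert modulation_index((2.5, 0.0)) == 100.0
        assert modulation_index((0.0, 2.5)) == -100.0

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            modulation_index((-1.0, 2.0))

    @settings(deadline=None, max_examples=200)
    @given(
        a=st.floats(0, 1e3, allow_nan=False),
        b=st.floats(0, 1e3, allow_nan=False),
    )
    def test_antisymmetric_and_bounded(self, a, b):
        m = modulation_index((a, b))
        assert -100.0 <= m <= 100.0
        assert m == pytest.approx(-modulation_index((b, a)), abs=1e-9)


class TestShuffleNull:
    def test_strong_activation_saturates_p(self, rng):
        events = make_events(50, gap_s=50.0)
        tr = poisson_train(rng, 3.0, 3000.0, events=events, gain=4.0)
        res = shuffle_null_test(tr, events, span=(0.0, 3000.0), rng=1)
        assert res.p_act == pytest.approx(1.0 / 1001.0)
        assert res.M > 30.0

    def test_suppression_detected_on_other_side(self, rng):
        events = make_events(50, gap_s=50.0)
        tr = poisson_train(rng, 6.0, 3000.0, events=events, gain=0.2)
        res = shuffle_null_test(tr, events, span=(0.0, 3000.0), rng=1)
        assert res.p_sup == pytest.approx(1.0 / 1001.0)
        assert res.M < -30.0

    def test_seed_reproducibility(self, rng):
        events = make_events(20)
        tr = poisson_train(rng, 3.0, 3000.0)
        a = shuffle_null_test(tr, events, span=(0.0, 3000.0), rng=42)
        b = shuffle_null_test(tr, events, span=(0.0, 3000.0), rng=42)
        assert (a.p_act, a.p_sup, a.M) == (b.p_act, b.p_sup, b.M)

    def test_no_events_error(self, rng):
        tr = poisson_train(rng, 3.0, 100.0)
        with pytest.raises(ValueError):
            shuffle_null_test(tr, [], span=(0.0, 100.0))


def _mk_result(uid, p_act, p_sup, family="f"):
    r = ModulationResult(uid, "shepherding", 0.0, p_act, p_sup, 10, family=family)
    return r


class TestFDR:
    def test_all_null_nothing_flagged(self):
        results = fdr_flags([_mk_result(f"u{i}", 1.0, 1.0) for i in range(20)])
        assert all(r.direction == "ns" for r in results)

    def test_step_up_matches_oracle(self):
        # 10 strong activations among 90 nulls at q=0.05
        results = [_mk_result(f"s{i}", 0.0005, 1.0) for i in range(10)]
        results += [_mk_result(f"n{i}", 0.5, 0.5) for i in range(90)]
        flagged = {r.unit_id for r in fdr_flags(results) if r.direction != "ns"}
        # Benjamini-Hochberg step-up computed longhand
        ps = sorted([min(1.0, 2 * min(r.p_act, r.p_sup)) for r in results])
        m = len(ps)
        k = max((i + 1 for i in range(m) if ps[i] <= 0.05 * (i + 1) / m), default=0)
        assert k == 10
        assert flagged == {f"s{i}" for i in range(10)}
        assert all(r.direction == "activated" for r in fdr_flags(results) if r.unit_id in flagged)

    def test_flags_monotone_in_q(self):
        results = [_mk_result(f"u{i}", p, 1.0) for i, p in enumerate([0.001, 0.01, 0.02, 0.2, 0.8])]
        n_flagged = []
        for q in (0.01, 0.05, 0.1, 0.3):
            flags = fdr_flags([_mk_result(r.unit_id, r.p_act, r.p_sup) for r in results], q=q)
            n_flagged.append(sum(f.direction != "ns" for f in flags))
        assert n_flagged == sorted(n_flagged)

    def test_families_corrected_separately(self):
        a = [_mk_result(f"a{i}", 0.001, 1.0, family="A") for i in range(5)]
        b = [_mk_result(f"b{i}", 1.0, 1.0, family="B") for i in range(5)]
        out = fdr_flags(a + b)
        assert all(r.direction == "activated" for r in out if r.family == "A")
        assert all(r.direction == "ns" for r in out if r.family == "B")


class TestPSTH:
    def test_bin_count_matches_window(self, rng):
        events = make_events(5, behaviour="nest_entry")
        tr = poisson_train(rng, 5.0, 500.0)
        p = psth_zscore(tr, events)
        assert p.z.size == int((40 - (-20)) / 0.25)
        p2 = psth_zscore(tr, make_events(5, behaviour="shepherding"))
        assert p2.z.size == int((20 - (-10)) / 0.25)

    def test_homogeneous_poisson_mean_z_near_zero(self, rng):
        events = make_events(40, dur_s=5.0, gap_s=60.0)
        tr = poisson_train(rng, 8.0, 3000.0)
        p = psth_zscore(tr, events, window=(-10.0, 20.0))
        post = p.z[p.bin_edges_s[1:] > 0]
        assert abs(np.nanmean(post)) < 1.0

    def test_rate_step_raises_post_bins(self, rng):
        events = make_events(40, dur_s=5.0, gap_s=60.0)
        tr = poisson_train(rng, 4.0, 3000.0, events=events, gain=3.0)
        p = psth_zscore(tr, events, window=(-10.0, 20.0))
        during = p.z[(p.bin_edges_s[1:] > 0) & (p.bin_edges_s[1:] <= 5.0)]
        assert np.nanmean(during) > 2.0
        assert np.max(p.display_z) <= 3.0

    def test_too_few_events_error(self, rng):
        tr = poisson_train(rng, 5.0, 100.0)
        with pytest.raises(ValueError):
            psth_zscore(tr, make_events(1))


class TestPairSync:
    def test_identical_trains_near_one(self, rng):
        events = make_events(10, dur_s=5.0)
        tr = poisson_train(rng, 20.0, 700.0)
        ps = pair_zero_lag_sync(tr, SpikeTrain("b", tr.spike_times_s), events)
        assert ps.r_combined > 0.99

    def test_symmetric_in_order(self, rng):
        events = make_events(10, dur_s=5.0)
        a = poisson_train(rng, 15.0, 700.0, unit_id="a")
        b = poisson_train(rng, 15.0, 700.0, unit_id="b")
        assert pair_zero_lag_sync(a, b, events).r_combined == pytest.approx(
            pair_zero_lag_sync(b, a, events).r_combined
        )

    def test_independent_trains_near_zero(self, rng):
        events = make_events(60, dur_s=8.0, gap_s=20.0)
        a = poisson_train(rng, 15.0, 2000.0, unit_id="a")
        b = poisson_train(rng, 15.0, 2000.0, unit_id="b")
        ps = pair_zero_lag_sync(a, b, events)
        assert abs(ps.r_combined) < 0.05

    def test_common_input_increases_sync(self, rng):
        events = make_events(30, dur_s=8.0, gap_s=20.0)
        shared = poisson_train(rng, 10.0, 1000.0).spike_times_s
        a = np.unique(np.concatenate([shared, poisson_train(rng, 5.0, 1000.0).spike_times_s]))
        b = np.unique(np.concatenate([shared, poisson_train(rng, 5.0, 1000.0).spike_times_s]))
        indep_a = poisson_train(rng, 15.0, 1000.0, unit_id="ia")
        indep_b = poisson_train(rng, 15.0, 1000.0, unit_id="ib")
        r_shared = pair_zero_lag_sync(SpikeTrain("a", a), SpikeTrain("b", b), events).r_combined
        r_indep = pair_zero_lag_sync(indep_a, indep_b, events).r_combined
        assert r_shared > r_indep + 0.1


class TestPlayback:
    def test_stationary_ratio_near_one(self, rng):
        calls = np.arange(100) * 20.0 + 10.0
        tr = poisson_train(rng, 10.0, 2100.0)
        res = playback_response(tr, calls)
        assert res.mean == pytest.approx(1.0, abs=0.25)

    def test_doubling_rate_doubles_ratio(self, rng):
        calls = np.arange(100) * 20.0 + 10.0
        events = [EthogramEvent("pup", "pup_call", c, c + 1.0) for c in calls]
        tr = poisson_train(rng, 10.0, 2100.0, events=events, gain=2.0)
        res = playback_response(tr, calls)
        assert res.mean == pytest.approx(2.0, abs=0.35)

    def test_silent_train_all_skipped(self):
        res = playback_response(SpikeTrain("u", np.array([])), [10.0, 20.0])
        assert res.n_skipped == 2 and np.isnan(res.mean)


class TestPopulationTrialModulation:
    def test_single_unit_equals_unit_index(self, rng):
        events = make_events(5, behaviour="dam_retrieval")
        tr = poisson_train(rng, 6.0, 500.0)
        pop = population_trial_modulation([tr], events)
        for j, ev in enumerate(events):
            m = modulation_index(event_aligned_rates(tr, ev, baseline_rule="fixed_10s"))
            assert pop[j] == pytest.approx(m)

    def test_order_invariant(self, rng):
        events = make_events(4, behaviour="dam_retrieval")
        trains = [poisson_train(rng, 5.0, 400.0, unit_id=f"u{i}") for i in range(3)]
        a = population_trial_modulation(trains, events)
        b = population_trial_modulation(trains[::-1], events)
        assert np.allclose(a, b)

    def test_null_population_near_zero(self, rng):
        events = make_events(10, behaviour="dam_retrieval")
        trains = [poisson_train(rng, 8.0, 800.0, unit_id=f"u{i}") for i in range(20)]
        pop = population_trial_modulation(trains, events)
        assert abs(pop.mean()) < 10.0
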