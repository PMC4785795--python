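"""Causal-pair classification, burst detection, and spike-train editing."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import ripplereplay as rr
from _oracles import bruteforce_classify, random_session
from conftest import make_train


def _spans(events):
    return [(ev.onset_s, ev.offset_s) for ev in events]


class TestDetectBursts:
    def test_three_close_spikes_form_one_burst(self):
        tr = make_train([0.0, 0.005, 0.008])
        (b,) = rr.detect_bursts(tr, burst_isi_ms=10)
        assert b.n_spikes == 3
        assert b.onset_s == 0.0

    def test_widely_spaced_spikes_form_no_burst(self):
        tr = make_train([0.0, 0.05, 0.10])
        assert rr.detect_bursts(tr, burst_isi_ms=10) == []

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=400), min_size=0,
                    max_size=40, unique=True))
    def test_matches_run_length_oracle(self, ticks):
        # spike times on a 2 ms grid; threshold 10 ms
        times = sorted(t * 0.002 for t in ticks)
        tr = make_train(times)
        got = rr.detect_bursts(tr, burst_isi_ms=10)
        # oracle: naive run grouping
        runs, cur = [], []
        for t in times:
            if cur and t - cur[-1] <= 0.010:
                cur.append(t)
            else:
                if len(cur) >= 2:
                    runs.append(tuple(cur))
                cur = [t]
        if len(cur) >= 2:
            runs.append(tuple(cur))
        assert [b.member_times_s for b in got] == runs


class TestClassifyRule:
    def setup_method(self):
        self.ripple = [rr.RippleEvent(0.0, 0.1, 10.0)]

    def test_pair_at_onset_with_10ms_lag(self):
        found = rr.classify(make_train([0.0], "CA3"), make_train([0.010]),
                            self.ripple)
        assert len(found) == 1
        ev = found[0]
        assert ev.lag_ms == pytest.approx(10.0)
        assert ev.phase == pytest.approx(0.0)
        assert ev.ripple_index == 0

    def test_anticausal_order_excluded(self):
        found = rr.classify(make_train([0.020], "CA3"), make_train([0.010]),
                            self.ripple)
        assert found == []

    def test_lag_exactly_30ms_excluded(self):
        found = rr.classify(make_train([0.0], "CA3"), make_train([0.030]),
                            self.ripple)
        assert found == []

    def test_anchor_outside_fractional_window_excluded(self):
        # window is [-0.3, +0.6] of a 100 ms ripple: [-0.03, +0.06]
        found = rr.classify(make_train([0.065], "CA3"), make_train([0.070]),
                            self.ripple)
        assert found == []
        found = rr.classify(make_train([-0.029], "CA3"), make_train([-0.020]),
                            self.ripple)
        assert len(found) == 1
        assert found[0].phase == pytest.approx(-0.29)

    def test_burst_partner_consumed_whole(self):
        found = rr.classify(make_train([0.0], "CA3"),
                            make_train([0.010, 0.015, 0.019]), self.ripple)
        assert len(found) == 1
        assert found[0].ca1_member_times_s == (0.010, 0.015, 0.019)
        assert found[0].is_burst_pair

    def test_one_ca1_spike_never_double_counted(self):
        found = rr.classify(make_train([0.0, 0.005], "CA3"),
                            make_train([0.020]), self.ripple)
        assert len(found) == 1
        assert found[0].ca3_time_s == 0.0  # greedy left-to-right

    def test_overlapping_ripples_rejected(self):
        bad = [rr.RippleEvent(0.0, 0.1, 9.0), rr.RippleEvent(0.05, 0.2, 9.0)]
        with pytest.raises(ValueError, match="overlap"):
            rr.classify(make_train([0.0], "CA3"), make_train([0.01]), bad)

    def test_event_count_monotone_in_lag_and_window(self):
        rng = np.random.default_rng(17)
        ca3_t, ca1_t, spans = random_session(rng)
        ca3, ca1 = make_train(ca3_t, "CA3"), make_train(ca1_t)
        events = [rr.RippleEvent(a, b, 9.0) for a, b in spans]
        prev = -1
        for lag in (5.0, 10.0, 20.0, 30.0, 50.0):
            n = len(rr.classify(ca3, ca1, events, rr.EventRuleConfig(max_lag_ms=lag)))
            assert n >= prev
            prev = n
        prev = -1
        for frac in (0.1, 0.3, 0.6, 1.0):
            cfg = rr.EventRuleConfig(pre_frac=frac / 2, post_frac=frac)
            n = len(rr.classify(ca3, ca1, events, cfg))
            assert n >= prev
            prev = n


class TestClassifyAgainstOracle:
    def test_exact_equality_on_random_sessions(self):
        rng = np.random.default_rng(42)
        for _ in range(150):
            ca3_t, ca1_t, spans = random_session(rng)
            events = [rr.RippleEvent(a, b, 9.0) for a, b in spans]
            got = rr.classify(make_train(ca3_t, "CA3"), make_train(ca1_t),
                              events)
            want = bruteforce_classify(ca3_t, ca1_t, spans)
            assert [(e.ca3_time_s, e.ca1_time_s, e.ripple_index,
                     e.ca1_member_times_s) for e in got] == want


class TestCountPredictors:
    def test_empty_trains(self):
        events = [rr.RippleEvent(0.0, 0.1, 9.0)]
        assert rr.count_predictors(make_train([], "CA3"), make_train([]),
                                   events) == (0, 0, 0)

    def test_single_spike_pairs_are_not_burst_pairs(self):
        cfg = rr.SynthConfig(seed=8, duration_s=80, ripple_rate_hz=0.4,
                             baseline_rate_hz=0.0, n_ca1=1,
                             planted_pairs_per_train=(8,))
        _, trains, gt = rr.gen_rest_session(cfg)
        events = [rr.RippleEvent(a, b, 9.0) for a, b in gt.ripple_times]
        n_pairs, n_burst, n_ca1 = rr.count_predictors(trains[0], trains[1], events)
        assert n_pairs == 8
        assert n_burst == 0
        assert n_ca1 == trains[1].n_spikes == 8

    def test_burst_partners_counted_as_burst_pairs(self):
        ripples = [rr.RippleEvent(float(k), float(k) + 0.1, 9.0) for k in range(3)]
        ca3 = make_train([0.01, 1.01, 2.01], "CA3")
        ca1 = make_train([0.02, 0.025, 1.02, 1.027, 2.02, 2.026])
        n_pairs, n_burst, n_ca1 = rr.count_predictors(ca3, ca1, ripples)
        assert n_pairs == 3
        assert n_burst == 3
        assert n_ca1 == 6


class TestSpikeTrainEditing:
    def test_remove_then_reclassify_gives_zero(self, eight_event_fixture):
        ca3, ca1, ripples = eight_event_fixture
        found = rr.classify(ca3, ca1, ripples)
        assert len(found) == 8
        stripped = rr.remove_event_spikes(ca1, found)
        assert ca1.n_spikes - stripped.n_spikes == 10
        assert rr.classify(ca3, stripped, ripples) == []

    def test_isolate_then_reclassify_reproduces_events(self, eight_event_fixture):
        ca3, ca1, ripples = eight_event_fixture
        found = rr.classify(ca3, ca1, ripples)
        iso3, iso1 = rr.isolate_events(ca3, ca1, found)
        assert iso3.n_spikes == 8
        assert iso1.n_spikes == 10
        refound = rr.classify(iso3, iso1, ripples)
        assert [(e.ca3_time_s, e.ca1_time_s) for e in refound] == \
               [(e.ca3_time_s, e.ca1_time_s) for e in found]

    def test_empty_event_list_is_identity(self):
        ca1 = make_train([0.1, 0.2])
        assert np.array_equal(rr.remove_event_spikes(ca1, []).times_s,
                              ca1.times_s)

    def test_isolate_with_no_events_empties_trains(self):
        iso3, iso1 = rr.isolate_events(make_train([0.1], "CA3"),
                                       make_train([0.2]), [])
        assert iso3.n_spikes == 0 and iso1.n_spikes == 0

    def test_stale_event_list_rejected(self):
        ca1 = make_train([0.1])
        fake = rr.CausalPairEvent(0.05, 0.07, 20.0, 0, 0.0, (0.07,))
        with pytest.raises(ValueError, match="stale"):
            rr.remove_event_spikes(ca1, [fake])

    def test_isolated_spike_count_matches_event_membership(self):
        rng = np.random.default_rng(5)
        ca3_t, ca1_t, spans = random_session(rng)
        ca3, ca1 = make_train(ca3_t, "CA3"), make_train(ca1_t)
        events = [rr.RippleEvent(a, b, 9.0) for a, b in spans]
        found = rr.classify(ca3, ca1, events)
        iso3, iso1 = rr.isolate_events(ca3, ca1, found)
        # anchors may coincide only if distinct events share a spike time,
        # which classification forbids
        assert iso3.n_spikes == len(found)
        assert iso1.n_spikes == len({t for e in found
                                     for t in e.ca1_member_times_s})


class TestOffsetInteraction:
    def test_early_shift_destroys_onset_phase_pairs(self):
        cfg = rr.SynthConfig(seed=13, duration_s=100, ripple_rate_hz=0.4,
                             baseline_rate_hz=0.2, n_ca1=1,
                             planted_pairs_per_train=(20,),
                             pair_phase_range=(0.0, 0.3))
        _, trains, gt = rr.gen_rest_session(cfg)
        events = [rr.RippleEvent(a, b, 9.0) for a, b in gt.ripple_times]
        n0 = len(rr.classify(trains[0], trains[1], events))
        shifted = rr.offset_ripples(events, -0.1)
        n1 = len(rr.classify(trains[0], trains[1], shifted))
        assert n0 >= 20
        assert n1 <= 0.2 * n0
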