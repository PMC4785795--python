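"""SWR-conditioned spike statistics."""

import numpy as np
import pytest

import ripplereplay as rr
from _oracles import bruteforce_pair_count
from conftest import make_train


def events_at(onsets, dur=0.1):
    return [rr.RippleEvent(o, o + dur, 9.0) for o in onsets]


class TestSpikesPerSwr:
    def test_empty_event_list_rejected(self):
        with pytest.raises(ValueError):
            rr.spikes_per_swr(make_train([0.1]), [])

    def test_no_spikes_gives_zero_median(self):
        out = rr.spikes_per_swr(make_train([]), events_at([1, 2, 3]))
        assert out["median"] == 0 and out["mean"] == 0

    def test_one_spike_per_event_mean_one(self):
        evs = events_at([1, 2, 3, 4])
        out = rr.spikes_per_swr(make_train([1.05, 2.05, 3.05, 4.05]), evs)
        assert out["mean"] == 1.0
        assert out["n_events"] == 4

    def test_planted_mean_recovered_on_synthetic_session(self):
        # one spike inside each event on average: plant Poisson spikes
        rng = np.random.default_rng(0)
        onsets = np.arange(500) * 1.0 + 0.2
        evs = events_at(onsets, dur=0.08)
        times = []
        for o in onsets:
            times.extend(o + rng.uniform(0, 0.08, rng.poisson(0.45)))
        out = rr.spikes_per_swr(make_train(np.unique(times)), evs)
        assert out["mean"] == pytest.approx(0.45, rel=0.10)


class TestPeriSwrPsth:
    def test_empty_trains_zero_psth(self):
        out = rr.peri_swr_psth([make_train([], "CA3"), make_train([], "CA1")],
                               events_at([1, 2]))
        assert np.all(out["CA3"].rate_hz == 0)
        assert np.all(out["CA1"].rate_hz == 0)

    def test_homogeneous_poisson_psth_is_flat(self):
        rng = np.random.default_rng(3)
        rate = 20.0
        train = make_train(np.unique(rng.uniform(0, 600, rng.poisson(rate * 600))))
        evs = events_at(np.arange(5, 595, 2.0))
        out = rr.peri_swr_psth([train], evs, window_s=(-0.1, 0.3), bin_s=0.01)["CA1"]
        n_per_bin = rate * 0.01 * len(evs)
        se = rate / np.sqrt(n_per_bin)
        assert np.all(np.abs(out.rate_hz - rate) <= 3 * se)

    def test_psth_integral_conserves_spike_count(self):
        rng = np.random.default_rng(4)
        train = make_train(np.unique(rng.uniform(0, 100, 500)))
        evs = events_at([20.0, 50.0, 80.0])
        out = rr.peri_swr_psth([train], evs, window_s=(-0.5, 0.5), bin_s=0.01)["CA1"]
        integral = out.rate_hz.sum() * 0.01  # mean spikes per event per unit
        counts = [np.sum((train.times_s >= o - 0.5) & (train.times_s < o + 0.5))
                  for o in (20.0, 50.0, 80.0)]
        assert integral * len(evs) == pytest.approx(sum(counts))

    def test_ca3_peak_precedes_ca1_peak_with_planted_lag(self):
        cfg = rr.SynthConfig(seed=15, duration_s=200, ripple_rate_hz=0.4,
                             baseline_rate_hz=0.05, n_ca1=1,
                             planted_pairs_per_train=(60,),
                             pair_lag_range_ms=(12.0, 12.0),
                             pair_phase_range=(0.2, 0.2))
        _, trains, gt = rr.gen_rest_session(cfg)
        evs = [rr.RippleEvent(a, b, 9.0) for a, b in gt.ripple_times]
        out = rr.peri_swr_psth(trains, evs, window_s=(-0.05, 0.1), bin_s=0.005)
        t3 = out["CA3"].bin_edges_s[np.argmax(out["CA3"].rate_hz)]
        t1 = out["CA1"].bin_edges_s[np.argmax(out["CA1"].rate_hz)]
        # planted 12 ms lead, quantized by 5 ms bins (half-bin slack)
        assert 0.0075 <= t1 - t3 <= 0.0225


class TestCoactivity:
    def test_silent_units_give_zero(self):
        edges, counts = rr.coactivity([make_train([]), make_train([])],
                                      t_range=(0, 5))
        assert np.all(counts == 0)

    def test_all_units_every_bin_saturates(self):
        trains = [make_train(np.arange(0.5, 5.0, 1.0) + 0.01 * k)
                  for k in range(5)]
        _, counts = rr.coactivity(trains, t_range=(0, 5))
        assert np.all(counts == 5)

    def test_staggered_schedule_recovered(self):
        # unit k spikes only in bin k
        trains = [make_train([k + 0.5]) for k in range(4)]
        _, counts = rr.coactivity(trains, t_range=(0, 4))
        assert np.array_equal(counts, np.ones(4, dtype=int))


class TestSwrCrosscorr:
    def test_shifted_train_concentrates_in_one_bin(self):
        ca3 = make_train(np.array([1.01, 2.01, 3.01]), "CA3")
        ca1 = make_train(ca3.times_s + 0.005)
        evs = events_at([1.0, 2.0, 3.0])
        out = rr.swr_crosscorr(ca3, ca1, evs)
        hot = np.flatnonzero(out.counts)
        assert hot.size == 1
        assert out.lag_bin_edges_ms[hot[0]] == 0.0  # +5 ms lag in [0, 10)
        assert out.n_ca1_in_swr == 3
        assert out.normalized_counts[hot[0]] == pytest.approx(1.0)

    def test_independent_poisson_trains_flat(self):
        # restriction windows tiled to cover the whole recording, so no
        # window-induced shaping remains and the correlogram is flat
        rng = np.random.default_rng(9)
        ca3 = make_train(np.unique(rng.uniform(0, 200, 1500)), "CA3")
        ca1 = make_train(np.unique(rng.uniform(0, 200, 1500)))
        evs = events_at(np.arange(0.5, 199.5, 1.0), dur=0.08)
        out = rr.swr_crosscorr(ca3, ca1, evs, restrict_s=(-0.6, 0.6))
        mean = out.counts.mean()
        assert np.all(np.abs(out.counts - mean) <= 3 * np.sqrt(mean))

    def test_unnormalized_sum_matches_bruteforce_pair_count(self):
        rng = np.random.default_rng(10)
        ca3 = make_train(np.unique(rng.uniform(0, 20, 100)), "CA3")
        ca1 = make_train(np.unique(rng.uniform(0, 20, 100)))
        evs = events_at(np.arange(0.5, 19.5, 0.7), dur=0.06)
        out = rr.swr_crosscorr(ca3, ca1, evs)
        # oracle on the same restricted spike sets
        onsets = [ev.onset_s for ev in evs]

        def restrict(t):
            keep = np.zeros(t.size, dtype=bool)
            for o in onsets:
                keep |= (t >= o - 0.05) & (t < o + 0.15)
            return t[keep]

        want = bruteforce_pair_count(restrict(ca3.times_s),
                                     restrict(ca1.times_s), -100.0, 100.0)
        assert out.counts.sum() == want

    def test_antisymmetry_of_construction(self):
        rng = np.random.default_rng(11)
        ca3 = make_train(np.unique(rng.uniform(0, 20, 80)), "CA3")
        ca1 = make_train(np.unique(rng.uniform(0, 20, 80)))
        evs = events_at(np.arange(0.5, 19.5, 0.9), dur=0.06)
        fwd = rr.swr_crosscorr(ca3, ca1, evs)
        # swap roles: lags negate; compare counts up to bin-edge handling
        rev = rr.swr_crosscorr(make_train(ca1.times_s, "CA3"),
                               make_train(ca3.times_s), evs)
        # continuous spike times: no lag falls exactly on a bin edge,
        # so the mirrored histogram matches bin for bin
        assert np.array_equal(fwd.counts, rev.counts[::-1])
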