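"""Stimulation schedules for in vitro replay of recorded activity.

Three channels drive an induction experiment: the presynaptic test
pathway (Schaffer-collateral stimulation evoking subthreshold EPSPs at
CA3 spike times), the postsynaptic channel (2 ms / 2 nA somatic current
pulses evoking action potentials at CA1 spike times), and the ripple
pathway (five-pulse 100 Hz trains at detected SWR onset times,
mimicking the phasic dendritic depolarization of a ripple).  Variants
omit or time-shift the ripple pathway, replace it with a somatic
sine-wave current command, or substitute the recorded trains with
artificial EPSP–AP pairing at fixed delays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ripples import RippleEvent
from .swrstats import SpikeTrain

__all__ = ["StimProtocol", "CurrentWaveform", "build_replay_protocol",
           "build_pairing_protocol", "sine_wave_command"]

RIPPLE_TRAIN_N_PULSES = 5
RIPPLE_TRAIN_RATE_HZ = 100.0
AP_PULSE_MS = 2.0
AP_PULSE_NA = 2.0


@dataclass(frozen=True)
class StimProtocol:
    """Three-channel event schedule for one induction experiment.

    ``ripple_path_trains`` holds (start_s, n_pulses, rate_hz) per SWR.
    ``metadata`` carries flags such as a constant holding-potential
    variant; schedules are event lists, not sampled waveforms.
    """

    presyn_test_times_s: np.ndarray
    postsyn_ap_times_s: np.ndarray
    ripple_path_trains: tuple[tuple[float, int, float], ...]
    mode: str
    duration_s: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pre = np.asarray(self.presyn_test_times_s, dtype=float)
        post = np.asarray(self.postsyn_ap_times_s, dtype=float)
        object.__setattr__(self, "presyn_test_times_s", pre)
        object.__setattr__(self, "postsyn_ap_times_s", post)
        for arr in (pre, post):
            if arr.size and (arr.min() < -1e-9 or arr.max() > self.duration_s + 1e-9):
                raise ValueError("schedule times outside protocol duration")
        for (s_a, n_a, r_a), (s_b, _, _) in zip(self.ripple_path_trains,
                                                self.ripple_path_trains[1:]):
            if s_b < s_a + (n_a - 1) / r_a:
                raise ValueError("ripple-path trains overlap")

    @property
    def n_ripple_pulses(self) -> int:
        return sum(n for _, n, _ in self.ripple_path_trains)

    def ripple_pulse_times(self) -> np.ndarray:
        out = []
        for start, n, rate in self.ripple_path_trains:
            out.extend(start + np.arange(n) / rate)
        return np.array(sorted(out))


@dataclass(frozen=True)
class CurrentWaveform:
    """A sampled somatic current command in pA."""

    samples_pa: np.ndarray
    rate_hz: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples_pa",
                           np.asarray(self.samples_pa, dtype=float))


def build_replay_protocol(ca3: SpikeTrain, ca1: SpikeTrain,
                          events: list[RippleEvent], swr_mode: str = "with",
                          epoch_s: float = 300.0) -> StimProtocol:
    """Build the replay induction schedule from recorded trains and SWRs.

    EPSP stimulation follows the CA3 spike times, somatic AP pulses the
    CA1 spike times; the ripple pathway receives one five-pulse 100 Hz
    train per SWR onset.  ``swr_mode`` selects the variant: ``with``
    (full protocol), ``without`` (ripple pathway omitted), or
    ``offset_100ms_early`` (ripple trains shifted -100 ms).
    """
    if swr_mode not in ("with", "without", "offset_100ms_early"):
        raise ValueError(f"unknown swr_mode {swr_mode!r}")
    for tr in (ca3, ca1):
        if tr.times_s.size and (tr.times_s.min() < 0 or tr.times_s.max() > epoch_s):
            raise ValueError(f"{tr.unit_id} spikes outside the {epoch_s} s epoch")
    if swr_mode == "without":
        trains: tuple[tuple[float, int, float], ...] = ()
    else:
        shift = -0.1 if swr_mode == "offset_100ms_early" else 0.0
        trains = tuple((ev.onset_s + shift, RIPPLE_TRAIN_N_PULSES,
                        RIPPLE_TRAIN_RATE_HZ) for ev in events)
    return StimProtocol(
        presyn_test_times_s=ca3.times_s.copy(),
        postsyn_ap_times_s=ca1.times_s.copy(),
        ripple_path_trains=trains,
        mode=f"replay_{swr_mode}",
        duration_s=epoch_s,
        metadata={"ap_pulse_ms": AP_PULSE_MS, "ap_pulse_na": AP_PULSE_NA},
    )


def build_pairing_protocol(variant: str, n_reps: int = 300,
                           rep_rate_hz: float = 5.0,
                           epsp_ap_gap_ms: float = 10.0) -> StimProtocol:
    """Artificial EPSP–AP pairing protocols at fixed ripple delays.

    All variants repeat ``n_reps`` times at ``rep_rate_hz`` (defaults:
    300 repetitions at 5 Hz, 60 s total).  Per repetition starting at
    t0: ``pairing_only`` delivers one EPSP at t0 and one AP 10 ms
    later; ``pairing_at_13ms`` and ``pairing_at_53ms`` precede the same
    pairing with a ripple-pathway train at t0, delaying the EPSP by 13
    or 53 ms; ``epsp_only_at_13ms`` drops the AP.
    """
    delays_ms = {"pairing_only": None, "pairing_at_13ms": 13.0,
                 "pairing_at_53ms": 53.0, "epsp_only_at_13ms": 13.0}
    if variant not in delays_ms:
        raise ValueError(f"unknown variant {variant!r}")
    delay = delays_ms[variant]
    period = 1.0 / rep_rate_hz
    duration = n_reps * period
    t0 = period * np.arange(n_reps)
    if delay is None:
        epsp = t0
        trains: tuple[tuple[float, int, float], ...] = ()
    else:
        epsp = t0 + delay * 1e-3
        trains = tuple((float(s), RIPPLE_TRAIN_N_PULSES, RIPPLE_TRAIN_RATE_HZ)
                       for s in t0)
    ap = np.array([]) if variant == "epsp_only_at_13ms" else epsp + epsp_ap_gap_ms * 1e-3
    return StimProtocol(
        presyn_test_times_s=epsp,
        postsyn_ap_times_s=ap,
        ripple_path_trains=trains,
        mode=variant,
        duration_s=duration,
        metadata={"ap_pulse_ms": AP_PULSE_MS, "ap_pulse_na": AP_PULSE_NA},
    )


def sine_wave_command(events: list[RippleEvent], max_pa: float = 100.0,
                      rate_hz: float = 10000.0, n_cycles: int = 1,
                      duration_s: float | None = None) -> CurrentWaveform:
    """Somatic sine-wave current surrogate for ripple depolarization.

    The command is zero at baseline; during each SWR it traces
    ``n_cycles`` full sine cycles spanning [onset, offset] with
    amplitude ``max_pa``, so the frequency scales inversely with the
    event duration and both a +max and a -max extremum occur within
    every event.
    """
    if duration_s is None:
        duration_s = max((ev.offset_s for ev in events), default=0.0) + 0.1
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    out = np.zeros(n)
    for ev in events:
        sel = (t >= ev.onset_s) & (t < ev.offset_s)
        phase = (t[sel] - ev.onset_s) / ev.duration_s
        out[sel] = max_pa * np.sin(2 * np.pi * n_cycles * phase)
    return CurrentWaveform(samples_pa=out, rate_hz=rate_hz)
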