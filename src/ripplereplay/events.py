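"""Plasticity-potent causal CA3->CA1 spike-pair events.

A causal pair is a CA3 spike followed strictly less than ``max_lag_ms``
(default 30 ms) later by a CA1 spike or burst onset, with the CA3 spike
falling inside a fractional window around an SWR: from
``pre_frac`` x duration before onset to ``post_frac`` x duration after
onset (defaults 0.3 / 0.6).  Pairs in this window are the units of
timing that predict LTP induction.

Pairing is greedy left-to-right: CA3 anchors are visited in time order
and each takes the earliest eligible unconsumed CA1 spike or burst, so
no CA1 spike is counted in two events and no CA3 spike anchors two
events.  A burst is consumed whole: all its member spikes belong to the
event, and a burst whose later members straddle the lag boundary still
qualifies if its onset is inside the window.

The module also provides the spike-train edits used to test necessity
and sufficiency of these events: removing their CA1 member spikes, or
isolating the trains down to the events alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ripples import RippleEvent
from .swrstats import SpikeTrain

__all__ = [
    "Burst",
    "CausalPairEvent",
    "EventRuleConfig",
    "detect_bursts",
    "classify",
    "count_predictors",
    "remove_event_spikes",
    "isolate_events",
]


@dataclass(frozen=True)
class Burst:
    """A maximal run of >= 2 spikes with successive ISIs below threshold."""

    onset_s: float
    n_spikes: int
    member_times_s: tuple[float, ...]


@dataclass(frozen=True)
class CausalPairEvent:
    """One CA3->CA1 causal pairing inside the SWR window.

    ``phase`` is the CA3 anchor time expressed as a fraction of the SWR
    duration relative to onset (negative = before onset).
    ``ca1_member_times_s`` lists every CA1 spike constituting the event
    (one for a single-spike partner, all members for a burst partner).
    """

    ca3_time_s: float
    ca1_time_s: float
    lag_ms: float
    ripple_index: int
    phase: float
    ca1_member_times_s: tuple[float, ...]

    @property
    def is_burst_pair(self) -> bool:
        return len(self.ca1_member_times_s) >= 2


@dataclass(frozen=True)
class EventRuleConfig:
    """Parameters of the causal-pair rule.

    ``anchor`` selects which spike's time is tested against the
    fractional SWR window; the presynaptic (CA3) spike initiates the
    pairing and is the default.
    """

    max_lag_ms: float = 30.0
    pre_frac: float = 0.3
    post_frac: float = 0.6
    burst_isi_ms: float = 10.0
    anchor: str = "ca3"

    def __post_init__(self) -> None:
        if self.max_lag_ms <= 0:
            raise ValueError("max_lag_ms must be positive")
        if self.pre_frac < 0 or self.post_frac < 0:
            raise ValueError("window fractions must be nonnegative")
        if self.anchor not in ("ca3", "ca1"):
            raise ValueError("anchor must be 'ca3' or 'ca1'")


def detect_bursts(train: SpikeTrain, burst_isi_ms: float = 10.0) -> list[Burst]:
    """Find maximal runs of >= 2 spikes with ISIs <= ``burst_isi_ms``."""
    t = train.times_s
    bursts: list[Burst] = []
    i = 0
    thresh = burst_isi_ms * 1e-3
    while i < t.size - 1:
        j = i
        while j + 1 < t.size and (t[j + 1] - t[j]) <= thresh:
            j += 1
        if j > i:
            members = tuple(float(x) for x in t[i:j + 1])
            bursts.append(Burst(onset_s=members[0], n_spikes=len(members),
                                member_times_s=members))
        i = j + 1
    return bursts


def _candidates(ca1: SpikeTrain, burst_isi_ms: float) -> list[tuple[float, tuple[float, ...]]]:
    """CA1 pairing candidates: burst onsets (with members) and lone spikes."""
    bursts = detect_bursts(ca1, burst_isi_ms)
    in_burst: set[float] = set()
    for b in bursts:
        in_burst.update(b.member_times_s)
    cands = [(b.onset_s, b.member_times_s) for b in bursts]
    cands += [(float(t), (float(t),)) for t in ca1.times_s if float(t) not in in_burst]
    cands.sort(key=lambda c: c[0])
    return cands


def _window_of(t: float, events: list[RippleEvent], cfg: EventRuleConfig) -> tuple[int, float] | None:
    """Earliest ripple whose fractional window contains ``t``, with phase."""
    for idx, ev in enumerate(events):
        dur = ev.duration_s
        lo = ev.onset_s - cfg.pre_frac * dur
        hi = ev.onset_s + cfg.post_frac * dur
        if lo <= t <= hi:
            return idx, (t - ev.onset_s) / dur
    return None


def classify(ca3: SpikeTrain, ca1: SpikeTrain, events: list[RippleEvent],
             cfg: EventRuleConfig | None = None) -> list[CausalPairEvent]:
    """Classify causal CA3->CA1 pairs within SWR windows.

    Anchored CA3 spikes (those inside some event's fractional window)
    are paired greedily in time order with the earliest unconsumed CA1
    spike or burst onset strictly within ``(0, max_lag_ms)`` after them.
    Raises if the ripple events overlap (phase would be ambiguous).
    """
    cfg = cfg or EventRuleConfig()
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError("overlapping ripple events make phase ambiguous")

    cands = _candidates(ca1, cfg.burst_isi_ms)
    consumed = [False] * len(cands)
    max_lag_s = cfg.max_lag_ms * 1e-3
    found: list[CausalPairEvent] = []
    for t3 in ca3.times_s:
        t3 = float(t3)
        if cfg.anchor == "ca3":
            loc = _window_of(t3, events, cfg)
            if loc is None:
                continue
        partner = None
        for k, (t1, members) in enumerate(cands):
            if consumed[k]:
                continue
            lag = t1 - t3
            if lag <= 0:
                continue
            if lag >= max_lag_s:
                break
            partner = (k, t1, members)
            break
        if partner is None:
            continue
        k, t1, members = partner
        if cfg.anchor == "ca1":
            loc = _window_of(t1, events, cfg)
            if loc is None:
                continue
        idx, phase = loc
        consumed[k] = True
        found.append(CausalPairEvent(
            ca3_time_s=t3, ca1_time_s=t1, lag_ms=(t1 - t3) * 1e3,
            ripple_index=idx, phase=phase, ca1_member_times_s=members,
        ))
    return found


def count_predictors(ca3: SpikeTrain, ca1: SpikeTrain, events: list[RippleEvent],
                     cfg: EventRuleConfig | None = None,
                     restrict_bursts_to_swr: bool = False) -> tuple[int, int, int]:
    """The three candidate predictors of synaptic change.

    Returns ``(n_pairs, n_ca3_burst_pairs, n_ca1_spikes)``:
    the number of causal pairs within SWR windows; the number of CA3
    spikes followed < max_lag by a CA1 burst (whole-train by default,
    SWR-restricted if ``restrict_bursts_to_swr``); and the total CA1
    spike count of the train.
    """
    cfg = cfg or EventRuleConfig()
    pairs = classify(ca3, ca1, events, cfg)
    n_pairs = len(pairs)
    if restrict_bursts_to_swr:
        n_burst = sum(1 for p in pairs if p.is_burst_pair)
    else:
        n_burst = _count_burst_followers(ca3, ca1, cfg)
    return n_pairs, n_burst, ca1.n_spikes


def _count_burst_followers(ca3: SpikeTrain, ca1: SpikeTrain,
                           cfg: EventRuleConfig) -> int:
    """CA3 spikes followed < max_lag by a CA1 burst onset, greedy, unwindowed."""
    bursts = detect_bursts(ca1, cfg.burst_isi_ms)
    consumed = [False] * len(bursts)
    max_lag_s = cfg.max_lag_ms * 1e-3
    n = 0
    for t3 in ca3.times_s:
        for k, b in enumerate(bursts):
            if consumed[k]:
                continue
            lag = b.onset_s - float(t3)
            if lag <= 0:
                continue
            if lag >= max_lag_s:
                break
            consumed[k] = True
            n += 1
            break
    return n


def _remove_times(train: SpikeTrain, times: set[float], what: str) -> SpikeTrain:
    t = train.times_s
    keep = np.ones(t.size, dtype=bool)
    present = {float(x) for x in t}
    missing = times - present
    if missing:
        raise ValueError(f"stale event list: {what} times {sorted(missing)[:3]}... "
                         "absent from train")
    for i, x in enumerate(t):
        if float(x) in times:
            keep[i] = False
    return train.with_times(t[keep])


def remove_event_spikes(ca1: SpikeTrain, found: list[CausalPairEvent]) -> SpikeTrain:
    """Delete every CA1 spike constituting the given events from the train."""
    member_times = {t for ev in found for t in ev.ca1_member_times_s}
    return _remove_times(ca1, member_times, "CA1 member")


def isolate_events(ca3: SpikeTrain, ca1: SpikeTrain,
                   found: list[CausalPairEvent]) -> tuple[SpikeTrain, SpikeTrain]:
    """Reduce both trains to the event spikes alone.

    The returned CA3 train holds exactly the event anchors; the CA1
    train, exactly the member spikes of the events.
    """
    anchors = {ev.ca3_time_s for ev in found}
    members = {t for ev in found for t in ev.ca1_member_times_s}
    present3 = {float(x) for x in ca3.times_s}
    present1 = {float(x) for x in ca1.times_s}
    if anchors - present3 or members - present1:
        raise ValueError("stale event list: event spikes absent from trains")
    new3 = ca3.with_times(np.array(sorted(anchors)))
    new1 = ca1.with_times(np.array(sorted(members)))
    return new3, new1
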