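"""SWR-conditioned spike statistics.

Spikes-per-SWR summaries, peri-SWR time histograms (PSTHs), population
co-activity traces, and SWR-restricted CA3 x CA1 cross-correlograms.
All histogram bins are half-open ``[lo, hi)``: a spike exactly on an
edge belongs to the later bin.  The cross-correlogram lag sign
convention is positive = CA1 after CA3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ripples import RippleEvent

__all__ = [
    "SpikeTrain",
    "PsthResult",
    "CrossCorrResult",
    "spikes_per_swr",
    "peri_swr_psth",
    "coactivity",
    "swr_crosscorr",
]

_REGIONS = ("CA3", "CA1")


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike timestamps of one unit with its region label."""

    unit_id: str
    region: str
    times_s: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        object.__setattr__(self, "times_s", t)
        if self.region not in _REGIONS:
            raise ValueError(f"region must be one of {_REGIONS}, got {self.region!r}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError(f"spike times of {self.unit_id} must be strictly increasing")

    @property
    def n_spikes(self) -> int:
        return int(self.times_s.size)

    def with_times(self, times_s: np.ndarray) -> "SpikeTrain":
        return SpikeTrain(self.unit_id, self.region, np.asarray(times_s, dtype=float))


@dataclass(frozen=True)
class PsthResult:
    """Peri-event time histogram: mean rate vs time from SWR onset."""

    bin_edges_s: np.ndarray
    rate_hz: np.ndarray
    n_events: int
    region: str = ""


@dataclass(frozen=True)
class CrossCorrResult:
    """SWR-restricted cross-correlogram of CA1 lags relative to CA3 spikes.

    ``normalized_counts`` are per-bin pair counts divided by
    ``n_ca1_in_swr``, the number of CA1 spikes inside SWR event
    intervals (the normalizer used for comparing correlograms across
    cells with different firing levels).
    """

    lag_bin_edges_ms: np.ndarray
    counts: np.ndarray
    normalized_counts: np.ndarray
    n_ca1_in_swr: int


def _check_non_overlapping(events: list[RippleEvent]) -> None:
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError("ripple events overlap; merge them upstream")


def spikes_per_swr(train: SpikeTrain, events: list[RippleEvent]) -> dict[str, float]:
    """Per-event spike counts in ``[onset, offset)`` and their summary.

    Returns mean, median, first and third quartiles, and the number of
    events.  Raises on an empty event list (the statistic is undefined).
    """
    if not events:
        raise ValueError("spikes_per_swr undefined for an empty event list")
    _check_non_overlapping(events)
    t = train.times_s
    counts = np.array([
        np.searchsorted(t, ev.offset_s, side="left")
        - np.searchsorted(t, ev.onset_s, side="left")
        for ev in events
    ], dtype=float)
    q1, med, q3 = np.percentile(counts, [25, 50, 75])
    return {
        "mean": float(counts.mean()),
        "median": float(med),
        "q1": float(q1),
        "q3": float(q3),
        "n_events": len(events),
    }


def peri_swr_psth(trains: list[SpikeTrain], events: list[RippleEvent],
                  window_s: tuple[float, float] = (-0.1, 0.3),
                  bin_s: float = 0.005) -> dict[str, PsthResult]:
    """Mean firing rate around SWR onset, per region.

    Spike times are re-referenced to each event onset, histogrammed in
    uniform bins over ``window_s``, averaged over events and over the
    units of each region, and converted to Hz.
    """
    lo, hi = window_s
    if not hi > lo:
        raise ValueError("window must be a nonempty interval")
    n_bins = int(round((hi - lo) / bin_s))
    edges = lo + bin_s * np.arange(n_bins + 1)
    onsets = np.array([ev.onset_s for ev in events])
    out: dict[str, PsthResult] = {}
    for region in _REGIONS:
        members = [tr for tr in trains if tr.region == region]
        acc = np.zeros(n_bins)
        for tr in members:
            for onset in onsets:
                rel = tr.times_s - onset
                acc += np.histogram(rel, bins=edges)[0]
        denom = max(len(members), 1) * max(len(events), 1) * bin_s
        out[region] = PsthResult(bin_edges_s=edges, rate_hz=acc / denom,
                                 n_events=len(events), region=region)
    return out


def coactivity(trains: list[SpikeTrain], bin_s: float = 1.0,
               t_range: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Number of units active (>= 1 spike) per time bin.

    Returns ``(bin_edges_s, counts)``; counts are bounded by the number
    of units.  ``t_range`` defaults to the span of all spikes.
    """
    if t_range is None:
        all_t = np.concatenate([tr.times_s for tr in trains]) if trains else np.array([])
        if all_t.size == 0:
            return np.array([0.0, bin_s]), np.zeros(1, dtype=int)
        t_range = (float(np.floor(all_t.min() / bin_s) * bin_s),
                   float(all_t.max()))
    lo, hi = t_range
    n_bins = max(int(np.ceil((hi - lo) / bin_s)), 1)
    edges = lo + bin_s * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    for tr in trains:
        per_unit = np.histogram(tr.times_s, bins=edges)[0]
        counts += (per_unit > 0).astype(int)
    return edges, counts


def swr_crosscorr(ca3: SpikeTrain, ca1: SpikeTrain, events: list[RippleEvent],
                  restrict_s: tuple[float, float] = (-0.05, 0.15),
                  lag_ms: float = 100.0, bin_ms: float = 10.0,
                  restrict_both: bool = True) -> CrossCorrResult:
    """Cross-correlogram of CA1 spike lags relative to CA3 spikes near SWRs.

    Only spikes falling within ``restrict_s`` (seconds relative to any
    event onset) enter the histogram; by default both trains are
    restricted (``restrict_both=False`` restricts only CA1).  Lags
    ``ca1 - ca3`` within ``+/- lag_ms`` are histogrammed at ``bin_ms``
    pitch, and counts are divided by the number of CA1 spikes occurring
    inside SWR event intervals.
    """
    _check_non_overlapping(events)
    onsets = np.array([ev.onset_s for ev in events])

    def _restrict(t: np.ndarray) -> np.ndarray:
        if onsets.size == 0 or t.size == 0:
            return np.array([])
        keep = np.zeros(t.size, dtype=bool)
        for onset in onsets:
            keep |= (t >= onset + restrict_s[0]) & (t < onset + restrict_s[1])
        return t[keep]

    ca3_t = _restrict(ca3.times_s) if restrict_both else ca3.times_s
    ca1_t = _restrict(ca1.times_s)

    n_half = int(round(lag_ms / bin_ms))
    edges = bin_ms * np.arange(-n_half, n_half + 1)
    counts = np.zeros(2 * n_half, dtype=float)
    if ca3_t.size and ca1_t.size:
        lags_ms = (ca1_t[None, :] - ca3_t[:, None]).ravel() * 1e3
        lags_ms = lags_ms[(lags_ms >= -lag_ms) & (lags_ms < lag_ms)]
        counts = np.histogram(lags_ms, bins=edges)[0].astype(float)

    n_in_swr = 0
    for ev in events:
        n_in_swr += int(np.searchsorted(ca1.times_s, ev.offset_s, side="left")
                        - np.searchsorted(ca1.times_s, ev.onset_s, side="left"))
    if n_in_swr == 0 and counts.sum() > 0:
        raise ValueError("no CA1 spikes inside SWRs but correlogram is nonzero; "
                         "restriction window and events are inconsistent")
    norm = counts / n_in_swr if n_in_swr > 0 else counts.copy()
    return CrossCorrResult(lag_bin_edges_ms=edges, counts=counts,
                           normalized_counts=norm, n_ca1_in_swr=n_in_swr)
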