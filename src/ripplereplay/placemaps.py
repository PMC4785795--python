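"""Place-field rate maps and per-trial firing-position rasters.

A linear track (200 cm by 10 cm) is divided into 10 cm bins along its
length; the lateral dimension collapses.  Rates are occupancy
normalized: spikes assigned to bins via position interpolation at spike
time, divided by the time the animal spent in each bin.  Trials are
maximal monotone traversals covering a configurable fraction of the
track.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .swrstats import SpikeTrain

__all__ = ["TrajectorySeries", "RateMap", "rate_map", "trial_raster"]


@dataclass(frozen=True)
class TrajectorySeries:
    """Sampled animal position along the track.

    ``times_s`` strictly increasing; ``position_cm`` within
    ``[0, track_length_cm]``.
    """

    times_s: np.ndarray
    position_cm: np.ndarray
    track_length_cm: float = 200.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times_s, dtype=float)
        x = np.asarray(self.position_cm, dtype=float)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "position_cm", x)
        if t.size != x.size:
            raise ValueError("times and positions must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if x.size and (x.min() < -1e-9 or x.max() > self.track_length_cm + 1e-9):
            raise ValueError("positions outside track bounds")


@dataclass(frozen=True)
class RateMap:
    """Occupancy-normalized firing-rate map over track bins.

    Bins with zero occupancy carry NaN rate (flagged, not zero-filled);
    ``occupancy_s`` sums to the on-track session duration.
    """

    bin_edges_cm: np.ndarray
    occupancy_s: np.ndarray
    spike_counts: np.ndarray
    rate_hz: np.ndarray
    mean_rate_hz: float

    @property
    def argmax_bin(self) -> tuple[float, float]:
        """Edges of the bin with the highest rate (NaN bins ignored)."""
        i = int(np.nanargmax(self.rate_hz))
        return float(self.bin_edges_cm[i]), float(self.bin_edges_cm[i + 1])


def rate_map(spikes: SpikeTrain, traj: TrajectorySeries, bin_cm: float = 10.0,
             max_gap_s: float = 0.5, smooth_bins: float = 0.0) -> RateMap:
    """Compute the occupancy-normalized rate map of one unit.

    Spike positions are linearly interpolated from the trajectory at
    spike times; occupancy accumulates inter-sample intervals (gaps
    longer than ``max_gap_s`` are excluded) into the bin of the interval
    start.  ``smooth_bins`` > 0 applies an optional Gaussian smoothing
    (in bins) to the rate for display.
    """
    t, x = traj.times_s, traj.position_cm
    if t.size < 2:
        raise ValueError("trajectory too short for a rate map")
    s = spikes.times_s
    outside = (s < t[0]) | (s > t[-1])
    if outside.any():
        raise ValueError(f"spikes outside trajectory span: {s[outside][:5]}")

    n_bins = int(round(traj.track_length_cm / bin_cm))
    edges = bin_cm * np.arange(n_bins + 1)

    dt = np.diff(t)
    valid = dt <= max_gap_s
    start_bins = np.clip(np.floor(x[:-1] / bin_cm).astype(int), 0, n_bins - 1)
    occupancy = np.bincount(start_bins[valid], weights=dt[valid], minlength=n_bins)

    spike_x = np.interp(s, t, x)
    spike_bins = np.clip(np.floor(spike_x / bin_cm).astype(int), 0, n_bins - 1)
    counts = np.bincount(spike_bins, minlength=n_bins).astype(float)

    with np.errstate(divide="ignore", invalid="ignore"):
        rate = np.where(occupancy > 0, counts / occupancy, np.nan)
    if smooth_bins > 0:
        filled = np.where(np.isnan(rate), 0.0, rate)
        rate = gaussian_filter1d(filled, smooth_bins, mode="nearest")
    total_occ = occupancy.sum()
    mean_rate = float(counts.sum() / total_occ) if total_occ > 0 else float("nan")
    return RateMap(bin_edges_cm=edges, occupancy_s=occupancy,
                   spike_counts=counts, rate_hz=rate, mean_rate_hz=mean_rate)


def _segment_runs(traj: TrajectorySeries, min_frac: float) -> list[tuple[int, int, str]]:
    """Maximal monotone traversals covering >= ``min_frac`` of the track.

    Turning points are position extrema with prominence of half the
    track length (robust to sampling jitter); a run is the stretch
    between consecutive turning points whose net displacement is long
    enough.  Direction 'outbound' means increasing position.
    """
    x = traj.position_cm
    if x.size < 2:
        return []
    L = traj.track_length_cm
    prom = 0.5 * L
    peaks, _ = find_peaks(x, prominence=prom)
    troughs, _ = find_peaks(-x, prominence=prom)
    turns = np.unique(np.r_[0, peaks, troughs, x.size - 1])
    runs: list[tuple[int, int, str]] = []
    for s, e in zip(turns[:-1], turns[1:]):
        span = x[e] - x[s]
        if abs(span) >= min_frac * L:
            runs.append((int(s), int(e), "outbound" if span > 0 else "inbound"))
    return runs


def trial_raster(spikes: SpikeTrain, traj: TrajectorySeries, direction: str,
                 min_frac: float = 0.8) -> list[np.ndarray]:
    """Spike positions per traversal ('trial') in the requested direction.

    Trials are maximal monotone traversals covering at least
    ``min_frac`` of the track length; trials without spikes appear as
    empty rows.  A trajectory with no complete traversal yields an
    empty list.
    """
    if direction not in ("inbound", "outbound"):
        raise ValueError("direction must be 'inbound' or 'outbound'")
    runs = [r for r in _segment_runs(traj, min_frac) if r[2] == direction]
    t, x = traj.times_s, traj.position_cm
    out: list[np.ndarray] = []
    for start, stop, _ in runs:
        t_lo, t_hi = t[start], t[stop]
        sel = (spikes.times_s >= t_lo) & (spikes.times_s < t_hi)
        out.append(np.interp(spikes.times_s[sel], t, x))
    return out
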