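"""Sharp-wave-ripple (SWR) detection from a single-channel LFP trace.

Ripples are transient 120–250 Hz oscillations in the hippocampal local
field potential.  Detection follows the classical recipe: zero-phase
band-pass filtering, analytic-signal (Hilbert) envelope extraction with
Gaussian smoothing, and thresholding of the envelope expressed in
standard deviations from its mean.  An event is a supra-threshold
excursion of the envelope; its boundaries are extended outward to the
nearest crossings of a lower boundary threshold, so that the reported
onset approximates where ripple power first rises out of the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "LfpTrace",
    "RippleEvent",
    "RippleDetectConfig",
    "bandpass",
    "envelope",
    "detect",
    "offset_ripples",
]


@dataclass(frozen=True)
class LfpTrace:
    """A uniformly sampled single-channel LFP segment.

    Parameters
    ----------
    samples : ndarray
        Amplitudes in microvolts (or arbitrary units).
    rate : float
        Sampling rate in Hz.
    t0 : float
        Time of the first sample in seconds.
    """

    samples: np.ndarray
    rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if self.samples.ndim != 1:
            raise ValueError("LfpTrace holds a single channel (1-D samples)")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate

    @property
    def times_s(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate


@dataclass(frozen=True)
class RippleEvent:
    """One detected SWR: boundary times plus the envelope peak in SD units."""

    onset_s: float
    offset_s: float
    peak_sd: float

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError("offset must follow onset")

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class RippleDetectConfig:
    """Detection parameters.

    ``detect_sd`` is the peak threshold that declares an event and
    ``bound_sd`` the lower threshold that defines event boundaries, both
    in SDs of the smoothed envelope.  ``smooth_ms`` is the sigma of the
    Gaussian envelope-smoothing kernel; without smoothing, intra-ripple
    envelope troughs split single events.
    Adjacent events separated by less than ``merge_ms`` are merged, and
    events shorter than ``min_dur_ms`` are discarded.

    ``sd_estimation`` selects how the envelope mean and SD are
    estimated: ``"robust"`` (default) iteratively excludes
    supra-boundary samples so the ripples themselves do not inflate the
    baseline statistics and bias event boundaries inward;
    ``"whole"`` uses the raw whole-trace moments.
    """

    band_hz: tuple[float, float] = (120.0, 250.0)
    detect_sd: float = 5.0
    bound_sd: float = 2.0
    smooth_ms: float = 8.0
    merge_ms: float = 20.0
    min_dur_ms: float = 20.0
    filter_order: int = 4
    sd_estimation: str = "robust"

    def __post_init__(self) -> None:
        lo, hi = self.band_hz
        if not lo < hi:
            raise ValueError("band low edge must be below high edge")
        if not self.detect_sd > self.bound_sd > 0:
            raise ValueError("require detect_sd > bound_sd > 0")
        if self.sd_estimation not in ("robust", "whole"):
            raise ValueError("sd_estimation must be 'robust' or 'whole'")


def bandpass(trace: LfpTrace, band_hz: tuple[float, float] = (120.0, 250.0),
             order: int = 4) -> LfpTrace:
    """Zero-phase Butterworth band-pass filter.

    Forward-backward filtering keeps event onset times unbiased.  The
    band must lie strictly inside the Nyquist range.
    """
    lo, hi = band_hz
    nyq = trace.rate / 2.0
    if not (0 < lo < hi < nyq):
        raise ValueError(
            f"band ({lo}, {hi}) Hz invalid for sampling rate {trace.rate} Hz"
        )
    sos = signal.butter(order, [lo, hi], btype="bandpass", fs=trace.rate,
                        output="sos")
    filtered = signal.sosfiltfilt(sos, trace.samples)
    return replace(trace, samples=filtered)


def envelope(filtered: LfpTrace, smooth_ms: float = 8.0) -> LfpTrace:
    """Instantaneous magnitude of a band-passed trace, Gaussian-smoothed.

    Uses the analytic-signal (Hilbert transform) magnitude; output is
    nonnegative and shares the input's time base.
    """
    env = np.abs(signal.hilbert(filtered.samples))
    if smooth_ms > 0:
        sigma_samples = smooth_ms * 1e-3 * filtered.rate
        if sigma_samples > 0:
            env = gaussian_filter1d(env, sigma_samples, mode="nearest")
    return replace(filtered, samples=env)


def _merge_close(events: list[RippleEvent], merge_s: float) -> list[RippleEvent]:
    if not events:
        return []
    merged = [events[0]]
    for ev in events[1:]:
        prev = merged[-1]
        if ev.onset_s - prev.offset_s < merge_s:
            merged[-1] = RippleEvent(
                onset_s=prev.onset_s,
                offset_s=max(prev.offset_s, ev.offset_s),
                peak_sd=max(prev.peak_sd, ev.peak_sd),
            )
        else:
            merged.append(ev)
    return merged


def detect(trace: LfpTrace, cfg: RippleDetectConfig | None = None) -> list[RippleEvent]:
    """Detect SWRs in a raw LFP trace.

    The envelope of the band-passed signal is z-scored against its
    baseline mean and SD (quantile-estimated by default, see
    ``RippleDetectConfig``).  Every excursion above ``cfg.detect_sd``
    yields a candidate event whose boundaries are pushed outward to the
    nearest ``cfg.bound_sd`` crossings; candidates closer than
    ``cfg.merge_ms`` are merged and events shorter than
    ``cfg.min_dur_ms`` dropped.  Returned events are sorted and
    non-overlapping.
    """
    cfg = cfg or RippleDetectConfig()
    if trace.duration_s < 1.0:
        raise ValueError("trace shorter than 1 s: cannot estimate envelope SD")
    if np.ptp(trace.samples) == 0:
        raise ValueError("degenerate input: constant trace has zero SD")
    filt = bandpass(trace, cfg.band_hz, order=cfg.filter_order)
    env = envelope(filt, cfg.smooth_ms).samples
    mu, sd = env.mean(), env.std()
    if sd == 0:
        raise ValueError("degenerate input: envelope has zero variance")
    if cfg.sd_estimation == "robust":
        # quantile-based baseline statistics: insensitive to the small
        # fraction of high-amplitude ripple samples that would otherwise
        # inflate the SD and bias event boundaries inward
        mu = float(np.median(env))
        iqr = float(np.subtract(*np.percentile(env, [75, 25])))
        if iqr > 0:
            sd = iqr / 1.349  # Gaussian-equivalent sigma
    z = (env - mu) / sd

    above_detect = z > cfg.detect_sd
    if not above_detect.any():
        return []
    above_bound = z > cfg.bound_sd
    # contiguous runs above the boundary threshold
    edges = np.diff(above_bound.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    stops = np.flatnonzero(edges == -1) + 1
    if above_bound[0]:
        starts = np.r_[0, starts]
    if above_bound[-1]:
        stops = np.r_[stops, above_bound.size]

    events: list[RippleEvent] = []
    for s, e in zip(starts, stops):
        seg = z[s:e]
        peak = float(seg.max())
        if peak <= cfg.detect_sd:
            continue
        # linear interpolation of the exact boundary crossings
        onset = float(s)
        if s > 0 and z[s] > z[s - 1]:
            onset = s - (z[s] - cfg.bound_sd) / (z[s] - z[s - 1])
        offset = float(e - 1)
        if e < z.size and z[e - 1] > z[e]:
            offset = (e - 1) + (z[e - 1] - cfg.bound_sd) / (z[e - 1] - z[e])
        events.append(RippleEvent(
            onset_s=trace.t0 + onset / trace.rate,
            offset_s=trace.t0 + offset / trace.rate,
            peak_sd=peak,
        ))
    events = _merge_close(events, cfg.merge_ms * 1e-3)
    events = [ev for ev in events if ev.duration_s >= cfg.min_dur_ms * 1e-3]
    return events


def offset_ripples(events: list[RippleEvent], dt_s: float) -> list[RippleEvent]:
    """Shift every event boundary by ``dt_s`` seconds (durations unchanged).

    A negative shift moves ripple times earlier relative to the spike
    trains, decoupling spikes from the ripple window they occurred in.
    """
    return [RippleEvent(ev.onset_s + dt_s, ev.offset_s + dt_s, ev.peak_sd)
            for ev in events]
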