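"""Ground-truth-labeled synthetic electrophysiology sessions.

Every downstream stage of the pipeline is testable without recordings:
this module generates (a) rest-epoch LFP with ripple-band transients at
known times plus CA3/CA1 spike trains carrying a controllable number of
planted causal pairs, (b) linear-track sessions with Gaussian
place-field units and a back-and-forth trajectory, and (c) two-pathway
EPSC sweep series with a planted slow-rising potentiation factor.

All generators are deterministic given the master seed: per-component
substreams are spawned from one ``numpy`` SeedSequence, so changing one
component's draw count never perturbs another's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import ripples as _ripples
from .placemaps import TrajectorySeries
from .plasticity import EpscSeries
from .ripples import LfpTrace
from .swrstats import SpikeTrain

__all__ = ["SynthConfig", "GroundTruth", "gen_rest_session",
           "gen_track_session", "gen_epsc_series"]


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for a synthetic rest or track session.

    Ripple parameters follow the statistics of hippocampal SWRs: a
    carrier in the 120–250 Hz band (default 150 Hz), durations of
    50–100 ms, about 0.19 events/s during quiet rest, and a peak
    ripple-band envelope of ``ripple_snr`` background SDs.  Spiking is
    sparse Poisson background plus, per CA1 unit, a configured number of
    planted causal pairs: a CA3 spike in the fractional SWR window
    followed by its CA1 partner at a lag strictly below 30 ms.
    """

    seed: int = 0
    duration_s: float = 200.0
    lfp_rate_hz: float = 2000.0
    ripple_rate_hz: float = 0.19
    ripple_freq_hz: float = 150.0
    ripple_dur_range_s: tuple[float, float] = (0.05, 0.1)
    ripple_snr: float = 8.0
    n_ca3: int = 1
    n_ca1: int = 4
    baseline_rate_hz: float = 0.5
    planted_pairs_per_train: tuple[int, ...] = (8, 4, 2, 0)
    pair_lag_range_ms: tuple[float, float] = (5.0, 25.0)
    pair_phase_range: tuple[float, float] = (0.0, 0.5)
    noise_color: str = "pink"
    # linear-track session parameters
    track_length_cm: float = 200.0
    run_speed_cm_s: float = 20.0
    traj_rate_hz: float = 50.0
    traj_jitter_cm: float = 0.0
    field_sigma_cm: float = 10.0
    field_peak_hz: float = 10.0
    field_centers_cm: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        lo, hi = self.pair_lag_range_ms
        if not (0 < lo <= hi < 30.0):
            raise ValueError("pair lags must lie strictly within (0, 30) ms")
        plo, phi = self.pair_phase_range
        if not (-0.3 <= plo <= phi <= 0.6):
            raise ValueError("pair phases must lie within [-0.3, 0.6]")
        if len(self.planted_pairs_per_train) != self.n_ca1:
            raise ValueError("need one planted-pair count per CA1 unit")
        if any(k < 0 for k in self.planted_pairs_per_train):
            raise ValueError("planted pair counts must be nonnegative")
        if sum(self.planted_pairs_per_train) > 0 and self.n_ca3 < 1:
            raise ValueError("planted pairs need at least one CA3 unit")
        if self.noise_color not in ("pink", "white"):
            raise ValueError("noise_color must be 'pink' or 'white'")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for use as a test oracle."""

    ripple_times: tuple[tuple[float, float], ...]
    planted_pairs: tuple[tuple[tuple[float, float, int], ...], ...]

    @property
    def n_ripples(self) -> int:
        return len(self.ripple_times)


def _ca3_id(i: int) -> str:
    return f"CA3{chr(ord('a') + i)}"


def _ca1_id(i: int) -> str:
    return f"CA1{chr(ord('b') + i)}"


def _background_noise(rng: np.random.Generator, n: int, color: str) -> np.ndarray:
    """Unit-SD background; pink (1/f amplitude) by default."""
    white = rng.standard_normal(n)
    if color == "white":
        return white
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    scale = np.ones_like(freqs)
    nz = freqs > 0
    scale[nz] = 1.0 / np.sqrt(freqs[nz])
    scale[0] = 0.0
    out = np.fft.irfft(spec * scale, n)
    return out / out.std()


def _draw_ripple_times(rng: np.random.Generator, cfg: SynthConfig) -> list[tuple[float, float]]:
    """Non-overlapping (onset, offset) pairs at roughly the configured rate.

    Events keep a 0.3 s guard interval from each other and from the
    session edges so that fractional classification windows of distinct
    ripples never interact.
    """
    n_target = rng.poisson(cfg.ripple_rate_hz * cfg.duration_s)
    guard = 0.3
    lo_t, hi_t = 0.5, cfg.duration_s - 0.7
    if hi_t <= lo_t:
        return []
    onsets: list[float] = []
    durs: list[float] = []
    attempts = 0
    max_attempts = 200 * max(n_target, 1)
    while len(onsets) < n_target and attempts < max_attempts:
        attempts += 1
        onset = float(rng.uniform(lo_t, hi_t))
        dur = float(rng.uniform(*cfg.ripple_dur_range_s))
        if all(abs(onset - o) > (dur + d + guard) for o, d in zip(onsets, durs)):
            onsets.append(onset)
            durs.append(dur)
    order = np.argsort(onsets)
    return [(onsets[i], onsets[i] + durs[i]) for i in order]


def _ripple_waveform(times: np.ndarray, onset: float, offset: float,
                     freq_hz: float, amplitude: float) -> np.ndarray:
    """Gaussian-windowed oscillation; sigma = duration/4 puts the 2-sigma
    envelope boundary at the nominal onset/offset."""
    center = 0.5 * (onset + offset)
    sigma = (offset - onset) / 4.0
    env = amplitude * np.exp(-0.5 * ((times - center) / sigma) ** 2)
    return env * np.sin(2 * np.pi * freq_hz * (times - center))


def _poisson_times(rng: np.random.Generator, rate_hz: float, duration_s: float) -> np.ndarray:
    n = rng.poisson(rate_hz * duration_s)
    return np.sort(rng.uniform(0.0, duration_s, size=n))


def gen_rest_session(cfg: SynthConfig) -> tuple[LfpTrace, list[SpikeTrain], GroundTruth]:
    """Generate a rest-epoch session: LFP, spike trains, and ground truth.

    The LFP is pink-noise background plus Gaussian-windowed
    ``ripple_freq_hz`` oscillations at the ground-truth ripple times,
    scaled so each peak envelope is ``ripple_snr`` SDs of the
    band-passed background.  Each CA1 train carries exactly its
    configured number of planted causal pairs — the CA3 partner spike
    goes into the first CA3 train — on top of independent Poisson
    background at ``baseline_rate_hz``.  Each planted pair occupies its
    own ripple; a config requesting more pairs than ripples is rejected
    as over-constrained.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_rip, rng_lfp, rng_pairs, rng_bg = map(np.random.default_rng, ss.spawn(4))

    ripple_times = _draw_ripple_times(rng_rip, cfg)
    n_samples = int(round(cfg.duration_s * cfg.lfp_rate_hz))
    t = np.arange(n_samples) / cfg.lfp_rate_hz

    noise = _background_noise(rng_lfp, n_samples, cfg.noise_color)
    lfp = noise.copy()
    if ripple_times:
        band_sd = _ripples.bandpass(
            LfpTrace(noise, cfg.lfp_rate_hz), (120.0, 250.0)).samples.std()
        amp = cfg.ripple_snr * band_sd
        for onset, offset in ripple_times:
            i0 = max(int((onset - 0.1) * cfg.lfp_rate_hz), 0)
            i1 = min(int((offset + 0.1) * cfg.lfp_rate_hz), n_samples)
            lfp[i0:i1] += _ripple_waveform(t[i0:i1], onset, offset,
                                           cfg.ripple_freq_hz, amp)
    trace = LfpTrace(lfp, cfg.lfp_rate_hz, 0.0)

    total_pairs = sum(cfg.planted_pairs_per_train)
    if total_pairs > len(ripple_times):
        raise ValueError(
            f"over-constrained config: {total_pairs} planted pairs requested "
            f"but only {len(ripple_times)} ripples available")

    # each pair gets its own ripple so planted events never interact
    if total_pairs:
        chosen = rng_pairs.choice(len(ripple_times), size=total_pairs, replace=False)
    else:
        chosen = np.array([], dtype=int)
    pair_iter = iter(chosen)
    planted: list[tuple[tuple[float, float, int], ...]] = []
    ca3_extra: list[float] = []
    ca1_planted: list[list[float]] = []
    for k in cfg.planted_pairs_per_train:
        unit_pairs = []
        unit_times = []
        for _ in range(k):
            ridx = int(next(pair_iter))
            onset, offset = ripple_times[ridx]
            dur = offset - onset
            phase = rng_pairs.uniform(*cfg.pair_phase_range)
            lag_s = rng_pairs.uniform(*cfg.pair_lag_range_ms) * 1e-3
            t3 = onset + phase * dur
            t1 = t3 + lag_s
            unit_pairs.append((float(t3), float(t1), ridx))
            unit_times.append(float(t1))
            ca3_extra.append(float(t3))
        planted.append(tuple(sorted(unit_pairs)))
        ca1_planted.append(unit_times)

    trains: list[SpikeTrain] = []
    for i in range(cfg.n_ca3):
        bg = _poisson_times(rng_bg, cfg.baseline_rate_hz, cfg.duration_s)
        times = np.sort(np.r_[bg, ca3_extra]) if i == 0 else bg
        trains.append(SpikeTrain(_ca3_id(i), "CA3", np.unique(times)))
    for j in range(cfg.n_ca1):
        bg = _poisson_times(rng_bg, cfg.baseline_rate_hz, cfg.duration_s)
        times = np.unique(np.r_[bg, ca1_planted[j]])
        trains.append(SpikeTrain(_ca1_id(j), "CA1", times))

    gt = GroundTruth(ripple_times=tuple(ripple_times), planted_pairs=tuple(planted))
    return trace, trains, gt


def gen_track_session(cfg: SynthConfig) -> tuple[TrajectorySeries, list[SpikeTrain]]:
    """Generate a linear-track session: trajectory plus place-cell spiking.

    The trajectory is a constant-speed back-and-forth sweep of the
    track (optional position jitter); each unit fires as an
    inhomogeneous Poisson process with a Gaussian place field, sampled
    by thinning a homogeneous process at the peak rate.
    """
    ss = np.random.SeedSequence(cfg.seed)
    _, _, _, _, rng_traj, rng_spk = map(np.random.default_rng, ss.spawn(6))

    n = int(round(cfg.duration_s * cfg.traj_rate_hz))
    t = np.arange(n) / cfg.traj_rate_hz
    L = cfg.track_length_cm
    period = 2 * L / cfg.run_speed_cm_s
    saw = np.mod(t, period) / period          # 0..1
    x = L * (1 - np.abs(2 * saw - 1))          # triangular sweep 0->L->0
    if cfg.traj_jitter_cm > 0:
        x = np.clip(x + rng_traj.normal(0, cfg.traj_jitter_cm, size=n), 0, L)
    traj = TrajectorySeries(t, x, track_length_cm=L)

    n_units = cfg.n_ca3 + cfg.n_ca1
    if cfg.field_centers_cm is not None:
        centers = list(cfg.field_centers_cm)
        if len(centers) != n_units:
            raise ValueError("need one field center per unit")
    else:
        centers = list(np.linspace(0.1 * L, 0.9 * L, n_units))

    trains: list[SpikeTrain] = []
    for u in range(n_units):
        c = centers[u]
        if cfg.field_peak_hz <= 0:
            times = np.array([])
        else:
            cand = _poisson_times(rng_spk, cfg.field_peak_hz, cfg.duration_s)
            pos = np.interp(cand, t, x)
            p_accept = np.exp(-0.5 * ((pos - c) / cfg.field_sigma_cm) ** 2)
            keep = rng_spk.uniform(size=cand.size) < p_accept
            times = np.unique(cand[keep])
        region = "CA3" if u < cfg.n_ca3 else "CA1"
        uid = _ca3_id(u) if u < cfg.n_ca3 else _ca1_id(u - cfg.n_ca3)
        trains.append(SpikeTrain(uid, region, times))
    return traj, trains


def gen_epsc_series(n_baseline_min: float = 5.0, n_post_min: float = 30.0,
                    true_factor: float = 1.0, noise_cv: float = 0.1,
                    seed: int = 0, sweep_interval_s: float = 10.0,
                    baseline_pa: float = 30.0, pathway: str = "test",
                    rise_t50_min: float = 7.0, rise_tau_min: float = 2.0) -> EpscSeries:
    """Generate one pathway's EPSC amplitude series with planted LTP.

    Pre-induction sweeps sit at ``baseline_pa``; after the induction
    marker the clean amplitude rises along a logistic (slow-onset)
    curve toward ``true_factor`` x baseline, reaching saturation well
    before the standard 25–30 min comparison window.  Multiplicative
    Gaussian noise with coefficient of variation ``noise_cv`` is
    applied per sweep.
    """
    if true_factor <= 0:
        raise ValueError("true_factor must be positive")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    t_ind = n_baseline_min * 60.0
    total_s = (n_baseline_min + n_post_min) * 60.0
    times = np.arange(0.0, total_s, sweep_interval_s)
    m_post = (times - t_ind) / 60.0
    rise = 1.0 / (1.0 + np.exp(-(m_post - rise_t50_min) / rise_tau_min))
    clean = baseline_pa * np.where(times < t_ind, 1.0,
                                   1.0 + (true_factor - 1.0) * rise)
    if noise_cv > 0:
        clean = clean * (1.0 + noise_cv * rng.standard_normal(times.size))
    return EpscSeries(sweep_times_s=times, amplitudes_pa=clean,
                      pathway=pathway, induction_time_s=t_ind)
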