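"""Synaptic-strength quantification from EPSC sweep series.

The in vitro readout of plasticity: per-pathway EPSC amplitude series
are averaged into one point per minute (six sweeps at 0.1 Hz),
normalized to the pre-induction baseline mean, and compared between the
induced (test) and non-induced (control) pathway in a fixed window
after induction.  The relative change in synaptic strength is the mean
normalized test response minus the mean normalized control response
over the final window, and a paired two-tailed t-test across
experiments (biological replicates) assesses pathway specificity.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import stats

__all__ = [
    "EpscSeries",
    "PlasticityOutcome",
    "qc_series_resistance",
    "minute_average",
    "normalize_to_baseline",
    "compare_pathways",
    "correlate_predictor",
]


@dataclass(frozen=True)
class EpscSeries:
    """Per-sweep EPSC amplitudes for one pathway of one experiment.

    ``induction_time_s`` is explicit metadata marking when the
    induction protocol was delivered; it is never inferred from the
    data.  ``series_resistance_mohm`` is optional per-sweep access
    resistance for quality control.
    """

    sweep_times_s: np.ndarray
    amplitudes_pa: np.ndarray
    pathway: str = "test"
    induction_time_s: float | None = None
    series_resistance_mohm: np.ndarray | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.sweep_times_s, dtype=float)
        a = np.asarray(self.amplitudes_pa, dtype=float)
        object.__setattr__(self, "sweep_times_s", t)
        object.__setattr__(self, "amplitudes_pa", a)
        if self.series_resistance_mohm is not None:
            rs = np.asarray(self.series_resistance_mohm, dtype=float)
            object.__setattr__(self, "series_resistance_mohm", rs)
        if t.size != a.size:
            raise ValueError("times and amplitudes must have equal length")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("sweep times must be increasing")
        if not np.all(np.isfinite(a)):
            raise ValueError("amplitudes must be finite")
        if self.pathway not in ("test", "control", "ripple"):
            raise ValueError("pathway must be test|control|ripple")


@dataclass(frozen=True)
class PlasticityOutcome:
    """Test-vs-control comparison across experiments."""

    norm_test_final: float
    norm_control_final: float
    relative_change: float
    p_value: float
    n: int


def qc_series_resistance(series: EpscSeries, max_change: float = 0.20,
                         missing_ok: bool = False) -> bool:
    """True (pass) unless series resistance drifts > ``max_change``.

    Drift is measured relative to the initial value; any sweep beyond
    the bound fails the recording.
    """
    rs = series.series_resistance_mohm
    if rs is None or rs.size == 0:
        if missing_ok:
            return True
        raise ValueError("series resistance missing; pass missing_ok=True to accept")
    r0 = rs[0]
    if r0 == 0:
        raise ValueError("initial series resistance is zero")
    return bool(np.all(np.abs(rs - r0) / abs(r0) <= max_change))


def minute_average(series: EpscSeries, group: int = 6) -> EpscSeries:
    """Average consecutive non-overlapping groups of ``group`` sweeps.

    Six sweeps at 0.1 Hz give one data point per minute; a partial
    trailing group is dropped.  Point times are group means.
    """
    n = series.amplitudes_pa.size
    if n < group:
        raise ValueError(f"need at least {group} sweeps, got {n}")
    n_pts = n // group
    amp = series.amplitudes_pa[: n_pts * group].reshape(n_pts, group).mean(axis=1)
    t = series.sweep_times_s[: n_pts * group].reshape(n_pts, group).mean(axis=1)
    rs = series.series_resistance_mohm
    if rs is not None:
        rs = rs[: n_pts * group].reshape(n_pts, group).mean(axis=1)
    return replace(series, sweep_times_s=t, amplitudes_pa=amp,
                   series_resistance_mohm=rs)


def normalize_to_baseline(series: EpscSeries, baseline_min: float = 5.0) -> EpscSeries:
    """Divide every point by the mean of the pre-induction baseline window.

    The baseline window is the ``baseline_min`` minutes immediately
    before ``induction_time_s``; the normalized baseline mean is 1 by
    construction.
    """
    if series.induction_time_s is None:
        raise ValueError("induction_time_s metadata required for normalization")
    t0 = series.induction_time_s
    sel = (series.sweep_times_s >= t0 - baseline_min * 60.0) & (series.sweep_times_s < t0)
    if not sel.any():
        raise ValueError("no sweeps inside the baseline window")
    base = series.amplitudes_pa[sel].mean()
    if base == 0:
        raise ValueError("zero baseline mean")
    return replace(series, amplitudes_pa=series.amplitudes_pa / base)


def _window_mean(series: EpscSeries, window_min: tuple[float, float]) -> float:
    if series.induction_time_s is None:
        raise ValueError("induction_time_s metadata required")
    lo = series.induction_time_s + window_min[0] * 60.0
    hi = series.induction_time_s + window_min[1] * 60.0
    sel = (series.sweep_times_s >= lo) & (series.sweep_times_s < hi)
    if not sel.any():
        raise ValueError(f"no points in the {window_min} min post-induction window")
    return float(series.amplitudes_pa[sel].mean())


def compare_pathways(test: list[EpscSeries], control: list[EpscSeries],
                     window_min: tuple[float, float] = (25.0, 30.0)) -> PlasticityOutcome:
    """Paired test-vs-control comparison over the final window.

    Inputs are normalized per-experiment series (one test and one
    control per experiment, same order).  Per-experiment window means
    are compared with a paired two-tailed Student's t-test; the
    relative change is mean(test) - mean(control) over the window.
    """
    if len(test) != len(control):
        raise ValueError("unequal experiment counts for test and control")
    if len(test) < 2:
        raise ValueError("need >= 2 experiments for a paired comparison")
    t_means = np.array([_window_mean(s, window_min) for s in test])
    c_means = np.array([_window_mean(s, window_min) for s in control])
    diffs = t_means - c_means
    if np.allclose(diffs.std(), 0.0):
        p = 1.0 if np.allclose(diffs, 0.0) else 0.0
    else:
        p = float(stats.ttest_rel(t_means, c_means).pvalue)
    return PlasticityOutcome(
        norm_test_final=float(t_means.mean()),
        norm_control_final=float(c_means.mean()),
        relative_change=float(t_means.mean() - c_means.mean()),
        p_value=p,
        n=len(test),
    )


def correlate_predictor(changes: np.ndarray, predictor: np.ndarray) -> float:
    """Coefficient of determination (r^2) of change regressed on predictor.

    Ordinary least squares of relative synaptic change on a spike-train
    predictor count; at least three points and nonzero predictor
    variance are required.
    """
    changes = np.asarray(changes, dtype=float)
    predictor = np.asarray(predictor, dtype=float)
    if changes.size != predictor.size:
        raise ValueError("changes and predictor must have equal length")
    if changes.size < 3:
        raise ValueError("need >= 3 points for a correlation")
    if np.allclose(predictor.std(), 0.0):
        raise ValueError("zero predictor variance")
    res = stats.linregress(predictor, changes)
    return float(res.rvalue ** 2)
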