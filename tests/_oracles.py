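"""Independent brute-force reference implementations used as test oracles.

These deliberately use naive nested-loop logic (no searchsorted, no
vectorization, no shared code with the package) while honoring the same
documented policies: strict (0, max_lag) pairing window, CA3-anchored
fractional SWR window, maximal-run burst grouping, and greedy
left-to-right consumption of CA1 candidates.
"""

from __future__ import annotations


def bruteforce_classify(ca3_times, ca1_times, ripple_spans,
                        max_lag_ms: float = 30.0, pre_frac: float = 0.3,
                        post_frac: float = 0.6, burst_isi_ms: float = 10.0):
    """Exhaustive causal-pair classification.

    ``ripple_spans`` is a sorted list of (onset, offset).  Returns a
    list of (ca3_t, ca1_t, ripple_idx, member_times) tuples in CA3 time
    order.
    """
    ca1 = sorted(float(t) for t in ca1_times)
    # group CA1 spikes into maximal runs with ISIs <= threshold
    groups: list[list[float]] = []
    for t in ca1:
        if groups and t - groups[-1][-1] <= burst_isi_ms * 1e-3:
            groups[-1].append(t)
        else:
            groups.append([t])
    consumed = [False] * len(groups)
    out = []
    for t3 in sorted(float(t) for t in ca3_times):
        window = None
        for idx, (onset, offset) in enumerate(ripple_spans):
            dur = offset - onset
            if onset - pre_frac * dur <= t3 <= onset + post_frac * dur:
                window = idx
                break
        if window is None:
            continue
        best = None
        for k, g in enumerate(groups):
            if consumed[k]:
                continue
            lag = g[0] - t3
            if 0 < lag < max_lag_ms * 1e-3:
                if best is None or g[0] < groups[best][0]:
                    best = k
        if best is None:
            continue
        consumed[best] = True
        out.append((t3, groups[best][0], window, tuple(groups[best])))
    return out


def bruteforce_pair_count(ca3_times, ca1_times, lag_lo_ms, lag_hi_ms):
    """O(n^2) count of (ca3, ca1) pairs with lag in [lag_lo, lag_hi) ms."""
    n = 0
    for t3 in ca3_times:
        for t1 in ca1_times:
            lag = (t1 - t3) * 1e3
            if lag_lo_ms <= lag < lag_hi_ms:
                n += 1
    return n


def random_session(rng, n_ripples=8, n_ca3=40, n_ca1=40, duration=20.0,
                   dur_range=(0.04, 0.1)):
    """A random spike/ripple session for oracle comparison."""
    spans = []
    t = rng.uniform(0.3, 0.8)
    while len(spans) < n_ripples and t < duration - 0.5:
        d = rng.uniform(*dur_range)
        spans.append((t, t + d))
        t += d + rng.uniform(0.35, 1.2)
    import numpy as np
    ca3 = np.unique(rng.uniform(0, duration, size=rng.integers(0, n_ca3 + 1)))
    ca1 = np.unique(rng.uniform(0, duration, size=rng.integers(0, n_ca1 + 1)))
    # sprinkle some spikes right around ripples so windows are exercised
    extra3, extra1 = [], []
    for onset, offset in spans:
        dur = offset - onset
        for _ in range(rng.integers(0, 4)):
            extra3.append(onset + rng.uniform(-0.5, 1.0) * dur)
            extra1.append(onset + rng.uniform(-0.5, 1.0) * dur
                          + rng.uniform(-0.02, 0.04))
    ca3 = np.unique(np.r_[ca3, extra3])
    ca1 = np.unique(np.r_[ca1, extra1])
    return ca3, ca1, spans
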