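import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ripplereplay import RippleEvent, SpikeTrain


def make_train(times, region="CA1", unit_id=None):
    return SpikeTrain(unit_id or f"{region}x", region, np.asarray(times, dtype=float))


@pytest.fixture
def eight_event_fixture():
    """Eight causal events comprising ten CA1 spikes.

    Six single-spike pairs plus two pairs whose CA1 partner is a
    two-spike burst (6 + 2*2 = 10 CA1 member spikes), one event per
    ripple, with non-event background spikes far from every window.
    """
    ripples = [RippleEvent(float(k + 1), float(k + 1) + 0.1, 10.0) for k in range(8)]
    ca3_times, ca1_times = [], []
    for k in range(6):
        t3 = ripples[k].onset_s + 0.010
        ca3_times.append(t3)
        ca1_times.append(t3 + 0.012)
    for k in range(6, 8):
        t3 = ripples[k].onset_s + 0.010
        ca3_times.append(t3)
        ca1_times.extend([t3 + 0.010, t3 + 0.015])
    # background spikes outside all windows and >30 ms from any anchor
    ca3_times.extend([0.5, 9.5])
    ca1_times.extend([0.6, 9.6])
    ca3 = make_train(sorted(ca3_times), "CA3", "CA3a")
    ca1 = make_train(sorted(ca1_times), "CA1", "CA1d")
    return ca3, ca1, ripples
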