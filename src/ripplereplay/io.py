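"""Plain-text readers and writers for every artifact in the pipeline.

Formats are deliberately trivial delimited text with ``#`` headers so
that stimulus-delivery or acquisition software can parse them with one
split per line.  All writers round-trip through the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .plasticity import EpscSeries
from .protocols import StimProtocol
from .ripples import LfpTrace, RippleEvent
from .swrstats import SpikeTrain
from .synthio import GroundTruth

__all__ = [
    "write_spike_trains", "read_spike_trains",
    "write_lfp", "read_lfp",
    "write_ripple_events", "read_ripple_events",
    "write_ground_truth", "read_ground_truth",
    "write_protocol", "read_protocol",
    "write_epsc_series", "read_epsc_series",
]


def _region_of(unit_id: str) -> str:
    for region in ("CA3", "CA1"):
        if unit_id.upper().startswith(region):
            return region
    raise ValueError(f"cannot infer region from unit id {unit_id!r}; "
                     "ids must start with CA3 or CA1")


def write_spike_trains(path: str | Path, trains: list[SpikeTrain]) -> None:
    """Two-column delimited text: unit_id, time_s (region from the id prefix)."""
    with open(path, "w") as fh:
        fh.write("# unit_id\ttime_s\n")
        for tr in trains:
            for t in tr.times_s:
                fh.write(f"{tr.unit_id}\t{t:.6f}\n")


def read_spike_trains(path: str | Path) -> list[SpikeTrain]:
    by_unit: dict[str, list[float]] = {}
    order: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            uid, t = line.split("\t")
            if uid not in by_unit:
                by_unit[uid] = []
                order.append(uid)
            by_unit[uid].append(float(t))
    return [SpikeTrain(uid, _region_of(uid), np.sort(by_unit[uid]))
            for uid in order]


def write_lfp(path: str | Path, trace: LfpTrace) -> None:
    """Single amplitude column with a sidecar header (rate, start time)."""
    with open(path, "w") as fh:
        fh.write(f"# rate_hz={trace.rate}\n# t0_s={trace.t0}\n")
        np.savetxt(fh, trace.samples, fmt="%.6f")


def read_lfp(path: str | Path) -> LfpTrace:
    rate = t0 = None
    with open(path) as fh:
        header = []
        for line in fh:
            if line.startswith("#"):
                header.append(line)
            else:
                break
    for line in header:
        key, _, val = line.lstrip("# ").strip().partition("=")
        if key == "rate_hz":
            rate = float(val)
        elif key == "t0_s":
            t0 = float(val)
    if rate is None:
        raise ValueError(f"{path}: missing rate_hz header")
    samples = np.loadtxt(path, comments="#")
    return LfpTrace(np.atleast_1d(samples), rate, t0 or 0.0)


def write_ripple_events(path: str | Path, events: list[RippleEvent],
                        header: dict | None = None) -> None:
    """onset_s, offset_s, peak_sd per line; parameters echoed in the header."""
    with open(path, "w") as fh:
        for key, val in (header or {}).items():
            fh.write(f"# {key}={val}\n")
        fh.write("# onset_s\toffset_s\tpeak_sd\n")
        for ev in events:
            fh.write(f"{ev.onset_s:.6f}\t{ev.offset_s:.6f}\t{ev.peak_sd:.4f}\n")


def read_ripple_events(path: str | Path) -> list[RippleEvent]:
    events = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            onset, offset, peak = line.split("\t")
            events.append(RippleEvent(float(onset), float(offset), float(peak)))
    return events


def write_ground_truth(path: str | Path, gt: GroundTruth) -> None:
    payload = {
        "ripple_times": [list(rt) for rt in gt.ripple_times],
        "planted_pairs": [[list(p) for p in unit] for unit in gt.planted_pairs],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        ripple_times=tuple((a, b) for a, b in payload["ripple_times"]),
        planted_pairs=tuple(tuple((a, b, int(i)) for a, b, i in unit)
                            for unit in payload["planted_pairs"]),
    )


def write_protocol(path: str | Path, proto: StimProtocol) -> None:
    """One line per scheduled event: channel, time_s, param1, param2."""
    with open(path, "w") as fh:
        fh.write(f"# mode={proto.mode}\n# duration_s={proto.duration_s}\n")
        for key, val in proto.metadata.items():
            fh.write(f"# {key}={val}\n")
        fh.write("# channel\ttime_s\tparam1\tparam2\n")
        for t in proto.presyn_test_times_s:
            fh.write(f"epsp\t{t:.6f}\t0\t0\n")
        for t in proto.postsyn_ap_times_s:
            fh.write(f"ap\t{t:.6f}\t2\t2\n")
        for start, n, rate in proto.ripple_path_trains:
            fh.write(f"ripple_train\t{start:.6f}\t{n}\t{rate}\n")


def read_protocol(path: str | Path) -> StimProtocol:
    mode, duration = "unknown", 0.0
    metadata: dict = {}
    epsp, ap, trains = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, val = line.lstrip("# ").partition("=")
                if not sep:
                    continue
                if key == "mode":
                    mode = val
                elif key == "duration_s":
                    duration = float(val)
                else:
                    metadata[key] = val
                continue
            channel, t, p1, p2 = line.split("\t")
            if channel == "epsp":
                epsp.append(float(t))
            elif channel == "ap":
                ap.append(float(t))
            elif channel == "ripple_train":
                trains.append((float(t), int(p1), float(p2)))
    return StimProtocol(
        presyn_test_times_s=np.array(epsp),
        postsyn_ap_times_s=np.array(ap),
        ripple_path_trains=tuple(trains),
        mode=mode, duration_s=duration, metadata=metadata,
    )


def write_epsc_series(path: str | Path, series: EpscSeries) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pathway={series.pathway}\n")
        if series.induction_time_s is not None:
            fh.write(f"# induction_time_s={series.induction_time_s}\n")
        has_rs = series.series_resistance_mohm is not None
        fh.write("# time_s\tamplitude_pa" + ("\trs_mohm" if has_rs else "") + "\n")
        for i, (t, a) in enumerate(zip(series.sweep_times_s, series.amplitudes_pa)):
            row = f"{t:.3f}\t{a:.6f}"
            if has_rs:
                row += f"\t{series.series_resistance_mohm[i]:.4f}"
            fh.write(row + "\n")


def read_epsc_series(path: str | Path) -> EpscSeries:
    pathway, t_ind = "test", None
    times, amps, rs = [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, sep, val = line.lstrip("# ").partition("=")
                if key == "pathway":
                    pathway = val
                elif key == "induction_time_s":
                    t_ind = float(val)
                continue
            parts = line.split("\t")
            times.append(float(parts[0]))
            amps.append(float(parts[1]))
            if len(parts) > 2:
                rs.append(float(parts[2]))
    return EpscSeries(
        sweep_times_s=np.array(times), amplitudes_pa=np.array(amps),
        pathway=pathway, induction_time_s=t_ind,
        series_resistance_mohm=np.array(rs) if rs else None,
    )
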