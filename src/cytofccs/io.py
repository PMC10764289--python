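"""Readers and writers for every on-disk artifact of the pipeline.

Formats:

* photon traces — a chunked HDF5 container, one group per measurement with
  the two count vectors plus bin width/duration/metadata attributes; or a
  delimited-text fallback (two count columns, ``#``-prefixed header lines);
* correlation curves — delimited text (lag_us, G, sigma) with a header;
* TCSPC decays — delimited text (bin edges and counts);
* measurement records — JSON lines, one object per measurement;
* ground truth and manifests — JSON.

Every writer round-trips through its reader to an equal in-memory value.
"""

from __future__ import annotations

import json
import math
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np

from .affinity import FccsMeasurement
from .correlate import CorrelationCurve, PhotonTrace
from .flim import TcspcDecay

__all__ = [
    "write_traces_h5",
    "read_traces_h5",
    "write_trace_text",
    "read_trace_text",
    "write_curve_text",
    "read_curve_text",
    "write_decay_text",
    "read_decay_text",
    "write_measurements_jsonl",
    "read_measurements_jsonl",
    "write_json",
    "read_json",
]


def _json_safe(obj):
    if isinstance(obj, Mapping):
        return {str(k): _json_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_json_safe(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, float) and math.isinf(obj):
        return "inf" if obj > 0 else "-inf"
    return obj


def _json_restore_inf(obj):
    if isinstance(obj, dict):
        return {k: _json_restore_inf(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_json_restore_inf(v) for v in obj]
    if obj == "inf":
        return math.inf
    if obj == "-inf":
        return -math.inf
    return obj


# ---------------------------------------------------------------------------
# Photon traces


def write_traces_h5(path: str | Path, traces: Mapping[str, PhotonTrace]) -> None:
    """Write traces to an HDF5 container, one group per measurement id."""
    with h5py.File(path, "w", track_order=True) as f:
        for name, trace in traces.items():
            g = f.create_group(name, track_order=True)
            for channel, counts in (
                ("counts_green", trace.counts_green),
                ("counts_red", trace.counts_red),
            ):
                g.create_dataset(
                    channel,
                    data=np.asarray(counts, dtype=np.int64),
                    chunks=(min(len(counts), 1 << 16),),
                    compression="gzip",
                    compression_opts=4,
                    track_times=False,
                )
            g.attrs["bin_width_us"] = trace.bin_width
            g.attrs["duration_s"] = trace.duration
            g.attrs["metadata_json"] = json.dumps(_json_safe(trace.metadata))


def read_traces_h5(path: str | Path) -> dict[str, PhotonTrace]:
    traces = {}
    with h5py.File(path, "r") as f:
        for name in f:
            g = f[name]
            traces[name] = PhotonTrace(
                counts_green=g["counts_green"][:],
                counts_red=g["counts_red"][:],
                bin_width=float(g.attrs["bin_width_us"]),
                duration=float(g.attrs["duration_s"]),
                metadata=_json_restore_inf(json.loads(g.attrs["metadata_json"])),
            )
    return traces


def write_trace_text(path: str | Path, trace: PhotonTrace) -> None:
    """Delimited-text fallback: two count columns, '#'-prefixed headers."""
    with open(path, "w") as f:
        f.write(f"# bin_width_us {trace.bin_width!r}\n")
        f.write(f"# duration_s {trace.duration!r}\n")
        f.write(f"# metadata {json.dumps(_json_safe(trace.metadata))}\n")
        f.write("# counts_green\tcounts_red\n")
        for g, r in zip(trace.counts_green, trace.counts_red):
            f.write(f"{int(g)}\t{int(r)}\n")


def read_trace_text(path: str | Path) -> PhotonTrace:
    bin_width = duration = None
    metadata: dict = {}
    greens, reds = [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("bin_width_us"):
                    bin_width = float(body.split(None, 1)[1])
                elif body.startswith("duration_s"):
                    duration = float(body.split(None, 1)[1])
                elif body.startswith("metadata"):
                    metadata = _json_restore_inf(json.loads(body.split(None, 1)[1]))
                continue
            g, r = line.split("\t")
            greens.append(int(g))
            reds.append(int(r))
    if bin_width is None or duration is None:
        raise ValueError(f"{path}: missing bin_width/duration headers")
    return PhotonTrace(
        counts_green=np.array(greens, dtype=np.int64),
        counts_red=np.array(reds, dtype=np.int64),
        bin_width=bin_width,
        duration=duration,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Correlation curves


def write_curve_text(path: str | Path, curve: CorrelationCurve) -> None:
    with open(path, "w") as f:
        f.write(f"# kind {curve.kind}\n")
        f.write(f"# metadata {json.dumps(_json_safe(curve.metadata))}\n")
        f.write("# lag_us\tG\tsigma\n")
        sigma = curve.sigma if curve.sigma is not None else [math.nan] * len(curve)
        for lag, g, s in zip(curve.lags, curve.g, sigma):
            f.write(f"{float(lag)!r}\t{float(g)!r}\t{float(s)!r}\n")


def read_curve_text(path: str | Path) -> CorrelationCurve:
    kind = None
    metadata: dict = {}
    rows = []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("kind"):
                    kind = body.split(None, 1)[1]
                elif body.startswith("metadata"):
                    metadata = json.loads(body.split(None, 1)[1])
                continue
            rows.append([float(x) for x in line.split("\t")])
    arr = np.array(rows)
    sigma = arr[:, 2]
    return CorrelationCurve(
        lags=arr[:, 0],
        g=arr[:, 1],
        sigma=None if np.isnan(sigma).all() else sigma,
        kind=kind,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# TCSPC decays


def write_decay_text(path: str | Path, decay: TcspcDecay) -> None:
    with open(path, "w") as f:
        f.write(f"# irf_sigma_ns {decay.irf_sigma!r}\n")
        f.write(f"# metadata {json.dumps(_json_safe(decay.metadata))}\n")
        f.write("# t_low_ns\tt_high_ns\tcounts\n")
        for lo, hi, c in zip(decay.bin_edges[:-1], decay.bin_edges[1:], decay.counts):
            f.write(f"{float(lo)!r}\t{float(hi)!r}\t{int(c)}\n")


def read_decay_text(path: str | Path) -> TcspcDecay:
    irf_sigma = None
    metadata: dict = {}
    lows, highs, counts = [], [], []
    with open(path) as f:
        for line in f:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("irf_sigma_ns"):
                    irf_sigma = float(body.split(None, 1)[1])
                elif body.startswith("metadata"):
                    metadata = json.loads(body.split(None, 1)[1])
                continue
            lo, hi, c = line.split("\t")
            lows.append(float(lo))
            highs.append(float(hi))
            counts.append(int(c))
    edges = np.array(lows + [highs[-1]])
    return TcspcDecay(
        bin_edges=edges,
        counts=np.array(counts, dtype=np.int64),
        irf_sigma=irf_sigma,
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# Measurement records


def measurement_to_dict(meas: FccsMeasurement) -> dict:
    return _json_safe(
        {
            "n1": meas.n1,
            "n2": meas.n2,
            "ncc": meas.ncc,
            "c_green": meas.c_green,
            "c_red": meas.c_red,
            "c_cc": meas.c_cc,
            "kd": meas.kd,
            "kd_is_lower_bound": meas.kd_is_lower_bound,
            "excluded": meas.excluded,
            "exclusion_reason": meas.exclusion_reason,
            "location_label": meas.location_label,
            "flags": list(meas.flags),
        }
    )


def measurement_from_dict(d: dict) -> FccsMeasurement:
    d = _json_restore_inf(dict(d))
    return FccsMeasurement(
        n1=d["n1"],
        n2=d["n2"],
        ncc=d["ncc"],
        c_green=d["c_green"],
        c_red=d["c_red"],
        c_cc=d["c_cc"],
        kd=d["kd"],
        kd_is_lower_bound=d["kd_is_lower_bound"],
        excluded=d["excluded"],
        exclusion_reason=d["exclusion_reason"],
        location_label=d["location_label"],
        flags=list(d["flags"]),
    )


def write_measurements_jsonl(path: str | Path, measurements) -> None:
    with open(path, "w") as f:
        for meas in measurements:
            f.write(json.dumps(measurement_to_dict(meas), sort_keys=True) + "\n")


def read_measurements_jsonl(path: str | Path) -> list[FccsMeasurement]:
    out = []
    with open(path) as f:
        for line in f:
            if line.strip():
                out.append(measurement_from_dict(json.loads(line)))
    return out


# ---------------------------------------------------------------------------
# JSON helpers


def write_json(path: str | Path, obj) -> None:
    with open(path, "w") as f:
        json.dump(_json_safe(obj), f, indent=2, sort_keys=True)
        f.write("\n")


def read_json(path: str | Path):
    with open(path) as f:
        return _json_restore_inf(json.load(f))
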