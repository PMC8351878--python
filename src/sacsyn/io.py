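"""Readers and writers for sessions, traces, models and configuration.

Two on-disk layouts are supported: a two-column delimited trace table
(time_s, value) with a one-line header for single traces, and an HDF5
container for multi-trial sessions with groups ``/stimulus`` and
``/trials/<k>`` carrying ``dt``/``units`` attributes and recording
metadata on the root group.  Round trips are lossless (float64
throughout, metadata exact).
"""

from __future__ import annotations

import dataclasses
import io
import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .exceptions import EmptyTraceError, SchemaError
from .traces import (
    CellType,
    HoldingLabel,
    RecordingMetadata,
    SampledTrace,
    StimulusProtocol,
    WNRecordingSession,
)

__all__ = [
    "SCHEMA_VERSION",
    "read_trace_table",
    "write_trace_table",
    "read_session",
    "write_session",
    "load_config",
]

SCHEMA_VERSION = 1

_PROTOCOL_FIELDS = [f.name for f in dataclasses.fields(StimulusProtocol)]


def write_trace_table(trace: SampledTrace, path: str | Path) -> None:
    """Two-column delimited text: time_s <TAB> value, one header line."""
    header = f"time_s\tvalue_{trace.units or 'au'}"
    data = np.column_stack([trace.times, trace.values])
    np.savetxt(path, data, delimiter="\t", header=header, comments="", fmt="%.9g")


def read_trace_table(path: str | Path, units: str = "") -> SampledTrace:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        body = fh.read()
    if not body.strip():
        raise EmptyTraceError(f"{path} contains a header but no samples")
    data = np.loadtxt(io.StringIO(body), delimiter="\t", ndmin=2)
    if data.shape[0] < 2:
        raise EmptyTraceError(f"{path} has fewer than two samples; dt unresolvable")
    if not units and "\t" in header:
        col = header.split("\t")[1]
        units = col.removeprefix("value_")
    times, values = data[:, 0], data[:, 1]
    dt = float(np.mean(np.diff(times)))
    return SampledTrace(values, dt, float(times[0]), units)


def _write_trace(group: h5py.Group, name: str, trace: SampledTrace) -> None:
    ds = group.create_dataset(name, data=trace.values, dtype="f8")
    ds.attrs["dt"] = trace.dt
    ds.attrs["t0"] = trace.t0
    ds.attrs["units"] = trace.units


def _read_trace(ds: h5py.Dataset, path: str) -> SampledTrace:
    for attr in ("dt", "units"):
        if attr not in ds.attrs:
            raise SchemaError(f"{path}: missing required attribute '{attr}'")
    return SampledTrace(
        ds[()], float(ds.attrs["dt"]), float(ds.attrs.get("t0", 0.0)), str(ds.attrs["units"])
    )


def write_session(session: WNRecordingSession, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["cell_type"] = session.metadata.cell_type.value
        f.attrs["holding_label"] = session.metadata.holding_label.value
        f.attrs["polarity"] = session.metadata.polarity
        f.attrs["pre_stimulus_baseline_s"] = session.metadata.pre_stimulus_baseline_s
        for name in _PROTOCOL_FIELDS:
            f.attrs[f"protocol_{name}"] = getattr(session.protocol, name)
        _write_trace(f, "stimulus", session.stimulus)
        trials = f.create_group("trials")
        for k, tr in enumerate(session.trials):
            _write_trace(trials, f"{k:03d}", tr)
        if session.baseline is not None:
            _write_trace(f, "baseline", session.baseline)


def read_session(path: str | Path) -> WNRecordingSession:
    with h5py.File(path, "r") as f:
        for attr in ("cell_type", "holding_label"):
            if attr not in f.attrs:
                raise SchemaError(f"{path}: missing required attribute '{attr}'")
        proto_kwargs = {}
        for name in _PROTOCOL_FIELDS:
            key = f"protocol_{name}"
            if key not in f.attrs:
                raise SchemaError(f"{path}: missing required attribute '{key}'")
            proto_kwargs[name] = f.attrs[key]
        proto_kwargs["n_trials"] = int(proto_kwargs["n_trials"])
        proto_kwargs["seed"] = int(proto_kwargs["seed"])
        protocol = StimulusProtocol(**proto_kwargs)
        metadata = RecordingMetadata(
            cell_type=CellType(f.attrs["cell_type"]),
            holding_label=HoldingLabel(f.attrs["holding_label"]),
            polarity=int(f.attrs.get("polarity", 1)),
            pre_stimulus_baseline_s=float(f.attrs.get("pre_stimulus_baseline_s", 1.0)),
        )
        stimulus = _read_trace(f["stimulus"], f"{path}:/stimulus")
        trials = [
            _read_trace(f["trials"][k], f"{path}:/trials/{k}")
            for k in sorted(f["trials"].keys())
        ]
        baseline = _read_trace(f["baseline"], f"{path}:/baseline") if "baseline" in f else None
    return WNRecordingSession(
        stimulus=stimulus, trials=trials, protocol=protocol, metadata=metadata, baseline=baseline
    )


def load_config(path: str | Path) -> dict:
    """Structured-text pipeline configuration (YAML mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise SchemaError(f"{path}: config must be a mapping")
    return cfg


def dump_json(obj, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=_default) + "\n")
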