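"""Readers and writers for traces and run manifests.

Native trace format is CSV with explicit um units in the column names;
SWC (the de-facto neuron-morphology interchange format) is written for
interoperability with morphology tools.  Every CLI run also writes a JSON
manifest capturing the inputs, parameters, and seed needed to re-execute it.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, is_dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .tracer import TraceResult
from .trajectory import FiberTrace

__all__ = [
    "write_trace_csv",
    "read_trace_csv",
    "write_trace_swc",
    "read_trace_swc",
    "write_manifest",
]

_CORE_COLUMNS = ["step", "x_um", "y_um", "z_um"]
_LOG_COLUMNS = ["section", "brightness", "extension_i", "origin"]

#: SWC structure identifier for axons
_SWC_AXON = 2
_SWC_DEFAULT_RADIUS_UM = 0.5


def write_trace_csv(obj: Union[FiberTrace, TraceResult],
                    path: Union[str, Path]) -> Path:
    """Write a trace (or full trace result, with its log) as CSV.

    Columns are ``step,x_um,y_um,z_um`` for a bare trace and additionally
    ``section,brightness,extension_i,origin`` for a :class:`TraceResult`.
    """
    path = Path(path)
    if isinstance(obj, TraceResult):
        pts = obj.trace.points
        df = pd.DataFrame({
            "step": np.arange(pts.shape[0]),
            "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
            "section": [e["section"] for e in obj.log],
            "brightness": [e["brightness"] for e in obj.log],
            "extension_i": [e["extension_i"] for e in obj.log],
            "origin": [e["origin"] for e in obj.log],
        })
    else:
        pts = obj.points
        df = pd.DataFrame({
            "step": np.arange(pts.shape[0]),
            "x_um": pts[:, 0], "y_um": pts[:, 1], "z_um": pts[:, 2],
        })
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_csv(path: Union[str, Path],
                   step_len: Optional[float] = None) -> FiberTrace:
    """Read a trace CSV back into a :class:`FiberTrace` (coordinates only)."""
    df = pd.read_csv(path)
    missing = [c for c in _CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    pts = df[["x_um", "y_um", "z_um"]].to_numpy(float)
    return FiberTrace(pts, step_len=step_len, meta={"source": str(path)})


def write_trace_swc(obj: Union[FiberTrace, TraceResult],
                    path: Union[str, Path],
                    radius_um: Optional[float] = None) -> Path:
    """Write a trace as SWC: sample, type(=2, axon), x, y, z, radius, parent.

    Points form a simple chain (parent links -1, 1, 2, ...).  The radius
    column uses ``radius_um`` if given, else the trace's ``radius_um`` meta
    entry, else a constant default.
    """
    path = Path(path)
    trace = obj.trace if isinstance(obj, TraceResult) else obj
    r = radius_um
    if r is None:
        r = trace.meta.get("radius_um", _SWC_DEFAULT_RADIUS_UM)
    lines = ["# generated by flashtrace",
             "# columns: sample type x y z radius parent (um)"]
    for i, (x, y, z) in enumerate(trace.points, start=1):
        parent = i - 1 if i > 1 else -1
        lines.append(f"{i} {_SWC_AXON} {x:.6f} {y:.6f} {z:.6f} "
                     f"{r:.4f} {parent}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_trace_swc(path: Union[str, Path]) -> FiberTrace:
    """Read an SWC chain back into a :class:`FiberTrace`."""
    rows = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) < 7:
            raise ValueError(f"{path}: malformed SWC line: {line!r}")
        rows.append([float(parts[2]), float(parts[3]), float(parts[4])])
    return FiberTrace(np.asarray(rows), meta={"source": str(path)})


def write_manifest(path: Union[str, Path], command: str, params,
                   inputs: Optional[dict] = None,
                   seed: Optional[int] = None,
                   extra: Optional[dict] = None) -> Path:
    """Write a JSON manifest sufficient to re-execute a run."""
    from . import __version__

    def _clean(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            obj = asdict(obj)
        if isinstance(obj, dict):
            return {k: _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        return obj

    payload = {
        "command": command,
        "params": _clean(params),
        "inputs": _clean(inputs or {}),
        "seed": seed,
        "versions": {"flashtrace": __version__,
                     "python": platform.python_version(),
                     "numpy": np.__version__},
    }
    if extra:
        payload.update(_clean(extra))
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2) + "\n")
    return path
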