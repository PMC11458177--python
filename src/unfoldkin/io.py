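"""Reading and writing traces, manifests and result files.

Traces travel as plain CSV: a few ``# key: value`` comment lines carrying
metadata, then a header ``time_s,fluorescence`` (raw) or
``time_s,rel_enhancement`` (normalized) and the numeric rows.  Floats are
written with enough digits to round-trip exactly, so write-then-read
reproduces arrays bit for bit.  Manifests and fit reports are YAML.
"""
from __future__ import annotations

import io as _io
import re
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dataset import Dataset
from .errors import DataError
from .timecourse import TimeCourse

__all__ = [
    "read_timecourse",
    "write_timecourse",
    "read_dataset",
    "write_dataset",
    "read_manifest",
    "write_manifest",
]

_COLUMN_FOR_STATE = {"raw": "fluorescence", "relative": "rel_enhancement"}
_STATE_FOR_COLUMN = {v: k for k, v in _COLUMN_FOR_STATE.items()}
#: %.17g round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def write_timecourse(tc: TimeCourse, path: str | Path) -> Path:
    """Write one trace as commented CSV; returns the path."""
    path = Path(path)
    col = _COLUMN_FOR_STATE[tc.state]
    with open(path, "w") as fh:
        fh.write(f"# substrate: {tc.substrate}\n")
        fh.write(f"# length_aa: {tc.length:.17g}\n")
        fh.write(f"# dt1_s: {tc.dt1:.17g}\n")
        fh.write(f"# replicate: {tc.replicate}\n")
        pd.DataFrame({"time_s": tc.t, col: tc.y}).to_csv(
            fh, index=False, float_format=_FLOAT_FMT)
    return path


def read_timecourse(path: str | Path) -> TimeCourse:
    """Read a trace written by :func:`write_timecourse` (or compatible).

    The normalization state is inferred from the signal column name.
    Parse errors name the offending row.
    """
    path = Path(path)
    meta: dict[str, str] = {}
    body_lines = []
    with open(path) as fh:
        for line in fh:
            m = re.match(r"#\s*([\w]+)\s*:\s*(.*)", line)
            if m:
                meta[m.group(1)] = m.group(2).strip()
            elif line.strip():
                body_lines.append(line)
    try:
        df = pd.read_csv(_io.StringIO("".join(body_lines)),
                         float_precision="round_trip")
    except Exception as exc:
        raise DataError(f"{path}: cannot parse CSV body: {exc}") from exc
    if "time_s" not in df.columns:
        raise DataError(f"{path}: missing required column 'time_s'")
    signal_col = next((c for c in df.columns if c in _STATE_FOR_COLUMN), None)
    if signal_col is None:
        raise DataError(
            f"{path}: need a 'fluorescence' or 'rel_enhancement' column")
    for col in ("time_s", signal_col):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.isna().idxmax()) + 2  # 1-based + header line
            raise DataError(f"{path}: non-numeric value in '{col}' at row {row}")
        df[col] = vals
    t = df["time_s"].to_numpy(float)
    if t.size > 1 and np.any(np.diff(t) <= 0):
        row = int(np.argmax(np.diff(t) <= 0)) + 3
        raise DataError(f"{path}: time not strictly increasing at row {row}")
    try:
        return TimeCourse(
            t=t, y=df[signal_col].to_numpy(float),
            substrate=meta.get("substrate", ""),
            length=float(meta.get("length_aa", 0.0)),
            dt1=float(meta.get("dt1_s", 0.0)),
            replicate=int(meta.get("replicate", 0)),
            state=_STATE_FOR_COLUMN[signal_col],
        )
    except DataError as exc:
        raise DataError(f"{path}: {exc}") from exc


def _trace_filename(tc: TimeCourse) -> str:
    sub = re.sub(r"[^\w.-]", "_", tc.substrate or "trace")
    return f"{sub}_dt1-{tc.dt1:g}_rep{tc.replicate}.csv"


def write_manifest(manifest: dict, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return path


def read_manifest(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_dataset(ds: Dataset, out_dir: str | Path) -> Path:
    """Write all traces plus ``manifest.yaml`` into a directory."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files = []
    for tc in ds.traces:
        name = _trace_filename(tc)
        write_timecourse(tc, out_dir / name)
        files.append(name)
    manifest = dict(ds.manifest)
    manifest["files"] = files
    write_manifest(manifest, out_dir / "manifest.yaml")
    return out_dir


def read_dataset(path: str | Path) -> Dataset:
    """Read a dataset directory (or its manifest.yaml) back in.

    Every file named in the manifest must exist and parse.
    """
    path = Path(path)
    mpath = path / "manifest.yaml" if path.is_dir() else path
    root = mpath.parent
    manifest = read_manifest(mpath)
    traces = []
    for name in manifest.get("files", []):
        fpath = root / name
        if not fpath.exists():
            raise DataError(f"manifest names missing file: {fpath}")
        traces.append(read_timecourse(fpath))
    return Dataset(traces=traces, manifest=manifest)
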