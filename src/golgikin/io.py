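"""CSV/JSON reading and writing for trace data.

One replicate = one CSV with mandatory header ``time_s,ifr,irr,ibr`` plus a
sidecar JSON (same stem, ``.json``) holding the scalars ``irr_pre``,
``irr_after`` and ``bleach_frame``.  Normalized traces and aligned means use
small flat CSV dialects so every artifact stays diffable text.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import RawTraceSet
from .correction import NormalizedTrace

__all__ = [
    "write_raw_trace", "read_raw_trace",
    "write_normalized_trace", "read_normalized_trace",
    "write_aligned_set",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(".json")


def write_raw_trace(raw: RawTraceSet, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": raw.time_s, "ifr": raw.ifr,
                  "irr": raw.irr, "ibr": raw.ibr}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(
        {"irr_pre": raw.irr_pre, "irr_after": raw.irr_after,
         "bleach_frame": int(raw.bleach_frame)}, indent=2, sort_keys=True))
    return path


def read_raw_trace(path) -> RawTraceSet:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "ifr", "irr", "ibr"):
        if col not in df.columns:
            raise ValueError(f"trace CSV {path} is missing column {col!r}")
    meta = json.loads(_sidecar(path).read_text())
    return RawTraceSet(time_s=df["time_s"].to_numpy(float),
                       ifr=df["ifr"].to_numpy(float),
                       irr=df["irr"].to_numpy(float),
                       ibr=df["ibr"].to_numpy(float),
                       irr_pre=float(meta["irr_pre"]),
                       irr_after=float(meta["irr_after"]),
                       bleach_frame=int(meta["bleach_frame"]))


def write_normalized_trace(trace: NormalizedTrace, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": trace.time_s,
                  "value_pct": trace.value_pct}).to_csv(path, index=False)
    return path


def read_normalized_trace(path) -> NormalizedTrace:
    df = pd.read_csv(path)
    values = df["value_pct"].to_numpy(float)
    return NormalizedTrace(time_s=df["time_s"].to_numpy(float),
                           value_pct=values, imax=float(values.max()))


def write_aligned_set(aligned, path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": aligned.common_time_s, "mean": aligned.mean,
                  "sd": aligned.sd, "ci_low": aligned.ci95_low,
                  "ci_high": aligned.ci95_high}).to_csv(path, index=False)
    return path
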