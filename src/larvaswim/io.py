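"""Tabular text formats used between pipeline stages.

All tables are tab-separated UTF-8 text with a mandatory header row and
'.' as the decimal mark.  One row per frame for traces, one row per bout
for bout tables, one row per fish for summaries.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

#: per-frame trace columns (frame indices are 0-based)
TRACE_COLUMNS = ["frame_index", "time_s", "x_mm", "y_mm", "heading_deg", "tail_angle_deg"]

#: optional per-frame tracking-quality column appended by the tracker
FLAG_COLUMN = "flagged"

SEP = "\t"


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep=SEP, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=SEP)


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"trace is missing columns: {missing}")
    write_table(trace, path)


def read_trace(path: str | Path) -> pd.DataFrame:
    trace = read_table(path)
    missing = [c for c in TRACE_COLUMNS if c not in trace.columns]
    if missing:
        raise ValueError(f"{path} is not a trace file (missing {missing})")
    return trace


def trace_rate_hz(trace: pd.DataFrame) -> float:
    """Sampling rate inferred from the time column of a uniform trace."""
    t = trace["time_s"].to_numpy()
    if len(t) < 2:
        raise ValueError("trace too short to infer a sampling rate")
    dt = (t[-1] - t[0]) / (len(t) - 1)
    return 1.0 / dt
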