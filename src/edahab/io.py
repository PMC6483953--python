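"""Delimited-text readers/writers for traces, schedules, events and cohorts."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .eda import EdaTrace, ScrEvent
from .errors import ParameterError
from .synthetic import StimulusSchedule

__all__ = [
    "write_trace",
    "read_trace",
    "write_schedule",
    "read_schedule",
    "write_events",
    "read_events",
    "write_table",
    "read_table",
]


def write_trace(trace: EdaTrace, path: str | Path) -> None:
    """Two-column CSV: time_s, eda_uS."""
    pd.DataFrame({"time_s": trace.times_s(), "eda_uS": trace.values_uS}).to_csv(
        path, index=False
    )


def read_trace(path: str | Path) -> EdaTrace:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    dt = np.diff(t)
    if t.size < 2 or not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ParameterError(f"{path}: trace must be uniformly sampled")
    return EdaTrace(df["eda_uS"].to_numpy(dtype=float), rate_hz=1.0 / dt[0], start_s=float(t[0]))


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    """Three-column CSV: trial (1-based), onset_s, duration_s."""
    pd.DataFrame(
        {
            "trial": np.arange(1, schedule.n_trials + 1),
            "onset_s": schedule.onsets_s,
            "duration_s": schedule.duration_s,
        }
    ).to_csv(path, index=False)


def read_schedule(path: str | Path) -> StimulusSchedule:
    df = pd.read_csv(path)
    durations = df["duration_s"].unique()
    if durations.size != 1:
        raise ParameterError(f"{path}: one stimulus duration per schedule")
    return StimulusSchedule(tuple(df["onset_s"].astype(float)), float(durations[0]))


def write_events(events: list[ScrEvent], path: str | Path) -> None:
    pd.DataFrame(
        {
            "trough_time_s": [e.trough_time_s for e in events],
            "peak_time_s": [e.peak_time_s for e in events],
            "amplitude_uS": [e.amplitude_uS for e in events],
        }
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[ScrEvent]:
    df = pd.read_csv(path)
    return [
        ScrEvent(float(r.trough_time_s), float(r.peak_time_s), float(r.amplitude_uS))
        for r in df.itertuples()
    ]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)
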