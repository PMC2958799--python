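"""Tabular readers/writers tying the pipeline together.

Spikes travel as CSV with header ``unit_id,time_s``; flash/spot event
tables as ``event_time_s,event_type``; results as flat per-unit CSV.  All
CSV is UTF-8, comma-separated, with a header row.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ensemble import SpikeTrain

__all__ = ["read_spikes_csv", "write_spikes_csv", "write_events_csv",
           "read_events_csv"]


def read_spikes_csv(path: str | Path) -> list[SpikeTrain]:
    df = pd.read_csv(path)
    if not {"unit_id", "time_s"} <= set(df.columns):
        raise ValueError("spike CSV needs columns unit_id,time_s")
    trains = []
    for uid, grp in df.groupby("unit_id", sort=True):
        trains.append(SpikeTrain(unit_id=str(uid), times=np.sort(grp["time_s"].to_numpy())))
    return trains


def write_spikes_csv(trains: list[SpikeTrain], path: str | Path) -> None:
    frames = [
        pd.DataFrame({"unit_id": t.unit_id, "time_s": t.times}) for t in trains
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9g")


def write_events_csv(times: np.ndarray, types: list[str], path: str | Path) -> None:
    pd.DataFrame({"event_time_s": times, "event_type": types}).to_csv(
        path, index=False, float_format="%.9g"
    )


def read_events_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if not {"event_time_s", "event_type"} <= set(df.columns):
        raise ValueError("event CSV needs columns event_time_s,event_type")
    return df
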