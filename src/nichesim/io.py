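"""CSV and config I/O helpers.

All floating-point output uses Python's repr formatting (pandas default),
which round-trips float64 exactly.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .errors import SchemaError
from .simulation import Trajectory
from .spots import validate_spot_table
from .tracks import TrackSet

TRACK_COLUMNS = [
    "dataset_id", "track_id", "t", "x_um", "y_um", "z_um", "group", "is_reference",
]


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    trajectory.to_frame().to_csv(path, index=False)


def write_events(trajectory: Trajectory, path: str | Path) -> None:
    trajectory.events_frame().to_csv(path, index=False)


def read_spot_table(path: str | Path, channels: tuple[str, ...] = ()) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    validate_spot_table(table, channels=channels)
    return table


def write_spot_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False)


def read_track_set(path: str | Path, frame_interval: float = 15.0) -> TrackSet:
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TRACK_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"track table missing column(s): {', '.join(missing)}")
    return TrackSet.from_frame(frame, frame_interval=frame_interval)


def write_track_set(track_set: TrackSet, path: str | Path) -> None:
    track_set.to_frame().to_csv(path, index=False)
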