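"""CSV / JSON interfaces for trajectories and configurations.

Trajectory files are plain CSV, one row per display frame:

* target-only: columns ``frame`` (0-based int), ``target_x`` (float)
* paired: columns ``frame``, ``target_x``, ``cursor_x`` and an optional
  ``trial`` column grouping multiple trials in one file.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import TrajectoryPair
from .signals import SignalConfig, TargetSignal

__all__ = [
    "write_target_csv",
    "read_target_csv",
    "write_pairs_csv",
    "read_pairs_csv",
    "signal_config_to_json",
    "signal_config_from_json",
]


def write_target_csv(signal: TargetSignal, path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(signal)), "target_x": signal.positions}
    ).to_csv(path, index=False)


def read_target_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    if "target_x" not in df.columns:
        raise ValueError(f"{path}: missing required column 'target_x'")
    return df["target_x"].to_numpy(float)


def write_pairs_csv(pairs, path) -> None:
    """Write one or more trajectory pairs; a ``trial`` column is added when
    more than one pair is given."""
    if isinstance(pairs, TrajectoryPair):
        pairs = [pairs]
    frames = []
    for i, p in enumerate(pairs):
        df = pd.DataFrame(
            {"frame": np.arange(len(p)), "target_x": p.target, "cursor_x": p.tracking}
        )
        if len(pairs) > 1:
            df.insert(0, "trial", i)
        frames.append(df)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_pairs_csv(path, frame_rate: float = 60.0) -> list[TrajectoryPair]:
    """Read trajectory pairs, one per ``trial`` value (a single pair when the
    column is absent)."""
    df = pd.read_csv(path)
    missing = {"target_x", "cursor_x"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    if "trial" in df.columns:
        groups = [g for _, g in df.groupby("trial", sort=True)]
    else:
        groups = [df]
    return [
        TrajectoryPair(
            target=g["target_x"].to_numpy(float),
            tracking=g["cursor_x"].to_numpy(float),
            frame_rate=frame_rate,
        )
        for g in groups
    ]


def signal_config_to_json(config: SignalConfig, path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(config), indent=2))


def signal_config_from_json(path) -> SignalConfig:
    return SignalConfig(**json.loads(Path(path).read_text()))
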