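"""File formats: trajectory tables, interval annotations, and configuration.

Trajectory files are comma-delimited with header ``t,x,y,detected`` (one file
per arena); times in s, positions in px or mm as declared by the config.
Interval files are ``start,stop,label`` in s and serve both for software
output and manual reference annotations.  Configuration is YAML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import ArenaGeometry, Interval, Trajectory

__all__ = [
    "AcquisitionConfig",
    "read_config",
    "read_trajectory",
    "write_trajectory",
    "read_intervals",
    "write_intervals",
]


@dataclass
class AcquisitionConfig:
    """Acquisition metadata and arena geometry for one recording setup."""

    pixel_scale: float = 16.583  # px per mm
    frame_rate: float = 25.0
    analysis_rate: float = 5.0
    smooth_window: int = 5
    gap_max: float = 1.0
    positions: str = "px"  # unit of x,y columns in trajectory files
    average_positions: bool = False
    zone1_distance_only: bool = True
    arenas: dict[str, ArenaGeometry] = field(default_factory=dict)

    def arena(self, arena_id: str | None = None) -> ArenaGeometry:
        if not self.arenas:
            return ArenaGeometry()
        if arena_id is None:
            if len(self.arenas) == 1:
                return next(iter(self.arenas.values()))
            raise KeyError("config defines several arenas; arena id required")
        return self.arenas[arena_id]


def read_config(path: str | Path) -> AcquisitionConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    arenas = {}
    for aid, geom in (raw.pop("arenas", None) or {}).items():
        arenas[str(aid)] = ArenaGeometry(
            centre=tuple(geom.get("centre", (3.25, 3.25))),
            disc_radius=float(geom.get("disc_radius", 3.0)),
            wall_radius=float(geom.get("wall_radius", 3.25)),
            zone1_margin=float(geom.get("zone1_margin", 0.75)),
        )
    known = {f for f in AcquisitionConfig.__dataclass_fields__ if f != "arenas"}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return AcquisitionConfig(arenas=arenas, **raw)


def read_trajectory(
    path: str | Path, config: AcquisitionConfig, arena_id: str | None = None
) -> Trajectory:
    """Read a ``t,x,y,detected`` table and return positions in mm.

    Undetected frames are preserved (``detected=false``; empty positions
    become NaN).  Malformed rows and non-monotone times raise with the
    offending line number.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pandas names the bad line
        raise ValueError(f"{path}: malformed trajectory file: {exc}") from exc
    missing = {"t", "x", "y", "detected"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    for col in ("t", "x", "y"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header + 1-based
            raise ValueError(f"{path}: unparseable {col!r} value at line {line}")
        df[col] = coerced
    detected = (
        df["detected"]
        .map(lambda v: str(v).strip().lower() in ("1", "true", "t", "yes"))
        .to_numpy()
    )
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1 and np.any(np.diff(t) <= 0):
        line = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 3
        raise ValueError(f"{path}: time not strictly increasing at line {line}")
    scale = config.pixel_scale if config.positions == "px" else 1.0
    return Trajectory(
        t=t,
        x=df["x"].to_numpy(dtype=float) / scale,
        y=df["y"].to_numpy(dtype=float) / scale,
        detected=detected,
        frame_rate=config.frame_rate,
        pixel_scale=config.pixel_scale,
        arena_id=arena_id or path.stem,
    )


def write_trajectory(traj: Trajectory, path: str | Path, config: AcquisitionConfig) -> None:
    """Inverse of :func:`read_trajectory` (field-for-field round trip)."""
    scale = config.pixel_scale if config.positions == "px" else 1.0
    df = pd.DataFrame(
        {
            "t": traj.t,
            "x": traj.x * scale,
            "y": traj.y * scale,
            "detected": traj.detected.astype(int),
        }
    )
    df.loc[~traj.detected, ["x", "y"]] = np.nan
    df.to_csv(path, index=False)


def read_intervals(path: str | Path, labels: set[str] | None = None) -> list[Interval]:
    df = pd.read_csv(path)
    missing = {"start", "stop", "label"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    events = [
        Interval(float(r.start), float(r.stop), str(r.label)) for r in df.itertuples()
    ]
    if labels is not None:
        bad = {e.label for e in events} - labels
        if bad:
            raise ValueError(f"{path}: unexpected labels {sorted(bad)}")
    return events


def write_intervals(events: list[Interval], path: str | Path) -> None:
    pd.DataFrame(
        {
            "start": [e.start for e in events],
            "stop": [e.stop for e in events],
            "label": [e.label for e in events],
        }
    ).to_csv(path, index=False)
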