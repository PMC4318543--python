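"""Core domain types: trajectories, arena geometry, intervals, and kinematics.

A no-choice arena is a well of a microtitre plate holding a circular leaf
disc (zone 1) on agar, surrounded by the agar/wall annulus (zone 2).  The
subject is a single aphid whose body centre point is tracked at the
acquisition frame rate (25 frames/s in the reference setup).  Kinematics are
computed on a coarser analysis grid (5 samples/s) with a centred moving
average over the instantaneous speeds, which is what the probe and movement
state machines in :mod:`aphidtrack.probes` consume.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Zone",
    "TrajectorySample",
    "Trajectory",
    "ArenaGeometry",
    "KinematicsSeries",
    "Interval",
    "PROBE",
    "NON_PROBE",
    "MOVING",
    "NOT_MOVING",
    "assign_zone",
    "compute_kinematics",
    "check_tiling",
    "complement_intervals",
]

#: Interval labels.  Probe/non-probe and moving/not-moving form two
#: label families; each family tiles the observation.
PROBE = "probe"
NON_PROBE = "non_probe"
MOVING = "moving"
NOT_MOVING = "not_moving"


class Zone(enum.IntEnum):
    """Arena zone of a sample.  Stored as small ints in arrays."""

    UNDETECTED = 0
    ZONE1 = 1  # leaf disc, minus the excluded outer margin
    ZONE2 = 2  # surrounding agar / wall annulus


@dataclass(frozen=True)
class TrajectorySample:
    """One acquisition frame: time (s), position (mm) and detection flag."""

    t: float
    x: float
    y: float
    detected: bool = True


@dataclass
class ArenaGeometry:
    """Circular arena: leaf disc (zone 1) inside the arena wall.

    ``zone1_margin`` excludes the outer edge of the disc from zone 1 so that
    subjects on the wall are not falsely assigned to the disc.  With a 6-mm
    disc the default 0.75-mm margin leaves a zone-1 diameter of ~5 mm.
    """

    centre: tuple[float, float] = (3.25, 3.25)
    disc_radius: float = 3.0
    wall_radius: float = 3.25
    zone1_margin: float = 0.75

    def __post_init__(self) -> None:
        if not (0.0 < self.disc_radius < self.wall_radius):
            raise ValueError("require 0 < disc_radius < wall_radius")
        if self.zone1_margin < 0:
            raise ValueError("zone1_margin must be >= 0")

    @property
    def zone1_radius(self) -> float:
        return self.disc_radius - self.zone1_margin


@dataclass
class Trajectory:
    """Centre-point track of one subject in one arena.

    Positions are in mm; undetected frames are retained with
    ``detected=False`` (their positions may be NaN).
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    detected: np.ndarray
    frame_rate: float = 25.0
    pixel_scale: float = 16.583  # px per mm; sqrt(275 px/mm^2)
    arena_id: str = "arena"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)
        n = len(self.t)
        if not (len(self.x) == len(self.y) == len(self.detected) == n):
            raise ValueError("trajectory arrays must have equal length")
        if self.pixel_scale <= 0:
            raise ValueError("pixel_scale must be > 0")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be > 0")
        if n:
            if self.t[0] < 0:
                raise ValueError("time must be non-negative")
            if n > 1:
                dt = np.diff(self.t)
                if np.any(dt <= 0):
                    i = int(np.flatnonzero(dt <= 0)[0]) + 1
                    raise ValueError(f"time not strictly increasing at sample {i}")
                expected = 1.0 / self.frame_rate
                if np.any(np.abs(dt - expected) > 0.25 * expected):
                    raise ValueError(
                        "sample spacing inconsistent with frame_rate"
                    )
            det = self.detected
            if np.any(~np.isfinite(self.x[det])) or np.any(~np.isfinite(self.y[det])):
                raise ValueError("detected samples must have finite positions")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Observation span in s: each frame covers one frame interval."""
        return len(self.t) / self.frame_rate

    @property
    def samples(self) -> list[TrajectorySample]:
        return [
            TrajectorySample(float(t), float(x), float(y), bool(d))
            for t, x, y, d in zip(self.t, self.x, self.y, self.detected)
        ]


@dataclass
class KinematicsSeries:
    """Smoothed-speed series on the analysis grid.

    ``speed`` is the centred moving average of instantaneous speeds (mm/s);
    it is NaN where positions are unavailable (undetected gaps longer than
    the interpolation limit).  ``step_distance`` holds the per-sample
    displacement credited to the distance-moved response variable (zone-1
    displacements by default); ``cumulative_distance`` is its running sum.
    ``detected`` carries the raw per-sample detection flag for QC.
    """

    t: np.ndarray
    speed: np.ndarray
    zone: np.ndarray
    step_distance: np.ndarray
    detected: np.ndarray
    rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.speed = np.asarray(self.speed, dtype=float)
        self.zone = np.asarray(self.zone, dtype=np.int8)
        self.step_distance = np.asarray(self.step_distance, dtype=float)
        self.detected = np.asarray(self.detected, dtype=bool)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        return len(self.t) / self.rate

    @property
    def cumulative_distance(self) -> np.ndarray:
        return np.cumsum(self.step_distance)

    @property
    def qc_detected_fraction(self) -> float:
        return float(np.mean(self.detected)) if len(self.detected) else 0.0


@dataclass(frozen=True)
class Interval:
    """Half-open labelled interval [start, stop) in s from observation start."""

    start: float
    stop: float
    label: str

    def __post_init__(self) -> None:
        if not self.stop > self.start:
            raise ValueError(f"interval must have stop > start: {self}")

    @property
    def duration(self) -> float:
        return self.stop - self.start

    def overlap(self, other: "Interval") -> float:
        return max(0.0, min(self.stop, other.stop) - max(self.start, other.start))


def assign_zone(sample, arena: ArenaGeometry) -> Zone:
    """Assign a single sample to an arena zone.

    Zone 1 iff the distance to the arena centre is <= disc_radius -
    zone1_margin; zone 2 otherwise (including, with a warning, positions
    beyond the arena wall); undetected samples map to ``Zone.UNDETECTED``.
    """
    if not getattr(sample, "detected", True):
        return Zone.UNDETECTED
    r = float(np.hypot(sample.x - arena.centre[0], sample.y - arena.centre[1]))
    if r <= arena.zone1_radius:
        return Zone.ZONE1
    if r > arena.wall_radius:
        warnings.warn(
            f"sample at r={r:.2f} mm lies outside the arena wall "
            f"({arena.wall_radius} mm); assigned zone 2",
            stacklevel=2,
        )
    return Zone.ZONE2


def _zones_from_positions(
    x: np.ndarray, y: np.ndarray, valid: np.ndarray, arena: ArenaGeometry
) -> np.ndarray:
    r = np.hypot(x - arena.centre[0], y - arena.centre[1])
    zone = np.full(len(x), Zone.ZONE2, dtype=np.int8)
    with np.errstate(invalid="ignore"):
        zone[r <= arena.zone1_radius] = Zone.ZONE1
        outside = valid & (r > arena.wall_radius)
    zone[~valid] = Zone.UNDETECTED
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} samples lie outside the arena wall; "
            "assigned zone 2",
            stacklevel=3,
        )
    return zone


def _interpolate_gaps(
    t: np.ndarray, x: np.ndarray, y: np.ndarray, detected: np.ndarray, gap_max: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Linearly fill undetected gaps of at most ``gap_max`` s.

    Returns filled copies of x, y and a boolean mask of samples with a
    usable position.  Longer gaps (and undetected leading/trailing runs)
    remain unusable: no motion is invented there.
    """
    x = x.copy()
    y = y.copy()
    valid = detected.copy()
    det_idx = np.flatnonzero(detected)
    if det_idx.size == 0:
        return x, y, np.zeros_like(detected)
    # walk runs of undetected samples between detected anchors
    missing = ~detected
    i = 0
    n = len(t)
    while i < n:
        if not missing[i]:
            i += 1
            continue
        j = i
        while j < n and missing[j]:
            j += 1
        if i > 0 and j < n and (t[j] - t[i - 1]) <= gap_max:
            frac = (t[i:j] - t[i - 1]) / (t[j] - t[i - 1])
            x[i:j] = x[i - 1] + frac * (x[j] - x[i - 1])
            y[i:j] = y[i - 1] + frac * (y[j] - y[i - 1])
            valid[i:j] = True
        i = j
    return x, y, valid


def compute_kinematics(
    traj: Trajectory,
    arena: ArenaGeometry,
    analysis_rate: float = 5.0,
    smooth_window: int = 5,
    gap_max: float = 1.0,
    average_positions: bool = False,
    zone1_distance_only: bool = True,
) -> KinematicsSeries:
    """Down-sample a trajectory and compute smoothed speeds and zones.

    The acquisition track is down-sampled to ``analysis_rate`` by taking
    every k-th frame (k = frame_rate / analysis_rate); with
    ``average_positions=True`` the k frames around each analysis sample are
    averaged instead.  Instantaneous speed is the backward finite difference
    between consecutive analysis samples; the reported speed is its centred
    moving average over ``smooth_window`` samples, shrunk at the boundaries.
    The first sample inherits the first defined difference so that a
    constant-velocity track reports a constant speed.

    Undetected gaps up to ``gap_max`` s are linearly interpolated for the
    kinematics (samples stay flagged undetected); longer gaps leave speed
    undefined (NaN) and zone ``UNDETECTED``.
    """
    n = len(traj)
    if n == 0:
        raise ValueError("empty trajectory")
    if n < smooth_window + 1:
        raise ValueError(
            f"trajectory needs at least smooth_window+1={smooth_window + 1} samples"
        )
    if smooth_window < 1 or smooth_window % 2 == 0:
        raise ValueError("smooth_window must be a positive odd sample count")
    step = traj.frame_rate / analysis_rate
    k = int(round(step))
    if abs(step - k) > 1e-9 or k < 1:
        raise ValueError("frame_rate must be an integer multiple of analysis_rate")

    x, y, valid = _interpolate_gaps(traj.t, traj.x, traj.y, traj.detected, gap_max)

    if average_positions and k > 1:
        # average each block of k acquisition frames; block valid iff all
        # member positions are usable
        m = n // k
        if m < smooth_window + 1:
            raise ValueError("too few analysis samples after down-sampling")
        xb = x[: m * k].reshape(m, k)
        yb = y[: m * k].reshape(m, k)
        vb = valid[: m * k].reshape(m, k).all(axis=1)
        xs = np.where(vb, np.nanmean(xb, axis=1), np.nan)
        ys = np.where(vb, np.nanmean(yb, axis=1), np.nan)
        ts = traj.t[: m * k : k]
        det = traj.detected[: m * k].reshape(m, k).any(axis=1)
        vs = vb
    else:
        xs, ys, ts = x[::k], y[::k], traj.t[::k]
        vs = valid[::k]
        det = traj.detected[::k]
        m = len(ts)
    if m < smooth_window + 1:
        raise ValueError("too few analysis samples after down-sampling")

    dt = 1.0 / analysis_rate
    dx = np.diff(xs)
    dy = np.diff(ys)
    disp = np.hypot(dx, dy)
    pair_ok = vs[1:] & vs[:-1]
    inst = np.full(m, np.nan)
    inst[1:] = np.where(pair_ok, disp / dt, np.nan)
    inst[0] = inst[1] if m > 1 else np.nan

    # centred moving average, NaN-aware, shrunk at boundaries
    finite = np.isfinite(inst)
    kernel = np.ones(smooth_window)
    num = np.convolve(np.where(finite, inst, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        speed = num / den
    speed[~finite] = np.nan

    zone = _zones_from_positions(xs, ys, vs, arena)

    step_distance = np.zeros(m)
    counted = pair_ok.copy()
    if zone1_distance_only:
        counted &= zone[1:] == Zone.ZONE1
    step_distance[1:] = np.where(counted, disp, 0.0)

    return KinematicsSeries(
        t=ts - ts[0],
        speed=speed,
        zone=zone,
        step_distance=step_distance,
        detected=det,
        rate=analysis_rate,
    )


# ---------------------------------------------------------------------------
# interval helpers


def complement_intervals(
    intervals: list[Interval], span: tuple[float, float], label: str
) -> list[Interval]:
    """Intervals labelled ``label`` covering ``span`` minus the inputs."""
    out: list[Interval] = []
    cursor = span[0]
    for iv in sorted(intervals, key=lambda i: i.start):
        if iv.start > cursor + 1e-12:
            out.append(Interval(cursor, iv.start, label))
        cursor = max(cursor, iv.stop)
    if span[1] > cursor + 1e-12:
        out.append(Interval(cursor, span[1], label))
    return out


def check_tiling(events: list[Interval], duration: float, tol: float = 1e-6) -> None:
    """Validate that ``events`` exactly tile [0, duration)."""
    if not events:
        raise ValueError("empty event stream")
    evs = sorted(events, key=lambda i: i.start)
    if abs(evs[0].start) > tol or abs(evs[-1].stop - duration) > tol:
        raise ValueError("event stream does not span the observation")
    for a, b in zip(evs, evs[1:]):
        if abs(a.stop - b.start) > tol:
            raise ValueError(f"gap or overlap between {a} and {b}")
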