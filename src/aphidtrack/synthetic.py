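"""Ground-truthed synthetic data: behaviour schedules, trajectories, frames.

The generator emulates bout-structured aphid behaviour in a circular
leaf-disc arena: walking bouts (bounded random walk at a set speed), probing
bouts (a fixed anchor plus sub-threshold positional jitter), brief
confounding movement spikes (body movements during probing, e.g. honeydew
excretion), and edge-dwell bouts (the subject straddling the disc edge so
that its assigned position flickers between on-disc and off-disc, the known
zone-transition artifact).  A schedule carries its own ground-truth probe
intervals, so detector output can be scored against a known truth.

Optionally, trajectories are rendered into greyscale frames (backlit arena:
light background, darker disc, dark elliptical subject, anti-aliased by area
coverage) and a minimal grey-threshold blob tracker closes the loop
video -> trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import imageio.v3 as iio
import numpy as np
from scipy import ndimage, stats

from .core import PROBE, ArenaGeometry, Interval, Trajectory, Zone

__all__ = [
    "Bout",
    "BehaviorSchedule",
    "ScheduleParams",
    "FrameSpec",
    "generate_schedule",
    "schedule_from_bouts",
    "ground_truth_probes",
    "render_trajectory",
    "render_frames",
    "track_frames",
    "write_frames",
    "read_frames",
    "DEFAULT_THRESHOLDS",
]

WALK = "walk"
PROBE_BOUT = "probe"
SPIKE = "confound_spike"
EDGE = "edge_dwell"


@dataclass(frozen=True)
class Bout:
    kind: str
    duration: float
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("bout duration must be > 0")


@dataclass
class BehaviorSchedule:
    bouts: list[Bout]
    arena: ArenaGeometry
    seed: int = 0

    @property
    def duration(self) -> float:
        return sum(b.duration for b in self.bouts)

    @property
    def boundaries(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum([b.duration for b in self.bouts])))


@dataclass
class ScheduleParams:
    """Bout mix and duration distributions of the generator.

    Defaults sketch an aphid settling into probing on a suitable disc:
    roughly equal chances of walking and probing bouts with occasional
    movement spikes and rare edge dwells.  Duration distributions are
    scipy frozen distributions so their fit can be verified directly.
    Jitter statistics of real probing aphids are unpublished; the defaults
    are illustrative and chosen to sit safely below the probe-start
    velocity threshold.
    """

    p_walk: float = 0.46
    p_probe: float = 0.40
    p_spike: float = 0.10
    p_edge: float = 0.04
    walk_duration: object = field(default_factory=lambda: stats.expon(loc=5.0, scale=55.0))
    probe_duration: object = field(default_factory=lambda: stats.expon(loc=30.0, scale=570.0))
    edge_duration: object = field(default_factory=lambda: stats.expon(loc=20.0, scale=40.0))
    spike_duration: float = 0.8
    walk_speed: float = 0.8  # mm/s, well above the probe-stop threshold
    heading_sigma: float = 0.3  # rad per frame
    spike_peak: float = 0.8  # mm/s
    edge_period_in: float = 2.2  # s on the disc per flicker cycle
    edge_period_out: float = 1.2  # s off the disc
    edge_amplitude: float = 0.025  # mm radial flicker, keeps speeds sub-stop

    def kind_probabilities(self) -> dict[str, float]:
        p = {WALK: self.p_walk, PROBE_BOUT: self.p_probe, SPIKE: self.p_spike, EDGE: self.p_edge}
        total = sum(p.values())
        if total <= 0:
            raise ValueError("bout-kind probabilities must sum to > 0")
        return {k: v / total for k, v in p.items()}


def _bout_params(kind: str, params: ScheduleParams) -> dict:
    if kind == WALK:
        return {"speed": params.walk_speed, "heading_sigma": params.heading_sigma}
    if kind == SPIKE:
        return {"peak": params.spike_peak}
    if kind == EDGE:
        return {
            "period_in": params.edge_period_in,
            "period_out": params.edge_period_out,
            "amplitude": params.edge_amplitude,
        }
    return {}


def generate_schedule(
    params: ScheduleParams,
    duration: float,
    seed: int = 0,
    arena: ArenaGeometry | None = None,
) -> tuple[BehaviorSchedule, list[Interval]]:
    """Draw a reproducible bout schedule and its ground-truth probe stream."""
    arena = arena or ArenaGeometry()
    rng = np.random.default_rng(seed)
    probs = params.kind_probabilities()
    kinds = list(probs)
    weights = np.array([probs[k] for k in kinds])
    bouts: list[Bout] = []
    total = 0.0
    prev: str | None = None
    while total < duration:
        kind = kinds[int(rng.choice(len(kinds), p=weights))]
        if prev == EDGE and kind != WALK:
            kind = WALK  # re-enter the disc interior before anything else
        if kind == SPIKE:
            d = params.spike_duration
        elif kind == WALK:
            d = float(params.walk_duration.rvs(random_state=rng))
        elif kind == EDGE:
            d = float(params.edge_duration.rvs(random_state=rng))
        else:
            d = float(params.probe_duration.rvs(random_state=rng))
        d = min(d, duration - total)
        if d <= 0:
            break
        bouts.append(Bout(kind, d, _bout_params(kind, params)))
        total += d
        prev = kind
    schedule = BehaviorSchedule(bouts=bouts, arena=arena, seed=seed)
    return schedule, ground_truth_probes(schedule)


def schedule_from_bouts(
    bouts: list[tuple[str, float]] | list[Bout],
    arena: ArenaGeometry | None = None,
    seed: int = 0,
    params: ScheduleParams | None = None,
) -> tuple[BehaviorSchedule, list[Interval]]:
    """Build a schedule from an explicit bout list (kind, duration)."""
    params = params or ScheduleParams()
    norm = [
        b if isinstance(b, Bout) else Bout(b[0], b[1], _bout_params(b[0], params))
        for b in bouts
    ]
    schedule = BehaviorSchedule(bouts=norm, arena=arena or ArenaGeometry(), seed=seed)
    return schedule, ground_truth_probes(schedule)


def ground_truth_probes(schedule: BehaviorSchedule) -> list[Interval]:
    """True probe intervals of a schedule.

    Consecutive probe bouts merge; a movement spike flanked by probe bouts
    is absorbed into the probe (the stylets stay inserted during such body
    movements).  Edge dwells are not ground-truth probing: their true state
    is ambiguous by construction.
    """
    bounds = schedule.boundaries
    kinds = [b.kind for b in schedule.bouts]
    probes: list[Interval] = []
    cur_start: float | None = None
    for i, kind in enumerate(kinds):
        is_probing = kind == PROBE_BOUT or (
            kind == SPIKE
            and 0 < i < len(kinds) - 1
            and kinds[i - 1] == PROBE_BOUT
            and kinds[i + 1] == PROBE_BOUT
        )
        if is_probing and cur_start is None:
            cur_start = float(bounds[i])
        elif not is_probing and cur_start is not None:
            probes.append(Interval(cur_start, float(bounds[i]), PROBE))
            cur_start = None
    if cur_start is not None:
        probes.append(Interval(cur_start, float(bounds[-1]), PROBE))
    return probes


def render_trajectory(
    schedule: BehaviorSchedule,
    noise_sd: float = 0.002,
    frame_rate: float = 25.0,
    pixel_scale: float = 16.583,
    seed: int | None = None,
) -> Trajectory:
    """Render a schedule into a centre-point trajectory (mm, fully detected).

    Probe bouts hold a fixed anchor plus isotropic Gaussian jitter of
    ``noise_sd`` mm (sub-threshold by construction for small values); walk
    bouts follow a bounded random walk kept inside the zone-1 core; spikes
    are brief out-and-back excursions; edge dwells flicker radially across
    the zone-1 boundary.  Positions never leave the arena wall.
    """
    arena = schedule.arena
    rng = np.random.default_rng(schedule.seed + 7919 if seed is None else seed)
    dt = 1.0 / frame_rate
    n = int(round(schedule.duration * frame_rate))
    pos = np.empty((n, 2))
    cx, cy = arena.centre
    r_walk = max(arena.zone1_radius - 0.55, 0.3 * arena.zone1_radius)

    ang = rng.uniform(0, 2 * math.pi)
    rad = rng.uniform(0, 0.5 * r_walk)
    cur = np.array([cx + rad * math.cos(ang), cy + rad * math.sin(ang)])
    heading = rng.uniform(0, 2 * math.pi)

    bounds = schedule.boundaries
    frame_bounds = np.round(bounds * frame_rate).astype(int)
    frame_bounds[-1] = n
    for b, bout in enumerate(schedule.bouts):
        i0, i1 = int(frame_bounds[b]), int(frame_bounds[b + 1])
        m = i1 - i0
        if m <= 0:
            continue
        if bout.kind == PROBE_BOUT:
            anchor = cur.copy()
            pos[i0:i1] = anchor + rng.normal(0.0, noise_sd, size=(m, 2))
            cur = anchor
        elif bout.kind == WALK:
            speed = bout.params.get("speed", 0.8)
            sigma = bout.params.get("heading_sigma", 0.3)
            step = speed * dt
            for i in range(i0, i1):
                nxt = cur + step * np.array([math.cos(heading), math.sin(heading)])
                if math.hypot(nxt[0] - cx, nxt[1] - cy) > r_walk:
                    heading = math.atan2(cy - cur[1], cx - cur[0]) + rng.normal(0, 0.2)
                    nxt = cur + step * np.array([math.cos(heading), math.sin(heading)])
                pos[i] = nxt
                cur = nxt
                heading += rng.normal(0.0, sigma)
        elif bout.kind == SPIKE:
            peak = bout.params.get("peak", 0.8)
            amp = peak * bout.duration / math.pi
            direction = rng.uniform(0, 2 * math.pi)
            u = np.array([math.cos(direction), math.sin(direction)])
            tau = (np.arange(m) + 1) / m
            offset = amp * np.sin(math.pi * tau)
            pos[i0:i1] = cur + offset[:, None] * u + rng.normal(0, noise_sd, (m, 2))
        elif bout.kind == EDGE:
            p_in = bout.params.get("period_in", 2.2)
            p_out = bout.params.get("period_out", 1.2)
            amp = bout.params.get("amplitude", 0.025)
            phi = math.atan2(cur[1] - cy, cur[0] - cx)
            if math.hypot(cur[0] - cx, cur[1] - cy) < 1e-9:
                phi = rng.uniform(0, 2 * math.pi)
            tau = np.arange(m) * dt
            inside = (tau % (p_in + p_out)) < p_in
            r = np.where(inside, arena.zone1_radius - amp, arena.zone1_radius + amp)
            u = np.array([math.cos(phi), math.sin(phi)])
            pts = np.array([cx, cy]) + r[:, None] * u
            pos[i0:i1] = pts + rng.normal(0, noise_sd, (m, 2))
            cur = np.array([cx, cy]) + (arena.zone1_radius - amp) * u
        else:
            raise ValueError(f"unknown bout kind {bout.kind!r}")

    # never exit the arena wall
    r = np.hypot(pos[:, 0] - cx, pos[:, 1] - cy)
    over = r > arena.wall_radius - 1e-6
    if over.any():
        shrink = (arena.wall_radius - 1e-6) / r[over]
        pos[over, 0] = cx + (pos[over, 0] - cx) * shrink
        pos[over, 1] = cy + (pos[over, 1] - cy) * shrink

    return Trajectory(
        t=np.arange(n) * dt,
        x=pos[:, 0],
        y=pos[:, 1],
        detected=np.ones(n, dtype=bool),
        frame_rate=frame_rate,
        pixel_scale=pixel_scale,
        arena_id=f"synthetic-{schedule.seed}",
    )


# ---------------------------------------------------------------------------
# frame rendering and the minimal grey-threshold tracker


@dataclass
class FrameSpec:
    """Backlit greyscale scene: image geometry, grey levels, subject shape."""

    shape: tuple[int, int] = (112, 112)  # rows, cols
    background_grey: int = 200
    disc_grey: int = 120
    aphid_grey: int = 30
    aphid_axes: tuple[float, float] = (0.85, 0.5)  # semi-axes, mm (~1.7 mm body)
    pixel_scale: float = 16.583  # px per mm
    frame_rate: float = 25.0

    def __post_init__(self) -> None:
        greys = {self.background_grey, self.disc_grey, self.aphid_grey}
        if len(greys) != 3:
            raise ValueError("grey levels must be distinct")


#: Per-zone segmentation thresholds: pixels darker than the zone's threshold
#: are foreground.  The disc region needs a tighter threshold than the
#: brighter agar/background annulus.
DEFAULT_THRESHOLDS = {Zone.ZONE1: 75, Zone.ZONE2: 100}


def _background(spec: FrameSpec, arena: ArenaGeometry) -> np.ndarray:
    h, w = spec.shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    px = (jj + 0.5) / spec.pixel_scale
    py = (ii + 0.5) / spec.pixel_scale
    d_px = np.hypot(px - arena.centre[0], py - arena.centre[1]) * spec.pixel_scale
    cov = np.clip(arena.disc_radius * spec.pixel_scale - d_px + 0.5, 0.0, 1.0)
    return spec.background_grey * (1.0 - cov) + spec.disc_grey * cov


def _headings(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    dx = np.diff(x, prepend=x[0])
    dy = np.diff(y, prepend=y[0])
    head = np.zeros(len(x))
    cur = 0.0
    # orientation tracks genuine locomotion only; sub-pixel jitter while
    # probing must not spin the body
    move = np.hypot(dx, dy) > 0.01
    for i in range(len(x)):  # orientation follows motion heading, held when still
        if move[i]:
            cur = math.atan2(dy[i], dx[i])
        head[i] = cur
    return head


def render_frames(
    traj: Trajectory, spec: FrameSpec, arena: ArenaGeometry
) -> Iterator[np.ndarray]:
    """Yield one greyscale uint8 frame per trajectory sample.

    The elliptical subject is anti-aliased by approximate area coverage so
    sub-pixel centroids are meaningful; its orientation follows the motion
    heading.  Undetected samples yield an empty (subject-free) scene.  A
    subject extending beyond the image raises.
    """
    bg = _background(spec, arena)
    h, w = spec.shape
    a_px = spec.aphid_axes[0] * spec.pixel_scale
    b_px = spec.aphid_axes[1] * spec.pixel_scale
    pad = int(math.ceil(a_px + 2))
    heads = _headings(traj.x, traj.y)
    for i in range(len(traj)):
        if not traj.detected[i]:
            yield np.round(bg).astype(np.uint8)
            continue
        cxp = traj.x[i] * spec.pixel_scale - 0.5  # pixel-index coordinates
        cyp = traj.y[i] * spec.pixel_scale - 0.5
        r0, r1 = int(math.floor(cyp)) - pad, int(math.ceil(cyp)) + pad + 1
        c0, c1 = int(math.floor(cxp)) - pad, int(math.ceil(cxp)) + pad + 1
        if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
            raise ValueError(f"subject at frame {i} extends outside the image")
        jj, ii = np.meshgrid(np.arange(c0, c1), np.arange(r0, r1))
        du = jj - cxp
        dv = ii - cyp
        ct, st = math.cos(heads[i]), math.sin(heads[i])
        u = (du * ct + dv * st) / a_px
        v = (-du * st + dv * ct) / b_px
        rho = np.hypot(u, v)
        cov = np.clip(0.5 - (rho - 1.0) * b_px, 0.0, 1.0)
        frame = bg.copy()
        frame[r0:r1, c0:c1] = frame[r0:r1, c0:c1] * (1.0 - cov) + spec.aphid_grey * cov
        yield np.round(frame).astype(np.uint8)


def _threshold_map(
    shape: tuple[int, int],
    arena: ArenaGeometry,
    pixel_scale: float,
    thresholds: dict,
) -> np.ndarray:
    h, w = shape
    jj, ii = np.meshgrid(np.arange(w), np.arange(h))
    px = (jj + 0.5) / pixel_scale
    py = (ii + 0.5) / pixel_scale
    on_disc = np.hypot(px - arena.centre[0], py - arena.centre[1]) <= arena.disc_radius
    thr = np.where(on_disc, thresholds[Zone.ZONE1], thresholds[Zone.ZONE2])
    return thr.astype(float)


_EIGHT = np.ones((3, 3), dtype=int)


def track_frames(
    frames: Iterable[np.ndarray],
    arena: ArenaGeometry,
    pixel_scale: float = 16.583,
    thresholds: dict | None = None,
    frame_rate: float = 25.0,
    arena_id: str = "tracked",
) -> Trajectory:
    """Segment each frame with per-zone grey thresholds and track the subject.

    Pixels darker than the zone-appropriate threshold are foreground; the
    centroid of the largest 8-connected component becomes the sample.  Equal
    sizes are tied-broken by darker mean grey, then by top-left position.
    Frames without foreground yield undetected samples.
    """
    thresholds = thresholds or DEFAULT_THRESHOLDS
    thr = None
    xs, ys, det = [], [], []
    for frame in frames:
        frame = np.asarray(frame)
        if thr is None:
            thr = _threshold_map(frame.shape, arena, pixel_scale, thresholds)
        mask = frame < thr
        labels, n_comp = ndimage.label(mask, structure=_EIGHT)
        if n_comp == 0:
            xs.append(np.nan)
            ys.append(np.nan)
            det.append(False)
            continue
        sizes = np.bincount(labels.ravel())[1:]
        best_size = sizes.max()
        cands = np.flatnonzero(sizes == best_size) + 1
        if len(cands) > 1:
            means = np.array(
                [frame[labels == c].mean() for c in cands], dtype=float
            )
            cands = cands[means == means.min()]
            if len(cands) > 1:
                firsts = np.array(
                    [np.argmax((labels == c).ravel()) for c in cands]
                )
                cands = cands[[int(np.argmin(firsts))]]
        rows, cols = np.nonzero(labels == cands[0])
        xs.append((cols.mean() + 0.5) / pixel_scale)
        ys.append((rows.mean() + 0.5) / pixel_scale)
        det.append(True)
    n = len(xs)
    return Trajectory(
        t=np.arange(n) / frame_rate,
        x=np.array(xs),
        y=np.array(ys),
        detected=np.array(det, dtype=bool),
        frame_rate=frame_rate,
        pixel_scale=pixel_scale,
        arena_id=arena_id,
    )


def write_frames(frames: Iterable[np.ndarray], out_dir: str | Path) -> int:
    """Write frames as a zero-padded PNG stack; returns the frame count."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    n = 0
    for i, frame in enumerate(frames):
        iio.imwrite(out_dir / f"frame_{i:06d}.png", np.asarray(frame, dtype=np.uint8))
        n = i + 1
    return n


def read_frames(in_dir: str | Path) -> Iterator[np.ndarray]:
    """Yield frames from a PNG/TIFF stack directory in filename order."""
    in_dir = Path(in_dir)
    paths = sorted(
        p for p in in_dir.iterdir() if p.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not paths:
        raise FileNotFoundError(f"no image frames in {in_dir}")
    for p in paths:
        yield iio.imread(p)
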