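"""Per-observation and per-time-bin response variables.

Probe categories follow the EPG-derived duration classes: probes shorter
than 3 min are epidermis/mesophyll test probes ("short"); probes of at least
25 min approximate phloem-uptake events ("long"); probes longer than 35 min
are "sustained".  "Other" probes are the complement of long.  Durations are
reported in minutes and distance in cm, matching how such assays are
conventionally tabulated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .core import NON_PROBE, NOT_MOVING, PROBE, Interval, KinematicsSeries

__all__ = [
    "ProbeCategories",
    "ObservationSummary",
    "categorize_probe",
    "summarize_observation",
    "summarize_bins",
    "qc_exclude",
]


@dataclass(frozen=True)
class ProbeCategories:
    """Duration thresholds (s): short < short_max; long >= long_min;
    sustained > sustained_min."""

    short_max: float = 180.0
    long_min: float = 1500.0
    sustained_min: float = 2100.0

    def __post_init__(self) -> None:
        if not (self.short_max < self.long_min < self.sustained_min):
            raise ValueError("require short_max < long_min < sustained_min")


def categorize_probe(duration: float, cats: ProbeCategories = ProbeCategories()) -> set[str]:
    """Category labels of one probe; ``other`` is the complement of ``long``."""
    if duration <= 0:
        raise ValueError("probe duration must be > 0")
    out = set()
    if duration < cats.short_max:
        out.add("short")
    if duration >= cats.long_min:
        out.add("long")
    else:
        out.add("other")
    if duration > cats.sustained_min:
        out.add("sustained")
    return out


@dataclass
class ObservationSummary:
    """Video-tracking response variables for one arena.

    Durations in minutes, distance in cm, speed in mm/s.  Mean duration and
    latency of long probes are ``None`` when no long probe occurred (absent,
    not zero).
    """

    arena_id: str
    nonprobe_total_min: float
    long_total_min: float
    sustained_total_min: float
    other_total_min: float
    notmoving_total_min: float
    n_nonprobe_bouts: int
    n_short_probes: int
    n_long_probes: int
    mean_long_min: Optional[float]
    latency_long_min: Optional[float]
    distance_cm: float
    max_velocity_mms: float
    qc_detected_fraction: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _family(events: list[Interval], labels: set[str], duration: float) -> list[Interval]:
    evs = sorted((e for e in events if e.label in labels), key=lambda e: e.start)
    total = sum(e.duration for e in evs)
    if abs(total - duration) > 1e-6 * max(1.0, duration):
        raise ValueError(
            f"event stream ({total:.3f} s) does not tile the observation "
            f"({duration:.3f} s)"
        )
    return evs


def summarize_observation(
    events: list[Interval],
    movement: list[Interval],
    kin: KinematicsSeries,
    cats: ProbeCategories = ProbeCategories(),
    duration: float | None = None,
    arena_id: str | None = None,
) -> ObservationSummary:
    """Compute the per-observation response variables from event streams."""
    if duration is None:
        duration = kin.duration
    evs = _family(events, {PROBE, NON_PROBE}, duration)
    movs = _family(movement, {"moving", NOT_MOVING}, duration)
    probes = [e for e in evs if e.label == PROBE]
    nonprobes = [e for e in evs if e.label == NON_PROBE]

    long_probes = [p for p in probes if "long" in categorize_probe(p.duration, cats)]
    sustained = [p for p in probes if "sustained" in categorize_probe(p.duration, cats)]
    other = [p for p in probes if "other" in categorize_probe(p.duration, cats)]
    short = [p for p in probes if "short" in categorize_probe(p.duration, cats)]

    with np.errstate(invalid="ignore"):
        max_v = float(np.nanmax(kin.speed)) if np.isfinite(kin.speed).any() else float("nan")

    return ObservationSummary(
        arena_id=arena_id or "arena",
        nonprobe_total_min=sum(e.duration for e in nonprobes) / 60.0,
        long_total_min=sum(p.duration for p in long_probes) / 60.0,
        sustained_total_min=sum(p.duration for p in sustained) / 60.0,
        other_total_min=sum(p.duration for p in other) / 60.0,
        notmoving_total_min=sum(e.duration for e in movs if e.label == NOT_MOVING) / 60.0,
        n_nonprobe_bouts=len(nonprobes),
        n_short_probes=len(short),
        n_long_probes=len(long_probes),
        mean_long_min=(
            float(np.mean([p.duration for p in long_probes])) / 60.0
            if long_probes
            else None
        ),
        latency_long_min=long_probes[0].start / 60.0 if long_probes else None,
        distance_cm=float(kin.cumulative_distance[-1]) / 10.0,
        max_velocity_mms=max_v,
        qc_detected_fraction=kin.qc_detected_fraction,
    )


def summarize_bins(
    events: list[Interval],
    kin: KinematicsSeries,
    bin_width: float = 3600.0,
    duration: float | None = None,
    cats: ProbeCategories = ProbeCategories(),
) -> pd.DataFrame:
    """Per-time-bin percentage of time in long probes and distance moved.

    A probe's category is decided by its full duration; its time is
    apportioned to bins pro rata by overlap.  Distance is the sum of zone-1
    displacements of analysis samples falling in the bin.  Returns a frame
    with columns ``bin``, ``t_start_min``, ``pct_long_probes``,
    ``distance_cm``.
    """
    if duration is None:
        duration = kin.duration
    n_bins = duration / bin_width
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ValueError("bin_width must divide the observation duration")
    n_bins = int(round(n_bins))
    evs = _family(events, {PROBE, NON_PROBE}, duration)
    long_probes = [
        e
        for e in evs
        if e.label == PROBE and "long" in categorize_probe(e.duration, cats)
    ]
    long_time = np.zeros(n_bins)
    for p in long_probes:
        for b in range(int(p.start // bin_width), n_bins):
            bin_iv = Interval(b * bin_width, (b + 1) * bin_width, "bin")
            ov = bin_iv.overlap(p)
            if ov <= 0 and bin_iv.start >= p.stop:
                break
            long_time[b] += ov
    bin_of_sample = np.minimum(
        (kin.t / bin_width).astype(int), n_bins - 1
    )
    dist = np.bincount(bin_of_sample, weights=kin.step_distance, minlength=n_bins)
    return pd.DataFrame(
        {
            "bin": np.arange(n_bins),
            "t_start_min": np.arange(n_bins) * bin_width / 60.0,
            "pct_long_probes": 100.0 * long_time / bin_width,
            "distance_cm": dist / 10.0,
        }
    )


def qc_exclude(
    summaries: list[ObservationSummary], min_detected_fraction: float = 0.9
) -> tuple[list[ObservationSummary], list[tuple[ObservationSummary, str]]]:
    """Partition observations by detection quality.

    Returns ``(retained, excluded)``; each excluded entry carries a reason
    string.  Mirrors the practice of dropping arenas with no or low-quality
    subject detection before analysis.
    """
    retained: list[ObservationSummary] = []
    excluded: list[tuple[ObservationSummary, str]] = []
    for s in summaries:
        if s.qc_detected_fraction < min_detected_fraction:
            excluded.append(
                (
                    s,
                    f"detected fraction {s.qc_detected_fraction:.3f} "
                    f"< {min_detected_fraction:.3f}",
                )
            )
        else:
            retained.append(s)
    return retained, excluded
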