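"""Probe and movement state machines with velocity hysteresis.

A probe (plant penetration) is inferred from sustained stillness of the body
centre point on the leaf disc: it starts when the smoothed speed drops below
``v_probe_start`` while the subject is on the disc and stays at or below
``v_probe_stop`` for at least ``t_probe_start`` seconds.  It ends when speed
exceeds ``v_probe_stop`` and does not fall back below the ``v_hysteresis``
level for at least ``t_probe_stop`` seconds — brief body movements during a
probe (reproduction, honeydew excretion, grooming) dip back quickly and are
thereby ignored.  Leaving the disc force-ends a probe; a subject straddling
the disc edge therefore produces trains of very short probes, which
:func:`filter_zone_transitions` removes after acquisition.

Timestamp conventions: a probe starts at the first sample of its qualifying
stillness window and stops at the onset of the confirming excursion (the
excursion itself is non-probing).  Threshold comparisons are strict;
at-threshold samples do not trigger transitions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import (
    MOVING,
    NON_PROBE,
    NOT_MOVING,
    PROBE,
    Interval,
    KinematicsSeries,
    Zone,
    complement_intervals,
)

__all__ = [
    "SpeciesProfile",
    "FilterParams",
    "M_PERSICAE",
    "N_RIBISNIGRI",
    "SPECIES",
    "detect_probes",
    "detect_movement",
    "filter_zone_transitions",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Velocity/dwell thresholds calibrated per aphid species (mm/s, s)."""

    v_probe_start: float = 0.02
    t_probe_start: float = 10.0
    v_probe_stop: float = 0.3
    v_hysteresis: float = 0.1
    t_probe_stop: float = 2.0
    v_move_start: float = 0.3
    v_move_stop: float = 0.02

    def __post_init__(self) -> None:
        if not (0 < self.v_probe_start < self.v_hysteresis < self.v_probe_stop):
            raise ValueError(
                "require 0 < v_probe_start < v_hysteresis < v_probe_stop"
            )
        if self.t_probe_start <= 0 or self.t_probe_stop <= 0:
            raise ValueError("dwell times must be > 0")


#: Wingless Myzus persicae (~1.7 mm body length).
M_PERSICAE = SpeciesProfile(v_probe_stop=0.3)
#: Winged Nasonovia ribisnigri (~1.9 mm): body movements around the fixated
#: mouthparts give higher tangential speeds, hence the higher stop threshold.
N_RIBISNIGRI = SpeciesProfile(v_probe_stop=0.35)

SPECIES = {"m_persicae": M_PERSICAE, "n_ribisnigri": N_RIBISNIGRI}


@dataclass(frozen=True)
class FilterParams:
    """Zone-transition artifact filter: remove probes shorter than
    ``max_filtered_probe`` s preceded by a non-probe bout of at most
    ``max_preceding_gap`` s."""

    max_filtered_probe: float = 3.0
    max_preceding_gap: float = 15.0

    def __post_init__(self) -> None:
        if self.max_filtered_probe <= 0 or self.max_preceding_gap <= 0:
            raise ValueError("filter parameters must be > 0")


def _checked(kin: KinematicsSeries) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if len(kin) == 0:
        raise ValueError("empty kinematics series")
    valid = np.isfinite(kin.speed)
    return kin.speed, np.asarray(kin.zone), valid


def detect_probes(kin: KinematicsSeries, profile: SpeciesProfile) -> list[Interval]:
    """Segment an observation into alternating probe / non-probe intervals.

    Returns intervals tiling ``[0, kin.duration)``.  An all-undetected
    series yields a single non-probe interval with a QC warning.
    """
    speed, zone, valid = _checked(kin)
    n = len(kin)
    span = (float(kin.t[0]), float(kin.t[0]) + kin.duration)
    if not valid.any():
        warnings.warn("no valid samples; whole observation scored non-probing")
        return [Interval(span[0], span[1], NON_PROBE)]

    t = kin.t
    # window membership: speed must never exceed v_probe_stop (strict) and be
    # defined throughout the qualifying window
    ok = valid & ~(speed > profile.v_probe_stop)
    still = valid & (speed < profile.v_probe_start) & (zone == Zone.ZONE1)
    w = int(np.ceil(profile.t_probe_start * kin.rate))  # samples spanning the dwell
    bad_prefix = np.concatenate(([0], np.cumsum(~ok)))
    idx = np.arange(n)
    window_ok = np.zeros(n, dtype=bool)
    fits = idx + w < n
    window_ok[fits] = (bad_prefix[idx[fits] + w + 1] - bad_prefix[idx[fits]]) == 0
    candidates = np.flatnonzero(still & window_ok)

    probes: list[Interval] = []
    i = 0
    while True:
        pos = np.searchsorted(candidates, i)
        if pos == len(candidates):
            break
        s = int(candidates[pos])
        start_t = float(t[s])
        end_t = span[1]
        resume = n
        k = s + 1
        while k < n:
            if not valid[k] or zone[k] != Zone.ZONE1:
                end_t = float(t[k])  # zone exit / detection loss ends the probe
                resume = k
                break
            if speed[k] > profile.v_probe_stop:
                # candidate stop excursion beginning at k
                m = k + 1
                outcome = "unresolved"
                while m < n:
                    if not valid[m] or zone[m] != Zone.ZONE1:
                        outcome = "forced"
                        break
                    if speed[m] < profile.v_hysteresis:
                        outcome = "aborted"
                        break
                    if t[m] - t[k] >= profile.t_probe_stop:
                        outcome = "confirmed"
                        break
                    m += 1
                if outcome == "confirmed":
                    end_t = float(t[k])
                    resume = m
                    break
                if outcome == "forced":
                    end_t = float(t[m])
                    resume = m
                    break
                if outcome == "aborted":
                    k = m + 1
                    continue
                # excursion ran to end of data without confirmation:
                # probe extends to the observation end
                end_t = span[1]
                resume = n
                break
            k += 1
        if end_t > start_t:
            probes.append(Interval(start_t, end_t, PROBE))
        i = max(resume, s + 1)

    events = sorted(
        probes + complement_intervals(probes, span, NON_PROBE),
        key=lambda e: e.start,
    )
    return events


def detect_movement(kin: KinematicsSeries, profile: SpeciesProfile) -> list[Interval]:
    """Two-threshold moving / not-moving segmentation (no dwell times).

    Moving begins when speed rises above ``v_move_start`` and ends when it
    falls below ``v_move_stop``; undefined samples hold the previous state.
    """
    speed, _zone, valid = _checked(kin)
    n = len(kin)
    span = (float(kin.t[0]), float(kin.t[0]) + kin.duration)
    if not valid.any():
        warnings.warn("no valid samples; whole observation scored not moving")
        return [Interval(span[0], span[1], NOT_MOVING)]
    t = kin.t
    state = bool(valid[0] and speed[0] > profile.v_move_start)
    events: list[Interval] = []
    seg_start = span[0]
    for k in range(1, n):
        if not valid[k]:
            continue
        if not state and speed[k] > profile.v_move_start:
            events.append(Interval(seg_start, float(t[k]), NOT_MOVING))
            seg_start, state = float(t[k]), True
        elif state and speed[k] < profile.v_move_stop:
            events.append(Interval(seg_start, float(t[k]), MOVING))
            seg_start, state = float(t[k]), False
    if span[1] > seg_start:
        events.append(Interval(seg_start, span[1], MOVING if state else NOT_MOVING))
    return events


def filter_zone_transitions(
    events: list[Interval], params: FilterParams = FilterParams()
) -> list[Interval]:
    """Remove zone-transition probe trains from a probe event stream.

    A subject sitting exactly on the disc edge flickers between an on-disc
    and off-disc position, chopping one probe into a train of very short
    probes separated by very short gaps.  Every probe shorter than
    ``max_filtered_probe`` whose preceding non-probe bout (in the original
    stream) lasted at most ``max_preceding_gap`` is relabelled non-probing,
    in a single left-to-right pass; neighbouring non-probe intervals merge.
    A probe at the stream start (no preceding non-probe bout) is retained.
    """
    if not events:
        return []
    evs = sorted(events, key=lambda e: e.start)
    labels = {e.label for e in evs}
    if not labels <= {PROBE, NON_PROBE}:
        raise ValueError(f"expected a probe/non-probe stream, got labels {labels}")
    for a, b in zip(evs, evs[1:]):
        if abs(a.stop - b.start) > 1e-9 or a.label == b.label:
            raise ValueError("stream must be alternating and contiguous")
    span = (evs[0].start, evs[-1].stop)
    kept: list[Interval] = []
    prev_gap: float | None = None
    for e in evs:
        if e.label == NON_PROBE:
            prev_gap = e.duration
            continue
        remove = (
            e.duration < params.max_filtered_probe
            and prev_gap is not None
            and prev_gap <= params.max_preceding_gap
        )
        if not remove:
            kept.append(e)
        prev_gap = None
    return sorted(
        kept + complement_intervals(kept, span, NON_PROBE), key=lambda e: e.start
    )
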