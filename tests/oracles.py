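"""Independent brute-force reference implementations used as test oracles.

These re-derive each operation literally from its definition (explicit
per-sample scans, window slicing, all-pairs overlap checks) instead of the
run-length / vectorized routes taken by the package, so agreement between
the two is meaningful.
"""

from __future__ import annotations

import numpy as np

from aphidtrack.core import (
    MOVING,
    NON_PROBE,
    NOT_MOVING,
    PROBE,
    Interval,
    KinematicsSeries,
    Zone,
)

ZONE1 = int(Zone.ZONE1)


def make_kin(speed, zone=None, rate=5.0, detected=None, step=None) -> KinematicsSeries:
    """Assemble a KinematicsSeries directly from a speed array."""
    speed = np.asarray(speed, dtype=float)
    n = len(speed)
    if zone is None:
        zone = np.full(n, ZONE1)
    zone = np.asarray(zone)
    if detected is None:
        detected = zone != int(Zone.UNDETECTED)
    if step is None:
        step = np.zeros(n)
    return KinematicsSeries(
        t=np.arange(n) / rate,
        speed=speed,
        zone=zone,
        step_distance=np.asarray(step, dtype=float),
        detected=np.asarray(detected, dtype=bool),
        rate=rate,
    )


def probe_reference(kin, profile) -> list[Interval]:
    """Sample-by-sample probe automaton, straight from the stated rules."""
    t = kin.t
    speed = kin.speed
    zone = np.asarray(kin.zone)
    n = len(t)
    valid = np.isfinite(speed)
    duration = kin.duration
    span_end = float(t[0]) + duration
    if not valid.any():
        return [Interval(float(t[0]), span_end, NON_PROBE)]

    def qualifies(s: int) -> bool:
        if not (valid[s] and zone[s] == ZONE1 and speed[s] < profile.v_probe_start):
            return False
        # the window must span at least t_probe_start seconds of data during
        # which speed is defined and never exceeds v_probe_stop
        stop_t = t[s] + profile.t_probe_start
        ks = [k for k in range(s, n) if t[k] <= stop_t + 1e-12]
        if t[ks[-1]] < stop_t - 1e-12:
            return False
        return all(valid[k] and not (speed[k] > profile.v_probe_stop) for k in ks)

    probes: list[tuple[float, float]] = []
    i = 0
    while i < n:
        if not qualifies(i):
            i += 1
            continue
        start = float(t[i])
        end = span_end
        nxt = n
        k = i + 1
        while k < n:
            if not valid[k] or zone[k] != ZONE1:
                end, nxt = float(t[k]), k
                break
            if speed[k] > profile.v_probe_stop:
                verdict = None
                m = k + 1
                while m < n:
                    if not valid[m] or zone[m] != ZONE1:
                        verdict = ("forced", m)
                        break
                    if speed[m] < profile.v_hysteresis:
                        verdict = ("aborted", m)
                        break
                    if t[m] - t[k] >= profile.t_probe_stop:
                        verdict = ("stop", m)
                        break
                    m += 1
                if verdict is None:  # data ended mid-excursion
                    end, nxt = span_end, n
                    break
                kind, m = verdict
                if kind == "stop":
                    end, nxt = float(t[k]), m
                    break
                if kind == "forced":
                    end, nxt = float(t[m]), m
                    break
                k = m + 1
                continue
            k += 1
        if end > start:
            probes.append((start, end))
        i = max(nxt, i + 1)

    events: list[Interval] = []
    cursor = float(t[0])
    for s, e in probes:
        if s > cursor + 1e-12:
            events.append(Interval(cursor, s, NON_PROBE))
        events.append(Interval(s, e, PROBE))
        cursor = e
    if span_end > cursor + 1e-12:
        events.append(Interval(cursor, span_end, NON_PROBE))
    return events


def movement_reference(kin, profile) -> list[Interval]:
    t = kin.t
    speed = kin.speed
    n = len(t)
    valid = np.isfinite(speed)
    span_end = float(t[0]) + kin.duration
    if not valid.any():
        return [Interval(float(t[0]), span_end, NOT_MOVING)]
    states = []
    state = bool(valid[0] and speed[0] > profile.v_move_start)
    states.append(state)
    for k in range(1, n):
        if valid[k]:
            if not state and speed[k] > profile.v_move_start:
                state = True
            elif state and speed[k] < profile.v_move_stop:
                state = False
        states.append(state)
    events = []
    seg_start = float(t[0])
    for k in range(1, n):
        if states[k] != states[k - 1]:
            events.append(
                Interval(seg_start, float(t[k]), MOVING if states[k - 1] else NOT_MOVING)
            )
            seg_start = float(t[k])
    events.append(Interval(seg_start, span_end, MOVING if states[-1] else NOT_MOVING))
    return events


def filter_reference(events, params) -> list[Interval]:
    """Literal application of the 3-s/15-s removal rule, then re-tiling."""
    evs = sorted(events, key=lambda e: e.start)
    keep = []
    for idx, e in enumerate(evs):
        if e.label != PROBE:
            continue
        prev = evs[idx - 1] if idx > 0 else None
        short = e.duration < params.max_filtered_probe
        short_gap = (
            prev is not None
            and prev.label == NON_PROBE
            and prev.duration <= params.max_preceding_gap
        )
        if not (short and short_gap):
            keep.append(e)
    out = []
    cursor = evs[0].start
    for e in keep:
        if e.start > cursor + 1e-12:
            out.append(Interval(cursor, e.start, NON_PROBE))
        out.append(e)
        cursor = e.stop
    if evs[-1].stop > cursor + 1e-12:
        out.append(Interval(cursor, evs[-1].stop, NON_PROBE))
    return out


def random_speed_series(rng, n_min=80, n_max=200, rate=5.0):
    """Piecewise-constant speed/zone series exercising every transition.

    Levels straddle all four threshold bands, with occasional exact
    threshold values, zone-2 excursions, and undefined (NaN) runs.
    """
    n = int(rng.integers(n_min, n_max + 1))
    speed = np.empty(n)
    zone = np.full(n, ZONE1)
    i = 0
    while i < n:
        seg = int(rng.integers(1, 70))
        j = min(n, i + seg)
        cat = rng.choice(6, p=[0.38, 0.08, 0.08, 0.26, 0.1, 0.1])
        if cat == 0:
            level = rng.uniform(0.0, 0.02)
        elif cat == 1:
            level = rng.uniform(0.02, 0.1)
        elif cat == 2:
            level = rng.uniform(0.1, 0.3)
        elif cat == 3:
            level = rng.uniform(0.3, 1.0)
        elif cat == 4:  # detection gap: undefined speed
            level = np.nan
        else:  # zone-2 excursion
            level = rng.uniform(0.0, 0.5)
            zone[i:j] = int(Zone.ZONE2)
        if cat < 4 and rng.random() < 0.1:
            level = float(rng.choice([0.02, 0.1, 0.3]))  # exactly at a threshold
        speed[i:j] = level
        if cat == 4:
            zone[i:j] = int(Zone.UNDETECTED) if rng.random() < 0.5 else ZONE1
        i = j
    return make_kin(speed, zone=zone, rate=rate)


def summary_reference(events, movement, kin, cats, duration):
    """First-principles interval accounting for the response variables."""
    probes = sorted(
        [e for e in events if e.label == PROBE], key=lambda e: e.start
    )
    nonprobes = [e for e in events if e.label == NON_PROBE]
    durs = [p.duration for p in probes]
    longs = [p for p in probes if p.duration >= cats.long_min]
    out = {
        "nonprobe_total_min": sum(e.duration for e in nonprobes) / 60,
        "long_total_min": sum(d for d in durs if d >= cats.long_min) / 60,
        "sustained_total_min": sum(d for d in durs if d > cats.sustained_min) / 60,
        "other_total_min": sum(d for d in durs if d < cats.long_min) / 60,
        "notmoving_total_min": sum(
            e.duration for e in movement if e.label == NOT_MOVING
        )
        / 60,
        "n_nonprobe_bouts": len(nonprobes),
        "n_short_probes": sum(d < cats.short_max for d in durs),
        "n_long_probes": len(longs),
        "mean_long_min": (np.mean([p.duration for p in longs]) / 60) if longs else None,
        "latency_long_min": (longs[0].start / 60) if longs else None,
        "distance_cm": float(np.sum(kin.step_distance)) / 10,
        "max_velocity_mms": float(np.nanmax(kin.speed)),
    }
    return out


def bins_reference(events, kin, bin_width, duration, cats):
    """Fine-grid per-sample accumulation of long-probe time and distance."""
    n_bins = int(round(duration / bin_width))
    fine = 0.01
    grid = np.arange(0.0, duration, fine)
    long_time = np.zeros(n_bins)
    for e in events:
        if e.label != PROBE or e.duration < cats.long_min:
            continue
        inside = (grid >= e.start) & (grid < e.stop)
        for b in range(n_bins):
            sel = inside & (grid >= b * bin_width) & (grid < (b + 1) * bin_width)
            long_time[b] += sel.sum() * fine
    dist = np.zeros(n_bins)
    for ti, d in zip(kin.t, kin.step_distance):
        dist[min(int(ti // bin_width), n_bins - 1)] += d
    return 100.0 * long_time / bin_width, dist / 10.0


def match_reference(auto, manual):
    """All-pairs overlap bookkeeping for event matching."""
    autos = sorted([e for e in auto if e.label == PROBE], key=lambda e: e.start)
    manuals = sorted([e for e in manual if e.label == PROBE], key=lambda e: e.start)
    detected = []
    multiplicity = []
    for m in manuals:
        hits = [a for a in autos if m.overlap(a) > 0]
        detected.append(bool(hits))
        multiplicity.append(len(hits))
    auto_matched = [any(a.overlap(m) > 0 for m in manuals) for a in autos]
    return detected, multiplicity, auto_matched
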