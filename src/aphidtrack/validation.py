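"""Benchmarking automated probe detection against manual annotations.

A manual (reference) probe counts as *detected* when at least one automated
probe overlaps it in time (open-interval intersection > 0).  A detected
probe matched by several automated probes is *overrated* (the software split
one true probe); one automated probe overlapping several manual probes makes
those *underrated* (the software merged true probes).  Start/stop/duration
offsets (automated minus manual) are computed per matched pair; when several
automated probes overlap one manual probe, the one with the most similar
duration is paired (ties broken by earlier start).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval

__all__ = ["MatchedPair", "MatchReport", "match_events", "accuracy_summary", "correlate_summaries"]


@dataclass(frozen=True)
class MatchedPair:
    manual_index: int
    auto_index: int
    start_offset: float
    stop_offset: float
    duration_offset: float


@dataclass
class MatchReport:
    """Outcome of matching one automated stream against one manual stream."""

    manual: list[Interval]
    auto: list[Interval]
    manual_detected: list[bool]
    manual_multiplicity: list[int]  # automated probes overlapping each manual probe
    auto_matched: list[bool]
    auto_manual_count: list[int]  # manual probes overlapping each automated probe
    pairs: list[MatchedPair] = field(default_factory=list)

    @property
    def n_manual(self) -> int:
        return len(self.manual)

    @property
    def n_detected(self) -> int:
        return sum(self.manual_detected)

    @property
    def n_false_positive(self) -> int:
        return sum(not m for m in self.auto_matched)

    @property
    def n_overrated(self) -> int:
        """Manual probes split into several automated probes."""
        return sum(m >= 2 for m in self.manual_multiplicity)

    @property
    def n_redundant(self) -> int:
        """Surplus automated probes beyond one per overrated manual probe."""
        return sum(m - 1 for m in self.manual_multiplicity if m >= 2)

    @property
    def n_underrated(self) -> int:
        """Manual probes sharing their automated probe with another one."""
        return sum(c - 1 for c in self.auto_manual_count if c >= 2)


def _probes_only(events: list[Interval]) -> list[Interval]:
    evs = [e for e in events if e.label == "probe"] or list(events)
    return sorted(evs, key=lambda e: e.start)


def match_events(auto: list[Interval], manual: list[Interval]) -> MatchReport:
    """Match automated probes to manual reference probes by temporal overlap."""
    autos = _probes_only(auto)
    manuals = _probes_only(manual)
    overlap = np.zeros((len(manuals), len(autos)))
    for i, m in enumerate(manuals):
        for j, a in enumerate(autos):
            overlap[i, j] = m.overlap(a)
    hits = overlap > 0
    multiplicity = hits.sum(axis=1).astype(int)
    auto_counts = hits.sum(axis=0).astype(int)
    pairs: list[MatchedPair] = []
    for i, m in enumerate(manuals):
        js = np.flatnonzero(hits[i])
        if js.size == 0:
            continue
        # most similar duration; ties broken by earlier start
        key = [(abs(autos[j].duration - m.duration), autos[j].start) for j in js]
        j = int(js[int(np.lexsort(([k[1] for k in key], [k[0] for k in key]))[0])])
        a = autos[j]
        pairs.append(
            MatchedPair(
                manual_index=i,
                auto_index=j,
                start_offset=a.start - m.start,
                stop_offset=a.stop - m.stop,
                duration_offset=a.duration - m.duration,
            )
        )
    return MatchReport(
        manual=manuals,
        auto=autos,
        manual_detected=[bool(m) for m in multiplicity > 0],
        manual_multiplicity=list(multiplicity),
        auto_matched=[bool(c) for c in auto_counts > 0],
        auto_manual_count=list(auto_counts),
        pairs=pairs,
    )


def _t_ci(values: np.ndarray, level: float = 0.95) -> tuple[float, float, float]:
    """Mean and t-based confidence interval (half-width 0 for n<2 or sd=0)."""
    values = np.asarray(values, dtype=float)
    mean = float(np.mean(values))
    if len(values) < 2 or np.std(values, ddof=1) == 0:
        return mean, mean, mean
    half = stats.t.ppf(0.5 + level / 2, len(values) - 1) * stats.sem(values)
    return mean, mean - half, mean + half


def accuracy_summary(reports: list[MatchReport]) -> dict:
    """Aggregate detection percentages, error classes, and offset CIs."""
    if not reports:
        raise ValueError("at least one match report required")
    n_manual = sum(r.n_manual for r in reports)
    n_detected = sum(r.n_detected for r in reports)
    offsets = {
        name: np.array(
            [getattr(p, name) for r in reports for p in r.pairs], dtype=float
        )
        for name in ("start_offset", "stop_offset", "duration_offset")
    }
    out: dict = {
        "n_manual": n_manual,
        "n_detected": n_detected,
        "pct_detected": 100.0 * n_detected / n_manual if n_manual else float("nan"),
        "n_undetected": n_manual - n_detected,
        "n_false_positive": sum(r.n_false_positive for r in reports),
        "n_overrated": sum(r.n_overrated for r in reports),
        "n_redundant": sum(r.n_redundant for r in reports),
        "n_underrated": sum(r.n_underrated for r in reports),
    }
    for name, vals in offsets.items():
        if vals.size:
            mean, lo, hi = _t_ci(vals)
            out[f"{name}_mean"], out[f"{name}_ci95"] = mean, (lo, hi)
    # mean probe duration per class
    durs = {
        "detected": [
            m.duration
            for r in reports
            for m, d in zip(r.manual, r.manual_detected)
            if d
        ],
        "undetected": [
            m.duration
            for r in reports
            for m, d in zip(r.manual, r.manual_detected)
            if not d
        ],
        "false_positive": [
            a.duration
            for r in reports
            for a, m in zip(r.auto, r.auto_matched)
            if not m
        ],
    }
    for cls, vals in durs.items():
        out[f"mean_duration_{cls}_s"] = float(np.mean(vals)) if vals else None
    return out


def correlate_summaries(
    auto: pd.DataFrame,
    manual: pd.DataFrame,
    variable_pairs: list[tuple[str, str]] | None = None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Correlate automated and manual per-observation summaries.

    For each variable pair a Shapiro normality check selects the test:
    Pearson (``Pe``) on raw data, Pearson on log-transformed data (``Pl``)
    when only the logs look normal, otherwise Spearman (``S``).  Degenerate
    (constant) vectors are flagged rather than tested.
    """
    if variable_pairs is None:
        common = [c for c in auto.columns if c in manual.columns]
        variable_pairs = [(c, c) for c in common]
    rows = []
    for va, vm in variable_pairs:
        x = pd.to_numeric(auto[va], errors="coerce")
        y = pd.to_numeric(manual[vm], errors="coerce")
        ok = x.notna() & y.notna()
        x, y = x[ok].to_numpy(), y[ok].to_numpy()
        if len(x) < 3:
            raise ValueError(f"fewer than 3 paired observations for {va}/{vm}")
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            rows.append(
                dict(auto=va, manual=vm, test="degenerate", r2=np.nan, p=np.nan, n=len(x))
            )
            continue

        def _normal(v: np.ndarray) -> bool:
            return bool(stats.shapiro(v).pvalue > normality_alpha)

        if _normal(x) and _normal(y):
            r, p = stats.pearsonr(x, y)
            test = "Pe"
        elif (x > 0).all() and (y > 0).all() and _normal(np.log(x)) and _normal(np.log(y)):
            r, p = stats.pearsonr(np.log(x), np.log(y))
            test = "Pl"
        else:
            r, p = stats.spearmanr(x, y)
            test = "S"
        rows.append(dict(auto=va, manual=vm, test=test, r2=r**2, p=p, n=len(x)))
    return pd.DataFrame(rows)
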