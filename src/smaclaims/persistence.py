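"""Discontinuation detection and a from-scratch Kaplan-Meier estimator.

Discontinuation fires when no refill appears within the allowable gap
(default 30 days) after the previous days of supply are exhausted, or at a
switch to another disease-modifying therapy, whichever comes first.  A gap
of exactly ``gap_days`` is allowable; the event requires a gap of at least
``gap_days + 1`` uncovered days, and the event is dated at the supply
exhaustion day.  Patients with neither event inside the study window are
censored at the window end.

Time origin is the index date; times are in days.
"""

from __future__ import annotations

import datetime as dt
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .claims import PharmacyClaim
from .cohort import StudyWindow

REASONS = ("gap", "switch_nusinersen", "switch_onasemnogene", "censored")


@dataclass(frozen=True)
class PersistenceRecord:
    patient_id: str
    time_days: int
    event: bool
    reason: str

    def __post_init__(self) -> None:
        if self.time_days < 0:
            raise ValueError("negative persistence time")
        if self.reason not in REASONS:
            raise ValueError(f"unknown reason {self.reason!r}")
        if self.event == (self.reason == "censored"):
            raise ValueError("event flag inconsistent with reason")


@dataclass(frozen=True)
class KMPoint:
    time: float
    n_risk: int
    n_event: int
    n_censor: int
    survival: float


@dataclass(frozen=True)
class KMCurve:
    points: tuple[KMPoint, ...]

    def survival_at(self, t: float) -> float:
        s = 1.0
        for p in self.points:
            if p.time <= t:
                s = p.survival
            else:
                break
        return s

    def median(self) -> float | None:
        """Smallest time with S(t) ≤ 0.5, or None ("not reached")."""
        for p in self.points:
            if p.survival <= 0.5:
                return p.time
        return None


def _stack_intervals(fills: Sequence[PharmacyClaim]) -> list[tuple[dt.date, dt.date]]:
    intervals: list[tuple[dt.date, dt.date]] = []
    prev_end: dt.date | None = None
    for f in sorted(fills, key=lambda f: f.fill_date):
        start = f.fill_date
        if prev_end is not None and start <= prev_end:
            start = prev_end + dt.timedelta(days=1)
        end = start + dt.timedelta(days=f.days_supply - 1)
        intervals.append((start, end))
        prev_end = end
    return intervals


def detect_discontinuation(fills: Iterable[PharmacyClaim],
                           switch_events: Mapping[str, dt.date] | None,
                           window: StudyWindow,
                           gap_days: int = 30,
                           drug: str = "risdiplam") -> PersistenceRecord:
    """First gap- or switch-discontinuation inside the window, else censoring.

    ``switch_events`` maps reason ("switch_nusinersen"/"switch_onasemnogene")
    to the earliest qualifying post-index event date.  A switch while supply
    remains on hand still discontinues at the switch date.
    """
    usable = [f for f in fills
              if f.drug == drug
              and window.index_date <= f.fill_date <= window.end_date]
    intervals = _stack_intervals(usable)

    gap_date: dt.date | None = None
    if not intervals:
        # no observable supply: exhausted at index
        if (window.end_date - window.index_date).days > gap_days:
            gap_date = window.index_date
    else:
        # compare each fill's dispensing date against the effective
        # exhaustion of the supply chain before it
        for i in range(len(usable) - 1):
            exhaust = intervals[i][1]
            next_fill = usable[i + 1].fill_date
            if (next_fill - exhaust).days > gap_days and exhaust <= window.end_date:
                gap_date = exhaust
                break
        if gap_date is None:
            last_exhaust = intervals[-1][1]
            if last_exhaust < window.end_date and \
                    (window.end_date - last_exhaust).days > gap_days:
                gap_date = last_exhaust

    switch_date: dt.date | None = None
    switch_reason: str | None = None
    for reason, date in sorted((switch_events or {}).items()):
        if date is None:
            continue
        if window.index_date < date <= window.end_date:
            if switch_date is None or date < switch_date:
                switch_date, switch_reason = date, reason

    candidates: list[tuple[dt.date, str]] = []
    if switch_date is not None and switch_reason is not None:
        candidates.append((switch_date, switch_reason))
    if gap_date is not None:
        candidates.append((gap_date, "gap"))

    if candidates:
        # earlier date wins; on a tie the switch reason takes precedence
        # (switching is sufficient regardless of remaining supply)
        date, reason = min(candidates, key=lambda c: (c[0], c[1] == "gap"))
        return PersistenceRecord(patient_id=window.patient_id,
                                 time_days=(date - window.index_date).days,
                                 event=True, reason=reason)
    return PersistenceRecord(patient_id=window.patient_id,
                             time_days=window.n_days,
                             event=False, reason="censored")


def km_estimate(records: Sequence[PersistenceRecord]) -> KMCurve:
    """Product-limit estimate; censorings at t leave the risk set after events at t."""
    if not records:
        raise ValueError("no records")
    events = Counter(r.time_days for r in records if r.event)
    censors = Counter(r.time_days for r in records if not r.event)
    n = len(records)
    s = 1.0
    points = []
    for t in sorted(set(events) | set(censors)):
        d = events.get(t, 0)
        c = censors.get(t, 0)
        if d:
            s *= 1.0 - d / n
        points.append(KMPoint(time=float(t), n_risk=n, n_event=d,
                              n_censor=c, survival=s))
        n -= d + c
    return KMCurve(points=tuple(points))


def summarize_persistence(records: Sequence[PersistenceRecord],
                          by: Mapping[str, str] | None = None,
                          ) -> list[dict]:
    """Per-stratum n, events, discontinuation %, and KM median (or "NR")."""
    strata: dict[str, list[PersistenceRecord]] = {}
    for r in records:
        label = by.get(r.patient_id, "overall") if by is not None else "overall"
        strata.setdefault(label, []).append(r)
    rows = []
    for label in sorted(strata):
        recs = strata[label]
        n_events = sum(r.event for r in recs)
        median = km_estimate(recs).median()
        rows.append({
            "stratum": label,
            "n": len(recs),
            "n_events": n_events,
            "pct_discontinued": 100.0 * n_events / len(recs),
            "median_days": median if median is not None else "NR",
        })
    return rows
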