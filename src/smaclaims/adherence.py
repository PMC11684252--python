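"""Coverage calendars and proportion-of-days-covered (PDC) adherence.

Stacking is carry-forward by default: a refill dispensed while supply
remains on hand starts the day after the previous supply is exhausted, so
oversupply is banked.  Banked supply never extends past the study-window
end — truncation is applied after stacking.  A non-carry-forward variant
(each fill covers its own calendar interval, overlap days counted once) is
available for sensitivity analysis via ``carry_forward=False``.

The PDC denominator is the full study-window length in days, inclusive of
the index day.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .claims import PharmacyClaim
from .cohort import StudyWindow

logger = logging.getLogger(__name__)

PDC_THRESHOLD = 0.80
BAND_EDGES = (0.80, 0.90)
BANDS = ("lt_080", "band_080_090", "band_090_100")

#: age bins as (lo, hi) completed years, hi=None meaning unbounded
AGE_BINS_METHODS: tuple[tuple[int, int | None], ...] = ((0, 2), (3, 5), (6, 17), (18, None))
AGE_BINS_RESULTS: tuple[tuple[int, int | None], ...] = ((0, 2), (3, 5), (6, 12), (13, 17), (18, None))


@dataclass(frozen=True)
class CoverageCalendar:
    patient_id: str
    window: StudyWindow
    covered_days: int
    intervals: tuple[tuple[dt.date, dt.date], ...]

    def __post_init__(self) -> None:
        if not 0 <= self.covered_days <= self.window.n_days:
            raise ValueError("covered_days outside [0, window length]")


@dataclass(frozen=True)
class AdherenceResult:
    patient_id: str
    pdc: float
    adherent: bool
    band: str
    age_group: str


def build_coverage(fills: Iterable[PharmacyClaim], window: StudyWindow,
                   carry_forward: bool = True,
                   drug: str = "risdiplam") -> CoverageCalendar:
    """Stack fills into effective supply intervals and count covered days."""
    usable = []
    for f in sorted((f for f in fills if f.drug == drug), key=lambda f: f.fill_date):
        if f.fill_date < window.index_date or f.fill_date > window.end_date:
            logger.warning("ignoring fill on %s outside window [%s, %s] for %s",
                           f.fill_date, window.index_date, window.end_date, f.patient_id)
            continue
        usable.append(f)

    if carry_forward:
        intervals: list[tuple[dt.date, dt.date]] = []
        prev_end: dt.date | None = None
        for f in usable:
            start = f.fill_date
            if prev_end is not None and start <= prev_end:
                start = prev_end + dt.timedelta(days=1)
            end = start + dt.timedelta(days=f.days_supply - 1)
            intervals.append((start, end))
            prev_end = end
    else:
        raw = [(f.fill_date, f.fill_date + dt.timedelta(days=f.days_supply - 1))
               for f in usable]
        intervals = []
        for start, end in sorted(raw):
            if intervals and start <= intervals[-1][1] + dt.timedelta(days=1):
                if end > intervals[-1][1]:
                    intervals[-1] = (intervals[-1][0], end)
            else:
                intervals.append((start, end))

    truncated = []
    for start, end in intervals:
        start = max(start, window.index_date)
        end = min(end, window.end_date)
        if start <= end:
            truncated.append((start, end))

    covered = sum((end - start).days + 1 for start, end in truncated)
    return CoverageCalendar(patient_id=window.patient_id, window=window,
                            covered_days=covered, intervals=tuple(truncated))


def compute_pdc(calendar: CoverageCalendar) -> float:
    """covered days / window length (window inclusive of the index day)."""
    return calendar.covered_days / calendar.window.n_days


def classify_adherence(pdc: float,
                       threshold: float = PDC_THRESHOLD,
                       band_edges: tuple[float, float] = BAND_EDGES,
                       ) -> tuple[bool, str]:
    """Dichotomize at the threshold and assign the PDC band.

    Bands partition [0, 1]: [0, lo), [lo, hi), [hi, 1].
    """
    if not 0.0 <= pdc <= 1.0:
        raise ValueError(f"PDC {pdc} outside [0, 1]")
    lo, hi = band_edges
    if pdc < lo:
        band = BANDS[0]
    elif pdc < hi:
        band = BANDS[1]
    else:
        band = BANDS[2]
    return pdc >= threshold, band


def age_in_years(birth_date: dt.date, on_date: dt.date) -> int:
    """Completed years of age on a date."""
    years = on_date.year - birth_date.year
    if (on_date.month, on_date.day) < (birth_date.month, birth_date.day):
        years -= 1
    return years


def format_age_group(lo: int, hi: int | None) -> str:
    return f"{lo}-{hi}" if hi is not None else f"{lo}+"


def assign_age_group(birth_date: dt.date, index_date: dt.date,
                     bins: Sequence[tuple[int, int | None]] = AGE_BINS_RESULTS,
                     ) -> str:
    if birth_date > index_date:
        raise ValueError("birth date after index date")
    age = age_in_years(birth_date, index_date)
    for lo, hi in bins:
        if age >= lo and (hi is None or age <= hi):
            return format_age_group(lo, hi)
    raise ValueError(f"age {age} not covered by bins {bins}")


def compute_adherence(bundle, windows: Sequence[StudyWindow],
                      carry_forward: bool = True,
                      bins: Sequence[tuple[int, int | None]] = AGE_BINS_RESULTS,
                      ) -> list[AdherenceResult]:
    """Per-patient PDC, adherence flag, band, and age group for a cohort."""
    results = []
    for w in windows:
        cal = build_coverage(bundle.pharmacy_for(w.patient_id), w,
                             carry_forward=carry_forward)
        pdc = compute_pdc(cal)
        adherent, band = classify_adherence(pdc)
        demo = bundle.demographics_for(w.patient_id)
        results.append(AdherenceResult(
            patient_id=w.patient_id, pdc=pdc, adherent=adherent, band=band,
            age_group=assign_age_group(demo.birth_date, w.index_date, bins)))
    return results
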