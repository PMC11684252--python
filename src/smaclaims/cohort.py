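"""Cohort selection: inclusion criteria, index-date assignment, study windows.

Selection order:

1. at least one qualifying SMA diagnosis code (G12.0/G12.1/G12.9, on any
   claim inside the data window, pre- or post-index);
2. an assignable index date — the earliest qualifying drug fill on or after
   the approval date;
3. continuous enrollment for the post-index window;
4. continuous enrollment for the pre-index window, required only for the
   configured disease types (2–4 by default), so typing runs before this step.

"6 months" and "3 months" are interpreted as 183 and 92 days (configurable;
month length is otherwise ambiguous).  The follow-up cap is 365 days after
index and the window is inclusive of the index day, so the maximum window
length is 366 days.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .claims import ClaimsBundle, EnrollmentSpan, PharmacyClaim, normalize_spans

APPROVAL_DATE = dt.date(2020, 8, 7)
DATA_START = dt.date(2020, 1, 1)
DATA_END = dt.date(2022, 6, 30)
SMA_DX_CODES = frozenset({"G12.0", "G12.1", "G12.9"})

END_REASONS = ("enrollment_end", "data_end", "one_year_cap")


@dataclass(frozen=True)
class StudyWindow:
    patient_id: str
    index_date: dt.date
    end_date: dt.date
    end_reason: str

    def __post_init__(self) -> None:
        if self.index_date > self.end_date:
            raise ValueError("index_date after end_date")
        if self.end_reason not in END_REASONS:
            raise ValueError(f"unknown end_reason {self.end_reason!r}")

    @property
    def n_days(self) -> int:
        """Window length in days, inclusive of the index day."""
        return (self.end_date - self.index_date).days + 1


@dataclass
class SelectionLog:
    """Ordered (criterion label, n remaining) pairs; counts are non-increasing."""

    steps: list[tuple[str, int]] = field(default_factory=list)

    def record(self, label: str, n: int) -> None:
        if self.steps and n > self.steps[-1][1]:
            raise ValueError("selection counts must be non-increasing")
        self.steps.append((label, n))


@dataclass(frozen=True)
class CohortConfig:
    approval_date: dt.date = APPROVAL_DATE
    data_start: dt.date = DATA_START
    data_end: dt.date = DATA_END
    post_index_days: int = 183      # "≥ 6 months" after index
    pre_index_days: int = 92        # "≥ 3 months" before index
    pre_index_required_types: tuple[int, ...] = (2, 3, 4)
    allowable_gap_days: int = 0     # enrollment continuity tolerance
    followup_cap_days: int = 365
    sma_dx_codes: frozenset[str] = SMA_DX_CODES


def assign_index_date(fills: Iterable[PharmacyClaim],
                      approval_date: dt.date = APPROVAL_DATE,
                      drug: str = "risdiplam") -> dt.date | None:
    """Earliest qualifying fill on/after the approval date, else None."""
    dates = [f.fill_date for f in fills
             if f.drug == drug and f.fill_date >= approval_date]
    return min(dates) if dates else None


def check_enrollment(spans: Sequence[EnrollmentSpan],
                     index_date: dt.date,
                     pre_days: int = 0,
                     post_days: int = 183,
                     allowable_gap_days: int = 0) -> bool:
    """True iff enrollment covers [index − pre_days, index + post_days].

    Internal gaps of at most ``allowable_gap_days`` uncovered days are
    tolerated; the window edges themselves must be covered.
    """
    lo = index_date - dt.timedelta(days=pre_days)
    hi = index_date + dt.timedelta(days=post_days)
    merged = normalize_spans(spans, merge_gap_days=allowable_gap_days)
    return any(s.start_date <= lo and s.end_date >= hi for s in merged)


def _enrollment_end(spans: Sequence[EnrollmentSpan], index_date: dt.date,
                    allowable_gap_days: int) -> dt.date:
    merged = normalize_spans(spans, merge_gap_days=allowable_gap_days)
    for s in merged:
        if s.start_date <= index_date <= s.end_date:
            return s.end_date
    raise ValueError("index date not inside any enrollment span")


def compute_study_window(index_date: dt.date,
                         spans: Sequence[EnrollmentSpan],
                         data_end: dt.date = DATA_END,
                         followup_cap_days: int = 365,
                         allowable_gap_days: int = 0) -> StudyWindow:
    """Window end = min(enrollment end, data end, index + cap).

    Ties are attributed in the order one_year_cap > data_end > enrollment_end.
    """
    enrl_end = _enrollment_end(spans, index_date, allowable_gap_days)
    cap_end = index_date + dt.timedelta(days=followup_cap_days)
    end = min(enrl_end, data_end, cap_end)
    if end == cap_end:
        reason = "one_year_cap"
    elif end == data_end:
        reason = "data_end"
    else:
        reason = "enrollment_end"
    pid = spans[0].patient_id if spans else ""
    return StudyWindow(patient_id=pid, index_date=index_date,
                       end_date=end, end_reason=reason)


def select_cohort(bundle: ClaimsBundle,
                  config: CohortConfig | None = None,
                  ) -> tuple[list[StudyWindow], SelectionLog]:
    """Apply the inclusion criteria in order; return windows plus the funnel log."""
    from .sma_types import TypingRuleTable, classify_patient

    config = config or CohortConfig()
    log = SelectionLog()
    all_ids = bundle.patient_ids()
    log.record("initial", len(all_ids))

    # 1. ≥1 qualifying SMA diagnosis within the data window
    with_dx = []
    for pid in all_ids:
        claims = bundle.medical_for(pid)
        if any(config.data_start <= c.service_date <= config.data_end
               and set(c.dx_codes) & config.sma_dx_codes for c in claims):
            with_dx.append(pid)
    log.record("sma_diagnosis", len(with_dx))

    # 2. index date assignable
    indexed: dict[str, dt.date] = {}
    for pid in with_dx:
        idx = assign_index_date(bundle.pharmacy_for(pid), config.approval_date)
        if idx is not None:
            indexed[pid] = idx
    log.record("index_assignable", len(indexed))

    # 3. post-index continuous enrollment
    post_ok: dict[str, dt.date] = {}
    for pid, idx in indexed.items():
        if check_enrollment(bundle.spans_for(pid), idx,
                            pre_days=0, post_days=config.post_index_days,
                            allowable_gap_days=config.allowable_gap_days):
            post_ok[pid] = idx
    log.record("post_index_enrollment", len(post_ok))

    # 4. pre-index continuous enrollment, only for configured types
    rules = TypingRuleTable.default()
    selected: dict[str, dt.date] = {}
    for pid, idx in post_ok.items():
        typed = classify_patient(bundle, pid, rules, data_end=config.data_end)
        if typed.sma_type in config.pre_index_required_types:
            if not check_enrollment(bundle.spans_for(pid), idx,
                                    pre_days=config.pre_index_days, post_days=0,
                                    allowable_gap_days=config.allowable_gap_days):
                continue
        selected[pid] = idx
    log.record("pre_index_enrollment", len(selected))

    windows = [
        compute_study_window(idx, bundle.spans_for(pid),
                             data_end=config.data_end,
                             followup_cap_days=config.followup_cap_days,
                             allowable_gap_days=config.allowable_gap_days)
        for pid, idx in sorted(selected.items())
    ]
    return windows, log
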