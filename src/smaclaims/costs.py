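"""Cost categorization, inflation, per-patient-per-year annualization, summaries.

Category layout per patient:

* setting buckets: ``inpatient``, ``outpatient``, ``ed``, ``other_medical``
  — these sum to ``medical_total``;
* overlay subcategories ``mechanical_ventilation`` and ``nutritional_support``
  — contained within the setting buckets (reported "as part of" medical
  costs), so excluded from the conservation identity;
* ``pharmacy``; and ``total = medical_total + pharmacy``.

Disease-modifying-therapy costs never enter any category: claims flagged
``dmt_nusinersen``/``dmt_onasemnogene`` and qualifying drug fills (risdiplam)
contribute zero everywhere.

Amounts are inflated claim-by-claim to the reference year using a
year-indexed price index (Personal Consumption Expenditures Health Index by
default; the packaged snapshot is a stand-in).  PPPY divides by follow-up
years = window days / 365.25.  The outlier exclusion removes patients whose
(inflated, pre-annualization) total exceeds a threshold, $4,000,000 by
default.

Summary statistics: mean, sample SD (n−1), median, and quartiles with
linear interpolation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .claims import ClaimsBundle
from .cohort import StudyWindow

DAYS_PER_YEAR = 365.25
OUTLIER_THRESHOLD = 4_000_000.0

SETTING_TO_CATEGORY = {
    "inpatient": "inpatient",
    "outpatient": "outpatient",
    "emergency": "ed",
    "other": "other_medical",
}

SETTING_CATEGORIES = ("inpatient", "outpatient", "ed", "other_medical")
OVERLAY_CATEGORIES = ("mechanical_ventilation", "nutritional_support")
CATEGORIES = ("total", "medical_total") + SETTING_CATEGORIES + OVERLAY_CATEGORIES + ("pharmacy",)


@dataclass(frozen=True)
class InflationIndex:
    values: Mapping[int, float]
    reference_year: int = 2023

    def __post_init__(self) -> None:
        if self.reference_year not in self.values:
            raise ValueError(f"reference year {self.reference_year} missing from index")
        if any(v <= 0 for v in self.values.values()):
            raise ValueError("index values must be positive")

    @classmethod
    def from_csv(cls, path: str | Path, reference_year: int = 2023) -> "InflationIndex":
        with open(path, newline="", encoding="utf-8") as fh:
            rows = list(csv.DictReader(fh))
        return cls({int(r["year"]): float(r["value"]) for r in rows}, reference_year)

    @classmethod
    def default(cls) -> "InflationIndex":
        from importlib.resources import files

        text = files("smaclaims.data").joinpath("pce_health_index.csv").read_text()
        rows = list(csv.DictReader(text.splitlines()))
        return cls({int(r["year"]): float(r["value"]) for r in rows})

    @classmethod
    def identity(cls, years=range(2019, 2024), reference_year: int = 2023) -> "InflationIndex":
        return cls({y: 1.0 for y in years}, reference_year)


def inflate(amount: float, service_year: int, index: InflationIndex) -> float:
    """amount × index[reference_year] / index[service_year]."""
    if service_year not in index.values:
        raise KeyError(f"inflation index has no value for year {service_year}")
    return amount * index.values[index.reference_year] / index.values[service_year]


@dataclass(frozen=True)
class PatientCosts:
    patient_id: str
    follow_up_years: float
    raw: Mapping[str, float]     # inflated totals, pre-annualization
    pppy: Mapping[str, float]


def categorize_costs(bundle: ClaimsBundle, window: StudyWindow,
                     patient_id: str,
                     index: InflationIndex | None = None,
                     excluded_drugs: frozenset[str] = frozenset({"risdiplam"}),
                     ) -> dict[str, float]:
    """Per-category (inflated) cost totals over [index, window end].

    With ``index=None`` amounts pass through uninflated.
    """
    def _adj(amount: float, year: int) -> float:
        return amount if index is None else inflate(amount, year, index)

    totals = {c: 0.0 for c in CATEGORIES}
    for claim in bundle.medical_for(patient_id):
        if not window.index_date <= claim.service_date <= window.end_date:
            continue
        if claim.is_dmt:
            continue
        amount = _adj(claim.allowed_cost, claim.service_date.year)
        totals[SETTING_TO_CATEGORY[claim.setting]] += amount
        for overlay in OVERLAY_CATEGORIES:
            if overlay in claim.flags:
                totals[overlay] += amount
    for fill in bundle.pharmacy_for(patient_id):
        if not window.index_date <= fill.fill_date <= window.end_date:
            continue
        if fill.drug in excluded_drugs:
            continue
        totals["pharmacy"] += _adj(fill.allowed_cost, fill.fill_date.year)

    totals["medical_total"] = sum(totals[c] for c in SETTING_CATEGORIES)
    totals["total"] = totals["medical_total"] + totals["pharmacy"]
    return totals


def annualize_pppy(raw_total: float, window: StudyWindow) -> float:
    """raw total / (window days / 365.25)."""
    return raw_total / (window.n_days / DAYS_PER_YEAR)


def compute_patient_costs(bundle: ClaimsBundle, window: StudyWindow,
                          index: InflationIndex | None = None) -> PatientCosts:
    raw = categorize_costs(bundle, window, window.patient_id, index=index)
    years = window.n_days / DAYS_PER_YEAR
    return PatientCosts(
        patient_id=window.patient_id,
        follow_up_years=years,
        raw=raw,
        pppy={c: v / years for c, v in raw.items()},
    )


def apply_outlier_exclusion(patients: Sequence[PatientCosts],
                            threshold: float = OUTLIER_THRESHOLD,
                            ) -> tuple[list[PatientCosts], list[PatientCosts]]:
    """Split patients at the raw-total threshold (kept, excluded)."""
    kept = [p for p in patients if p.raw["total"] <= threshold]
    excluded = [p for p in patients if p.raw["total"] > threshold]
    return kept, excluded


@dataclass(frozen=True)
class CategoryStats:
    n: int
    mean: float | None
    sd: float | None
    median: float | None
    q1: float | None
    q3: float | None


@dataclass(frozen=True)
class CostSummary:
    stratum: str
    n: int
    stats: Mapping[str, CategoryStats]


def _describe(values: Sequence[float]) -> CategoryStats:
    n = len(values)
    if n == 0:
        return CategoryStats(n=0, mean=None, sd=None, median=None, q1=None, q3=None)
    arr = np.asarray(values, dtype=float)
    sd = float(np.std(arr, ddof=1)) if n > 1 else None
    q1, med, q3 = (float(q) for q in np.percentile(arr, [25, 50, 75]))
    return CategoryStats(n=n, mean=float(arr.mean()), sd=sd, median=med, q1=q1, q3=q3)


def summarize_costs(patients: Sequence[PatientCosts],
                    strata: Mapping[str, str],
                    categories: Sequence[str] = CATEGORIES,
                    ) -> list[CostSummary]:
    """Descriptive PPPY statistics per stratum; every patient in exactly one."""
    groups: dict[str, list[PatientCosts]] = {}
    for p in patients:
        groups.setdefault(strata[p.patient_id], []).append(p)
    summaries = []
    for label in sorted(groups):
        members = groups[label]
        stats = {c: _describe([m.pppy[c] for m in members]) for c in categories}
        summaries.append(CostSummary(stratum=label, n=len(members), stats=stats))
    return summaries
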