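"""Claims-based disease-type classification via an ordered, editable rule table.

The engine — first matching rule by (age at first diagnosis, minimum age at
end of observed clinical activity, marker requirements/exclusions) — is the
contract here.  The shipped default table is an explicitly NON-authoritative
stand-in: age-at-first-diagnosis bands 0–<1 yr → type 1, 1–<3 yr → type 2,
3–<18 yr → type 3, ≥18 yr → type 4, refined by support markers (ventilation
plus nutritional support escalate severity; long survival without supports
de-escalates).  Supply your own table for a validated algorithm.

Ages are exact day differences divided by 365.25.
"""

from __future__ import annotations

import csv
import datetime as dt
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .claims import ClaimsBundle, MARKER_FLAGS

DAYS_PER_YEAR = 365.25

UNCLASSIFIED = "unclassified"

#: diagnosis-code prefixes that contribute severity markers
DEFAULT_DX_MARKER_PREFIXES: dict[str, str] = {"M41": "scoliosis"}

SMA_DX_PREFIX = "G12"


@dataclass(frozen=True)
class TypingRule:
    rule_id: str
    priority: int
    target_type: int
    age_dx_lo: float
    age_dx_hi: float          # half-open [lo, hi); math.inf for unbounded
    age_end_min: float | None
    require_markers: frozenset[str]
    exclude_markers: frozenset[str]

    def matches(self, features: "TypingFeatures") -> bool:
        if not (self.age_dx_lo <= features.age_at_first_dx < self.age_dx_hi):
            return False
        if self.age_end_min is not None and features.age_at_end < self.age_end_min:
            return False
        if not self.require_markers <= features.markers:
            return False
        if self.exclude_markers & features.markers:
            return False
        return True


@dataclass(frozen=True)
class TypingFeatures:
    patient_id: str
    age_at_first_dx: float
    age_at_end: float
    markers: frozenset[str]


@dataclass(frozen=True)
class TypedPatient:
    patient_id: str
    sma_type: int | str       # 1..4, or UNCLASSIFIED
    rule_id: str | None
    evidence: frozenset[str]


class TypingRuleTable:
    """Priority-ordered rules; classification takes the first match."""

    def __init__(self, rules: Iterable[TypingRule]):
        self.rules = sorted(rules, key=lambda r: r.priority)
        if not self.rules:
            raise ValueError("rule table is empty")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TypingRuleTable":
        with open(path, newline="", encoding="utf-8") as fh:
            return cls._from_rows(csv.DictReader(fh))

    @classmethod
    def default(cls) -> "TypingRuleTable":
        from importlib.resources import files

        text = files("smaclaims.data").joinpath("default_typing_rules.csv").read_text()
        return cls._from_rows(csv.DictReader(text.splitlines()))

    @classmethod
    def _from_rows(cls, rows: Iterable[Mapping[str, str]]) -> "TypingRuleTable":
        rules = []
        for row in rows:
            rules.append(TypingRule(
                rule_id=row["rule_id"],
                priority=int(row["priority"]),
                target_type=int(row["type"]),
                age_dx_lo=float(row["age_dx_lo"]),
                age_dx_hi=math.inf if row["age_dx_hi"] in ("", "inf") else float(row["age_dx_hi"]),
                age_end_min=float(row["age_end_min"]) if row["age_end_min"] else None,
                require_markers=frozenset(m for m in row["require_markers"].split(";") if m),
                exclude_markers=frozenset(m for m in row["exclude_markers"].split(";") if m),
            ))
        return cls(rules)


def extract_typing_features(bundle: ClaimsBundle, patient_id: str,
                            data_end: dt.date,
                            dx_marker_prefixes: Mapping[str, str] | None = None,
                            ) -> TypingFeatures:
    """Age at first SMA diagnosis, age at end of observed activity, markers.

    Age-at-end uses the later of the last observed claim and the enrollment
    end (capped at ``data_end``).  Markers are severity flags observed on any
    claim plus diagnosis-prefix-derived markers (scoliosis by default).
    """
    if dx_marker_prefixes is None:
        dx_marker_prefixes = DEFAULT_DX_MARKER_PREFIXES
    demo = bundle.demographics_for(patient_id)
    claims = bundle.medical_for(patient_id)

    dx_dates = [c.service_date for c in claims
                if any(code.startswith(SMA_DX_PREFIX) for code in c.dx_codes)]
    if not dx_dates:
        raise ValueError(f"patient {patient_id!r} has no SMA diagnosis claim")
    first_dx = min(dx_dates)

    last_dates = [c.service_date for c in claims]
    last_dates += [f.fill_date for f in bundle.pharmacy_for(patient_id)]
    last_dates += [min(s.end_date, data_end) for s in bundle.spans_for(patient_id)]
    end_date = max(last_dates)

    markers = set()
    for c in claims:
        markers |= c.flags & set(MARKER_FLAGS)
        for code in c.dx_codes:
            for prefix, marker in dx_marker_prefixes.items():
                if code.startswith(prefix):
                    markers.add(marker)

    return TypingFeatures(
        patient_id=patient_id,
        age_at_first_dx=(first_dx - demo.birth_date).days / DAYS_PER_YEAR,
        age_at_end=(end_date - demo.birth_date).days / DAYS_PER_YEAR,
        markers=frozenset(markers),
    )


def classify_sma_type(features: TypingFeatures,
                      rules: TypingRuleTable) -> TypedPatient:
    """First rule in priority order that matches determines the type."""
    for rule in rules.rules:
        if rule.matches(features):
            return TypedPatient(patient_id=features.patient_id,
                                sma_type=rule.target_type,
                                rule_id=rule.rule_id,
                                evidence=features.markers)
    return TypedPatient(patient_id=features.patient_id,
                        sma_type=UNCLASSIFIED, rule_id=None,
                        evidence=features.markers)


def classify_patient(bundle: ClaimsBundle, patient_id: str,
                     rules: TypingRuleTable, data_end: dt.date) -> TypedPatient:
    features = extract_typing_features(bundle, patient_id, data_end)
    return classify_sma_type(features, rules)
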