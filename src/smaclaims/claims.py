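"""Domain types and delimited-text I/O for administrative-claims bundles.

The interchange format is four comma-separated files with ISO-8601 dates:

* ``enrollment.csv``       — ``patient_id,start_date,end_date``
* ``medical_claims.csv``   — ``patient_id,service_date,dx_codes,proc_code,setting,allowed_cost,flags``
  (``dx_codes`` and ``flags`` are semicolon-joined)
* ``pharmacy_claims.csv``  — ``patient_id,fill_date,drug,days_supply,allowed_cost``
* ``demographics.csv``     — ``patient_id,birth_date,sex,region``

All dates are calendar dates at day granularity and all intervals are closed
on both ends (``[start, end]`` inclusive), matching days-of-supply semantics.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

SETTINGS = ("inpatient", "outpatient", "emergency", "other")

MARKER_FLAGS = ("mechanical_ventilation", "nutritional_support", "dme")
DMT_FLAGS = ("dmt_nusinersen", "dmt_onasemnogene")
FLAGS = MARKER_FLAGS + DMT_FLAGS

DRUGS = ("risdiplam", "other")
REGIONS = ("South", "Midwest", "West", "Northeast")

ENROLLMENT_COLUMNS = ("patient_id", "start_date", "end_date")
MEDICAL_COLUMNS = ("patient_id", "service_date", "dx_codes", "proc_code",
                   "setting", "allowed_cost", "flags")
PHARMACY_COLUMNS = ("patient_id", "fill_date", "drug", "days_supply", "allowed_cost")
DEMOGRAPHICS_COLUMNS = ("patient_id", "birth_date", "sex", "region")

FILE_NAMES = {
    "enrollment": "enrollment.csv",
    "medical": "medical_claims.csv",
    "pharmacy": "pharmacy_claims.csv",
    "demographics": "demographics.csv",
}


class SchemaError(ValueError):
    """A file does not conform to the documented column schema."""


class RowError(ValueError):
    """A data row failed to parse; carries the file and 1-based line number."""

    def __init__(self, file_name: str, line: int, message: str):
        super().__init__(f"{file_name}, line {line}: {message}")
        self.file_name = file_name
        self.line = line


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True, order=True)
class EnrollmentSpan:
    patient_id: str
    start_date: dt.date
    end_date: dt.date

    def __post_init__(self) -> None:
        if self.start_date > self.end_date:
            raise ValidationError(
                f"enrollment span for {self.patient_id!r}: start "
                f"{self.start_date} after end {self.end_date}"
            )

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


@dataclass(frozen=True)
class MedicalClaim:
    patient_id: str
    service_date: dt.date
    dx_codes: tuple[str, ...] = ()
    proc_code: str = ""
    setting: str = "outpatient"
    allowed_cost: float = 0.0
    flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValidationError(f"unknown setting {self.setting!r}")
        if self.allowed_cost < 0:
            raise ValidationError(
                f"negative allowed_cost {self.allowed_cost} for {self.patient_id!r}"
            )
        unknown = self.flags - set(FLAGS)
        if unknown:
            raise ValidationError(f"unknown flags {sorted(unknown)}")
        if len(self.flags & set(DMT_FLAGS)) > 1:
            raise ValidationError(
                f"claim for {self.patient_id!r} carries more than one DMT flag"
            )

    @property
    def is_dmt(self) -> bool:
        return bool(self.flags & set(DMT_FLAGS))


@dataclass(frozen=True)
class PharmacyClaim:
    patient_id: str
    fill_date: dt.date
    drug: str
    days_supply: int
    allowed_cost: float = 0.0

    def __post_init__(self) -> None:
        if self.drug not in DRUGS:
            raise ValidationError(f"unknown drug {self.drug!r}")
        if self.days_supply < 1:
            raise ValidationError(
                f"days_supply must be >= 1, got {self.days_supply} "
                f"for {self.patient_id!r}"
            )
        if self.allowed_cost < 0:
            raise ValidationError(
                f"negative allowed_cost {self.allowed_cost} for {self.patient_id!r}"
            )


@dataclass(frozen=True)
class Demographics:
    patient_id: str
    birth_date: dt.date
    sex: str
    region: str

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValidationError(f"unknown region {self.region!r}")


@dataclass
class ClaimsBundle:
    """The three raw claim tables plus demographics; the pipeline's sole input."""

    enrollment: list[EnrollmentSpan] = field(default_factory=list)
    medical: list[MedicalClaim] = field(default_factory=list)
    pharmacy: list[PharmacyClaim] = field(default_factory=list)
    demographics: list[Demographics] = field(default_factory=list)

    def validate(self) -> None:
        known = {d.patient_id for d in self.demographics}
        for table_name, table in (("enrollment", self.enrollment),
                                  ("medical", self.medical),
                                  ("pharmacy", self.pharmacy)):
            for rec in table:
                if rec.patient_id not in known:
                    raise ValidationError(
                        f"patient {rec.patient_id!r} in {table_name} table "
                        "has no demographics record"
                    )
        births = {d.patient_id: d.birth_date for d in self.demographics}
        for claim in self.medical:
            if claim.service_date < births[claim.patient_id]:
                raise ValidationError(
                    f"claim for {claim.patient_id!r} predates birth date"
                )
        for fill in self.pharmacy:
            if fill.fill_date < births[fill.patient_id]:
                raise ValidationError(
                    f"fill for {fill.patient_id!r} predates birth date"
                )

    def patient_ids(self) -> list[str]:
        return sorted(d.patient_id for d in self.demographics)

    def demographics_for(self, patient_id: str) -> Demographics:
        for d in self.demographics:
            if d.patient_id == patient_id:
                return d
        raise KeyError(patient_id)

    def spans_for(self, patient_id: str) -> list[EnrollmentSpan]:
        return sorted(s for s in self.enrollment if s.patient_id == patient_id)

    def medical_for(self, patient_id: str) -> list[MedicalClaim]:
        return sorted((c for c in self.medical if c.patient_id == patient_id),
                      key=lambda c: c.service_date)

    def pharmacy_for(self, patient_id: str, drug: str | None = None) -> list[PharmacyClaim]:
        fills = [f for f in self.pharmacy if f.patient_id == patient_id
                 and (drug is None or f.drug == drug)]
        return sorted(fills, key=lambda f: f.fill_date)


@dataclass(frozen=True)
class ReadConfig:
    """Options applied while reading a bundle.

    ``dedup_exact`` drops byte-identical duplicate claim rows (the source
    database's multi-feed duplicates have no documented dedup rule, so the
    switch is exposed; default on).  ``code_flag_map`` maps procedure codes
    to claim flags and is applied only when a medical claim's ``flags``
    column is empty.
    """

    dedup_exact: bool = True
    code_flag_map: Mapping[str, str] | None = None


def default_code_flag_map() -> dict[str, str]:
    """Procedure-code → flag mapping shipped with the package (stand-in values)."""
    from importlib.resources import files

    text = files("smaclaims.data").joinpath("dmt_code_map.csv").read_text()
    rows = list(csv.DictReader(text.splitlines()))
    return {r["code"]: r["flag"] for r in rows}


def normalize_spans(spans: Iterable[EnrollmentSpan],
                    merge_gap_days: int = 0) -> list[EnrollmentSpan]:
    """Sort and merge per-patient enrollment spans.

    Spans separated by at most ``merge_gap_days`` uncovered days (default 0,
    i.e. overlapping or day-adjacent) are coalesced.  Idempotent and
    order-independent.
    """
    by_patient: dict[str, list[EnrollmentSpan]] = {}
    for s in spans:
        by_patient.setdefault(s.patient_id, []).append(s)
    out: list[EnrollmentSpan] = []
    for pid in sorted(by_patient):
        merged: list[EnrollmentSpan] = []
        for s in sorted(by_patient[pid]):
            if merged and (s.start_date - merged[-1].end_date).days <= merge_gap_days + 1:
                if s.end_date > merged[-1].end_date:
                    merged[-1] = replace(merged[-1], end_date=s.end_date)
            else:
                merged.append(s)
        out.extend(merged)
    return out


def _parse_date(value: str, file_name: str, line: int, column: str) -> dt.date:
    try:
        return dt.date.fromisoformat(value)
    except ValueError:
        raise RowError(file_name, line, f"unparseable date {value!r} in column {column}") from None


def _parse_cost(value: str, file_name: str, line: int) -> float:
    try:
        cost = float(value) if value else 0.0
    except ValueError:
        raise RowError(file_name, line, f"unparseable allowed_cost {value!r}") from None
    if cost < 0:
        raise ValidationError(f"{file_name}, line {line}: negative allowed_cost {cost}")
    return cost


def _read_rows(path: Path, required: Sequence[str]) -> list[tuple[int, dict[str, str]]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{path.name}: empty file, expected header {','.join(required)}")
        for col in required:
            if col not in reader.fieldnames:
                raise SchemaError(f"{path.name}: missing column {col!r}")
        return [(reader.line_num, row) for row in reader]


def read_bundle(dir_path: str | Path,
                config: ReadConfig | None = None) -> ClaimsBundle:
    """Read and validate the four schema files from ``dir_path``.

    Enrollment spans are normalized (overlapping/adjacent spans merged);
    longer-gap merging is the cohort builder's concern.
    """
    config = config or ReadConfig()
    d = Path(dir_path)

    enrollment: list[EnrollmentSpan] = []
    fname = FILE_NAMES["enrollment"]
    for line, row in _read_rows(d / fname, ENROLLMENT_COLUMNS):
        enrollment.append(EnrollmentSpan(
            patient_id=row["patient_id"],
            start_date=_parse_date(row["start_date"], fname, line, "start_date"),
            end_date=_parse_date(row["end_date"], fname, line, "end_date"),
        ))

    medical: list[MedicalClaim] = []
    fname = FILE_NAMES["medical"]
    for line, row in _read_rows(d / fname, MEDICAL_COLUMNS):
        flags = frozenset(f for f in row["flags"].split(";") if f)
        if not flags and config.code_flag_map and row["proc_code"] in config.code_flag_map:
            flags = frozenset({config.code_flag_map[row["proc_code"]]})
        try:
            claim = MedicalClaim(
                patient_id=row["patient_id"],
                service_date=_parse_date(row["service_date"], fname, line, "service_date"),
                dx_codes=tuple(c for c in row["dx_codes"].split(";") if c),
                proc_code=row["proc_code"],
                setting=row["setting"],
                allowed_cost=_parse_cost(row["allowed_cost"], fname, line),
                flags=flags,
            )
        except ValidationError as exc:
            raise ValidationError(f"{fname}, line {line}: {exc}") from None
        medical.append(claim)

    pharmacy: list[PharmacyClaim] = []
    fname = FILE_NAMES["pharmacy"]
    for line, row in _read_rows(d / fname, PHARMACY_COLUMNS):
        try:
            days_supply = int(row["days_supply"])
        except ValueError:
            raise RowError(fname, line, f"unparseable days_supply {row['days_supply']!r}") from None
        try:
            fill = PharmacyClaim(
                patient_id=row["patient_id"],
                fill_date=_parse_date(row["fill_date"], fname, line, "fill_date"),
                drug=row["drug"],
                days_supply=days_supply,
                allowed_cost=_parse_cost(row["allowed_cost"], fname, line),
            )
        except ValidationError as exc:
            raise ValidationError(f"{fname}, line {line}: {exc}") from None
        pharmacy.append(fill)

    demographics: list[Demographics] = []
    fname = FILE_NAMES["demographics"]
    for line, row in _read_rows(d / fname, DEMOGRAPHICS_COLUMNS):
        demographics.append(Demographics(
            patient_id=row["patient_id"],
            birth_date=_parse_date(row["birth_date"], fname, line, "birth_date"),
            sex=row["sex"],
            region=row["region"],
        ))

    if config.dedup_exact:
        medical = list(dict.fromkeys(medical))
        pharmacy = list(dict.fromkeys(pharmacy))

    bundle = ClaimsBundle(
        enrollment=normalize_spans(enrollment),
        medical=medical,
        pharmacy=pharmacy,
        demographics=demographics,
    )
    bundle.validate()
    return bundle


def write_bundle(bundle: ClaimsBundle, dir_path: str | Path) -> dict[str, Path]:
    """Write the four schema files; ``read_bundle`` round-trips the result."""
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _open(key: str):
        p = d / FILE_NAMES[key]
        paths[key] = p
        return open(p, "w", newline="", encoding="utf-8")

    with _open("enrollment") as fh:
        w = csv.writer(fh)
        w.writerow(ENROLLMENT_COLUMNS)
        for s in bundle.enrollment:
            w.writerow([s.patient_id, s.start_date.isoformat(), s.end_date.isoformat()])

    with _open("medical") as fh:
        w = csv.writer(fh)
        w.writerow(MEDICAL_COLUMNS)
        for c in bundle.medical:
            w.writerow([c.patient_id, c.service_date.isoformat(),
                        ";".join(c.dx_codes), c.proc_code, c.setting,
                        _fmt_cost(c.allowed_cost), ";".join(sorted(c.flags))])

    with _open("pharmacy") as fh:
        w = csv.writer(fh)
        w.writerow(PHARMACY_COLUMNS)
        for f in bundle.pharmacy:
            w.writerow([f.patient_id, f.fill_date.isoformat(), f.drug,
                        f.days_supply, _fmt_cost(f.allowed_cost)])

    with _open("demographics") as fh:
        w = csv.writer(fh)
        w.writerow(DEMOGRAPHICS_COLUMNS)
        for dm in bundle.demographics:
            w.writerow([dm.patient_id, dm.birth_date.isoformat(), dm.sex, dm.region])

    return paths


def _fmt_cost(x: float) -> str:
    # str(float) round-trips exactly and is deterministic
    return str(float(x))
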