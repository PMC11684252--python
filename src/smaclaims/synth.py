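"""Synthetic claims-bundle generator with per-patient ground truth.

The generator emulates the structure of a commercial claims extract —
enrollment spans, diagnosis claims, daily-oral-drug refill sequences with
controllable gap behavior, switch events to the injectable/gene therapies,
severity-marker claims, comorbidity codes, and log-normal costs per service
category — so that every downstream stage can be tested against known truth
without the proprietary source database.

Reproducibility: a single integer seed drives one root ``SeedSequence``;
each patient's substream is keyed by (seed, patient index), so insertion
order never changes any patient's draws and generation is byte-deterministic.

Decoy patients violating individual inclusion criteria (pre-approval fills
only, short post-index enrollment, a non-qualifying diagnosis code, short
pre-index enrollment) are mixed in at configurable fractions to exercise the
selection funnel.
"""

from __future__ import annotations

import csv
import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .claims import ClaimsBundle, Demographics, EnrollmentSpan, MedicalClaim, PharmacyClaim
from .cohort import APPROVAL_DATE, DATA_END, DATA_START

_SEED_MASK = 0xFFFFFFFFFFFFFFFF

ROLES = ("includable", "decoy_pre_approval", "decoy_short_enrollment",
         "decoy_no_sma_dx", "decoy_short_pre_enrollment")

#: qualifying diagnosis code emitted per true type
TYPE_DX = {1: "G12.0", 2: "G12.1", 3: "G12.1", 4: "G12.9"}
NONQUALIFYING_DX = "G12.8"

COMORBIDITY_CODES = {
    # code: per-type probability (types 1..4)
    "M41.9":  (0.9, 0.72, 0.70, 0.0),    # scoliosis
    "R06.00": (0.9, 0.45, 0.45, 0.05),   # dyspnea / respiratory anomalies
    "M62.81": (0.3, 0.67, 0.26, 0.25),   # generalized muscle weakness
    "J96.10": (0.9, 0.45, 0.32, 0.05),   # chronic respiratory failure
    "R63.3":  (0.5, 0.45, 0.19, 0.05),   # feeding difficulties
    "F84.0":  (0.5, 0.39, 0.15, 0.05),   # neurodevelopmental
    "F98.0":  (0.0, 0.11, 0.15, 0.05),   # elimination
    "F41.1":  (0.0, 0.0, 0.09, 0.25),    # anxiety
    "F32.9":  (0.0, 0.0, 0.06, 0.25),    # depressive
    "Z71.9":  (0.0, 0.11, 0.04, 0.15),   # other clinical attention
}

AGE_AT_DX_BANDS = {1: (0.15, 0.9), 2: (1.1, 2.8), 3: (3.5, 17.5), 4: (18.5, 60.0)}


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class AdherenceProfile:
    """Refill-gap behavior: probability a refill is late, and mean lateness."""

    gap_prob: float = 0.2
    mean_gap_days: float = 15.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gap_prob <= 1.0:
            raise ConfigError(f"gap_prob {self.gap_prob} outside [0, 1]")
        if self.mean_gap_days <= 0:
            raise ConfigError("mean_gap_days must be positive")


@dataclass(frozen=True)
class LogNormal:
    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigError("log-normal sigma must be positive")

    def draw(self, rng: np.random.Generator) -> float:
        return float(rng.lognormal(self.mu, self.sigma))


@dataclass(frozen=True)
class CostModel:
    inpatient: LogNormal = LogNormal(8.8, 1.0)
    outpatient: LogNormal = LogNormal(6.0, 0.8)
    emergency: LogNormal = LogNormal(7.0, 0.9)
    other: LogNormal = LogNormal(6.2, 0.8)
    ventilation: LogNormal = LogNormal(8.2, 1.0)
    nutrition: LogNormal = LogNormal(7.6, 1.0)
    pharmacy_other: LogNormal = LogNormal(5.0, 0.9)
    risdiplam_fill: LogNormal = LogNormal(10.1, 0.2)
    dmt_event: LogNormal = LogNormal(11.0, 0.3)
    # annual event rates
    inpatient_rate: float = 0.4
    outpatient_rate: float = 8.0
    emergency_rate: float = 1.0
    other_rate: float = 2.0
    support_rate: float = 4.0
    pharmacy_rate: float = 4.0
    #: true types whose severity enables ventilation/nutrition claims
    support_types: tuple[int, ...] = (1, 2)


@dataclass(frozen=True)
class EnrollmentModel:
    """Post-index enrollment = minimum + log-normal extra days."""

    min_post_days: int = 183
    extra_scale: float = 200.0
    extra_sigma: float = 0.6

    def __post_init__(self) -> None:
        if self.extra_scale <= 0 or self.extra_sigma <= 0:
            raise ConfigError("enrollment model scale parameters must be positive")


def _default_profiles() -> dict[int, AdherenceProfile]:
    return {t: AdherenceProfile() for t in (1, 2, 3, 4)}


def _default_decoys() -> dict[str, float]:
    return {"decoy_pre_approval": 0.1, "decoy_short_enrollment": 0.1,
            "decoy_no_sma_dx": 0.1, "decoy_short_pre_enrollment": 0.0}


@dataclass(frozen=True)
class SimConfig:
    n_patients: int = 100
    seed: int = 0
    type_mix: tuple[float, float, float, float] = (0.02, 0.21, 0.54, 0.23)
    adherence_profiles: Mapping[int, AdherenceProfile] = field(default_factory=_default_profiles)
    switch_prob: float = 0.08
    oa_prob: float = 0.01
    prior_nusinersen_prob: float = 0.3
    disc_rate: float = 0.0          # per-day hazard of permanent refill stop
    days_supply: int = 30
    cost_model: CostModel = field(default_factory=CostModel)
    enrollment_model: EnrollmentModel = field(default_factory=EnrollmentModel)
    calendar_bounds: tuple[dt.date, dt.date] = (DATA_START, DATA_END)
    approval_date: dt.date = APPROVAL_DATE
    decoy_fractions: Mapping[str, float] = field(default_factory=_default_decoys)

    def __post_init__(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be nonnegative")
        if abs(sum(self.type_mix) - 1.0) > 1e-9 or any(p < 0 for p in self.type_mix):
            raise ConfigError("type_mix must be a probability vector summing to 1")
        for p in (self.switch_prob, self.oa_prob, self.prior_nusinersen_prob):
            if not 0.0 <= p <= 1.0:
                raise ConfigError("probabilities must lie in [0, 1]")
        if self.disc_rate < 0:
            raise ConfigError("disc_rate must be nonnegative")
        if self.days_supply < 1:
            raise ConfigError("days_supply must be >= 1")
        total_decoy = sum(self.decoy_fractions.values())
        if total_decoy > 1.0 + 1e-9 or any(f < 0 for f in self.decoy_fractions.values()):
            raise ConfigError("decoy fractions must be nonnegative and sum to <= 1")
        unknown = set(self.decoy_fractions) - set(ROLES)
        if unknown:
            raise ConfigError(f"unknown decoy roles {sorted(unknown)}")


TRUTH_COST_CATEGORIES = ("total", "medical_total", "inpatient", "outpatient", "ed",
                         "other_medical", "mechanical_ventilation",
                         "nutritional_support", "pharmacy")


@dataclass(frozen=True)
class PatientTruth:
    patient_id: str
    role: str
    sma_type: int
    index_date: dt.date | None
    window_end: dt.date | None
    refills: tuple[tuple[dt.date, int], ...]
    switch_date: dt.date | None
    oa_date: dt.date | None
    category_costs: Mapping[str, float]
    true_pdc: float | None
    true_adherent: bool | None


@dataclass
class GroundTruth:
    patients: dict[str, PatientTruth] = field(default_factory=dict)


def daily_pdc(refills, index_date: dt.date, end_date: dt.date) -> float:
    """Day-by-day pill-stock simulation of coverage; the generator's own oracle."""
    supply: dict[dt.date, int] = {}
    for d, ds in refills:
        if d <= end_date:
            supply[d] = supply.get(d, 0) + ds
    stock = 0
    covered = 0
    day = index_date
    one = dt.timedelta(days=1)
    while day <= end_date:
        stock += supply.get(day, 0)
        if stock > 0:
            covered += 1
            stock -= 1
        day += one
    return covered / ((end_date - index_date).days + 1)


def _patient_rng(seed: int, i: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([seed & _SEED_MASK, i]))


def _rand_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    if hi < lo:
        return lo
    return lo + dt.timedelta(days=int(rng.integers(0, (hi - lo).days + 1)))


class _PatientBuilder:
    """Accumulates one patient's records and the matching ground truth."""

    def __init__(self, pid: str, config: SimConfig, rng: np.random.Generator):
        self.pid = pid
        self.config = config
        self.rng = rng
        self.medical: list[MedicalClaim] = []
        self.pharmacy: list[PharmacyClaim] = []
        self.index_date: dt.date | None = None
        self.window_end: dt.date | None = None
        self.costs = {c: 0.0 for c in TRUTH_COST_CATEGORIES}

    def _track(self, claim: MedicalClaim) -> None:
        """Accumulate truth costs for non-DMT medical claims inside the window."""
        self.medical.append(claim)
        if self.index_date is None or self.window_end is None or claim.is_dmt:
            return
        if not self.index_date <= claim.service_date <= self.window_end:
            return
        bucket = {"inpatient": "inpatient", "outpatient": "outpatient",
                  "emergency": "ed", "other": "other_medical"}[claim.setting]
        self.costs[bucket] += claim.allowed_cost
        for flag, cat in (("mechanical_ventilation", "mechanical_ventilation"),
                          ("nutritional_support", "nutritional_support")):
            if flag in claim.flags:
                self.costs[cat] += claim.allowed_cost

    def _track_fill(self, fill: PharmacyClaim) -> None:
        self.pharmacy.append(fill)
        if self.index_date is None or self.window_end is None:
            return
        if fill.drug == "risdiplam":
            return
        if self.index_date <= fill.fill_date <= self.window_end:
            self.costs["pharmacy"] += fill.allowed_cost

    def finalize_costs(self) -> dict[str, float]:
        self.costs["medical_total"] = sum(
            self.costs[c] for c in ("inpatient", "outpatient", "ed", "other_medical"))
        self.costs["total"] = self.costs["medical_total"] + self.costs["pharmacy"]
        return dict(self.costs)


def _generate_patient(i: int, config: SimConfig
                      ) -> tuple[Demographics, list[EnrollmentSpan],
                                 list[MedicalClaim], list[PharmacyClaim], PatientTruth]:
    rng = _patient_rng(config.seed, i)
    pid = f"P{i:05d}"
    data_start, data_end = config.calendar_bounds
    approval = config.approval_date
    cm = config.cost_model
    em = config.enrollment_model

    # role
    u = rng.random()
    role = "includable"
    acc = 0.0
    for r in ROLES[1:]:
        acc += config.decoy_fractions.get(r, 0.0)
        if u < acc:
            role = r
            break

    sma_type = int(rng.choice([1, 2, 3, 4], p=config.type_mix))
    if role == "decoy_short_pre_enrollment" and sma_type == 1:
        sma_type = 3  # the pre-index criterion applies to types 2-4 only

    # anchor / index date
    if role == "decoy_pre_approval":
        anchor = _rand_date(rng, data_start + dt.timedelta(days=60),
                            approval - dt.timedelta(days=35))
    else:
        latest = data_end - dt.timedelta(days=em.min_post_days)
        anchor = _rand_date(rng, approval, latest)

    # first diagnosis date and birth date
    dx_delta = int(rng.integers(0, 31 if role == "decoy_pre_approval" else 91))
    first_dx = anchor - dt.timedelta(days=dx_delta)
    lo, hi = AGE_AT_DX_BANDS[sma_type]
    age_dx = float(rng.uniform(lo, hi))
    birth = first_dx - dt.timedelta(days=int(round(age_dx * 365.25)))

    # enrollment span
    pre_draw = int(rng.integers(100, 201))
    enroll_start = max(anchor - dt.timedelta(days=pre_draw), birth)
    if role == "decoy_short_pre_enrollment":
        enroll_start = anchor - dt.timedelta(days=int(rng.integers(10, 80)))
        first_dx = max(first_dx, enroll_start)  # keep dx claim plausible
    if role == "decoy_short_enrollment":
        post_days = int(rng.integers(30, 150))
    else:
        extra = float(rng.lognormal(np.log(em.extra_scale), em.extra_sigma))
        post_days = em.min_post_days + int(round(extra))
    enroll_end = min(anchor + dt.timedelta(days=post_days), data_end)
    span = EnrollmentSpan(pid, enroll_start, enroll_end)

    builder = _PatientBuilder(pid, config, rng)

    if role == "includable":
        builder.index_date = anchor
        builder.window_end = min(enroll_end, data_end, anchor + dt.timedelta(days=365))

    # stop boundaries for the refill sequence
    switch_date: dt.date | None = None
    oa_date: dt.date | None = None
    if rng.random() < config.switch_prob:
        switch_date = anchor + dt.timedelta(days=int(rng.integers(60, 331)))
    if rng.random() < config.oa_prob:
        oa_date = anchor + dt.timedelta(days=int(rng.integers(30, 301)))
    stop_by_hazard: dt.date | None = None
    if config.disc_rate > 0:
        stop_by_hazard = anchor + dt.timedelta(
            days=int(np.ceil(rng.exponential(1.0 / config.disc_rate))))

    fill_bound = min(enroll_end, data_end)
    for bound in (switch_date, oa_date, stop_by_hazard):
        if bound is not None:
            fill_bound = min(fill_bound, bound - dt.timedelta(days=1))
    if role == "decoy_pre_approval":
        fill_bound = min(fill_bound, approval - dt.timedelta(days=1))

    # refill sequence (drug of interest)
    profile = config.adherence_profiles[sma_type] if isinstance(
        config.adherence_profiles, Mapping) else config.adherence_profiles
    refills: list[tuple[dt.date, int]] = []
    fill_date = anchor
    n_fill_cap = 40  # window is at most ~1 year; guard anyway
    while fill_date <= fill_bound and len(refills) < n_fill_cap:
        ds = config.days_supply
        refills.append((fill_date, ds))
        builder._track_fill(PharmacyClaim(
            pid, fill_date, "risdiplam", ds,
            round(cm.risdiplam_fill.draw(rng), 2)))
        exhaust = fill_date + dt.timedelta(days=ds - 1)
        next_date = exhaust + dt.timedelta(days=1)
        if rng.random() < profile.gap_prob:
            next_date += dt.timedelta(days=int(np.ceil(rng.exponential(profile.mean_gap_days))))
        fill_date = next_date

    dx_code = NONQUALIFYING_DX if role == "decoy_no_sma_dx" else TYPE_DX[sma_type]

    # DMT events (medical claims)
    if rng.random() < config.prior_nusinersen_prob:
        prior_date = max(anchor - dt.timedelta(days=int(rng.integers(60, 201))),
                         max(enroll_start, data_start))
        if prior_date < anchor:
            # no diagnosis code if this predates the first-diagnosis claim:
            # age at first diagnosis must stay where it was drawn
            prior_dx = (dx_code,) if prior_date >= first_dx else ()
            builder._track(MedicalClaim(
                pid, prior_date, dx_codes=prior_dx, proc_code="J2326",
                setting="outpatient", allowed_cost=round(cm.dmt_event.draw(rng), 2),
                flags=frozenset({"dmt_nusinersen"})))
    if switch_date is not None and switch_date <= min(enroll_end, data_end):
        builder._track(MedicalClaim(
            pid, switch_date, dx_codes=(dx_code,), proc_code="J2326",
            setting="outpatient", allowed_cost=round(cm.dmt_event.draw(rng), 2),
            flags=frozenset({"dmt_nusinersen"})))
    else:
        switch_date = None
    if oa_date is not None and oa_date <= min(enroll_end, data_end):
        builder._track(MedicalClaim(
            pid, oa_date, dx_codes=(dx_code,), proc_code="J3399",
            setting="inpatient", allowed_cost=round(cm.dmt_event.draw(rng), 2),
            flags=frozenset({"dmt_onasemnogene"})))
    else:
        oa_date = None

    # diagnosis claim establishing age-at-first-diagnosis
    builder._track(MedicalClaim(
        pid, first_dx, dx_codes=(dx_code,), proc_code="", setting="outpatient",
        allowed_cost=round(cm.outpatient.draw(rng), 2)))

    years_enrolled = span.n_days / 365.25

    def _visits(rate: float) -> int:
        return int(rng.poisson(rate * years_enrolled))

    # routine utilization by setting
    for setting, dist, rate in (("inpatient", cm.inpatient, cm.inpatient_rate),
                                ("outpatient", cm.outpatient, cm.outpatient_rate),
                                ("emergency", cm.emergency, cm.emergency_rate),
                                ("other", cm.other, cm.other_rate)):
        for _ in range(_visits(rate)):
            date = _rand_date(rng, enroll_start, enroll_end)
            dx = (dx_code,) if rng.random() < 0.3 and date >= first_dx else ()
            builder._track(MedicalClaim(
                pid, date, dx_codes=dx, setting=setting,
                allowed_cost=round(dist.draw(rng), 2)))

    # severity-marker support claims (ventilation / nutrition)
    allow_vent = sma_type in cm.support_types
    allow_nutrition = allow_vent
    if sma_type == 2 and age_dx < 2.0:
        # keep marker pattern consistent with the default typing rules:
        # a toddler with BOTH supports would classify as type 1
        allow_nutrition = False
    if allow_vent and sma_type != 1 and rng.random() < 0.4:
        allow_vent = False  # not every severe patient is ventilated
    if allow_vent:
        for _ in range(max(1, _visits(cm.support_rate))):
            date = _rand_date(rng, max(enroll_start, first_dx), enroll_end)
            builder._track(MedicalClaim(
                pid, date, proc_code="E0465", setting="other",
                allowed_cost=round(cm.ventilation.draw(rng), 2),
                flags=frozenset({"mechanical_ventilation"})))
    if allow_nutrition and (sma_type == 1 or rng.random() < 0.6):
        for _ in range(max(1, _visits(cm.support_rate))):
            date = _rand_date(rng, max(enroll_start, first_dx), enroll_end)
            builder._track(MedicalClaim(
                pid, date, proc_code="B4150", setting="other",
                allowed_cost=round(cm.nutrition.draw(rng), 2),
                flags=frozenset({"nutritional_support"})))

    # comorbidity diagnosis claims
    for code, probs in COMORBIDITY_CODES.items():
        if rng.random() < probs[sma_type - 1]:
            date = _rand_date(rng, max(enroll_start, first_dx), enroll_end)
            builder._track(MedicalClaim(
                pid, date, dx_codes=(code,), setting="outpatient",
                allowed_cost=round(cm.outpatient.draw(rng), 2)))

    # other-drug pharmacy fills
    for _ in range(_visits(cm.pharmacy_rate)):
        date = _rand_date(rng, enroll_start, enroll_end)
        builder._track_fill(PharmacyClaim(
            pid, date, "other", int(rng.integers(7, 91)),
            round(cm.pharmacy_other.draw(rng), 2)))

    demo = Demographics(
        pid, birth, sex=str(rng.choice(["F", "M"], p=[0.55, 0.45])),
        region=str(rng.choice(["South", "Midwest", "West", "Northeast"],
                              p=[0.37, 0.28, 0.2, 0.15])))

    true_pdc = true_adherent = None
    if builder.index_date is not None and builder.window_end is not None:
        true_pdc = daily_pdc(refills, builder.index_date, builder.window_end)
        true_adherent = true_pdc >= 0.80

    truth = PatientTruth(
        patient_id=pid, role=role, sma_type=sma_type,
        index_date=builder.index_date, window_end=builder.window_end,
        refills=tuple(refills), switch_date=switch_date, oa_date=oa_date,
        category_costs=builder.finalize_costs(),
        true_pdc=true_pdc, true_adherent=true_adherent)

    return demo, [span], builder.medical, builder.pharmacy, truth


def generate(config: SimConfig) -> tuple[ClaimsBundle, GroundTruth]:
    """Generate a claims bundle with matching ground truth; seed-deterministic."""
    bundle = ClaimsBundle()
    truth = GroundTruth()
    for i in range(config.n_patients):
        demo, spans, medical, pharmacy, pt = _generate_patient(i, config)
        bundle.demographics.append(demo)
        bundle.enrollment.extend(spans)
        bundle.medical.extend(medical)
        bundle.pharmacy.extend(pharmacy)
        truth.patients[pt.patient_id] = pt
    bundle.validate()
    return bundle, truth


def perturb_to_nonadherent(bundle: ClaimsBundle, truth: GroundTruth,
                           fraction: float, seed: int,
                           ) -> tuple[ClaimsBundle, GroundTruth]:
    """Thin out refill schedules for a random subset so their true PDC < 0.80.

    Each patient with a study window is selected independently with
    probability ``fraction``; selected patients keep only the leading fills
    whose total days of supply is at most 70% of the window length, which
    bounds their coverage — and hence PDC — below 0.8.  Patients without a
    window (decoys) are left untouched.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ConfigError(f"fraction {fraction} outside [0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([seed & _SEED_MASK, 0x9E3779B9]))

    drop: dict[str, set[tuple[dt.date, int]]] = {}
    new_truth = GroundTruth(patients=dict(truth.patients))
    for pid in sorted(truth.patients):
        pt = truth.patients[pid]
        selected = rng.random() < fraction
        if pt.index_date is None or pt.window_end is None or not pt.refills:
            continue
        if not selected:
            continue
        window_days = (pt.window_end - pt.index_date).days + 1
        budget = 0.7 * window_days
        kept: list[tuple[dt.date, int]] = []
        total = 0
        for d, ds in pt.refills:
            if kept and total + ds > budget:
                break
            kept.append((d, ds))
            total += ds
        dropped = set(pt.refills) - set(kept)
        if not dropped:
            continue
        drop[pid] = dropped
        new_pdc = daily_pdc(kept, pt.index_date, pt.window_end)
        new_truth.patients[pid] = replace(
            pt, refills=tuple(kept), true_pdc=new_pdc,
            true_adherent=new_pdc >= 0.80)

    new_pharmacy = []
    removed: dict[str, set[tuple[dt.date, int]]] = {p: set(v) for p, v in drop.items()}
    for f in bundle.pharmacy:
        key = (f.fill_date, f.days_supply)
        if f.drug == "risdiplam" and key in removed.get(f.patient_id, ()):  # drop once
            removed[f.patient_id].discard(key)
            continue
        new_pharmacy.append(f)

    new_bundle = ClaimsBundle(
        enrollment=list(bundle.enrollment),
        medical=list(bundle.medical),
        pharmacy=new_pharmacy,
        demographics=list(bundle.demographics))
    new_bundle.validate()
    return new_bundle, new_truth


TRUTH_COLUMNS = ("patient_id", "role", "sma_type", "index_date", "window_end",
                 "refills", "switch_date", "oa_date", "true_pdc", "true_adherent",
                 ) + TRUTH_COST_CATEGORIES


def write_truth(truth: GroundTruth, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(TRUTH_COLUMNS)
        for pid in sorted(truth.patients):
            pt = truth.patients[pid]
            w.writerow([
                pt.patient_id, pt.role, pt.sma_type,
                pt.index_date.isoformat() if pt.index_date else "",
                pt.window_end.isoformat() if pt.window_end else "",
                "|".join(f"{d.isoformat()}:{ds}" for d, ds in pt.refills),
                pt.switch_date.isoformat() if pt.switch_date else "",
                pt.oa_date.isoformat() if pt.oa_date else "",
                "" if pt.true_pdc is None else repr(pt.true_pdc),
                "" if pt.true_adherent is None else int(pt.true_adherent),
            ] + [pt.category_costs[c] for c in TRUTH_COST_CATEGORIES])
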