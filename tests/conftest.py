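import datetime as dt

import pytest

from smaclaims.claims import (ClaimsBundle, Demographics, EnrollmentSpan,
                              MedicalClaim, PharmacyClaim)
from smaclaims.cohort import StudyWindow

D = dt.date


def day(index: dt.date, offset: int) -> dt.date:
    return index + dt.timedelta(days=offset)


def make_window(index: dt.date = D(2020, 9, 1), length_days: int = 365,
                patient_id: str = "P1",
                end_reason: str = "one_year_cap") -> StudyWindow:
    """Window of ``length_days`` total days (index day inclusive)."""
    return StudyWindow(patient_id=patient_id, index_date=index,
                       end_date=index + dt.timedelta(days=length_days - 1),
                       end_reason=end_reason)


def make_fills(specs, patient_id: str = "P1", drug: str = "risdiplam"):
    """specs: iterable of (fill_date, days_supply)."""
    return [PharmacyClaim(patient_id, d, drug, ds, 100.0) for d, ds in specs]


def simple_patient(pid: str = "P1",
                   birth: dt.date = D(2000, 1, 1),
                   enroll=(D(2020, 1, 1), D(2021, 12, 31)),
                   dx_code: str = "G12.1",
                   dx_date: dt.date = D(2020, 6, 1),
                   fill_specs=((D(2020, 9, 1), 30),)) -> ClaimsBundle:
    """One-patient bundle passing all inclusion criteria by default."""
    bundle = ClaimsBundle()
    bundle.demographics.append(Demographics(pid, birth, "F", "South"))
    bundle.enrollment.append(EnrollmentSpan(pid, *enroll))
    bundle.medical.append(MedicalClaim(pid, dx_date, dx_codes=(dx_code,),
                                       setting="outpatient", allowed_cost=50.0))
    bundle.pharmacy.extend(make_fills(fill_specs, patient_id=pid))
    bundle.validate()
    return bundle


def merge_bundles(*bundles: ClaimsBundle) -> ClaimsBundle:
    out = ClaimsBundle()
    for b in bundles:
        out.enrollment.extend(b.enrollment)
        out.medical.extend(b.medical)
        out.pharmacy.extend(b.pharmacy)
        out.demographics.extend(b.demographics)
    out.validate()
    return out


@pytest.fixture
def clean_sim_config():
    """Simulation config with no decoys, no switches, no refill gaps."""
    from smaclaims.synth import AdherenceProfile, SimConfig

    return SimConfig(
        n_patients=40, seed=11,
        adherence_profiles={t: AdherenceProfile(gap_prob=0.0) for t in (1, 2, 3, 4)},
        switch_prob=0.0, oa_prob=0.0, prior_nusinersen_prob=0.0,
        decoy_fractions={})


@pytest.fixture(autouse=True)
def _quiet_logs(caplog):
    import logging

    logging.getLogger("smaclaims").setLevel(logging.ERROR)
    logging.getLogger("smaclaims.adherence").setLevel(logging.ERROR)
    yield
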