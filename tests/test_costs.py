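import pytest

from smaclaims.claims import MedicalClaim, PharmacyClaim
from smaclaims.costs import (CATEGORIES, InflationIndex, annualize_pppy,
                             apply_outlier_exclusion, categorize_costs,
                             compute_patient_costs, inflate, summarize_costs,
                             SETTING_CATEGORIES)
from conftest import D, make_window, simple_patient

INDEX = D(2020, 9, 1)
FLAT = InflationIndex.identity()


def one_patient_costs(extra_medical=(), extra_pharmacy=(), window_days=365):
    bundle = simple_patient(fill_specs=((INDEX, 30),))
    bundle.medical.extend(extra_medical)
    bundle.pharmacy.extend(extra_pharmacy)
    w = make_window(INDEX, window_days)
    return bundle, w


class TestCategorize:
    def test_risdiplam_only_gives_all_zeros(self):
        bundle = simple_patient(dx_date=D(2020, 1, 1),
                                fill_specs=((INDEX, 30),))
        bundle.pharmacy[0] = PharmacyClaim("P1", INDEX, "risdiplam", 30, 30_000.0)
        w = make_window(INDEX, 365)
        totals = categorize_costs(bundle, w, "P1", index=FLAT)
        assert all(v == 0.0 for v in totals.values())

    def test_ventilation_overlay_double_counts_into_setting(self):
        claim = MedicalClaim("P1", D(2020, 10, 1), setting="inpatient",
                             allowed_cost=1000.0,
                             flags=frozenset({"mechanical_ventilation"}))
        bundle, w = one_patient_costs(extra_medical=[claim])
        bundle.medical = [c for c in bundle.medical if c.allowed_cost == 1000.0]
        totals = categorize_costs(bundle, w, "P1", index=FLAT)
        assert totals["inpatient"] == 1000.0
        assert totals["mechanical_ventilation"] == 1000.0
        assert totals["medical_total"] == 1000.0
        assert totals["total"] == 1000.0

    def test_no_claims_all_zero(self):
        bundle = simple_patient(dx_date=D(2019, 6, 1),
                                enroll=(D(2019, 1, 1), D(2021, 12, 31)),
                                fill_specs=((INDEX, 30),))
        bundle.medical = []
        bundle.pharmacy = []
        totals = categorize_costs(bundle, make_window(INDEX, 365), "P1", index=FLAT)
        assert all(v == 0.0 for v in totals.values())

    def test_claims_outside_window_ignored(self):
        early = MedicalClaim("P1", D(2020, 1, 1), setting="inpatient",
                             allowed_cost=500.0)
        bundle, w = one_patient_costs(extra_medical=[early])
        totals = categorize_costs(bundle, w, "P1", index=FLAT)
        assert totals["inpatient"] == 0.0

    def test_dmt_flagged_claims_excluded(self):
        dmt = MedicalClaim("P1", D(2020, 10, 1), setting="outpatient",
                           allowed_cost=9e9, flags=frozenset({"dmt_nusinersen"}))
        bundle, w = one_patient_costs(extra_medical=[dmt])
        base = categorize_costs(simple_patient(fill_specs=((INDEX, 30),)), w,
                                "P1", index=FLAT)
        totals = categorize_costs(bundle, w, "P1", index=FLAT)
        assert totals == base


class TestInflate:
    def test_identity_index(self):
        assert inflate(123.45, 2021, FLAT) == 123.45

    def test_ratio(self):
        idx = InflationIndex({2021: 100.0, 2023: 105.0})
        assert inflate(1000.0, 2021, idx) == pytest.approx(1050.0)

    def test_zero_amount(self):
        assert inflate(0.0, 2020, FLAT) == 0.0

    def test_missing_year_names_it(self):
        with pytest.raises(KeyError, match="1999"):
            inflate(1.0, 1999, FLAT)

    def test_reference_year_required(self):
        with pytest.raises(ValueError):
            InflationIndex({2020: 1.0}, reference_year=2023)


class TestAnnualize:
    def test_identity_at_one_year(self):
        w = make_window(INDEX, 366)  # 366 days incl. index day = 365 intervals
        # 365.25-day-equivalent year: use length such that n_days/365.25 == 1
        assert annualize_pppy(10_000.0, w) == pytest.approx(10_000.0 * 365.25 / 366)

    def test_half_year_doubles(self):
        w = make_window(INDEX, 183)
        assert annualize_pppy(10_000.0, w) == pytest.approx(
            10_000.0 * 365.25 / 183)

    def test_zero_cost(self):
        assert annualize_pppy(0.0, make_window(INDEX, 200)) == 0.0


class TestOutlierExclusion:
    def _patients(self, totals):
        from smaclaims.costs import PatientCosts

        return [PatientCosts(str(i), 1.0,
                             {**{c: 0.0 for c in CATEGORIES}, "total": t},
                             {**{c: 0.0 for c in CATEGORIES}, "total": t})
                for i, t in enumerate(totals)]

    def test_all_below_threshold(self):
        kept, excluded = apply_outlier_exclusion(self._patients([100.0, 2e6]))
        assert len(kept) == 2 and excluded == []

    def test_above_4m_excluded(self):
        kept, excluded = apply_outlier_exclusion(self._patients([4_000_001.0, 10.0]))
        assert [p.patient_id for p in excluded] == ["0"]

    def test_infinite_threshold_is_identity(self):
        pts = self._patients([1e12])
        kept, excluded = apply_outlier_exclusion(pts, threshold=float("inf"))
        assert kept == pts and excluded == []


class TestSummaries:
    def _patients(self, values):
        from smaclaims.costs import PatientCosts

        return [PatientCosts(str(i), 1.0,
                             {**{c: 0.0 for c in CATEGORIES}, "total": v},
                             {**{c: 0.0 for c in CATEGORIES}, "total": v})
                for i, v in enumerate(values)]

    def test_hand_computed_stats(self):
        [s] = summarize_costs(self._patients([1.0, 2.0, 3.0]),
                              {"0": "a", "1": "a", "2": "a"})
        st = s.stats["total"]
        assert st.mean == 2.0 and st.median == 2.0 and st.sd == pytest.approx(1.0)
        assert st.q1 == 1.5 and st.q3 == 2.5  # linear interpolation

    def test_single_patient_sd_undefined(self):
        [s] = summarize_costs(self._patients([5.0]), {"0": "a"})
        assert s.stats["total"].mean == 5.0
        assert s.stats["total"].sd is None

    def test_two_stratifications_same_totals(self):
        pts = self._patients([1.0, 2.0, 3.0, 4.0])
        s1 = summarize_costs(pts, {p.patient_id: "all" for p in pts})
        s2 = summarize_costs(pts, {p.patient_id: ("a" if int(p.patient_id) < 2
                                                  else "b") for p in pts})
        grand1 = sum(s.stats["total"].mean * s.n for s in s1)
        grand2 = sum(s.stats["total"].mean * s.n for s in s2)
        assert grand1 == pytest.approx(grand2)


class TestSyntheticConservation:
    def test_conservation_and_truth_recovery(self, clean_sim_config):
        from smaclaims.cohort import select_cohort
        from smaclaims.synth import generate

        bundle, truth = generate(clean_sim_config)
        windows, _ = select_cohort(bundle)
        assert windows
        for w in windows:
            pc = compute_patient_costs(bundle, w, index=FLAT)
            assert sum(pc.raw[c] for c in SETTING_CATEGORIES) == pytest.approx(
                pc.raw["medical_total"], abs=1e-6)
            assert pc.raw["medical_total"] + pc.raw["pharmacy"] == pytest.approx(
                pc.raw["total"], abs=1e-6)
            tr = truth.patients[w.patient_id].category_costs
            for c in CATEGORIES:
                assert pc.raw[c] == pytest.approx(tr[c], abs=1e-6)
                assert pc.pppy[c] == pytest.approx(
                    tr[c] / pc.follow_up_years, abs=1e-6)

    def test_dmt_injection_changes_nothing(self, clean_sim_config):
        from smaclaims.cohort import select_cohort
        from smaclaims.synth import generate

        bundle, _ = generate(clean_sim_config)
        windows, _ = select_cohort(bundle)
        w = windows[0]
        before = compute_patient_costs(bundle, w, index=FLAT)
        bundle.medical.append(MedicalClaim(
            w.patient_id, w.index_date, setting="inpatient",
            allowed_cost=123_456_789.0, flags=frozenset({"dmt_onasemnogene"})))
        after = compute_patient_costs(bundle, w, index=FLAT)
        assert before == after
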