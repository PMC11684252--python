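import datetime as dt

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smaclaims.claims import (ClaimsBundle, Demographics, EnrollmentSpan,
                              MedicalClaim, PharmacyClaim, ReadConfig, RowError,
                              SchemaError, ValidationError, normalize_spans,
                              read_bundle, write_bundle)
from conftest import D, simple_patient
from _oracles import enumerate_covered_dates


class TestDomainTypes:
    def test_span_rejects_inverted_dates(self):
        with pytest.raises(ValidationError):
            EnrollmentSpan("P1", D(2020, 2, 1), D(2020, 1, 1))

    def test_negative_cost_rejected(self):
        with pytest.raises(ValidationError):
            MedicalClaim("P1", D(2020, 1, 1), allowed_cost=-1.0)

    def test_days_supply_at_least_one(self):
        with pytest.raises(ValidationError):
            PharmacyClaim("P1", D(2020, 1, 1), "risdiplam", 0)

    def test_at_most_one_dmt_flag(self):
        with pytest.raises(ValidationError):
            MedicalClaim("P1", D(2020, 1, 1),
                         flags=frozenset({"dmt_nusinersen", "dmt_onasemnogene"}))

    def test_unknown_patient_fails_validation(self):
        b = ClaimsBundle(pharmacy=[PharmacyClaim("ghost", D(2020, 1, 1),
                                                 "risdiplam", 30)])
        with pytest.raises(ValidationError):
            b.validate()


class TestNormalizeSpans:
    def test_adjacent_spans_merge(self):
        spans = [EnrollmentSpan("P1", D(2020, 1, 1), D(2020, 6, 30)),
                 EnrollmentSpan("P1", D(2020, 7, 1), D(2020, 12, 31))]
        merged = normalize_spans(spans)
        assert merged == [EnrollmentSpan("P1", D(2020, 1, 1), D(2020, 12, 31))]
        # oracle: the merged span covers exactly the union of dates
        dates = enumerate_covered_dates([(s.start_date, s.end_date) for s in spans])
        merged_dates = enumerate_covered_dates(
            [(s.start_date, s.end_date) for s in merged])
        assert merged_dates == dates

    def test_one_day_gap_not_merged_by_default(self):
        spans = [EnrollmentSpan("P1", D(2020, 1, 1), D(2020, 6, 30)),
                 EnrollmentSpan("P1", D(2020, 7, 2), D(2020, 12, 31))]
        assert len(normalize_spans(spans)) == 2
        assert len(normalize_spans(spans, merge_gap_days=1)) == 1

    @given(st.lists(
        st.tuples(st.integers(0, 300), st.integers(0, 60)), min_size=0, max_size=10))
    @settings(max_examples=50, deadline=None)
    def test_idempotent_and_order_independent(self, raw):
        base = D(2020, 1, 1)
        spans = [EnrollmentSpan("P1", base + dt.timedelta(days=a),
                                base + dt.timedelta(days=a + w)) for a, w in raw]
        once = normalize_spans(spans)
        assert normalize_spans(once) == once
        assert normalize_spans(list(reversed(spans))) == once
        covered = enumerate_covered_dates([(s.start_date, s.end_date) for s in spans])
        merged_cov = enumerate_covered_dates([(s.start_date, s.end_date) for s in once])
        assert merged_cov == covered


class TestRoundTrip:
    def test_empty_bundle_round_trip(self, tmp_path):
        write_bundle(ClaimsBundle(), tmp_path)
        b = read_bundle(tmp_path)
        assert b.patient_ids() == []
        for f in tmp_path.iterdir():
            assert len(f.read_text().splitlines()) == 1  # header only

    def test_three_pharmacy_rows(self, tmp_path):
        b = simple_patient(fill_specs=((D(2020, 9, 1), 30), (D(2020, 10, 1), 30),
                                       (D(2020, 11, 1), 30)))
        write_bundle(b, tmp_path)
        assert len(read_bundle(tmp_path).pharmacy) == 3

    def test_generated_bundle_round_trips(self, tmp_path, clean_sim_config):
        from smaclaims.synth import generate

        bundle, _ = generate(clean_sim_config)
        write_bundle(bundle, tmp_path)
        back = read_bundle(tmp_path)
        assert back.enrollment == normalize_spans(bundle.enrollment)
        assert back.medical == bundle.medical
        assert back.pharmacy == bundle.pharmacy
        assert back.demographics == bundle.demographics

    def test_non_ascii_patient_id_preserved(self, tmp_path):
        pid = "pätïent-Ω"
        b = simple_patient(pid=pid)
        write_bundle(b, tmp_path)
        back = read_bundle(tmp_path)
        assert back.patient_ids() == [pid]
        assert pid.encode("utf-8") in (tmp_path / "demographics.csv").read_bytes()


class TestReadErrors:
    def test_missing_column_names_it(self, tmp_path):
        write_bundle(ClaimsBundle(), tmp_path)
        (tmp_path / "pharmacy_claims.csv").write_text(
            "patient_id,fill_date,drug,allowed_cost\n")
        with pytest.raises(SchemaError, match="days_supply"):
            read_bundle(tmp_path)

    def test_bad_date_reports_line_number(self, tmp_path):
        b = simple_patient()
        write_bundle(b, tmp_path)
        path = tmp_path / "enrollment.csv"
        path.write_text("patient_id,start_date,end_date\nP1,2020-01-01,not-a-date\n")
        with pytest.raises(RowError, match="line 2"):
            read_bundle(tmp_path)

    def test_negative_cost_rejected_on_read(self, tmp_path):
        write_bundle(simple_patient(), tmp_path)
        path = tmp_path / "pharmacy_claims.csv"
        path.write_text("patient_id,fill_date,drug,days_supply,allowed_cost\n"
                        "P1,2020-09-01,risdiplam,30,-5\n")
        with pytest.raises(ValidationError):
            read_bundle(tmp_path)


class TestReadConfig:
    def test_exact_duplicates_dropped_by_default(self, tmp_path):
        write_bundle(simple_patient(), tmp_path)
        path = tmp_path / "pharmacy_claims.csv"
        text = path.read_text()
        data_line = text.splitlines()[1]
        path.write_text(text + data_line + "\n")
        assert len(read_bundle(tmp_path).pharmacy) == 1
        assert len(read_bundle(tmp_path, ReadConfig(dedup_exact=False)).pharmacy) == 2

    def test_code_flag_map_applied_when_flags_absent(self, tmp_path):
        write_bundle(simple_patient(), tmp_path)
        (tmp_path / "medical_claims.csv").write_text(
            "patient_id,service_date,dx_codes,proc_code,setting,allowed_cost,flags\n"
            "P1,2020-09-01,,J2326,outpatient,1000.0,\n")
        back = read_bundle(tmp_path, ReadConfig(code_flag_map={"J2326": "dmt_nusinersen"}))
        assert back.medical[0].flags == frozenset({"dmt_nusinersen"})
        # without the map the claim is unflagged
        plain = read_bundle(tmp_path)
        assert plain.medical[0].flags == frozenset()
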