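import filecmp

import numpy as np
import pytest
from scipy import stats

from smaclaims.claims import write_bundle
from smaclaims.synth import (AdherenceProfile, ConfigError, EnrollmentModel,
                             SimConfig, daily_pdc, generate,
                             perturb_to_nonadherent)
from conftest import D


class TestConfigValidation:
    def test_bad_type_mix_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(type_mix=(0.5, 0.5, 0.5, 0.5))

    def test_negative_fraction_rejected(self):
        with pytest.raises(ConfigError):
            SimConfig(decoy_fractions={"decoy_no_sma_dx": -0.1})

    def test_bad_gap_prob_rejected(self):
        with pytest.raises(ConfigError):
            AdherenceProfile(gap_prob=1.5)


class TestGenerate:
    def test_zero_patients(self):
        bundle, truth = generate(SimConfig(n_patients=0))
        assert bundle.patient_ids() == []
        assert truth.patients == {}

    def test_seed_determinism_byte_identical(self, tmp_path):
        cfg = SimConfig(n_patients=25, seed=42)
        for sub in ("a", "b"):
            bundle, _ = generate(cfg)
            write_bundle(bundle, tmp_path / sub)
        for name in ("enrollment.csv", "medical_claims.csv",
                     "pharmacy_claims.csv", "demographics.csv"):
            assert filecmp.cmp(tmp_path / "a" / name, tmp_path / "b" / name,
                               shallow=False)

    def test_different_seeds_differ(self):
        b1, _ = generate(SimConfig(n_patients=25, seed=1))
        b2, _ = generate(SimConfig(n_patients=25, seed=2))
        assert b1.pharmacy != b2.pharmacy

    def test_insertion_order_independence(self):
        # patient i's records are identical whether generated in a batch of
        # 10 or 30: substreams are keyed by (seed, index)
        small, _ = generate(SimConfig(n_patients=10, seed=9))
        large, _ = generate(SimConfig(n_patients=30, seed=9))
        for pid in small.patient_ids():
            assert small.pharmacy_for(pid) == large.pharmacy_for(pid)
            assert small.medical_for(pid) == large.medical_for(pid)

    def test_no_gaps_forces_pdc_one(self, clean_sim_config):
        from smaclaims.adherence import compute_adherence
        from smaclaims.cohort import select_cohort

        bundle, truth = generate(clean_sim_config)
        windows, _ = select_cohort(bundle)
        assert windows
        for a in compute_adherence(bundle, windows):
            assert a.pdc == 1.0
        for pt in truth.patients.values():
            assert pt.true_pdc == 1.0

    def test_truth_refills_reproduce_pharmacy_claims(self):
        bundle, truth = generate(SimConfig(n_patients=40, seed=6))
        for pid, pt in truth.patients.items():
            fills = [(f.fill_date, f.days_supply)
                     for f in bundle.pharmacy_for(pid, drug="risdiplam")]
            assert sorted(fills) == sorted(pt.refills)

    def test_every_patient_has_dx_and_covering_enrollment(self):
        bundle, truth = generate(SimConfig(n_patients=60, seed=8))
        for pid in bundle.patient_ids():
            assert any(any(code.startswith("G12") for code in c.dx_codes)
                       for c in bundle.medical_for(pid))
            spans = bundle.spans_for(pid)
            assert spans
            for f in bundle.pharmacy_for(pid):
                assert spans[0].start_date <= f.fill_date <= spans[-1].end_date

    def test_enrollment_length_distribution(self):
        # push the data horizon out so clipping never binds, then KS-test the
        # post-index extra days against the configured log-normal
        import datetime as dt

        em = EnrollmentModel(extra_scale=200.0, extra_sigma=0.6)
        data_end = D(2040, 12, 31)
        cfg = SimConfig(n_patients=3500, seed=13, enrollment_model=em,
                        calendar_bounds=(D(2020, 1, 1), data_end),
                        decoy_fractions={}, switch_prob=0.0, oa_prob=0.0)
        bundle, truth = generate(cfg)
        # spans ending at the calendar bound are right-censored draws; keep
        # only patients with headroom for any plausible extra (P(extra>3000)
        # ~ 3e-6), which is independent of the draw itself
        headroom = dt.timedelta(days=em.min_post_days + 3000)
        extras = []
        for pid, pt in truth.patients.items():
            if pt.index_date + headroom > data_end:
                continue
            span = bundle.spans_for(pid)[0]
            extras.append((span.end_date - pt.index_date).days - em.min_post_days)
        assert len(extras) >= 2000
        dist = stats.lognorm(s=em.extra_sigma, scale=em.extra_scale)
        res = stats.kstest(extras[:2000], dist.cdf)
        assert res.pvalue > 0.01


class TestPerturb:
    def _base(self, n=50, seed=3):
        from smaclaims.synth import AdherenceProfile

        cfg = SimConfig(
            n_patients=n, seed=seed,
            adherence_profiles={t: AdherenceProfile(gap_prob=0.0)
                                for t in (1, 2, 3, 4)},
            switch_prob=0.0, oa_prob=0.0, prior_nusinersen_prob=0.0,
            decoy_fractions={})
        return generate(cfg)

    def test_fraction_zero_is_identity(self):
        bundle, truth = self._base()
        b2, t2 = perturb_to_nonadherent(bundle, truth, 0.0, seed=1)
        assert b2.pharmacy == bundle.pharmacy
        assert t2.patients == truth.patients

    def test_fraction_one_forces_nonadherence(self):
        bundle, truth = self._base()
        _, t2 = perturb_to_nonadherent(bundle, truth, 1.0, seed=1)
        for pt in t2.patients.values():
            assert pt.true_pdc < 0.80

    def test_perturbed_count_in_binomial_range(self):
        bundle, truth = self._base(n=500, seed=21)
        _, t2 = perturb_to_nonadherent(bundle, truth, 0.2, seed=2)
        n_perturbed = sum(t2.patients[p].true_pdc < 0.80 for p in t2.patients)
        # binomial(500, 0.2): 99.9% central interval is about [71, 130];
        # the spec's nominal expectation band is 80..120
        assert 80 <= n_perturbed <= 120

    def test_truth_and_bundle_stay_consistent(self):
        bundle, truth = self._base()
        b2, t2 = perturb_to_nonadherent(bundle, truth, 0.5, seed=7)
        for pid, pt in t2.patients.items():
            fills = [(f.fill_date, f.days_supply)
                     for f in b2.pharmacy_for(pid, drug="risdiplam")]
            assert sorted(fills) == sorted(pt.refills)
            if pt.index_date is not None:
                assert pt.true_pdc == daily_pdc(pt.refills, pt.index_date,
                                                pt.window_end)

    def test_bad_fraction_rejected(self):
        bundle, truth = self._base(n=2)
        with pytest.raises(ConfigError):
            perturb_to_nonadherent(bundle, truth, 1.5, seed=0)
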