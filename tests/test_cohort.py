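"""Synthetic-cohort generator: contracts, prognostic indices, outcome model."""

import numpy as np
import pytest

from imscore.cohort import (CovariatePrevalences, HazardConfig, PatientRecord,
                            compute_ielsg, compute_mskcc, records_to_dataframe,
                            simulate_covariates, simulate_outcomes,
                            simulate_second_reader, simulate_true_scores)
from imscore.errors import ConfigurationError, MissingDataError
from imscore.scoring import cohen_kappa


def _record(**kw) -> PatientRecord:
    base = dict(patient_id="P0", age=55.0, sex="male", ecog=1, kps=80,
                ldh_elevated=False, csf_protein_elevated=False,
                deep_lesion=False, n_lesions=1, lesion_site="superficial",
                cohort="PET_CT")
    base.update(kw)
    return PatientRecord(**base)


class TestCovariates:
    def test_empty_cohort_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_covariates(0)

    def test_invalid_probability_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_covariates(5, CovariatePrevalences(p_male=1.3))

    def test_record_invariants(self):
        recs = simulate_covariates(38, seed=1)
        assert len(recs) == 38
        for r in recs:
            assert 18 <= r.age <= 85
            assert 0 <= r.ecog <= 4
            assert r.kps % 10 == 0 and 10 <= r.kps <= 100
            assert r.deep_lesion == (r.lesion_site in ("deep", "both"))
            assert r.n_lesions >= 1

    def test_male_fraction_matches_prevalence(self):
        # binomial: SE = sqrt(.53*.47/10000) ~ 0.005; 3 SE band
        recs = simulate_covariates(10_000, seed=3)
        frac = np.mean([r.sex == "male" for r in recs])
        assert abs(frac - 0.53) < 0.015

    def test_deterministic_and_prefix_stable(self):
        a = records_to_dataframe(simulate_covariates(10, seed=7))
        b = records_to_dataframe(simulate_covariates(10, seed=7))
        assert a.equals(b)
        # per-patient substreams: growing the cohort keeps existing patients
        big = records_to_dataframe(simulate_covariates(20, seed=7)).iloc[:10]
        assert a.equals(big.reset_index(drop=True))


class TestPrognosticIndices:
    @pytest.mark.parametrize("kw,score,group", [
        (dict(age=65, ecog=2, ldh_elevated=True, csf_protein_elevated=True,
              deep_lesion=True), 5, "2-3"),
        (dict(age=40, ecog=1, ldh_elevated=False, csf_protein_elevated=False,
              deep_lesion=False), 0, "0-1"),
        (dict(age=61, ecog=0, ldh_elevated=False, csf_protein_elevated=False,
              deep_lesion=True), 2, "2-3"),
    ])
    def test_ielsg_counts_risk_factors(self, kw, score, group):
        assert compute_ielsg(_record(**kw)) == (score, group)

    def test_ielsg_missing_covariate_is_an_error(self):
        rec = _record()
        rec.ldh_elevated = None
        with pytest.raises(MissingDataError):
            compute_ielsg(rec)

    @pytest.mark.parametrize("age,kps,cls", [(45, 60, 0), (60, 90, 1), (60, 60, 2)])
    def test_mskcc_three_class_mapping(self, age, kps, cls):
        assert compute_mskcc(_record(age=age, kps=kps)) == cls

    def test_mskcc_missing_covariate_is_an_error(self):
        rec = _record()
        rec.kps = None
        with pytest.raises(MissingDataError):
            compute_mskcc(rec)


class TestTrueScores:
    def test_degenerate_distribution_all_complete_response(self):
        recs = simulate_true_scores(simulate_covariates(20, seed=1),
                                    (1, 0, 0, 0, 0), seed=1)
        assert all(r.true_ims == 1 and r.n_lesions == 0 for r in recs)

    @pytest.mark.parametrize("dist", [(0.5, 0.5), (-0.1, 0.4, 0.3, 0.2, 0.2),
                                      (0.3, 0.3, 0.3, 0.3, 0.3)])
    def test_bad_distribution_rejected(self, dist):
        with pytest.raises(ConfigurationError):
            simulate_true_scores(simulate_covariates(2, seed=1), dist, seed=1)

    def test_empirical_fractions_match_configured_distribution(self):
        dist = tuple(np.array([8, 9, 11, 5, 5]) / 38.0)
        recs = simulate_true_scores(simulate_covariates(10_000, seed=5), dist, seed=5)
        counts = np.bincount([r.true_ims for r in recs], minlength=6)[1:]
        for k, p in enumerate(dist):
            se = np.sqrt(p * (1 - p) / 10_000)
            assert abs(counts[k] / 10_000 - p) < 3 * se

    def test_lesion_count_invariant(self):
        recs = simulate_true_scores(simulate_covariates(200, seed=9), seed=9)
        for r in recs:
            assert (r.n_lesions == 0) == (r.true_ims == 1 and not r.new_lesion_flag)


class TestOutcomes:
    def test_requires_true_scores(self):
        with pytest.raises(MissingDataError):
            simulate_outcomes(simulate_covariates(3, seed=1), seed=1)

    def test_invalid_hazard_rejected(self):
        recs = simulate_true_scores(simulate_covariates(3, seed=1), seed=1)
        with pytest.raises(ConfigurationError):
            simulate_outcomes(recs, HazardConfig(baseline_hazard=0.0), seed=1)

    def test_endpoint_coherence(self, small_cohort):
        for r in small_cohort:
            assert r.os_time >= r.pfs_time > 0
            if r.os_event:
                assert r.pfs_event  # death implies the composite PFS event

    def test_extreme_censoring_leaves_no_events(self):
        recs = simulate_true_scores(simulate_covariates(50, seed=2), seed=2)
        hz = HazardConfig(censor_rate=1e6)
        out = simulate_outcomes(recs, hz, seed=2)
        assert not any(r.pfs_event or r.os_event for r in out)
        assert all(r.pfs_time > 0 for r in out)

    def test_hazard_ratio_drives_group_contrast(self):
        # crude sanity: IMS 4-5 patients progress much faster on average
        recs = simulate_true_scores(simulate_covariates(2000, seed=4), seed=4)
        out = simulate_outcomes(recs, seed=4)
        hi = [r.pfs_time for r in out if r.true_ims >= 4]
        lo = [r.pfs_time for r in out if r.true_ims < 4]
        assert np.mean(hi) < 0.5 * np.mean(lo)


class TestSecondReader:
    def test_perfect_agreement_is_identity(self):
        scores = [1, 2, 3, 4, 5, 3, 2]
        out = simulate_second_reader(scores, agreement=1.0, seed=1)
        assert out == scores
        assert cohen_kappa(scores, out) == 1.0

    def test_empty_list(self):
        assert simulate_second_reader([], agreement=0.5, seed=1) == []

    def test_disagreements_move_one_level(self):
        scores = [3] * 500
        out = simulate_second_reader(scores, agreement=0.5, seed=2)
        assert set(out) <= {2, 3, 4}

    def test_kappa_envelope_at_default_agreement(self):
        rng = np.random.default_rng(0)
        scores = list(rng.integers(1, 6, size=10_000))
        out = simulate_second_reader(scores, agreement=0.95, seed=3)
        k = cohen_kappa(scores, out)
        assert 0.85 < k < 0.99
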