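"""Synthetic-cohort generator: determinism, quotas, noise calibration."""

import math

import numpy as np
import pytest

from eshval import (
    CohortSpec,
    DeviceErrorModel,
    IDEAL_DEVICE,
    check_quotas,
    generate_cohort,
    generate_screening_funnel,
    tally_recruitment,
    write_sessions,
)
from eshval.differences import build_cohort_pairs
from eshval.grading import grade_cohort_pairs
from eshval.report import observer_difference_summary


class TestDeterminism:
    def test_same_spec_and_seed_give_identical_file_bytes(self, tmp_path):
        paths = []
        for name in ("a.csv", "b.csv"):
            cohort = generate_cohort(CohortSpec(seed=42))
            path = tmp_path / name
            write_sessions(cohort, path)
            paths.append(path.read_bytes())
        assert paths[0] == paths[1]

    def test_different_seeds_differ(self):
        a = generate_cohort(CohortSpec(seed=1))
        b = generate_cohort(CohortSpec(seed=2))
        assert a.sessions != b.sessions


class TestDesignConstraints:
    def test_default_cohort_meets_quotas(self, paper_like_cohort):
        assert check_quotas(tally_recruitment(paper_like_cohort)).all_met

    def test_every_subject_is_obese(self, paper_like_cohort):
        assert all(s.bmi >= 30 for s in paper_like_cohort.sessions)

    def test_bmi_consistent_with_height_and_weight(self, paper_like_cohort):
        for s in paper_like_cohort.sessions:
            assert abs(s.bmi - s.weight / (s.height / 100) ** 2) <= 0.1

    def test_observer_readings_are_even_and_agree(self, paper_like_cohort):
        for s in paper_like_cohort.sessions:
            for slot, pair in s.observer_pairs().items():
                for obs in (pair.observer1, pair.observer2):
                    assert obs.sbp % 2 == 0 and obs.dbp % 2 == 0
                assert abs(pair.observer1.sbp - pair.observer2.sbp) < 4
                assert abs(pair.observer1.dbp - pair.observer2.dbp) < 4

    def test_unsatisfiable_quotas_rejected_before_sampling(self):
        with pytest.raises(ValueError, match="unsatisfiable"):
            CohortSpec(n_subjects=20, n_male=10, n_female=10, min_per_band=10)

    def test_entry_pressures_within_recruitment_spans(self, paper_like_cohort):
        for s in paper_like_cohort.sessions:
            sbp = (s.bpa.observer1.sbp + s.bpa.observer2.sbp) / 2
            dbp = (s.bpa.observer1.dbp + s.bpa.observer2.dbp) / 2
            assert 100 <= sbp <= 186  # band span plus observer noise margin
            assert 60 <= dbp <= 134


class TestScreeningFunnel:
    def test_default_funnel_reproduces_study_accounting(self):
        cohort = generate_screening_funnel(CohortSpec(seed=0))
        assert cohort.screened_total == 90
        assert cohort.total_excluded == 57
        assert cohort.exclusions == {
            "range adjustment": 36,
            "observer disagreement": 18,
            "other": 3,
        }
        assert len(cohort.sessions) == 33

    def test_zero_rates_mean_no_exclusions(self):
        cohort = generate_screening_funnel(CohortSpec(seed=0), exclusion_rates={})
        assert cohort.screened_total == len(cohort.sessions)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_accounting_invariant_for_random_rates(self, seed):
        rng = np.random.default_rng(seed)
        rates = {
            "range adjustment": float(rng.uniform(0, 0.4)),
            "observer disagreement": float(rng.uniform(0, 0.3)),
            "other": float(rng.uniform(0, 0.1)),
        }
        cohort = generate_screening_funnel(CohortSpec(seed=seed), exclusion_rates=rates)
        assert cohort.screened_total - cohort.total_excluded == len(cohort.sessions)


class TestNoiseCalibration:
    def test_noiseless_identity_device_passes_with_zero_differences(self, ideal_cohort):
        pairs = build_cohort_pairs(ideal_cohort.sessions)
        verdict = grade_cohort_pairs(pairs)
        assert verdict.part1["sbp"].counts == (99, 99, 99)
        assert verdict.part2["sbp"].n_subjects_with_2of3_within5 == 33
        assert verdict.overall == "PASS"

    def test_observer_difference_sd_matches_analytic_value(self):
        # o2 - o1 = difference of two independent N(0, s) readings each
        # rounded to the 2-mmHg grid: SD ~= sqrt(2 * (s^2 + 4/12)), shrunk
        # slightly by the repeat rule truncating |o1 - o2| >= 4
        s = 1.0
        sds = []
        for seed in range(40):
            spec = CohortSpec(seed=seed, observer_noise_sd=s)
            summary = observer_difference_summary(generate_cohort(spec, IDEAL_DEVICE))
            sds.append(summary["sbp"]["sd"])
        expected = math.sqrt(2 * (s**2 + 1 / 3))
        assert np.mean(sds) == pytest.approx(expected, rel=0.15)

    def test_signed_difference_sd_reflects_device_and_reference_noise(self):
        # flanking-mean reference: each of two flanking observer-pair means
        # carries (s^2 + 1/3)/2 variance, averaged again -> weight 1/2 overall;
        # drift and device rounding add small extra spread
        device = DeviceErrorModel(bias=1.9, noise_sd=1.5)
        s, drift = 1.0, 0.5
        sds = []
        for seed in range(40):
            spec = CohortSpec(seed=seed, observer_noise_sd=s,
                              within_session_drift_sd=drift)
            pairs = build_cohort_pairs(generate_cohort(spec, device).sessions)
            sds.append(np.std([p.signed_difference for p in pairs["sbp"]], ddof=1))
        floor = math.sqrt(device.noise_sd**2 + (s**2 + 1 / 3) / 2)
        assert floor * 0.9 < np.mean(sds) < floor * 1.35
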