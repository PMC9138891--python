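"""The synthetic cohort generator: structure, reproducibility, distributions."""

import dataclasses

import numpy as np
import pytest

from exgauss_workload.errors import DataError, ParameterError
from exgauss_workload.exgauss import sample_skewness
from exgauss_workload.records import LEVELS
from exgauss_workload.synth import (
    CohortConfig,
    default_workload_config,
    generate_cohort,
    generate_session,
    null_cohort,
    null_config,
)


@pytest.fixture(scope="module")
def spec():
    return default_workload_config().level_specs[0]


class TestGenerateSession:
    def test_all_onsets_within_session(self, spec):
        rec = generate_session("S01", spec, None, 0)
        for stream in (rec.fixations, rec.saccades, rec.blinks, rec.trials):
            assert stream[:, 0].min() >= 0
            assert stream[:, 0].max() < spec.duration

    def test_reproducible_for_fixed_seed(self, spec):
        a = generate_session("S01", spec, None, 5)
        b = generate_session("S01", spec, None, 5)
        assert a.equals(b)
        c = generate_session("S01", spec, None, 6)
        assert not a.equals(c)

    def test_timestamps_quantised_to_clock(self, spec):
        rec = generate_session("S01", spec, None, 1, timestamp_resolution=1 / 300)
        onsets = rec.fixations[:, 0]
        snapped = np.round(np.round(onsets * 300) / 300, 6)
        np.testing.assert_allclose(onsets, snapped, atol=5e-7)

    def test_expected_trial_count_matches_renewal_rate(self, spec):
        # with drift off, trials form a renewal process with mean interval
        # (mu + tau + gap); compare the Monte-Carlo mean against it
        clean = dataclasses.replace(spec, tempo_drift_sd=0.0, temporal_drift_sd=0.0)
        counts = [
            len(generate_session("S", clean, None, 1000 + i).trials) for i in range(80)
        ]
        expected = clean.duration / (clean.response_time.mean + clean.inter_trial_gap)
        assert np.mean(counts) == pytest.approx(expected, rel=0.05)

    def test_duration_too_short_errors(self, spec):
        tiny = dataclasses.replace(spec, duration=0.5)
        with pytest.raises(DataError):
            generate_session("S01", tiny, None, 0)

    def test_positive_skewness_when_tau_dominates(self, spec):
        rec = generate_session("S01", spec, None, 3)
        assert sample_skewness(rec.trials[:, 1]) > 0
        assert sample_skewness(rec.fixations[:, 1]) > 0


class TestGenerateCohort:
    def test_default_cohort_has_90_recordings(self):
        cohort = generate_cohort(default_workload_config(master_seed=1))
        assert len(cohort) == 90
        assert {r.level_id for r in cohort} == set(LEVELS)

    def test_two_subjects_give_six_recordings(self):
        cohort = generate_cohort(default_workload_config(master_seed=1, n_subjects=2))
        assert len(cohort) == 6

    def test_master_seed_controls_cohort(self):
        a = generate_cohort(default_workload_config(master_seed=1, n_subjects=2))
        b = generate_cohort(default_workload_config(master_seed=1, n_subjects=2))
        c = generate_cohort(default_workload_config(master_seed=2, n_subjects=2))
        assert all(x.equals(y) for x, y in zip(a, b))
        assert not a[0].equals(c[0])

    def test_null_cohort_shares_first_level_generator(self):
        cfg = default_workload_config(master_seed=0, n_subjects=2)
        cohort = null_cohort(cfg)
        assert len(cohort) == 6
        # durations keep their per-level values even though generators match
        assert [r.duration for r in cohort[:3]] == [90.0, 90.0, 180.0]

    def test_subject_effects_induce_intra_subject_consistency(self):
        def factory(sd):
            base = null_config(master_seed=9, n_subjects=25)
            return dataclasses.replace(base, subject_effect_sd=sd)

        def level_corr(cfg):
            cohort = generate_cohort(cfg)
            by = {}
            for rec in cohort:
                by.setdefault(rec.subject_id, {})[rec.level_id] = rec.trials[:, 1].mean()
            lows = [by[s]["low"] for s in by]
            highs = [by[s]["high"] for s in by]
            return np.corrcoef(lows, highs)[0, 1]

        assert level_corr(factory(0.25)) > max(level_corr(factory(0.0)), 0.3)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            default_workload_config(n_subjects=1)
        cfg = default_workload_config()
        with pytest.raises(ParameterError):
            CohortConfig(level_specs=cfg.level_specs[:2] * 1, n_subjects=5)
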