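"""Cohort generator: composition, determinism, and waveform construction."""

import numpy as np
import pytest

from pulseharm.errors import ConfigError
from pulseharm.pipeline import extract_subject_features
from pulseharm.segmentation import segment_beats
from pulseharm.synthetic import (
    AcquisitionConfig,
    CohortConfig,
    TEMPLATE_AMPLITUDES,
    generate_cohort,
    generate_subject_waveforms,
    synthesize_beat,
)

from conftest import make_subject


class TestCohortComposition:
    def test_source_cohort_counts(self):
        cohort = generate_cohort(CohortConfig(seed=0))
        males = [s for s in cohort if s.sex == "male"]
        females = [s for s in cohort if s.sex == "female"]
        assert len(males) == 249 and len(females) == 99
        assert sum(s.is_event for s in males) == 32
        assert sum(s.is_event for s in females) == 13
        assert all(s.syntax_score >= 22 for s in cohort if s.is_event)
        assert all(s.syntax_score < 22 for s in cohort if not s.is_event)

    def test_seeded_determinism(self, small_cohort_config):
        a = generate_cohort(small_cohort_config)
        b = generate_cohort(small_cohort_config)
        for s1, s2 in zip(a, b):
            assert s1.subject_id == s2.subject_id
            assert s1.syntax_score == s2.syntax_score
            np.testing.assert_array_equal(s1.base_amplitudes, s2.base_amplitudes)
            np.testing.assert_array_equal(s1.asym_amplitudes, s2.asym_amplitudes)
            assert s1.seed == s2.seed

    def test_prevalence_mode(self):
        cfg = CohortConfig(
            n_male=200, n_female=0, n_events_male=None, n_events_female=0,
            prevalence_male=0.2, seed=5,
        )
        cohort = generate_cohort(cfg)
        frac = np.mean([s.is_event for s in cohort])
        assert 0.1 < frac < 0.3

    @pytest.mark.parametrize(
        "field,value",
        [
            ("n_events_male", 500),
            ("prevalence_female", 1.5),
            ("syntax_low_range", (1.0, 25.0)),
            ("syntax_high_range", (20.0, 45.0)),
            ("noise_sd", -0.1),
        ],
    )
    def test_invalid_config_names_field(self, field, value):
        kwargs = {field: value}
        if field == "prevalence_female":
            kwargs["n_events_female"] = None
        with pytest.raises(ConfigError, match=field):
            CohortConfig(**kwargs)


class TestSynthesizeBeat:
    def test_single_harmonic_mean_and_ptp(self):
        A = np.zeros(12)
        theta = np.zeros(12)
        A[0], A[1], theta[1] = 5.0, 2.0, 1.0
        beat = synthesize_beat(A, theta, 256)
        assert beat.mean() == pytest.approx(5.0, abs=1e-9)
        assert np.ptp(beat) == pytest.approx(4.0, abs=1e-3)

    def test_all_zero_is_constant_zero(self):
        beat = synthesize_beat(np.zeros(12), np.zeros(12), 64)
        np.testing.assert_array_equal(beat, 0.0)

    def test_wrong_order_count_rejected(self):
        with pytest.raises(ValueError):
            synthesize_beat(np.zeros(11), np.zeros(11), 64)
        with pytest.raises(ValueError):
            synthesize_beat(np.zeros(13), np.zeros(13), 64)

    def test_template_decays_at_high_orders(self):
        assert np.all(np.diff(TEMPLATE_AMPLITUDES[5:]) < 0)


class TestSubjectWaveforms:
    def test_zero_noise_hands_identical(self, clean_subject, acq_60bpm):
        left, right = generate_subject_waveforms(clean_subject, acq_60bpm)
        np.testing.assert_array_equal(left.samples, right.samples)

    def test_expected_beat_count(self, clean_subject, acq_60bpm):
        """60 bpm for 60 s: segmentation finds 55-60 complete beats."""
        left, _ = generate_subject_waveforms(clean_subject, acq_60bpm)
        series = segment_beats(left)
        assert 55 <= series.n_accepted <= 60
        np.testing.assert_allclose(series.periods, 1.0, atol=1.5 / 200.0)

    def test_waveform_determinism(self, acq_60bpm):
        subject = make_subject()
        l1, _ = generate_subject_waveforms(subject, acq_60bpm)
        l2, _ = generate_subject_waveforms(subject, acq_60bpm)
        np.testing.assert_array_equal(l1.samples, l2.samples)

    def test_asymmetry_sign_recovered_downstream(self):
        """A right-hand amplitude offset on order 6 flips ΔC6 = left - right
        to the opposite sign in nearly all seeded subjects."""
        acq = AcquisitionConfig(sampling_rate=100.0, duration=30.0, heart_rate=70.0)
        hits = 0
        n = 100
        for seed in range(n):
            offset = 0.02 if seed % 2 == 0 else -0.02
            asym = np.zeros(12)
            asym[6] = offset
            subject = make_subject(asym_amplitudes=asym, seed=seed)
            left, right = generate_subject_waveforms(subject, acq)
            features = extract_subject_features(left, right)
            if np.sign(features["dC6"]) == -np.sign(offset):
                hits += 1
        assert hits >= 95

    def test_null_effect_calibration(self):
        """With degenerate (zero) asymmetry, signed Δ features are centred:
        |mean| < 3*SE over 200 subjects for representative orders."""
        acq = AcquisitionConfig(sampling_rate=100.0, duration=20.0, heart_rate=70.0)
        cols = ["dC3", "dC6", "dP4", "dD2", "dC5CV"]
        values = {c: [] for c in cols}
        for seed in range(200):
            subject = make_subject(seed=seed)
            left, right = generate_subject_waveforms(subject, acq)
            features = extract_subject_features(left, right)
            for c in cols:
                values[c].append(features[c])
        for c in cols:
            v = np.asarray(values[c])
            se = v.std(ddof=1) / np.sqrt(len(v))
            assert abs(v.mean()) < 3 * se, f"{c}: mean {v.mean():.2e}, SE {se:.2e}"
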