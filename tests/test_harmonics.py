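"""Harmonic decomposition, record summaries, and inter-hand differences."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pulseharm.errors import InsufficientBeatsError
from pulseharm.harmonics import (
    HarmonicBeatMatrix,
    N_ORDERS,
    beat_harmonics,
    circular_mean,
    inter_hand_differences,
    spectral_energy_fraction,
    summarize_record,
    wrap_phase,
)
from pulseharm.synthetic import TEMPLATE_AMPLITUDES, TEMPLATE_PHASES, synthesize_beat

from conftest import make_subject


def _matrix_from_params(amps_per_beat, phases_per_beat, L=256):
    beats = [synthesize_beat(a, p, L) for a, p in zip(amps_per_beat, phases_per_beat)]
    return HarmonicBeatMatrix.from_beats(beats)


class TestBeatHarmonics:
    def test_single_harmonic_closed_form(self):
        L = 256
        x = np.arange(L)
        beat = 5.0 + 2.0 * np.cos(2 * np.pi * x / L - 1.0)
        A, theta, E = beat_harmonics(beat)
        assert A[0] == pytest.approx(5.0, abs=1e-12)
        assert A[1] == pytest.approx(2.0, abs=1e-12)
        assert theta[1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(A[2:] < 1e-10)

    def test_pure_second_harmonic(self):
        L = 256
        x = np.arange(L)
        beat = 3.0 * np.cos(4 * np.pi * x / L)
        A, theta, E = beat_harmonics(beat)
        assert A[2] == pytest.approx(3.0, abs=1e-12)
        assert theta[2] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.delete(A, 2) < 1e-10)

    def test_constant_beat_degenerate(self):
        A, theta, E = beat_harmonics(np.full(64, 2.5))
        assert A[0] == pytest.approx(2.5)
        assert np.all(A[1:] == 0) and np.all(theta == 0)
        assert E[0] == pytest.approx(1.0)

    def test_short_beat_rejected(self):
        with pytest.raises(ValueError):
            beat_harmonics(np.ones(23))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_round_trip_and_parseval(self, seed):
        """Synthesis -> analysis recovers A, theta to 1e-9; energies sum to 1."""
        rng = np.random.default_rng(seed)
        A = rng.uniform(0.05, 2.0, N_ORDERS)
        theta = rng.uniform(-np.pi, np.pi, N_ORDERS)
        theta[0] = 0.0
        beat = synthesize_beat(A, theta, 256)
        A2, theta2, E = beat_harmonics(beat)
        np.testing.assert_allclose(A2, A, atol=1e-9)
        np.testing.assert_allclose(wrap_phase(theta2 - theta), 0.0, atol=1e-9)
        assert np.sum(E) == pytest.approx(1.0, abs=1e-12)

    def test_energy_concentration_of_default_template(self):
        beat = synthesize_beat(TEMPLATE_AMPLITUDES, TEMPLATE_PHASES, 256)
        assert spectral_energy_fraction(beat, max_order=11) >= 0.98


class TestSummarizeRecord:
    def test_identical_beats_have_zero_cv(self):
        amps = [TEMPLATE_AMPLITUDES] * 6
        phases = [TEMPLATE_PHASES] * 6
        summary = summarize_record(_matrix_from_params(amps, phases))
        assert np.all(summary.C_cv == pytest.approx(0.0, abs=1e-9))
        assert np.all(summary.P_cv == pytest.approx(0.0, abs=1e-7))
        assert np.all(summary.D_cv == pytest.approx(0.0, abs=1e-9))

    def test_amplitude_cv_two_beats(self):
        """a(3,.) = {1, 3} -> C3 = 2 and C3CV = sqrt(2)/2."""
        base = np.zeros(N_ORDERS)
        base[0] = 1.0
        a1, a2 = base.copy(), base.copy()
        a1[3], a2[3] = 1.0, 3.0
        matrix = _matrix_from_params([a1, a2], [np.zeros(N_ORDERS)] * 2)
        summary = summarize_record(matrix, min_beats=2)
        assert summary.C[3] == pytest.approx(2.0, abs=1e-9)
        assert summary.C_cv[3] == pytest.approx(np.sqrt(2) / 2, abs=1e-9)

    def test_circular_mean_near_pi(self):
        """Phases +3.1 and -3.1 average to ±pi, not 0."""
        mu = circular_mean(np.array([3.1, -3.1]))
        assert abs(abs(mu) - np.pi) < 1e-9

    def test_summary_phase_uses_circular_mean(self):
        amps = np.tile(TEMPLATE_AMPLITUDES, (6, 1))
        phases = np.tile(TEMPLATE_PHASES, (6, 1))
        phases[:, 4] = [3.1, -3.1, 3.05, -3.05, 3.12, -3.12]
        matrix = _matrix_from_params(amps, phases)
        summary = summarize_record(matrix)
        assert abs(abs(summary.P[4]) - np.pi) < 0.05

    def test_too_few_beats(self):
        amps = [TEMPLATE_AMPLITUDES] * 3
        with pytest.raises(InsufficientBeatsError):
            summarize_record(_matrix_from_params(amps, [TEMPLATE_PHASES] * 3))

    def test_scale_invariance(self, rng):
        """Multiplying the record by any c > 0 leaves all indices unchanged."""
        amps = TEMPLATE_AMPLITUDES * np.exp(rng.normal(0, 0.05, (6, N_ORDERS)))
        phases = np.tile(TEMPLATE_PHASES, (6, 1))
        s1 = summarize_record(_matrix_from_params(list(amps), list(phases)))
        s2 = summarize_record(_matrix_from_params(list(amps * 7.3), list(phases)))
        for attr in ("C", "P", "D", "C_cv", "P_cv", "D_cv"):
            np.testing.assert_allclose(
                getattr(s1, attr), getattr(s2, attr), atol=1e-9
            )

    def test_ground_truth_recovery_beat_level(self):
        """Noiseless beats from a subject reproduce its analytic summary."""
        from pulseharm.synthetic import ground_truth_summary

        subject = make_subject(asym_amplitudes=np.full(12, 0.003))
        for hand in ("left", "right"):
            amps, phases = subject.hand_harmonics(hand)
            matrix = _matrix_from_params([amps] * 6, [phases] * 6)
            got = summarize_record(matrix)
            want = ground_truth_summary(subject, hand)
            np.testing.assert_allclose(got.C, want.C, atol=1e-9)
            np.testing.assert_allclose(got.D, want.D, atol=1e-9)
            np.testing.assert_allclose(
                wrap_phase(got.P[1:] - want.P[1:]), 0.0, atol=1e-9
            )


class TestInterHandDifferences:
    def _summary(self):
        amps = [TEMPLATE_AMPLITUDES] * 6
        phases = [TEMPLATE_PHASES] * 6
        return summarize_record(_matrix_from_params(amps, phases))

    def test_simple_difference(self):
        left = self._summary()
        right = self._summary()
        left.C[6], right.C[6] = 0.50, 0.30
        fv = inter_hand_differences(left, right)
        assert fv.dC[6] == pytest.approx(0.20)
        assert abs(fv.dC[6]) == pytest.approx(0.20)

    def test_antisymmetry(self, rng):
        left, right = self._summary(), self._summary()
        left.C += rng.normal(0, 0.01, N_ORDERS)
        right.P[1:] += rng.normal(0, 0.1, N_ORDERS - 1)
        fwd = inter_hand_differences(left, right)
        rev = inter_hand_differences(right, left)
        for (_, a), (_, b) in zip(fwd.signed_items(), rev.signed_items()):
            np.testing.assert_allclose(a, -b, atol=1e-12)

    def test_phase_difference_wraps(self):
        """P4 of +3.0 vs -3.0 differs by -(2pi - 6), not 6."""
        left, right = self._summary(), self._summary()
        left.P[4], right.P[4] = 3.0, -3.0
        fv = inter_hand_differences(left, right)
        assert fv.dP[4] == pytest.approx(6.0 - 2 * np.pi, abs=1e-12)
        assert fv.dP[4] == pytest.approx(-0.28319, abs=1e-5)

    def test_feature_dict_naming(self):
        left, right = self._summary(), self._summary()
        d = inter_hand_differences(left, right).as_dict()
        assert set(["dC6", "absdC6", "dP1CV", "absdC10", "dD9", "dD3CV"]) <= set(d)
        for name in d:
            if name.startswith("abs"):
                assert d[name] == abs(d[name[3:]])
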