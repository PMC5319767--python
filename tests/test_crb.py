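"""Fisher information / CRB: closed form vs matrix-inverse and score oracles."""

import math

import numpy as np
import pytest

from relaxdesign import (
    PulseEvent,
    PulseKind,
    PulseSequence,
    crb_t1,
    decompose_crb,
    fisher_information,
    relative_error_curve,
    sensitivity_vector,
)
from relaxdesign.crb import DegenerateModelError, sensitivity_matrix
from relaxdesign.sequence_model import weighting_matrix


def random_pairs(n, rng, dim=3):
    for _ in range(n):
        yield rng.normal(size=dim), rng.normal(size=dim) * rng.uniform(1e-4, 1e-2)


class TestSensitivity:
    def test_zero_flip_sequence_has_zero_sensitivity(self):
        seq = PulseSequence(
            tr_ms=1000.0, events=(PulseEvent(0.0, 0.0, PulseKind.IMAGING),)
        )
        np.testing.assert_array_equal(sensitivity_vector(seq, 1500.0), [0.0])

    def test_saturated_single_pulse_insensitive(self):
        """TR >> T1: h = sin(alpha) regardless of T1, so dh/dT1 -> 0."""
        seq = PulseSequence(
            tr_ms=1e6, events=(PulseEvent(0.0, 60.0, PulseKind.IMAGING),)
        )
        assert abs(sensitivity_vector(seq, 100.0)[0]) < 1e-12

    def test_central_difference_matches_higher_order_stencil(self, tsi_new):
        """2nd-order central difference vs 5-point 4th-order stencil."""
        t1 = 1500.0
        rel = 1e-4
        h = rel * t1
        w = lambda x: weighting_matrix(tsi_new, np.array([x]))[0]
        stencil = (-w(t1 + 2 * h) + 8 * w(t1 + h) - 8 * w(t1 - h) + w(t1 - 2 * h)) / (12 * h)
        np.testing.assert_allclose(
            sensitivity_vector(tsi_new, t1, rel), stencil, rtol=1e-6
        )

    def test_rejects_out_of_range_step(self, tsi_new):
        with pytest.raises(ValueError):
            sensitivity_vector(tsi_new, 1500.0, rel_step=0.5)


class TestFisherInformation:
    def test_inverse_square_sigma_scaling(self):
        rng = np.random.default_rng(3)
        h, dh = rng.normal(size=4), rng.normal(size=4)
        a = fisher_information(h, dh, m0=3000.0, sigma=2.0)
        b = fisher_information(h, dh, m0=3000.0, sigma=20.0)
        for name in ("i11", "i12", "i22"):
            assert getattr(b, name) == pytest.approx(getattr(a, name) / 100.0, rel=1e-12)

    def test_insensitive_model_zeroes_t1_entries(self):
        fim = fisher_information(np.array([0.5, -0.2]), np.zeros(2), 3000.0, 24.0)
        assert fim.i12 == 0.0 and fim.i22 == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fisher_information(np.ones(3), np.ones(2), 1.0, 1.0)

    def test_matches_score_function_quadrature_oracle(self):
        """FIM entries equal E[score score'] integrated against the Gaussian.

        For independent Gaussian samples the expectation over each s_i is a
        1-D integral, evaluated here by Gauss-Hermite quadrature of the
        score outer product -- fully independent of the closed-form sums.
        """
        rng = np.random.default_rng(11)
        h = rng.normal(size=3)
        dh = rng.normal(size=3) * 1e-3
        m0, sigma = 2500.0, 20.0
        nodes, weights = np.polynomial.hermite_e.hermegauss(40)
        fim_num = np.zeros((2, 2))
        for hi, dhi in zip(h, dh):
            # s_i = m0*hi + sigma*z, z ~ N(0,1); score of N(m0*hi, sigma^2)
            # d/dM0 ln p = (s - m0 hi) hi / sigma^2 ; d/dT1 adds m0 dhi
            for z, wgt in zip(nodes, weights):
                resid = sigma * z
                g = np.array([resid * hi / sigma**2, resid * m0 * dhi / sigma**2])
                fim_num += (wgt / math.sqrt(2 * math.pi)) * np.outer(g, g)
        fim = fisher_information(h, dh, m0, sigma)
        np.testing.assert_allclose(fim.as_matrix(), fim_num, rtol=1e-10)


class TestCRB:
    def test_parallel_vectors_unidentifiable(self):
        h = np.array([0.3, -0.1, 0.2])
        fim = fisher_information(h, 5.0 * h, 3000.0, 24.0)
        assert crb_t1(fim) == math.inf

    def test_orthogonal_case_closed_form(self):
        h = np.array([1.0, 0.0])
        dh = np.array([0.0, 2e-4])
        m0, sigma = 3000.0, 24.0
        snr = m0 / sigma
        assert crb_t1(fisher_information(h, dh, m0, sigma)) == pytest.approx(
            (snr * np.linalg.norm(dh)) ** -2, rel=1e-12
        )

    def test_closed_form_equals_matrix_inverse(self):
        """Schur-complement formula vs brute-force 2x2 inverse, 500 instances."""
        rng = np.random.default_rng(2024)
        for h, dh in random_pairs(500, rng):
            fim = fisher_information(h, dh, 3000.0, 24.0)
            inv22 = np.linalg.inv(fim.as_matrix())[1, 1]
            assert crb_t1(fim) == pytest.approx(inv22, rel=1e-12)

    def test_zero_signal_is_degenerate(self):
        fim = fisher_information(np.zeros(3), np.ones(3), 1.0, 1.0)
        with pytest.raises(DegenerateModelError):
            crb_t1(fim)


class TestDecomposition:
    def test_geometric_identity_on_random_pairs(self):
        """(SNR ||dh|| sin phi)^-2 == [I^-1]_22 on 500 random pairs."""
        rng = np.random.default_rng(77)
        m0, sigma = 3000.0, 24.0
        for h, dh in random_pairs(500, rng):
            report = decompose_crb(h, dh, snr=m0 / sigma)
            direct = crb_t1(fisher_information(h, dh, m0, sigma))
            assert report.crb_t1 == pytest.approx(direct, rel=1e-10)

    def test_principal_angle_extremes(self):
        h = np.array([1.0, 1.0])
        assert decompose_crb(h, 3.0 * h, snr=100.0).orthogonality == 0.0
        assert decompose_crb(h, np.array([1.0, -1.0]), snr=100.0).orthogonality == pytest.approx(1.0)

    def test_scale_invariance_in_m0_and_sigma(self):
        rng = np.random.default_rng(5)
        h, dh = rng.normal(size=3), rng.normal(size=3) * 1e-3
        a = crb_t1(fisher_information(h, dh, 3000.0, 24.0))
        b = crb_t1(fisher_information(h, dh, 30000.0, 240.0))
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_weighting_rejected(self):
        with pytest.raises(DegenerateModelError):
            decompose_crb(np.zeros(3), np.ones(3), snr=100.0)

    def test_report_consistency(self, tsi_new):
        t1 = 1500.0
        h = weighting_matrix(tsi_new, np.array([t1]))[0]
        dh = sensitivity_vector(tsi_new, t1)
        rep = decompose_crb(h, dh, snr=125.0, t1_ms=t1)
        assert rep.relative_error == pytest.approx(math.sqrt(rep.crb_t1) / t1, rel=1e-12)
        assert 0.0 <= rep.orthogonality <= 1.0


class TestRelativeErrorCurve:
    def test_snr_doubling_halves_curve(self, tsi_new):
        grid = np.array([700.0, 1500.0, 5000.0])
        a = relative_error_curve(tsi_new, grid, 125.0)
        b = relative_error_curve(tsi_new, grid, 250.0)
        np.testing.assert_allclose(b, a / 2.0, rtol=1e-12)

    def test_single_point_reduces_to_decomposition(self, tsi_new):
        t1 = 1500.0
        curve = relative_error_curve(tsi_new, np.array([t1]), 125.0)
        h = weighting_matrix(tsi_new, np.array([t1]))[0]
        rep = decompose_crb(h, sensitivity_vector(tsi_new, t1), 125.0, t1_ms=t1)
        assert curve[0] == pytest.approx(rep.relative_error, rel=1e-9)

    def test_empty_grid_rejected(self, tsi_new):
        with pytest.raises(ValueError):
            relative_error_curve(tsi_new, np.array([]), 125.0)

    def test_crb_monotone_in_sensitivity_magnitude(self):
        """Growing |dh_i| with h and <h,dh> fixed shrinks the bound."""
        h = np.array([1.0, 0.5, 0.0])
        dh = np.array([1e-3, -2e-3, 1e-3])
        base = crb_t1(fisher_information(h, dh, 3000.0, 24.0))
        # grow the component orthogonal to h (keeps h.dh fixed)
        dh2 = dh + np.array([0.0, 0.0, 5e-3])
        assert crb_t1(fisher_information(h, dh2, 3000.0, 24.0)) < base

    def test_matrix_sensitivity_matches_vector(self, tsi_new):
        grid = np.array([800.0, 2000.0])
        M = sensitivity_matrix(tsi_new, grid)
        for k, t1 in enumerate(grid):
            np.testing.assert_allclose(M[k], sensitivity_vector(tsi_new, t1), rtol=1e-12)
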