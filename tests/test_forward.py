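import numpy as np
import pytest
from scipy.special import erf

from neuritemap import (
    TissueParams,
    brute_force_signal,
    delta_odf_coeffs,
    isotropic_odf_coeffs,
    kernel_coeffs,
    predict_signal,
    sh_basis,
    watson_odf_coeffs,
)
from neuritemap.forward import F00, n_coeffs, sh_orders

from conftest import random_rotation


def fibonacci_sphere(n):
    i = np.arange(n) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n
    r = np.sqrt(1 - z**2)
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


class TestShBasis:
    @pytest.mark.parametrize("l_max,expected", [(0, 1), (2, 6), (4, 15)])
    def test_column_count(self, l_max, expected):
        y = sh_basis(np.array([[0.0, 0.0, 1.0]]), l_max)
        assert y.shape == (1, expected)
        assert n_coeffs(l_max) == expected

    def test_constant_harmonic(self, rng):
        v = rng.normal(size=(20, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        np.testing.assert_allclose(sh_basis(v, 4)[:, 0], F00, rtol=1e-12)

    def test_north_pole_l2m0(self):
        y = sh_basis(np.array([[0.0, 0.0, 1.0]]), 2)
        col = sh_orders(2).index((2, 0))
        assert y[0, col] == pytest.approx(2 * np.sqrt(5 / (16 * np.pi)), rel=1e-12)

    def test_orthonormality(self):
        from neuritemap.forward import _sphere_quadrature

        pts, w = _sphere_quadrature(20_000)
        y = sh_basis(pts, 4)
        gram = (y * w[:, None]).T @ y
        np.testing.assert_allclose(gram, np.eye(15), atol=1e-3)

    def test_odd_lmax_rejected(self):
        with pytest.raises(ValueError, match="even"):
            sh_basis(np.array([[0.0, 0.0, 1.0]]), 3)

    def test_non_unit_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            sh_basis(np.array([[0.0, 0.0, 2.0]]), 2)


class TestKernelCoeffs:
    def test_alpha_zero(self):
        k = kernel_coeffs(0.0, 4)
        np.testing.assert_allclose(k, [4 * np.pi, 0.0, 0.0], atol=1e-12)

    def test_alpha_one_closed_form(self):
        k0 = kernel_coeffs(1.0, 0)[0]
        assert k0 == pytest.approx(2 * np.pi * np.sqrt(np.pi) * erf(1.0), rel=1e-12)

    def test_alpha_ten_vs_trapezoid(self):
        # brute-force 1e5-point trapezoid quadrature oracle
        t = np.linspace(-1, 1, 100_001)
        f = np.exp(-10.0 * t**2)
        k = kernel_coeffs(10.0, 4)
        for i, l in enumerate((0, 2, 4)):
            p = np.polynomial.legendre.Legendre.basis(l)(t)
            oracle = 2 * np.pi * np.trapezoid(f * p, t)
            assert k[i] == pytest.approx(oracle, rel=1e-8)

    def test_negative_alpha_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            kernel_coeffs(-0.1, 4)

    def test_k0_dominates(self, rng):
        alphas = rng.uniform(0.0, 60.0, 50)
        k = kernel_coeffs(alphas, 4)
        assert np.all(np.abs(k[:, 1:]) <= k[:, [0]] + 1e-12)

    def test_vectorized_matches_scalar(self, rng):
        alphas = rng.uniform(0.0, 30.0, 7)
        k = kernel_coeffs(alphas, 4)
        for i, a in enumerate(alphas):
            np.testing.assert_allclose(k[i], kernel_coeffs(float(a), 4), rtol=1e-14)


class TestTissueParams:
    def test_invariants(self):
        with pytest.raises(ValueError, match="nu"):
            TissueParams(1.0, 1.5, 1e-3, 1e-3, 1e-4)
        with pytest.raises(ValueError, match="d_trans"):
            TissueParams(1.0, 0.5, 1e-3, 1e-4, 1e-3)
        with pytest.raises(ValueError, match="f_00"):
            TissueParams(1.0, 0.5, 1e-3, 1e-3, 1e-4, odf_coeffs=np.zeros(15))

    def test_f00_normalization(self):
        p = TissueParams(1.0, 0.5, 1e-3, 1e-3, 1e-4, isotropic_odf_coeffs(4))
        assert p.odf_coeffs[0] == pytest.approx(F00)
        assert p.l_max == 4


class TestPredictSignal:
    def test_pure_isotropic_single_exponential(self, scheme):
        p = TissueParams(1.0, 0.0, 1e-3, 1.2e-3, 0.1e-3, isotropic_odf_coeffs(4))
        s = predict_signal(p, scheme)
        b2000 = scheme.b_values == 2000
        np.testing.assert_allclose(s[b2000], np.exp(-2.0), rtol=1e-12)

    def test_isotropic_odf_closed_form(self, scheme):
        p = TissueParams(1.0, 1.0, 1e-3, 1.5e-3, 0.2e-3, isotropic_odf_coeffs(4))
        s = predict_signal(p, scheme)
        shell = scheme.b_values == 3000
        delta_d = 1.3e-3
        arg = 3000 * delta_d
        closed = np.exp(-3000 * 0.2e-3) * np.sqrt(np.pi) * erf(np.sqrt(arg)) / (2 * np.sqrt(arg))
        np.testing.assert_allclose(s[shell], closed, rtol=1e-10)
        assert s[shell].std() < 1e-14  # direction independence

    def test_b0_returns_s0(self, scheme, rng):
        p = TissueParams(
            2.7, 0.6, 0.9e-3, 1.4e-3, 0.2e-3, watson_odf_coeffs(rng.normal(size=3), 4.0, 4)
        )
        s = predict_signal(p, scheme)
        np.testing.assert_allclose(s[scheme.b0_mask], 2.7, rtol=1e-12)

    def test_positive_everywhere(self, scheme, rng):
        for _ in range(20):
            p = TissueParams(
                1.0,
                rng.uniform(0, 1),
                rng.uniform(0.2e-3, 2e-3),
                rng.uniform(0.5e-3, 2.5e-3),
                rng.uniform(0.0, 0.4e-3),
                watson_odf_coeffs(rng.normal(size=3), rng.uniform(0, 4), 4),
            )
            assert np.all(predict_signal(p, scheme) > 0)

    def test_shell_mean_non_increasing(self, scheme, rng):
        # every shell must sample the same directions for its mean to track
        # the orientation average; reuse the full packaged set on each shell
        from neuritemap.acquisition import AcquisitionScheme
        from neuritemap._directions import DIRECTIONS54

        bvals = np.unique(scheme.b_values)
        dense = AcquisitionScheme(
            np.repeat(bvals, 54), np.tile(DIRECTIONS54, (bvals.size, 1))
        )
        for _ in range(5):
            p = TissueParams(
                1.0,
                rng.uniform(0, 1),
                rng.uniform(0.2e-3, 2e-3),
                rng.uniform(0.5e-3, 2.5e-3),
                rng.uniform(0.0, 0.4e-3),
                watson_odf_coeffs(rng.normal(size=3), rng.uniform(0, 4), 4),
            )
            s = predict_signal(p, dense)
            means = [s[dense.b_values == b].mean() for b in bvals]
            assert np.all(np.diff(means) <= 1e-12)

    def test_monotone_in_nu_at_high_b(self, scheme):
        # isotropic pool decays faster than the neurite pool at high b
        odf = watson_odf_coeffs([0, 0, 1], 4.0, 4)
        high = scheme.b_values == 15000
        prev = None
        for nu in (0.1, 0.3, 0.5, 0.7, 0.9):
            s = predict_signal(TissueParams(1.0, nu, 1.5e-3, 1.2e-3, 0.05e-3, odf), scheme)
            mean_high = s[high].mean()
            if prev is not None:
                assert mean_high > prev
            prev = mean_high

    def test_rotation_invariance(self, scheme, rng):
        # rotating gradients together with the ODF leaves the signal unchanged
        from neuritemap.acquisition import AcquisitionScheme

        for _ in range(5):
            rot = random_rotation(rng)
            axis = rng.normal(size=3)
            axis /= np.linalg.norm(axis)
            p = TissueParams(1.0, 0.55, 0.7e-3, 1.3e-3, 0.1e-3, delta_odf_coeffs(axis, 4))
            p_rot = TissueParams(1.0, 0.55, 0.7e-3, 1.3e-3, 0.1e-3, delta_odf_coeffs(rot @ axis, 4))
            rotated = AcquisitionScheme(
                scheme.b_values, scheme.directions @ rot.T, scheme.big_delta, scheme.small_delta
            )
            np.testing.assert_allclose(
                predict_signal(p, scheme), predict_signal(p_rot, rotated), atol=1e-6
            )


class TestBruteForceOracle:
    def test_isotropic_matches_closed_form(self, scheme):
        p = TissueParams(1.0, 1.0, 1e-3, 1.5e-3, 0.2e-3, isotropic_odf_coeffs(4))
        bf = brute_force_signal(p, scheme, 10_000)
        shell = scheme.b_values == 3000
        arg = 3000 * 1.3e-3
        closed = np.exp(-3000 * 0.2e-3) * np.sqrt(np.pi) * erf(np.sqrt(arg)) / (2 * np.sqrt(arg))
        np.testing.assert_allclose(bf[shell], closed, rtol=1e-5)

    def test_truncated_delta_matches_spectral(self, scheme):
        # gradient battery includes directions ~perpendicular to the axis;
        # the l_max=4 truncated delta rings negative, so lift the floor check
        p = TissueParams(1.0, 0.7, 0.7e-3, 1.2e-3, 0.1e-3, delta_odf_coeffs([0, 0, 1.0], 4))
        spectral = predict_signal(p, scheme)
        bf = brute_force_signal(p, scheme, 20_000, odf_floor=None)
        np.testing.assert_allclose(bf, spectral, rtol=1e-4)

    def test_nu_zero_identical(self, scheme):
        p = TissueParams(1.0, 0.0, 1e-3, 1.2e-3, 0.1e-3, isotropic_odf_coeffs(4))
        np.testing.assert_array_equal(
            brute_force_signal(p, scheme, 5_000), predict_signal(p, scheme)
        )

    def test_negative_odf_rejected(self, scheme):
        p = TissueParams(1.0, 0.7, 0.7e-3, 1.2e-3, 0.1e-3, delta_odf_coeffs([0, 0, 1.0], 4))
        with pytest.raises(ValueError, match="negative"):
            brute_force_signal(p, scheme, 5_000)

    def test_random_draw_equivalence(self, scheme, rng):
        # spectral vs quadrature on 30 random valid draws (full 100 in the
        # acceptance suite)
        for _ in range(30):
            kappa = rng.uniform(0.0, 4.0)
            p = TissueParams(
                rng.uniform(0.5, 2.0),
                rng.uniform(0.0, 1.0),
                rng.uniform(0.2e-3, 2e-3),
                rng.uniform(0.5e-3, 2.5e-3),
                rng.uniform(0.0, 0.4e-3),
                watson_odf_coeffs(rng.normal(size=3), kappa, 4),
            )
            s = predict_signal(p, scheme)
            bf = brute_force_signal(p, scheme, 10_000)
            np.testing.assert_allclose(bf, s, rtol=1e-4)
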