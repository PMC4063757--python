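import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from qbtrack.formats import GradientTable
from qbtrack.phantom import (DEFAULT_FIBER_EVALS, make_gradient_table,
                             multi_tensor_signal, tensor_from_axis)
from qbtrack.qball import (ContractError, SHCoefficients,
                           build_design_matrix, csa_odf, double_log_transform,
                           evaluate_sh, fa_from_evals, fit_signal_sh,
                           fit_tensor_fa, real_sym_sh_basis, sh_degrees)
from qbtrack.reference import reference_csa_odf
from qbtrack.sphere import angle_between_axes

from conftest import BVAL, S0, tensor_signal, voxel_dwi


class TestDesignMatrix:
    def test_shape_for_acquisition_scheme(self, gtab):
        B = build_design_matrix(gtab, L=4)
        assert B.shape == (55, 15)

    def test_order_zero_is_constant_y00(self, gtab):
        B = build_design_matrix(gtab, L=0)
        assert B.shape == (55, 1)
        assert np.allclose(B, 1.0 / np.sqrt(4 * np.pi))

    def test_underdetermined_rejected(self):
        g = make_gradient_table(n_dirs=20, seed=1)
        with pytest.raises(ContractError):
            build_design_matrix(g, L=6)  # 28 coefficients, 20 directions

    def test_basis_is_orthonormal_under_quadrature(self):
        # Gauss-Legendre x uniform-phi product rule: exact for order-4 pairs
        x, w = np.polynomial.legendre.leggauss(16)
        phi = np.arange(32) * 2 * np.pi / 32
        theta = np.arccos(x)
        tt, pp = np.meshgrid(theta, phi, indexing="ij")
        dirs = np.stack([np.sin(tt) * np.cos(pp), np.sin(tt) * np.sin(pp),
                         np.cos(tt)], axis=-1).reshape(-1, 3)
        weights = np.repeat(w, 32) * (2 * np.pi / 32)
        B = real_sym_sh_basis(4, dirs)
        gram = (B * weights[:, None]).T @ B
        assert np.allclose(gram, np.eye(15), atol=1e-12)

    def test_pure_harmonic_reproduced_exactly(self, gtab):
        # a function lying in the span of the basis is fit without residual
        B = build_design_matrix(gtab, L=4)
        k = sh_degrees(4).index((2, 0))
        y = B[:, k] * 3.7
        coeffs = np.linalg.pinv(B) @ y
        expect = np.zeros(15)
        expect[k] = 3.7
        assert np.allclose(coeffs, expect, atol=1e-10)


class TestSignalFit:
    def test_isotropic_signal_has_no_anisotropic_terms(self, gtab):
        d = 0.9e-3
        sig = multi_tensor_signal(gtab.bvecs, BVAL, [1.0], [d * np.eye(3)],
                                  S0=S0)
        sig[gtab.b0_mask] = S0
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        assert np.allclose(fit.sh.coeffs[0, 0, 0, 1:], 0.0, atol=1e-10)

    def test_single_tensor_fit_predicts_held_out_directions(self, gtab):
        D = tensor_from_axis([0.0, 0, 1.0], DEFAULT_FIBER_EVALS)
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        rng = np.random.default_rng(11)
        held = rng.normal(size=(100, 3))
        held /= np.linalg.norm(held, axis=1)[:, None]
        quad = np.einsum("ij,jk,ik->i", held, D, held)
        truth = np.log(-np.log(np.exp(-BVAL * quad)))
        pred = evaluate_sh(fit.sh, held)[0, 0, 0]
        # order-4 truncation error of the double-log of a prolate tensor;
        # bound frozen from the closed-form oracle evaluation
        rmse = np.sqrt(np.mean((pred - truth) ** 2))
        assert rmse < 0.04

    def test_unattenuated_direction_is_clamped(self, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        sig[~gtab.b0_mask][0] = S0  # E = 1 at one direction
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        assert np.all(np.isfinite(fit.sh.coeffs))

    def test_zero_signal_voxel_flagged_invalid(self, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        data = np.tile(sig, (2, 1, 1, 1))
        data[1, 0, 0] = 0.0
        from qbtrack.formats import DWIVolume, ImageGrid

        dwi = DWIVolume(data, ImageGrid.isotropic((2, 1, 1), 2.2), gtab)
        fit = fit_signal_sh(dwi)
        assert fit.valid[0, 0, 0] and not fit.valid[1, 0, 0]

    def test_residuals_plus_fitted_reproduce_transformed_signal(self, gtab):
        rng = np.random.default_rng(4)
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        noisy = sig * rng.uniform(0.95, 1.05, size=sig.shape)
        noisy[gtab.b0_mask] = S0
        fit = fit_signal_sh(voxel_dwi(noisy, gtab))
        E = np.clip(noisy[~gtab.b0_mask] / S0, 1e-3, 1 - 1e-3)
        y = np.log(-np.log(E))
        assert np.allclose(fit.transformed[0, 0, 0], y, atol=1e-12)

    def test_double_log_clamp_contract(self):
        y = double_log_transform(np.array([0.0, 1.0, 0.5]))
        assert np.all(np.isfinite(y))


class TestCsaOdf:
    def test_isotropic_input_gives_uniform_odf(self, gtab, sphere):
        sig = np.full(gtab.n_volumes, S0 * np.exp(-BVAL * 0.9e-3))
        sig[gtab.b0_mask] = S0
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        odf = evaluate_sh(csa_odf(fit.sh), sphere.vertices)[0, 0, 0]
        assert np.allclose(odf, 1.0 / (4 * np.pi), atol=1e-9)

    def test_unit_integral_for_random_voxels(self, gtab, sphere):
        rng = np.random.default_rng(7)
        for _ in range(10):
            axes = rng.normal(size=(2, 3))
            axes /= np.linalg.norm(axes, axis=1)[:, None]
            sig = tensor_signal(gtab, axes)
            fit = fit_signal_sh(voxel_dwi(sig, gtab))
            odf = evaluate_sh(csa_odf(fit.sh), sphere.vertices)[0, 0, 0]
            assert abs(sphere.integrate(odf) - 1.0) <= 1e-3

    def test_single_fiber_argmax_points_along_fiber(self, gtab, sphere):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        odf = evaluate_sh(csa_odf(fit.sh), sphere.vertices)[0, 0, 0]
        peak = sphere.vertices[np.argmax(odf)]
        assert angle_between_axes(peak, [0.0, 0, 1.0]) <= 3.0

    def test_antipodal_symmetry(self, gtab, sphere):
        sig = tensor_signal(gtab, [[1.0, 1.0, 0.2]])
        fit = fit_signal_sh(voxel_dwi(sig, gtab))
        odf = evaluate_sh(csa_odf(fit.sh), sphere.vertices)[0, 0, 0]
        assert np.abs(odf - odf[sphere.antipode]).max() < 1e-12

    def test_rotational_equivariance(self, gtab, sphere):
        R = Rotation.from_euler("zyx", [40, 25, 10], degrees=True).as_matrix()
        axis = np.array([0.0, 0, 1.0])
        sig = tensor_signal(gtab, [axis])
        rot_gtab = GradientTable(gtab.bvals, gtab.bvecs @ R.T)
        sig_rot = tensor_signal(rot_gtab, [R @ axis])
        for g, s, ax in ((gtab, sig, axis), (rot_gtab, sig_rot, R @ axis)):
            fit = fit_signal_sh(voxel_dwi(s, g))
            odf = evaluate_sh(csa_odf(fit.sh), sphere.vertices)[0, 0, 0]
            peak = sphere.vertices[np.argmax(odf)]
            assert angle_between_axes(peak, ax) <= 3.0

    def test_wrong_basis_tag_rejected(self, gtab):
        fit = fit_signal_sh(voxel_dwi(tensor_signal(gtab, [[0, 0, 1.0]]),
                                      gtab))
        bad = SHCoefficients(fit.sh.coeffs, fit.sh.L, basis="other")
        with pytest.raises(ContractError):
            csa_odf(bad)

    def test_matches_independent_reference(self, gtab, sphere):
        """Closed-form SH route vs numerical Funk-Radon quadrature route."""
        rng = np.random.default_rng(21)
        eval_dirs = sphere.vertices[rng.choice(sphere.n_vertices, 25,
                                               replace=False)]
        for _ in range(5):
            axes = rng.normal(size=(2, 3))
            axes /= np.linalg.norm(axes, axis=1)[:, None]
            sig = tensor_signal(gtab, axes)
            fit = fit_signal_sh(voxel_dwi(sig, gtab))
            mine = evaluate_sh(csa_odf(fit.sh), eval_dirs)[0, 0, 0]
            ref = reference_csa_odf(sig[~gtab.b0_mask], S0, gtab.gradients,
                                    eval_dirs)
            assert np.abs(mine - ref).max() <= 1e-6


class TestTensorFa:
    def test_isotropic_fa_zero(self, gtab):
        sig = np.full(gtab.n_volumes, S0 * np.exp(-BVAL * 0.9e-3))
        sig[gtab.b0_mask] = S0
        fa = fit_tensor_fa(voxel_dwi(sig, gtab))
        assert abs(fa.values[0, 0, 0]) <= 1e-6

    def test_stick_limit_fa_one(self):
        assert abs(fa_from_evals(np.array([1.0, 0.0, 0.0])) - 1.0) <= 1e-6

    def test_prolate_tensor_matches_closed_form(self, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        fa = fit_tensor_fa(voxel_dwi(sig, gtab))
        lam = DEFAULT_FIBER_EVALS
        expect = np.sqrt(1.5 * np.sum((lam - lam.mean()) ** 2)
                         / np.sum(lam ** 2))
        assert abs(fa.values[0, 0, 0] - expect) <= 1e-6

    def test_nonpositive_signal_gives_zero_fa(self, gtab):
        sig = tensor_signal(gtab, [[0.0, 0, 1.0]])
        sig[-1] = 0.0
        fa = fit_tensor_fa(voxel_dwi(sig, gtab))
        assert fa.values[0, 0, 0] == 0.0
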