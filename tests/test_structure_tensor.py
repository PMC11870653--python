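"""Structure tensor: filtering, eigen-decomposition, γ conversion, FA,
scale selection, and the physical kernel-size bookkeeping."""

import numpy as np
import pytest

from fibrest import (ImageVolume, PhantomSpec, ScaleParams, analyse_volume,
                     build_parallel_fibre_volume, compute_structure_tensor,
                     convert_eigenvalues, eigendecompose_field,
                     fractional_anisotropy, kernel_size_um, scale_space_select)
from fibrest.phantoms import acute_angle_deg
from fibrest.structure_tensor import EigenField, TensorField
from fibrest.validation import separable_vs_brute_force


class TestKernelSize:
    @pytest.mark.parametrize("rho,vox,factor,printed", [
        (2.5, 550.0, 2, 12.0),
        (5.5, 100.0, 4, 9.2),
        (1.0, 100.0, 4, 2.0),
        (4.0, 550.0, 2, 18.7),
        (6.0, 75.0, 5, 9.4),
    ])
    def test_reference_kernel_sizes(self, rho, vox, factor, printed):
        assert kernel_size_um(rho, vox, factor) == pytest.approx(printed,
                                                                 rel=0.01)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            kernel_size_um(0.0, 100.0, 1)


class TestComputeStructureTensor:
    def test_constant_volume_zero_tensor(self):
        vol = ImageVolume(np.full((24, 24, 24), 3.0), 1000.0)
        tf = compute_structure_tensor(vol, 1.0, 2.0)
        assert np.allclose(tf.components, 0.0)
        ef = eigendecompose_field(tf)
        assert ef.zero_mask.all()

    def test_tube_interior_direction(self, parallel_small,
                                     parallel_small_eigen):
        _, _, truth = parallel_small
        eigen, _ = parallel_small_eigen
        interior = truth.interior_mask(1.0) & ~eigen.border_mask()
        ang = acute_angle_deg(eigen.principal_direction()[interior],
                              truth.orientation[interior])
        assert np.quantile(ang, 0.99) < 5.0

    def test_psd_within_tolerance(self, rng):
        vol = ImageVolume(rng.uniform(size=(20, 20, 20)), 1000.0)
        tf = compute_structure_tensor(vol, 1.0, 1.5)
        w = np.linalg.eigvalsh(tf.matrices())
        assert w.min() > -1e-10 * np.abs(w).max()

    def test_too_small_volume_names_minimum(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), 1000.0)
        with pytest.raises(ValueError, match="at least"):
            compute_structure_tensor(vol, 2.0, 4.0)

    def test_separable_equals_brute_force(self):
        res = separable_vs_brute_force(seed=3, grid=16, sigma=1.0, rho=1.5)
        assert res["separable_vs_bruteforce_max_rel_err"] < 1e-6


class TestEigendecomposition:
    def _field_from_matrices(self, mats):
        mats = np.asarray(mats)[None, None]
        comps = np.stack([mats[..., 0, 0], mats[..., 1, 1], mats[..., 2, 2],
                          mats[..., 0, 1], mats[..., 0, 2], mats[..., 1, 2]],
                         axis=-1)
        return TensorField(comps, 1000.0, sigma=1.0, rho=1.0, zero_tol=1e-15)

    def test_identity_tensor_isotropic(self):
        ef = eigendecompose_field(self._field_from_matrices([np.eye(3)]))
        assert np.allclose(ef.raw[0, 0, 0], [1 / 3] * 3)

    def test_diagonal_tensor(self):
        ef = eigendecompose_field(
            self._field_from_matrices([np.diag([4.0, 1.0, 0.0])]))
        assert np.allclose(ef.raw[0, 0, 0], [0.8, 0.2, 0.0], atol=1e-12)
        # largest raw eigenvalue pairs with x
        assert np.allclose(np.abs(ef.vectors[0, 0, 0, 0]), [1, 0, 0])

    def test_spectral_reconstruction(self, rng):
        a = rng.normal(size=(6, 6, 6, 3, 3))
        mats = np.einsum("...ij,...kj->...ik", a, a)   # PSD
        comps = np.stack([mats[..., 0, 0], mats[..., 1, 1], mats[..., 2, 2],
                          mats[..., 0, 1], mats[..., 0, 2], mats[..., 1, 2]],
                         axis=-1)
        tf = TensorField(comps, 1000.0, sigma=1.0, rho=1.0, zero_tol=0.0)
        ef = eigendecompose_field(tf)
        trace = mats.trace(axis1=-2, axis2=-1)
        recon = np.einsum("...k,...ki,...kj->...ij",
                          ef.raw * trace[..., None], ef.vectors, ef.vectors)
        assert np.allclose(recon, mats, atol=1e-8 * np.abs(mats).max())

    def test_eigenvectors_orthonormal(self, parallel_small_eigen):
        eigen, _ = parallel_small_eigen
        v = eigen.vectors[::8, ::8, ::8]
        gram = np.einsum("...ik,...jk->...ij", v, v)
        assert np.allclose(gram, np.eye(3), atol=1e-10)


class TestConversion:
    def _eigenfield(self, raw):
        raw = np.asarray(raw, float)[None, None, None]
        return EigenField(raw=raw, vectors=np.eye(3)[None, None, None],
                          zero_mask=np.zeros((1, 1, 1), bool),
                          voxel_size=1000.0)

    def test_isotropic_fixed_point(self):
        ef = convert_eigenvalues(self._eigenfield([1 / 3] * 3), 0.123)
        assert np.allclose(ef.converted, 1 / 3)

    def test_stick_conversion_oracle(self):
        # λ* = (1, 0, 0), γ = 0.3: exp(−1/0.3)=0.0356740;
        # normalise (1, 1, 0.0356740) → (0.4912378, 0.4912378, 0.0175244)
        ef = convert_eigenvalues(self._eigenfield([1.0, 0.0, 0.0]), 0.3)
        assert np.allclose(ef.converted[0, 0, 0],
                           [0.4912378, 0.4912378, 0.0175244], atol=1e-6)

    def test_order_reversal_and_sum(self, rng):
        raw = np.sort(rng.dirichlet(np.ones(3), size=(4, 4, 4)), axis=-1)[..., ::-1]
        ef = EigenField(raw=raw, vectors=np.broadcast_to(np.eye(3), (4, 4, 4, 3, 3)),
                        zero_mask=np.zeros((4, 4, 4), bool), voxel_size=1000.0)
        for gamma in (0.25, 0.3, 0.35):
            convert_eigenvalues(ef, gamma)
            assert np.allclose(ef.converted.sum(axis=-1), 1.0, atol=1e-12)
            assert np.all(np.diff(ef.converted, axis=-1) <= 1e-15)

    def test_invalid_gamma(self):
        with pytest.raises(ValueError):
            convert_eigenvalues(self._eigenfield([1 / 3] * 3), 0.0)


class TestFractionalAnisotropy:
    @pytest.mark.parametrize("lam,expected", [
        ((1 / 3, 1 / 3, 1 / 3), 0.0),
        ((1.0, 0.0, 0.0), 1.0),
        ((0.6, 0.3, 0.1), 0.6427),    # direct formula evaluation
    ])
    def test_fa_values(self, lam, expected):
        ef = EigenField(raw=np.asarray(lam)[None, None, None],
                        vectors=np.eye(3)[None, None, None],
                        zero_mask=np.zeros((1, 1, 1), bool), voxel_size=1000.0)
        ef.converted = np.asarray(lam, float)[None, None, None]
        fa = fractional_anisotropy(ef)
        assert fa[0, 0, 0] == pytest.approx(expected, abs=1e-4)

    def test_zero_mask_gives_zero_fa(self):
        ef = EigenField(raw=np.full((1, 1, 1, 3), 1 / 3),
                        vectors=np.eye(3)[None, None, None],
                        zero_mask=np.ones((1, 1, 1), bool), voxel_size=1000.0)
        ef.converted = np.array([[[[1.0, 0.0, 0.0]]]])
        assert fractional_anisotropy(ef)[0, 0, 0] == 0.0


class TestScaleSelection:
    def _fake_field(self, fa):
        fa = np.asarray(fa, float)
        shape = fa.shape
        ef = EigenField(raw=np.full(shape + (3,), 1 / 3),
                        vectors=np.broadcast_to(np.eye(3), shape + (3, 3)),
                        zero_mask=np.zeros(shape, bool), voxel_size=1000.0)
        ef.converted = np.full(shape + (3,), 1 / 3)
        ef.fa = fa
        return ef

    def test_single_scale_identity(self):
        ef = self._fake_field(np.random.default_rng(0).uniform(size=(2, 2, 2)))
        sel, dom = scale_space_select([ef], ScaleParams(scales=((1, 1),)))
        assert sel is ef
        assert np.all(dom.index == 0)

    def test_proportional_maps_tie_to_lowest_index(self):
        fa = np.random.default_rng(1).uniform(size=(3, 3, 3))
        sel, dom = scale_space_select(
            [self._fake_field(fa), self._fake_field(0.5 * fa)],
            ScaleParams(scales=((1, 1), (2, 2))))
        assert np.all(dom.index == 0)

    def test_hand_worked_argmax(self):
        # scale A FA=(0.8, 0.2), scale B FA=(0.5, 0.45):
        # normalised A=(1.0, 0.25), B=(1.0, 0.9) ⇒ winners (A, B) = (0, 1)
        a = self._fake_field(np.array([0.8, 0.2]).reshape(1, 1, 2))
        b = self._fake_field(np.array([0.5, 0.45]).reshape(1, 1, 2))
        _, dom = scale_space_select([a, b], ScaleParams(scales=((1, 1), (2, 2))))
        assert dom.index[0, 0, 0] == 0
        assert dom.index[0, 0, 1] == 1
        assert dom.score[0, 0, 0] == pytest.approx(1.0)
        assert dom.score[0, 0, 1] == pytest.approx(0.9)

    def test_zero_fa_scale_scores_zero(self):
        a = self._fake_field(np.zeros((2, 2, 2)))
        b = self._fake_field(np.full((2, 2, 2), 0.4))
        _, dom = scale_space_select([a, b], ScaleParams(scales=((1, 1), (2, 2))))
        assert np.all(dom.index == 1)


class TestInvariants:
    def test_rotation_equivariance(self):
        """Rotating the volume 90° about z rotates the direction field."""
        spec = PhantomSpec(grid_shape=(40, 40, 40), voxel_size=1000.0,
                           rng_seed=9)
        vol, truth = build_parallel_fibre_volume(spec)
        params = ScaleParams(scales=((1.0, 2.0),), gamma=0.3)
        eigen, _ = analyse_volume(vol, params)
        rot = ImageVolume(np.rot90(vol.data, k=1, axes=(1, 2)).copy(),
                          vol.voxel_size)
        eigen_rot, _ = analyse_volume(rot, params)
        # fibre direction x maps to y under this rotation
        interior = truth.interior_mask(1.0) & ~eigen.border_mask()
        ang = acute_angle_deg(eigen.principal_direction()[interior],
                              np.array([1.0, 0.0, 0.0]))
        rot_interior = np.rot90(interior, k=1, axes=(1, 2))
        ang_rot = acute_angle_deg(eigen_rot.principal_direction()[rot_interior],
                                  np.array([0.0, 1.0, 0.0]))
        assert np.quantile(ang, 0.95) < 2.0
        assert np.quantile(ang_rot, 0.95) < 2.0

    def test_trace_conservation_everywhere(self, parallel_small_eigen):
        eigen, _ = parallel_small_eigen
        assert np.allclose(eigen.converted.sum(axis=-1), 1.0, atol=1e-12)

    def test_scale_params_defaults_match_published_suite(self):
        p = ScaleParams()
        rho = [r for _, r in p.scales]
        sig = [s for s, _ in p.scales]
        assert rho == [5.50, 4.50, 3.50, 3.50, 2.50, 2.50, 1.50, 1.00]
        assert sig == [3.00, 2.75, 2.50, 1.50, 1.50, 1.00, 1.00, 0.50]
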