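"""Phantom generators: geometry, labels, ground truth, determinism."""

import numpy as np
import pytest

from fibrest import (ObstacleSpec, PhantomSpec, add_imaging_noise,
                     apply_demyelination, build_crossing_volume,
                     build_laminar_volume, build_parallel_fibre_volume,
                     insert_obstacles)
from fibrest.phantoms import (DEMYELINATED, FIBRE_1, FIBRE_2, OBSTACLE,
                              acute_angle_deg, axial_unit, rerender)


class TestParallelFibres:
    def test_orientation_equals_fibre_axis(self, parallel_small):
        _, _, truth = parallel_small
        fibre = truth.labels > 0
        assert fibre.any()
        assert np.allclose(truth.orientation[fibre], [1.0, 0.0, 0.0])

    def test_volume_fraction_matches_packing(self, parallel_small):
        spec, _, truth = parallel_small
        measured = (truth.labels > 0).mean()
        r, s = spec.radii[0], spec.spacings[0]
        analytic = np.pi * r ** 2 / s ** 2
        assert measured == pytest.approx(analytic, rel=0.10)

    def test_two_radii_partition_halves(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           fibre_radius_um=(2.0, 4.0),
                           fibre_spacing_um=(6.0, 10.0), rng_seed=3)
        _, truth = build_parallel_fibre_volume(spec)
        y1 = np.argwhere(truth.labels == FIBRE_1)[:, 1]
        y2 = np.argwhere(truth.labels == FIBRE_2)[:, 1]
        assert len(y1) and len(y2)
        # populations occupy opposite bands; tubes may straddle the split
        # line by at most one radius
        lo_band, hi_band = (y1, y2) if np.median(y1) < np.median(y2) else (y2, y1)
        assert np.median(lo_band) < 16 < np.median(hi_band)
        assert lo_band.max() - hi_band.min() <= 2 * max(spec.radii)

    def test_unresolvable_radius_names_minimum(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           fibre_radius_um=1.0)
        with pytest.raises(ValueError, match="resolvable minimum"):
            build_parallel_fibre_volume(spec)

    def test_deterministic_given_seed(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), voxel_size=1000.0,
                           rng_seed=7, noise_sigma=3.0)
        v1, t1 = build_parallel_fibre_volume(spec)
        v2, t2 = build_parallel_fibre_volume(spec)
        assert np.array_equal(v1.data, v2.data)
        assert np.array_equal(t1.labels, t2.labels)

    def test_rendering_consistency(self, parallel_small):
        _, vol, truth = parallel_small
        assert np.array_equal(rerender(truth).data, vol.data)

    def test_intensity_convention(self, parallel_small):
        spec, vol, truth = parallel_small
        fibre_core = truth.interior_mask(1.0)
        background = truth.labels == 0
        assert vol.data[fibre_core].mean() < vol.data[background].mean()


class TestLaminarAndCrossing:
    def test_zero_inclination_single_direction(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           lamina_inclination_deg=0.0,
                           lamina_thickness_um=8.0, rng_seed=2)
        _, truth = build_laminar_volume(spec)
        fibre = truth.labels > 0
        assert np.allclose(np.abs(truth.orientation[fibre] @ [1, 0, 0]), 1.0)

    def test_inclination_35_between_adjacent_slabs(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           lamina_inclination_deg=35.0,
                           lamina_thickness_um=16.0, rng_seed=2)
        _, truth = build_laminar_volume(spec)
        d0, d1 = truth.render_params["slab_directions"]
        assert float(acute_angle_deg(d0, d1)) == pytest.approx(35.0, abs=1e-9)
        for d in (d0, d1):
            fibre_d = np.abs(truth.orientation[truth.labels > 0] @ d) > 0.9999
            assert fibre_d.any()

    def test_slab_spacing_along_normal(self):
        thickness = 16.0
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           lamina_inclination_deg=20.0,
                           lamina_thickness_um=thickness, rng_seed=2)
        _, truth = build_laminar_volume(spec)
        # probe along the slab normal (z): population labels alternate with
        # period = thickness / voxel size
        fibre = truth.labels > 0
        z_pop1 = np.argwhere(truth.labels == FIBRE_1)[:, 0]
        z_pop2 = np.argwhere(truth.labels == FIBRE_2)[:, 0]
        assert z_pop1.max() < 48 and z_pop2.max() < 48
        # slab k spans z in [k*16, (k+1)*16): population parity of the slab
        par1 = np.unique(z_pop1 // int(thickness))
        par2 = np.unique(z_pop2 // int(thickness))
        assert np.all(par1 % 2 == 0)
        assert np.all(par2 % 2 == 1)

    def test_inclination_out_of_range(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           lamina_inclination_deg=90.0)
        with pytest.raises(ValueError):
            build_laminar_volume(spec)

    def test_crossing_90_orthogonal_axes_and_fractions(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           crossing_angle_deg=90.0, lamina_thickness_um=12.0,
                           rng_seed=4)
        _, truth = build_crossing_volume(spec)
        d0, d1 = truth.render_params["slab_directions"]
        assert abs(float(np.dot(d0, d1))) < 1e-12
        n1 = (truth.labels == FIBRE_1).sum()
        n2 = (truth.labels == FIBRE_2).sum()
        assert abs(n1 - n2) / max(n1, n2) < 0.05

    def test_crossing_ground_truth_has_two_modes(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           crossing_angle_deg=90.0, lamina_thickness_um=8.0,
                           rng_seed=4)
        _, truth = build_crossing_volume(spec)
        fibre_dirs = truth.orientation[truth.labels > 0]
        uniq = np.unique(np.round(fibre_dirs, 6), axis=0)
        assert len(uniq) == 2


class TestObstacles:
    def test_empty_list_is_identity(self, parallel_small):
        _, vol, truth = parallel_small
        v2, t2 = insert_obstacles(vol, truth, [])
        assert v2 is vol and t2 is truth

    def test_vessel_displacement_bounds(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           rng_seed=4)
        vol, truth = build_parallel_fibre_volume(spec)
        vessel = ObstacleSpec(kind="cylinder", center=(24, 24, 24),
                              radius_um=6.0, deflection_halo_um=12.0,
                              axis=(0, 0, 1))
        _, t2 = insert_obstacles(vol, truth, [vessel])
        max_disp = 0.0
        for p_old, p_new in zip(truth.fibre_paths, t2.fibre_paths):
            if len(p_new.points) == len(p_old.points):
                continue   # untouched 2-point path
            disp = np.abs(p_new.points[:, 1] - p_new.points[0, 1]).max()
            max_disp = max(max_disp, disp)
        assert vessel.radius_um <= max_disp <= vessel.deflection_halo_um

    def test_far_path_pointwise_unchanged(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           rng_seed=4)
        vol, truth = build_parallel_fibre_volume(spec)
        vessel = ObstacleSpec(kind="cylinder", center=(24, 24, 24),
                              radius_um=4.0, deflection_halo_um=6.0,
                              axis=(0, 0, 1))
        _, t2 = insert_obstacles(vol, truth, [vessel])
        untouched = 0
        for p_old, p_new in zip(truth.fibre_paths, t2.fibre_paths):
            far = np.abs(p_old.points[0, 1] - 24.0) > 14.0
            if far:
                assert np.array_equal(p_old.points, p_new.points)
                untouched += 1
        assert untouched > 0

    def test_obstacle_voxels_bright_and_labelled(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           rng_seed=4)
        vol, truth = build_parallel_fibre_volume(spec)
        cell = ObstacleSpec(kind="sphere", center=(16, 16, 16), radius_um=4.0)
        v2, t2 = insert_obstacles(vol, truth, [cell])
        inside = t2.labels == OBSTACLE
        assert inside.any()
        assert v2.data[inside].mean() > spec.background_intensity

    def test_covering_obstacle_errors(self):
        spec = PhantomSpec(grid_shape=(24, 24, 24), voxel_size=1000.0,
                           rng_seed=4)
        vol, truth = build_parallel_fibre_volume(spec)
        huge = ObstacleSpec(kind="cylinder", center=(12, 12, 12),
                            radius_um=15.0, deflection_halo_um=15.0,
                            axis=(0, 0, 1))
        with pytest.raises(ValueError, match="cross-section"):
            insert_obstacles(vol, truth, [huge])


class TestDemyelination:
    def test_identity_parameters(self, parallel_small):
        _, vol, truth = parallel_small
        v2, t2 = apply_demyelination(vol, truth,
                                     ((8, 24), (8, 24), (8, 24)), 1.0, 0.0)
        assert np.array_equal(v2.data, vol.data)

    def test_contrast_gap_halved(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           rng_seed=6)
        vol, truth = build_parallel_fibre_volume(spec)
        region = ((8, 40), (8, 40), (8, 40))
        v2, t2 = apply_demyelination(vol, truth, region, 0.5, 0.0)
        bg = spec.background_intensity
        sl = tuple(slice(a, b) for a, b in region)
        in_core = (t2.labels[sl] == DEMYELINATED) & \
                  (truth.axis_distance_um[sl] < spec.radii[0] - 1.0)
        out_core = truth.interior_mask(1.0).copy()
        out_core[sl] = False
        gap_in = bg - v2.data[sl][in_core].mean()
        gap_out = bg - v2.data[out_core].mean()
        assert gap_in == pytest.approx(0.5 * gap_out, rel=0.02)

    def test_orientations_preserved(self):
        spec = PhantomSpec(grid_shape=(32, 32, 32), voxel_size=1000.0,
                           rng_seed=6)
        vol, truth = build_parallel_fibre_volume(spec)
        _, t2 = apply_demyelination(vol, truth, ((8, 24), (8, 24), (8, 24)),
                                    0.5, 0.0)
        assert np.array_equal(t2.orientation, truth.orientation)

    def test_extra_cells_added(self):
        spec = PhantomSpec(grid_shape=(48, 48, 48), voxel_size=1000.0,
                           rng_seed=6)
        vol, truth = build_parallel_fibre_volume(spec)
        # 48³ μm³ region = 1.1e-4 mm³; 1e5 cells/mm³ ≈ 12 cells
        _, t2 = apply_demyelination(vol, truth, ((0, 48), (0, 48), (0, 48)),
                                    0.9, 1.0e5, rng_seed=6)
        assert (t2.labels == OBSTACLE).any()

    def test_region_outside_grid_errors(self, parallel_small):
        _, vol, truth = parallel_small
        with pytest.raises(ValueError, match="outside the grid"):
            apply_demyelination(vol, truth, ((0, 60), (0, 16), (0, 16)), 0.5)


class TestNoise:
    def test_zero_sigma_identity(self, parallel_small):
        _, vol, _ = parallel_small
        assert np.array_equal(add_imaging_noise(vol, 0.0, 1).data, vol.data)

    def test_sample_sd_matches_sigma(self):
        from fibrest import ImageVolume
        clean = ImageVolume(np.zeros((128, 128, 128)), 500.0)
        noisy = add_imaging_noise(clean, 4.0, 11)
        sd = (noisy.data - clean.data).std()
        assert sd == pytest.approx(4.0, rel=0.02)

    def test_same_seed_bit_identical(self, parallel_small):
        _, vol, _ = parallel_small
        a = add_imaging_noise(vol, 2.0, 5)
        b = add_imaging_noise(vol, 2.0, 5)
        assert np.array_equal(a.data, b.data)


class TestAxialHelpers:
    @pytest.mark.parametrize("v,expected", [
        ([0, 0, -2], [0, 0, 1]),
        ([-1, 1, 0], [1 / np.sqrt(2), -1 / np.sqrt(2), 0]),
        ([3, 0, 0], [1, 0, 0]),
    ])
    def test_axial_unit_sign_convention(self, v, expected):
        assert np.allclose(axial_unit(np.array(v, float)), expected)

    def test_acute_angle_symmetry(self, rng):
        a = rng.normal(size=(50, 3))
        assert np.allclose(acute_angle_deg(a, -a), 0.0, atol=1e-5)
        assert np.all(acute_angle_deg(a, rng.normal(size=(50, 3))) <= 90.0)


class TestSpecValidation:
    @pytest.mark.parametrize("kwargs", [
        {"grid_shape": (8, 32, 32)},
        {"fibre_intensity": 200.0},
        {"crossing_angle_deg": 120.0},
        {"noise_sigma": -1.0},
        {"fibre_spacing_um": 0.0},
    ])
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PhantomSpec(**kwargs)
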