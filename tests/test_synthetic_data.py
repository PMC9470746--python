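"""Generators: ground truth, determinism and geometric convergence."""

import numpy as np
import pytest
from scipy import ndimage as ndi

import mitomorph as mm
from mitomorph.synthetic_data import (capsule_volume_um3, fused_beads_spec_3d,
                                      tubule_spec_3d)


class TestTubule2D:
    def test_truth_echoes_requested_length_and_single_component(self):
        mask, truth = mm.generate_tubule_2d(4.0, radius_um=0.15,
                                            calibration_um_per_px=0.1)
        assert truth.objects[0].true_length_um == 4.0
        _, n = ndi.label(mask, structure=np.ones((3, 3)))
        assert n == 1

    def test_shortest_confocal_length_bin_is_valid(self):
        mask, truth = mm.generate_tubule_2d(0.5)
        assert mask.any() and truth.objects[0].true_length_um == 0.5

    def test_subpixel_length_rejected(self):
        with pytest.raises(ValueError):
            mm.generate_tubule_2d(0.15, calibration_um_per_px=0.1)

    def test_object_exceeding_bounds_rejected(self):
        with pytest.raises(ValueError):
            mm.generate_tubule_2d(20.0, image_shape=(64, 64))


class TestBranched2D:
    def test_requires_a_branch(self):
        with pytest.raises(ValueError):
            mm.generate_branched_2d(2.0, [])

    def test_collinear_terminal_branch_degenerates_to_tubule(self):
        _, truth = mm.generate_branched_2d(2.0, [1.0], branch_positions=[1.0],
                                           branch_angles_deg=[0.0])
        assert truth.objects[0].true_element_counts == \
            {"ends": 2, "junctions": 0, "tubules": 1}

    def test_overlapping_branches_rejected(self):
        # two branches folded onto each other merge the topology
        with pytest.raises(ValueError):
            mm.generate_branched_2d(2.0, [1.5, 1.5],
                                    branch_positions=[0.4, 0.6],
                                    branch_angles_deg=[150.0, 170.0])

    def test_h_shape_exceeds_cluster_threshold(self):
        _, truth = mm.generate_branched_2d(3.0, [1.5, 1.5],
                                           branch_positions=[0.33, 0.67],
                                           branch_angles_deg=[70, -70])
        c = truth.objects[0].true_element_counts
        assert c == {"ends": 4, "junctions": 2, "tubules": 5}
        assert sum(c.values()) == 11 > 7


class TestRender2D:
    def test_zero_noise_zero_blur_thresholds_back_exactly(self):
        mask, _ = mm.generate_tubule_2d(3.0)
        img = mm.render_fluorescence_2d(mask, psf_sigma_um=0, poisson_scale=0,
                                        gaussian_sd=0, background=0.1, seed=0)
        rec = mm.binarize(mm.CalibratedImage(img, 0.1), min_object_area_um2=0)
        np.testing.assert_array_equal(rec.pixels, mask)

    def test_seed_determinism(self):
        mask, _ = mm.generate_tubule_2d(3.0)
        kwargs = dict(psf_sigma_um=0.2, poisson_scale=50, gaussian_sd=0.02,
                      background=0.05, seed=11)
        a = mm.render_fluorescence_2d(mask, **kwargs)
        b = mm.render_fluorescence_2d(mask, **kwargs)
        np.testing.assert_array_equal(a, b)

    def test_negative_parameters_rejected(self):
        mask, _ = mm.generate_tubule_2d(3.0)
        with pytest.raises(ValueError):
            mm.render_fluorescence_2d(mask, psf_sigma_um=-0.1)

    def test_noisy_scene_length_recovery(self):
        """Realistic PSF + noise still recovers the tubule length within
        max(2 px, 5%)."""
        mask, truth = mm.generate_tubule_2d(4.0, orientation_deg=30,
                                            image_shape=(80, 80))
        img = mm.render_fluorescence_2d(mask, psf_sigma_um=0.1,
                                        poisson_scale=100, gaussian_sd=0.02,
                                        background=0.05, seed=2)
        rec = mm.binarize(mm.CalibratedImage(img, 0.1))
        g = mm.skeletonize(rec.pixels, spacing_um=0.1)
        length = max(mm.component_length(gr) for gr in g)
        assert abs(length - 4.0) <= max(0.2, 0.05 * 4.0) + 0.1


class TestScene2D:
    def test_seed_determinism_and_truth_consistency(self):
        m1, t1 = mm.generate_scene_2d(n_objects=8, seed=5)
        m2, t2 = mm.generate_scene_2d(n_objects=8, seed=5)
        np.testing.assert_array_equal(m1, m2)
        assert t1.to_json() == t2.to_json()
        _, n = ndi.label(m1, structure=np.ones((3, 3)))
        assert n == len(t1.objects)


class TestVolume3D:
    def test_cylinder_volume_matches_analytic_capsule(self):
        spec = tubule_spec_3d(1.0, 0.2, start_um=(0.4, 0.5, 0.5))
        labels, truth = mm.generate_volume_3d(
            [spec], voxel_size_um=(0.01, 0.01, 0.01), volume_shape=(100, 100, 220))
        analytic = capsule_volume_um3(1.0, 0.2)
        assert truth.objects[0].true_volume_um3 == pytest.approx(analytic)
        voxel = mm.object_volume(labels > 0, (0.01, 0.01, 0.01))
        assert voxel == pytest.approx(analytic, rel=0.05)

    def test_voxel_volume_converges_with_refinement(self):
        """Mean relative error over random sub-voxel placements decreases
        monotonically over a 3-step voxel refinement (averaging removes
        the placement luck of any single rasterization)."""
        rng = np.random.default_rng(0)
        offsets = [0.3 + 0.1 * rng.random(3) for _ in range(6)]
        analytic = capsule_volume_um3(0.8, 0.2)
        means = []
        for v in (0.08, 0.04, 0.02):
            n = int(np.ceil(1.6 / v))
            errs = []
            for off in offsets:
                spec = tubule_spec_3d(
                    0.8, 0.2, start_um=(off[0], 0.5 + off[1], 0.5 + off[2]))
                labels, _ = mm.generate_volume_3d(
                    [spec], voxel_size_um=(v, v, v), volume_shape=(n, n, n))
                errs.append(abs(mm.object_volume(labels > 0, (v, v, v))
                                - analytic) / analytic)
            means.append(np.mean(errs))
        assert means[0] > means[1] > means[2]

    def test_fused_flag_single_label_truth_keeps_individuals(self, fused_beads_volume):
        labels, truth = fused_beads_volume
        assert len(np.unique(labels)) == 2  # background + one fused label
        assert len(truth.objects) == 3  # 2 beads + 1 neck

    def test_out_of_bounds_spec_rejected(self):
        spec = tubule_spec_3d(5.0, 0.2, start_um=(0.1, 0.5, 0.5))
        with pytest.raises(ValueError):
            mm.generate_volume_3d([spec], voxel_size_um=(0.01, 0.01, 0.01),
                                  volume_shape=(60, 60, 60))

    def test_anisotropic_default_voxel_size(self):
        from mitomorph.synthetic_data import DEFAULT_VOXEL_SIZE_UM
        assert DEFAULT_VOXEL_SIZE_UM == (0.005, 0.005, 0.010)

    def test_fused_beads_helper_geometry(self):
        specs = fused_beads_spec_3d(3, 0.2, 0.06, center_um=(1.0, 0.4, 0.4))
        assert len(specs) == 5  # 3 beads + 2 necks
        assert all(s.radius_um in (0.2, 0.06) for s in specs)
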