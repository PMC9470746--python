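"""3D labeling, watershed splitting, volumes and Feret diameters."""

import numpy as np
import pytest

import mitomorph as mm
from mitomorph.synthetic_data import (capsule_volume_um3, fused_beads_spec_3d,
                                      tubule_spec_3d)

ISO = (0.01, 0.01, 0.01)


class TestLabelComponents:
    def test_two_separated_cylinders_two_labels(self):
        vol = np.zeros((20, 20, 40), bool)
        vol[8:12, 8:12, 2:15] = True
        vol[8:12, 8:12, 25:38] = True
        lv = mm.label_components(vol, ISO)
        assert len(lv.labels()) == 2

    def test_corner_touch_merges_under_26_connectivity(self):
        vol = np.zeros((6, 6, 6), bool)
        vol[0:3, 0:3, 0:3] = True
        vol[3:6, 3:6, 3:6] = True
        lv = mm.label_components(vol, ISO)
        assert len(lv.labels()) == 1

    def test_empty_volume_zero_labels(self):
        lv = mm.label_components(np.zeros((5, 5, 5), bool), ISO)
        assert lv.labels() == []


class TestWatershedSplit:
    def test_single_cylinder_returned_unsplit(self):
        spec = tubule_spec_3d(1.0, 0.2, start_um=(0.4, 0.5, 0.5))
        labels, _ = mm.generate_volume_3d([spec], voxel_size_um=ISO,
                                          volume_shape=(100, 100, 220))
        subs = mm.watershed_split(labels > 0, ISO)
        assert len(subs) == 1
        np.testing.assert_array_equal(subs[0], labels > 0)

    def test_fused_beads_split_with_volume_recovery(self, fused_beads_volume):
        labels, truth = fused_beads_volume
        subs = mm.watershed_split(labels > 0, ISO)
        assert len(subs) == 2
        sphere = 4 / 3 * np.pi * 0.2**3
        for s in subs:
            assert mm.object_volume(s, ISO) == pytest.approx(sphere, rel=0.10)

    def test_three_bead_chain_splits_into_three(self):
        specs = fused_beads_spec_3d(3, 0.2, 0.06, center_um=(1.0, 0.4, 0.4))
        labels, _ = mm.generate_volume_3d(specs, voxel_size_um=ISO,
                                          volume_shape=(80, 80, 200), fuse=True)
        subs = mm.watershed_split(labels > 0, ISO)
        assert len(subs) == 3

    def test_voxel_conservation(self, fused_beads_volume):
        labels, _ = fused_beads_volume
        subs = mm.watershed_split(labels > 0, ISO)
        assert sum(int(s.sum()) for s in subs) == int((labels > 0).sum())
        stack = np.sum([s.astype(int) for s in subs], axis=0)
        assert stack.max() == 1  # no voxel assigned twice

    def test_empty_component_raises(self):
        with pytest.raises(ValueError):
            mm.watershed_split(np.zeros((5, 5, 5), bool), ISO)


class TestObjectVolume:
    def test_exact_arithmetic(self):
        obj = np.zeros((10, 10, 10), bool)
        obj.flat[:1000] = True
        assert mm.object_volume(obj, (0.005, 0.005, 0.010)) == \
            pytest.approx(1000 * 2.5e-7)

    def test_six_voxel_object_still_reported(self):
        obj = np.zeros((3, 3, 6), bool)
        obj[1, 1, :6] = True
        v = mm.object_volume(obj, (0.005, 0.005, 0.010))
        assert v == pytest.approx(1.5e-6)

    def test_additivity_over_labels(self):
        specs = [tubule_spec_3d(0.5, 0.1, (0.2, 0.3, 0.3)),
                 tubule_spec_3d(0.7, 0.12, (0.2, 0.9, 0.4))]
        labels, _ = mm.generate_volume_3d(specs, voxel_size_um=(0.01, 0.01, 0.02),
                                          volume_shape=(40, 130, 130))
        total = mm.object_volume(labels > 0, (0.01, 0.01, 0.02))
        parts = sum(mm.object_volume(labels == i, (0.01, 0.01, 0.02))
                    for i in (1, 2))
        assert total == pytest.approx(parts, rel=1e-12)


class TestFeret:
    def test_axis_aligned_cylinder(self):
        spec = tubule_spec_3d(1.0, 0.1, start_um=(0.25, 0.25, 0.25))
        labels, _ = mm.generate_volume_3d([spec], voxel_size_um=ISO,
                                          volume_shape=(50, 50, 160))
        fmin, fmax = mm.feret_diameters(labels > 0, ISO)
        diag = np.sqrt(3) * 0.01
        assert fmax == pytest.approx(1.2, abs=2 * diag)  # capsule: L + 2r
        assert fmin == pytest.approx(0.2, abs=2 * diag)

    def test_sphere_is_round(self):
        zz, yy, xx = np.mgrid[0:41, 0:41, 0:41]
        sphere = (zz - 20) ** 2 + (yy - 20) ** 2 + (xx - 20) ** 2 <= 15**2
        fmin, fmax = mm.feret_diameters(sphere, ISO)
        assert fmax == pytest.approx(fmin, rel=0.05)
        assert fmax == pytest.approx(0.30, abs=0.05)

    def test_single_voxel_degenerates_to_voxel_diagonal(self):
        obj = np.zeros((3, 3, 3), bool)
        obj[1, 1, 1] = True
        fmin, fmax = mm.feret_diameters(obj, (0.005, 0.005, 0.010))
        diag = np.linalg.norm([0.005, 0.005, 0.010])
        assert fmin == fmax == pytest.approx(diag)

    def test_min_never_exceeds_max_and_scales_with_voxel_size(self):
        spec = tubule_spec_3d(0.6, 0.1, (0.2, 0.3, 0.3))
        labels, _ = mm.generate_volume_3d([spec], voxel_size_um=(0.01, 0.01, 0.02),
                                          volume_shape=(40, 70, 110))
        f1 = mm.feret_diameters(labels > 0, (0.01, 0.01, 0.02))
        f2 = mm.feret_diameters(labels > 0, (0.02, 0.02, 0.04))
        assert f1[0] <= f1[1]
        assert f2[0] == pytest.approx(2 * f1[0], rel=1e-9)
        assert f2[1] == pytest.approx(2 * f1[1], rel=1e-9)

    def test_anisotropy_honored_when_rotating_into_z(self):
        """A cylinder measured in-plane and along the anisotropic z axis
        gives the same feret_max within 5% (would be ~2x off in voxel
        units)."""
        vs = (0.01, 0.01, 0.02)
        in_plane = tubule_spec_3d(1.0, 0.1, (0.25, 0.3, 0.3))
        along_z = tubule_spec_3d(1.0, 0.1, (0.3, 0.3, 0.25),
                                 direction=(0, 0, 1))
        l1, _ = mm.generate_volume_3d([in_plane], voxel_size_um=vs,
                                      volume_shape=(40, 60, 160))
        l2, _ = mm.generate_volume_3d([along_z], voxel_size_um=vs,
                                      volume_shape=(90, 60, 60))
        f1 = mm.feret_diameters(l1 > 0, vs)[1]
        f2 = mm.feret_diameters(l2 > 0, vs)[1]
        assert abs(f1 - f2) / f1 < 0.05


class TestClassify3D:
    def summary(self, e, j, t):
        from mitomorph.skeleton_graph import ElementSummary
        return ElementSummary(e, j, t, 1.0)

    def test_single_cylinder_isolated(self):
        assert mm.volume3d.classify_3d(self.summary(2, 0, 1), 1) == "isolated"

    def test_y_tube_branched(self):
        assert mm.volume3d.classify_3d(self.summary(3, 1, 3), 1) == "branched"

    def test_multi_sub_object_is_clustered_regardless_of_elements(self):
        assert mm.volume3d.classify_3d(self.summary(2, 0, 1), 2) == "clustered"


class TestVolumeReport:
    def rec(self, oid, pheno, vol, fmax=1.0):
        return mm.Mito3DRecord(object_id=oid, parent_component_id=oid,
                               volume_um3=vol, feret_max_um=fmax,
                               feret_min_um=0.1, summary=None, phenotype=pheno)

    def test_abundance_arithmetic(self):
        recs = [self.rec(i, "isolated", 0.01) for i in range(3)] + \
            [self.rec(3, "clustered", 0.5)]
        rep = mm.volume_report(recs)
        assert rep.abundance_fractions["isolated"] == pytest.approx(0.75)

    def test_single_object_is_everything(self):
        rep = mm.volume_report([self.rec(0, "isolated", 0.2)])
        assert rep.abundance_fractions["isolated"] == 1.0
        assert rep.volume_fractions["isolated"] == 1.0

    def test_fractions_sum_to_one(self):
        recs = [self.rec(0, "isolated", 0.01, fmax=0.5),
                self.rec(1, "branched", 0.3),
                self.rec(2, "clustered", 1.2),
                self.rec(3, "isolated", 0.05, fmax=2.5)]
        rep = mm.volume_report(recs)
        assert sum(rep.abundance_fractions.values()) == pytest.approx(1.0)
        assert sum(rep.volume_fractions.values()) == pytest.approx(1.0)
        assert sum(rep.isolated_length_bins.values()) == pytest.approx(1.0)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            mm.volume_report([])


def test_analyze_volume_end_to_end(fused_beads_volume):
    labels, _ = fused_beads_volume
    recs = mm.analyze_volume(mm.LabelVolume(labels, ISO))
    assert len(recs) == 2
    assert all(r.phenotype == "clustered" for r in recs)
    total = mm.object_volume(labels > 0, ISO)
    assert sum(r.volume_um3 for r in recs) == pytest.approx(total, rel=1e-12)
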