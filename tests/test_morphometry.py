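import numpy as np
import pytest

from voxtract.grid import VoxelGrid, LabelVolume, LabelEntry
from voxtract.morphometry import (OrganelleInstance, equivalent_ellipsoid,
                                  skeleton_longest_path, nanotunnel_flag,
                                  detect_cavities, cavity_metrics, CavityRecord,
                                  intrusion_poisson, morphometrics_table)
from voxtract.synthetic import PhantomSpec, dumbbell, make_phantom


def _solid_grid(mask, spacing=(1.0, 1.0, 1.0)):
    return VoxelGrid(np.asarray(mask, dtype=np.uint8) * 255, spacing=spacing)


class TestEquivalentEllipsoid:
    def test_box_aspect_ratio_recovered(self):
        box = np.zeros((50, 20, 20), dtype=bool)
        box[5:45, 5:15, 5:15] = True  # 40 x 10 x 10 voxels
        major, median, minor, elong = equivalent_ellipsoid(box)
        assert elong == pytest.approx(4.0, rel=0.01)
        assert median == pytest.approx(minor, rel=0.01)
        # Sheppard's correction maps a w-voxel box to a w-voxel extent
        assert major == pytest.approx(40 * np.sqrt(5.0 / 3.0), rel=0.01)

    def test_spheroid_axes(self):
        zz, yy, xx = np.meshgrid(*[np.arange(48)] * 3, indexing="ij")
        spheroid = ((zz - 24) / 20.0) ** 2 + ((yy - 24) / 10.0) ** 2 \
            + ((xx - 24) / 10.0) ** 2 <= 1.0
        major, _, minor, elong = equivalent_ellipsoid(spheroid)
        assert major == pytest.approx(40.0, rel=0.05)
        assert minor == pytest.approx(20.0, rel=0.05)
        assert elong == pytest.approx(2.0, rel=0.05)

    def test_anisotropic_spacing_in_nm(self):
        cube = np.ones((4, 10, 10), dtype=bool)  # 40 nm cube at (10,4,4) nm
        major, _, minor, _ = equivalent_ellipsoid(cube, spacing=(10.0, 4.0, 4.0))
        assert major == pytest.approx(minor, rel=0.01)

    def test_single_voxel_is_isotropic_not_degenerate(self):
        one = np.zeros((3, 3, 3), dtype=bool)
        one[1, 1, 1] = True
        major, _, minor, elong = equivalent_ellipsoid(one)
        assert minor > 0
        assert elong == pytest.approx(1.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            equivalent_ellipsoid(np.zeros((2, 2, 2), dtype=bool))


class TestSkeletonLongestPath:
    def test_straight_tube_length(self):
        zz, yy, xx = np.meshgrid(np.arange(12), np.arange(12), np.arange(80),
                                 indexing="ij")
        tube = (np.hypot(zz - 6, yy - 6) <= 2.0) & (xx >= 5) & (xx <= 65)
        length, path, ends = skeleton_longest_path(tube)
        assert length == pytest.approx(60.0, rel=0.10)
        assert len(path) >= 2
        assert set(map(tuple, ends)) <= set(map(tuple, path))

    def test_l_shaped_tube(self):
        vol = np.zeros((12, 70, 70), dtype=bool)
        zz, yy, xx = np.meshgrid(np.arange(12), np.arange(70), np.arange(70),
                                 indexing="ij")
        leg1 = (np.hypot(zz - 6, yy - 10) <= 2.0) & (xx >= 5) & (xx <= 60)
        leg2 = (np.hypot(zz - 6, xx - 60) <= 2.0) & (yy >= 10) & (yy <= 60)
        vol = leg1 | leg2
        length, _, _ = skeleton_longest_path(vol)
        assert length == pytest.approx(105.0, rel=0.15)

    def test_physical_spacing_scales_length(self):
        tube = np.zeros((5, 5, 30), dtype=bool)
        tube[2, 2, 2:28] = True
        l1, _, _ = skeleton_longest_path(tube, spacing=(1.0, 1.0, 1.0))
        l2, _, _ = skeleton_longest_path(tube, spacing=(1.0, 1.0, 3.0))
        assert l2 == pytest.approx(3 * l1)

    def test_disconnected_solid_returns_per_component(self):
        vol = np.zeros((5, 5, 30), dtype=bool)
        vol[2, 2, 2:10] = True
        vol[2, 2, 20:28] = True
        res = skeleton_longest_path(vol)
        assert isinstance(res, list) and len(res) == 2

    def test_loop_falls_back_to_farthest_span(self):
        vol = np.zeros((3, 20, 20), dtype=bool)
        vol[1, 5:15, 5] = vol[1, 5:15, 14] = True
        vol[1, 5, 5:15] = vol[1, 14, 5:15] = True  # square ring, no endpoints
        length, _, _ = skeleton_longest_path(vol)
        assert length > 9.0


class TestNanotunnel:
    def _dumbbell_instance(self):
        spec = PhantomSpec(
            shape=(24, 48, 96), spacing=(4.0, 4.0, 4.0),
            objects=dumbbell(center_nm=(48.0, 96.0, 192.0), lobe_radius_nm=40.0,
                             lobe_separation_nm=200.0, tunnel_radius_nm=12.0),
            membrane_thickness_nm=16.0, seed=0)
        _, t_memb, t_matter, _ = make_phantom(spec)
        membrane = _solid_grid(t_memb.values > 0.5, spec.spacing)
        matrix = _solid_grid(t_matter.values > 0.5, spec.spacing)
        return OrganelleInstance(1, membrane=membrane, matrix=matrix)

    def test_dumbbell_is_flagged(self):
        inst = self._dumbbell_instance()
        flagged, n_matrix = nanotunnel_flag(inst)
        assert flagged
        assert n_matrix == 2

    def test_plain_ball_is_not_flagged(self):
        zz, yy, xx = np.meshgrid(*[np.arange(24)] * 3, indexing="ij")
        dist = np.sqrt((zz - 12.) ** 2 + (yy - 12.) ** 2 + (xx - 12.) ** 2)
        membrane = _solid_grid((dist >= 7) & (dist <= 9))
        matrix = _solid_grid(dist < 7)
        flagged, n_matrix = nanotunnel_flag(OrganelleInstance(1, membrane=membrane,
                                                              matrix=matrix))
        assert not flagged
        assert n_matrix == 1

    def test_requires_matrix(self):
        g = _solid_grid(np.ones((4, 4, 4), dtype=bool))
        with pytest.raises(ValueError):
            nanotunnel_flag(OrganelleInstance(1, membrane=g))


def _drilled_sphere(sp=2.0, R=40.0, bore_r=8.0, bore_depth=30.0):
    shape = (64, 64, 64)
    zz, yy, xx = np.meshgrid(*[np.arange(s) * sp for s in shape], indexing="ij")
    c = 64.0
    ball = (zz - c) ** 2 + (yy - c) ** 2 + (xx - c) ** 2 <= R * R
    bore = (np.hypot(zz - c, yy - c) <= bore_r) & (xx >= c + R - bore_depth)
    return ball & ~bore, (sp, sp, sp)


class TestCavities:
    def test_drilled_bore_detected_with_correct_geometry(self):
        solid, spacing = _drilled_sphere()
        inst = OrganelleInstance(1, membrane=_solid_grid(solid, spacing))
        recs = detect_cavities(inst, closing_radius_nm=30.0, min_depth_nm=10.0)
        assert len(recs) == 1
        rec = recs[0]
        diag = np.sqrt(3) * spacing[0]
        assert abs(rec.depth_nm - 30.0) <= 2 * diag
        assert abs(rec.inscribed_radius_nm - 8.0) <= spacing[0]
        assert rec.category == "empty"
        assert rec.volume_nm3 > 0

    def test_intact_sphere_has_no_cavities(self):
        # same sphere as the drilled phantom, without the bore
        solid, spacing = _drilled_sphere(bore_r=0.0, bore_depth=0.0)
        inst = OrganelleInstance(1, membrane=_solid_grid(solid, spacing))
        assert detect_cavities(inst, closing_radius_nm=30.0, min_depth_nm=10.0) == []

    def test_cavity_categorized_by_occupying_label(self):
        solid, spacing = _drilled_sphere()
        labels = np.zeros(solid.shape, dtype=np.int32)
        # a foreign organelle filling the bore
        zz, yy, xx = np.meshgrid(*[np.arange(s) * spacing[0]
                                   for s in solid.shape], indexing="ij")
        labels[(np.hypot(zz - 64, yy - 64) <= 7) & (xx >= 64 + 40 - 28)] = 1
        other = LabelVolume(labels, table={1: LabelEntry("er", 1)},
                            spacing=spacing)
        inst = OrganelleInstance(1, membrane=_solid_grid(solid, spacing))
        recs = detect_cavities(inst, closing_radius_nm=30.0, min_depth_nm=10.0,
                               other_labels=other)
        assert recs[0].category == "er"

    def test_cavity_metrics_requires_voxels(self):
        with pytest.raises(ValueError):
            cavity_metrics(CavityRecord(mask=np.zeros((2, 2, 2), dtype=bool),
                                        category="empty", depth_nm=0.0),
                           (1.0, 1.0, 1.0))


class TestPoisson:
    def test_fifty_events_over_186_instances(self):
        counts = np.zeros(186, dtype=int)
        counts[:50] = 1
        fit = intrusion_poisson(counts)
        assert round(fit.lam, 3) == 0.269
        assert fit.n_instances == 186

    def test_expected_fraction_matches_closed_form(self):
        fit = intrusion_poisson(np.array([1, 0, 0, 1, 0], dtype=int))
        lam = 0.4
        assert fit.lam == pytest.approx(lam)
        assert fit.expected_fraction(0) == pytest.approx(np.exp(-lam))
        assert fit.expected_fraction(1) == pytest.approx(lam * np.exp(-lam))
        assert fit.expected_counts(0) == pytest.approx(5 * np.exp(-lam))

    def test_rejects_invalid_counts(self):
        with pytest.raises(ValueError):
            intrusion_poisson(np.array([], dtype=int))
        with pytest.raises(ValueError):
            intrusion_poisson(np.array([-1, 2]))
        with pytest.raises(ValueError):
            intrusion_poisson(np.array([0.5, 1.5]))


class TestMorphometricsTable:
    def test_clipped_instances_get_nan_shape_metrics(self):
        # a box touching the volume border is clipped
        clipped = np.zeros((8, 8, 8), dtype=bool)
        clipped[0:4, 2:6, 2:6] = True
        interior = np.zeros((16, 16, 32), dtype=bool)
        interior[6:10, 6:10, 6:26] = True
        instances = {
            1: OrganelleInstance(1, membrane=_solid_grid(clipped)),
            2: OrganelleInstance(2, membrane=_solid_grid(interior)),
        }
        table = morphometrics_table(instances)
        assert bool(table.loc[1, "clipped"])
        assert np.isnan(table.loc[1, "major_nm"])
        assert not bool(table.loc[2, "clipped"])
        assert table.loc[2, "major_nm"] > table.loc[2, "minor_nm"]
        assert table.loc[2, "longest_path_nm"] > 0
        assert table.loc[2, "solid_volume_nm3"] == pytest.approx(4 * 4 * 20)
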