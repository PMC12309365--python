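import numpy as np
import pytest

from voxtract.extraction import delta_v_compare
from voxtract.synthetic import (Ball, Shell, Tube, dumbbell, PhantomSpec,
                                make_phantom, intruded_spheres,
                                simulate_ai_variants)


def _single_shell_spec(seed=0):
    return PhantomSpec(shape=(24, 48, 48), spacing=(4.0, 4.0, 4.0),
                       objects=[Shell((48.0, 96.0, 96.0), 40.0)],
                       membrane_thickness_nm=16.0, seed=seed)


class TestMakePhantom:
    def test_deterministic_per_seed(self):
        a, _, _, _ = make_phantom(_single_shell_spec(seed=5))
        b, _, _, _ = make_phantom(_single_shell_spec(seed=5))
        c, _, _, _ = make_phantom(_single_shell_spec(seed=6))
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_membrane_band_matches_analytic_geometry(self):
        spec = _single_shell_spec()
        _, t_memb, t_matter, labels = make_phantom(spec)
        zz, yy, xx = np.meshgrid(*[np.arange(n) * s for n, s
                                   in zip(spec.shape, spec.spacing)], indexing="ij")
        dist = np.sqrt((zz - 48) ** 2 + (yy - 96) ** 2 + (xx - 96) ** 2)
        band = np.abs(dist - 40.0) <= 8.0
        assert np.array_equal(t_memb.values > 0.5, band)
        assert np.array_equal(t_matter.values > 0.5, (dist < 32.0))
        assert np.array_equal(labels.mask(1), dist <= 48.0)

    def test_truth_maps_are_binary_and_em_is_8bit(self):
        em, t_memb, t_matter, _ = make_phantom(_single_shell_spec())
        assert em.values.dtype == np.uint8
        assert set(np.unique(t_memb.values)) <= {0.0, 1.0}
        assert set(np.unique(t_matter.values)) <= {0.0, 1.0}

    def test_intensity_polarity_membrane_brightest(self):
        em, t_memb, t_matter, _ = make_phantom(_single_shell_spec())
        memb = t_memb.values > 0.5
        matter = t_matter.values > 0.5
        cytosol = ~memb & ~matter
        assert em.values[memb].mean() > em.values[matter].mean()
        assert em.values[matter].mean() > em.values[cytosol].mean()

    def test_object_outside_grid_rejected(self):
        spec = PhantomSpec(shape=(8, 8, 8), spacing=(4.0, 4.0, 4.0),
                           objects=[Ball((500.0, 500.0, 500.0), 10.0)])
        with pytest.raises(ValueError, match="outside"):
            make_phantom(spec)

    def test_dumbbell_membrane_not_threaded_through_lobes(self):
        from scipy import ndimage
        spec = PhantomSpec(
            shape=(24, 48, 96), spacing=(4.0, 4.0, 4.0),
            objects=dumbbell((48.0, 96.0, 192.0), lobe_radius_nm=40.0,
                             lobe_separation_nm=200.0, tunnel_radius_nm=12.0),
            membrane_thickness_nm=16.0)
        _, t_memb, t_matter, _ = make_phantom(spec)
        struct = np.ones((3, 3, 3))
        _, n_matter = ndimage.label(t_matter.values > 0.5, structure=struct)
        solid = (t_memb.values > 0.5) | (t_matter.values > 0.5)
        _, n_solid = ndimage.label(solid, structure=struct)
        assert n_matter == 2   # two lobes of matrix
        assert n_solid == 1    # joined into one organelle by the tunnel


class TestObjects:
    def test_tube_sdf_is_distance_to_segment(self):
        t = Tube((0, 0, 0), (0, 0, 10), radius_nm=2.0)
        zz = np.array([[[0.0]]]); yy = np.array([[[0.0]]])
        assert t.sdf(zz, yy, np.array([[[5.0]]])).item() == pytest.approx(-2.0)
        assert t.sdf(zz, yy, np.array([[[14.0]]])).item() == pytest.approx(2.0)

    def test_dumbbell_structure(self):
        objs = dumbbell((0, 0, 0), 10.0, 30.0, 3.0)
        assert len(objs) == 3
        assert isinstance(objs[0], Ball) and objs[0].filled
        assert isinstance(objs[2], Tube) and not objs[2].filled
        assert objs[0].center_nm[2] == pytest.approx(-15.0)
        assert objs[1].center_nm[2] == pytest.approx(15.0)


class TestIntrudedSpheres:
    def test_tangent_solids_touch_without_overlap(self):
        s1, s2, _ = intruded_spheres(diameter_vox=32, mode="tangent")
        assert not (s1 & s2).any()
        assert s1.any() and s2.any()

    def test_intruded_mode_moves_spheres_closer(self):
        s1t, s2t, _ = intruded_spheres(diameter_vox=32, mode="tangent")
        s1i, s2i, _ = intruded_spheres(diameter_vox=32, mode="intruded",
                                       intrusion_depth_nm=8.0)
        x2t = np.argwhere(s2t)[:, 2].min()
        x2i = np.argwhere(s2i)[:, 2].min()
        assert x2t - x2i == pytest.approx(8.0, abs=1.0)
        assert not (s1i & s2i).any()  # the invagination keeps the solids disjoint

    def test_zero_depth_matches_tangent(self):
        s1a, s2a, _ = intruded_spheres(diameter_vox=24, mode="tangent")
        s1b, s2b, _ = intruded_spheres(diameter_vox=24, mode="intruded",
                                       intrusion_depth_nm=0.0)
        assert np.array_equal(s1a, s1b) and np.array_equal(s2a, s2b)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            intruded_spheres(mode="overlapping")
        with pytest.raises(ValueError):
            intruded_spheres(diameter_vox=16, intrusion_depth_nm=100.0,
                             spacing=(1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            intruded_spheres(spacing=(1.0, 1.0, 2.0))


class TestSimulatedVariants:
    def _truth(self):
        _, t_memb, _, _ = make_phantom(_single_shell_spec())
        return t_memb

    def test_zero_jitter_returns_scaled_truth(self):
        truth = self._truth()
        variants = simulate_ai_variants(truth, k=3, boundary_jitter_nm=0.0,
                                        interior_conf=0.9)
        for v in variants:
            assert np.array_equal(v.values, 0.9 * (truth.values > 0.5))

    def test_deterministic_and_distinct_across_variants(self):
        truth = self._truth()
        a = simulate_ai_variants(truth, k=3, seed=4)
        b = simulate_ai_variants(truth, k=3, seed=4)
        for va, vb in zip(a, b):
            assert np.array_equal(va.values, vb.values)
        assert not np.array_equal(a[0].values, a[1].values)

    def test_interiors_agree_far_from_boundary(self):
        from scipy import ndimage
        from voxtract.grid import ProbabilityMap
        # a filled ball: deep interior exists (the 16-nm shell band does not
        # reach 3.5 jitter lengths from its own boundary)
        spacing = (4.0, 4.0, 4.0)
        zz, yy, xx = np.meshgrid(*[np.arange(n) * 4.0 for n in (24, 48, 48)],
                                 indexing="ij")
        dist = np.sqrt((zz - 48) ** 2 + (yy - 96) ** 2 + (xx - 96) ** 2)
        truth = ProbabilityMap((dist <= 40.0).astype(float), spacing=spacing,
                               class_name="Memb")
        mask = truth.values > 0.5
        sdf = (ndimage.distance_transform_edt(~mask, sampling=spacing)
               - ndimage.distance_transform_edt(mask, sampling=spacing))
        jitter = 6.0
        variants = simulate_ai_variants(truth, k=4, boundary_jitter_nm=jitter,
                                        interior_conf=0.9, seed=0)
        deep_in = sdf < -3.5 * jitter
        deep_out = sdf > 3.5 * jitter
        assert deep_in.any() and deep_out.any()
        for v in variants:
            assert np.allclose(v.values[deep_in], 0.9, atol=1e-9)
            assert np.allclose(v.values[deep_out], 0.0, atol=1e-9)

    def test_disagreement_grows_with_jitter(self):
        truth = self._truth()
        small = simulate_ai_variants(truth, k=4, boundary_jitter_nm=4.0, seed=1)
        large = simulate_ai_variants(truth, k=4, boundary_jitter_nm=12.0, seed=1)
        dv_small = delta_v_compare(small).mean_pairwise
        dv_large = delta_v_compare(large).mean_pairwise
        assert dv_large > dv_small

    def test_needs_at_least_two_variants(self):
        with pytest.raises(ValueError):
            simulate_ai_variants(self._truth(), k=1)
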