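"""Rigid transforms, pre-alignment, NMI refinement, resampling, ROI crop."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cortmorph.io import ImageVolume
from cortmorph.phantom import apply_acquisition
from cortmorph.registration import (RigidTransform, axial_roi_slices,
                                    crop_axial_roi, isolate_main_bone,
                                    normalized_mutual_information, prealign,
                                    register_rigid_nmi, resample,
                                    transform_difference)

angles = st.floats(-30, 30, allow_nan=False)
shifts = st.floats(-200, 200, allow_nan=False)


class TestRigidTransform:
    @given(st.tuples(angles, angles, angles), st.tuples(shifts, shifts, shifts))
    def test_inverse_composes_to_identity(self, rot, trans):
        t = RigidTransform(rot, trans, center_um=(50.0, -20.0, 10.0))
        terr, rerr = transform_difference(t.compose(t.inverse()),
                                          RigidTransform.identity())
        assert terr < 1e-6 and rerr < 1e-6

    @given(st.tuples(angles, angles, angles), st.tuples(shifts, shifts, shifts))
    def test_distances_preserved(self, rot, trans):
        t = RigidTransform(rot, trans)
        pts = np.array([[0.0, 0.0, 0.0], [100.0, -30.0, 42.0], [5.0, 5.0, 5.0]])
        moved = t.apply(pts)
        for i in range(3):
            for j in range(i):
                d0 = np.linalg.norm(pts[i] - pts[j])
                d1 = np.linalg.norm(moved[i] - moved[j])
                assert d1 == pytest.approx(d0, abs=1e-8)

    def test_recenter_preserves_mapping(self):
        t = RigidTransform((10, -5, 3), (30, 40, -10), (0, 0, 0))
        t2 = t.recenter((123.0, -4.0, 56.0))
        pts = np.array([[1.0, 2.0, 3.0], [-50.0, 10.0, 70.0]])
        np.testing.assert_allclose(t.apply(pts), t2.apply(pts), atol=1e-9)


class TestIsolateMainBone:
    def test_single_component_unchanged(self):
        mask = np.zeros((10, 10, 10), bool)
        mask[2:8, 2:8, 2:8] = True
        np.testing.assert_array_equal(isolate_main_bone(mask), mask)

    def test_largest_component_survives(self):
        mask = np.zeros((20, 20, 20), bool)
        mask[1:11, 1:11, 1:11] = True        # 1000 voxels
        mask[15:18, 15:18, 15:18] = True     # 27 voxels, disconnected
        out = isolate_main_bone(mask)
        assert out[5, 5, 5] and not out[16, 16, 16]
        assert out.sum() == 1000

    def test_tie_break_is_first_in_scan_order(self):
        mask = np.zeros((4, 4, 10), bool)
        mask[0, 0, 0:2] = True
        mask[3, 3, 7:9] = True
        out = isolate_main_bone(mask)
        assert out[0, 0, 0] and not out[3, 3, 7]

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="no bone"):
            isolate_main_bone(np.zeros((3, 3, 3), bool))


class TestPrealign:
    def test_self_alignment_is_identity(self, clean_cylinder):
        _, volumes, _ = clean_cylinder
        t = prealign(volumes[0], volumes[0])
        terr, rerr = transform_difference(t, RigidTransform.identity())
        assert terr < 1e-6 and rerr < 0.01

    def test_known_translation_recovered(self, clean_cylinder):
        # axially compact object (the shell cropped to the central slab,
        # padded with background): the centre of gravity then tracks all
        # three shift components, including the axial one
        spec, volumes, _ = clean_cylinder
        mask = volumes[0].data >= 425
        compact = np.zeros_like(mask)
        compact[16:48] = mask[16:48]
        reference = apply_acquisition(compact, 0.0, 0.0, 700.0, 150.0,
                                      RigidTransform.identity(), seed=0,
                                      voxel_size_um=spec.voxel_size_um)
        shift = (31.5, -21.0, 10.5)
        moving = apply_acquisition(compact, 0.0, 0.0, 700.0, 150.0,
                                   RigidTransform(translation_um=shift),
                                   seed=0, voxel_size_um=spec.voxel_size_um)
        t = prealign(moving, reference)
        # the corrective transform equals the applied shift's inverse
        np.testing.assert_allclose(t.apply(np.zeros(3)), -np.asarray(shift),
                                   atol=0.1 * spec.voxel_size_um)

    def test_sphere_triggers_translation_only_fallback(self):
        z, y, x = np.mgrid[0:40, 0:40, 0:40]
        sphere = ((z - 20.0) ** 2 + (y - 20.0) ** 2 + (x - 20.0) ** 2) <= 144
        grey = np.where(sphere, 700.0, 150.0)
        vol = ImageVolume(grey, 10.5)
        _, info = prealign(vol, vol, return_info=True)
        assert info["rotation_used"] is False


class TestNMI:
    def test_self_similarity_beats_perturbations(self, clean_cylinder):
        spec, volumes, _ = clean_cylinder
        ref = volumes[0]
        self_nmi = normalized_mutual_information(ref.data, ref.data)
        rng = np.random.default_rng(0)
        for _ in range(10):
            shift = rng.uniform(1.0, 4.0, 3) * spec.voxel_size_um \
                * rng.choice([-1, 1], 3)
            moved = apply_acquisition((ref.data >= 425), 0.0, 0.0, 700.0,
                                      150.0,
                                      RigidTransform(translation_um=tuple(shift)),
                                      seed=0, voxel_size_um=spec.voxel_size_um)
            assert self_nmi > normalized_mutual_information(moved.data, ref.data)

    def test_range(self, rng):
        a = rng.random((20, 20, 20))
        v = normalized_mutual_information(a, rng.random((20, 20, 20)))
        assert 1.0 <= v <= 2.0


class TestRegisterRigidNMI:
    def test_identity_registration_stays_identity(self, default_phantom):
        _, volumes, _ = default_phantom
        result = register_rigid_nmi(volumes[0], volumes[0],
                                    RigidTransform.identity())
        terr, rerr = transform_difference(
            result.transform, RigidTransform.identity(),
            center_um=volumes[0].physical_center_um())
        assert terr / volumes[0].voxel_size_um < 0.05
        assert rerr < 0.05
        assert result.final_metric >= result.info["nmi_init"] - 1e-4


class TestResample:
    def test_identity_preserves_interior(self, default_phantom):
        _, volumes, _ = default_phantom
        out = resample(volumes[0], RigidTransform.identity(), volumes[0])
        a = out.data[4:-4, 4:-4, 4:-4]
        b = volumes[0].data[4:-4, 4:-4, 4:-4]
        np.testing.assert_allclose(a, b, atol=1e-6)

    def test_integer_shift_exact_in_interior(self, clean_cylinder):
        spec, volumes, _ = clean_cylinder
        vs = spec.voxel_size_um
        t = RigidTransform(translation_um=(3 * vs, 0.0, 0.0))
        out = resample(volumes[0], t, volumes[0])
        np.testing.assert_allclose(out.data[4:-4, 4:-4, 4:-7],
                                   volumes[0].data[4:-4, 4:-4, 7:-4],
                                   atol=1e-6)

    def test_constant_volume_nearly_constant(self):
        # the unnormalised Lanczos kernel carries a known ~0.4% DC ripple
        # at fractional offsets; the interior must stay within that bound
        vol = ImageVolume(np.full((24, 24, 24), 400.0), 10.5)
        t = RigidTransform((3.0, -2.0, 5.0), (7.0, -4.0, 2.0),
                           tuple(vol.physical_center_um()))
        out = resample(vol, t, vol)
        np.testing.assert_allclose(out.data[5:-5, 5:-5, 5:-5], 400.0,
                                   atol=0.005 * 400.0)

    def test_roundtrip_error_small(self, default_phantom):
        _, volumes, _ = default_phantom
        vol = volumes[0]
        t = RigidTransform((1.5, -1.0, 2.0), (12.0, -7.0, 4.0),
                           tuple(vol.physical_center_um()))
        back = resample(resample(vol, t, vol), t.inverse(), vol)
        interior = np.s_[6:-6, 6:-6, 6:-6]
        mae = np.abs(back.data[interior] - vol.data[interior]).mean()
        dynamic = vol.data.max() - vol.data.min()
        assert mae < 0.01 * dynamic


class TestAxialROI:
    def test_slice_count_arithmetic(self):
        sl = axial_roi_slices(200, 10.5, tibia_length_um=17850.0,
                              fraction=0.05)
        assert sl.stop - sl.start == 85

    def test_full_fraction_returns_everything(self):
        vol = ImageVolume(np.zeros((40, 8, 8)), 10.5)
        out = crop_axial_roi(vol, tibia_length_um=40 * 10.5, fraction=1.0)
        assert out.shape == vol.shape

    def test_shared_roi_across_timepoints(self):
        sl1 = axial_roi_slices(100, 10.5, 5250.0, 0.1)
        sl2 = axial_roi_slices(100, 10.5, 5250.0, 0.1)
        assert (sl1.start, sl1.stop) == (sl2.start, sl2.stop)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            axial_roi_slices(10, 10.5, 17850.0, 0.5)
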