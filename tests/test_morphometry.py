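"""Static and dynamic 3D morphometric parameters."""

import numpy as np
import pytest

from cortmorph.io import RegionLabelVolume
from cortmorph.morphometry import (MorphometryRecord, dynamic_surfaces,
                                   dynamic_volumes, local_thickness,
                                   net_change_curves, rates,
                                   static_morphometry, thickness_stats)
from cortmorph.remodeling import classify_voxels, label_packages
from cortmorph.segmentation import extract_surfaces, peel_surface_layer, \
    split_cortical_regions

VS = 10.5


def _slab(thickness, size=24):
    mask = np.zeros((size, 16, 16), bool)
    mask[size // 2 - thickness // 2:size // 2 - thickness // 2 + thickness] = True
    return mask


class TestStaticMorphometry:
    def test_cube_arithmetic(self):
        mask = np.zeros((10, 12, 12), bool)
        mask[:, 1:11, 1:11] = True      # 10 x 10 x 10 bone cube
        ct_bv, ct_ar, ct_th = static_morphometry(mask, VS)
        assert ct_bv == pytest.approx(1000 * VS ** 3)
        assert ct_ar == pytest.approx(ct_bv / (10 * VS))

    def test_slab_thickness_approaches_true_thickness(self):
        # slab spans the full cross-section: laterally unbounded behaviour
        for t in (6, 10):
            _, _, ct_th = static_morphometry(_slab(t), VS)
            assert ct_th == pytest.approx(t * VS, abs=VS)

    def test_cylinder_wall_thickness(self, clean_cylinder):
        spec, _, truth = clean_cylinder
        _, _, ct_th = static_morphometry(truth.true_bone_masks[0], VS)
        wall = spec.outer_radius_um - spec.inner_radius_um   # 84 um
        assert ct_th == pytest.approx(wall, abs=VS)

    def test_empty_mask_errors(self):
        with pytest.raises(ValueError, match="empty"):
            static_morphometry(np.zeros((4, 4, 4), bool), VS)


class TestLocalThickness:
    def test_two_voxel_slab_upsampled(self):
        th = local_thickness(_slab(2), VS, upsample=2)
        assert th[th > 0].mean() == pytest.approx(2 * VS, abs=VS / 2)

    def test_single_voxel_is_one_voxel_thick(self):
        mask = np.zeros((7, 7, 7), bool)
        mask[3, 3, 3] = True
        th = local_thickness(mask, VS, upsample=2)
        assert th[th > 0].mean() == pytest.approx(VS)

    def test_scale_equivariance(self):
        mask = _slab(4)
        a = local_thickness(mask, VS)
        b = local_thickness(mask, 2 * VS)
        np.testing.assert_allclose(b, 2 * a)


def _rmap_from_masks(m0, m1, region_label=1):
    labels = RegionLabelVolume(
        np.where(m0 | m1, region_label, 0).astype(np.uint8), VS)
    return classify_voxels(m0, m1, labels)


class TestDynamicVolumes:
    def test_no_events_zero(self, rng):
        m = rng.random((8, 8, 8)) < 0.5
        rmap = _rmap_from_masks(m, m)
        assert dynamic_volumes(rmap, m, "endocortical") == (0.0, 0.0)

    def test_percentage_arithmetic(self):
        m0 = np.zeros((20, 20, 20), bool)
        m0[:5] = True                              # 2000 voxels
        m1 = m0.copy()
        m1[10, 4:9, 4:8] = True                    # 20 formed voxels
        rmap = _rmap_from_masks(m0, m1)
        mv, ev = dynamic_volumes(rmap, m0, "endocortical")
        assert mv == pytest.approx(100.0 * 20 / 2000)
        assert ev == 0.0

    def test_zero_denominator_errors(self):
        m = np.zeros((4, 4, 4), bool)
        m1 = m.copy()
        m1[1, 1, 1] = True
        rmap = _rmap_from_masks(m, m1)
        with pytest.raises(ValueError, match="zero"):
            dynamic_volumes(rmap, m, "endocortical")


@pytest.fixture(scope="module")
def cylinder_setup(clean_cylinder):
    spec, _, truth = clean_cylinder
    m0 = truth.true_bone_masks[0]
    labels = split_cortical_regions(m0, 42.0, VS)
    surfaces = extract_surfaces(labels)
    return spec, truth, m0, labels, surfaces


class TestDynamicSurfaces:
    def test_whole_surface_apposition_is_100_percent(self, cylinder_setup):
        spec, truth, m0, labels, surfaces = cylinder_setup
        from scipy import ndimage
        m1 = ndimage.binary_dilation(m0)           # grow both surfaces
        rmap = classify_voxels(peel_surface_layer(m0), peel_surface_layer(m1),
                               surfaces.peeled_labels)
        for region in ("endocortical", "periosteal"):
            ms, es = dynamic_surfaces(rmap, surfaces, region)
            assert ms == pytest.approx(100.0)
            assert es == 0.0

    def test_no_events_zero(self, cylinder_setup):
        _, _, m0, _, surfaces = cylinder_setup
        p = peel_surface_layer(m0)
        rmap = classify_voxels(p, p, surfaces.peeled_labels)
        assert dynamic_surfaces(rmap, surfaces, "periosteal") == (0.0, 0.0)

    def test_quarter_stripe_covers_quarter_of_surface(self):
        """A formation stripe over 25% of the circumference along the full
        ROI marks 25 +/- 2 percentage points of the periosteal surface."""
        from cortmorph.phantom import PhantomSpec, RemodelingEvent, \
            generate_phantom
        spec = PhantomSpec(bow_amplitude_um=0.0, ellipticity=0.0,
                           noise_sd=0.0, blur_sigma_um=0.0, seed=2)
        length = (spec.grid_shape[0] - 1) * spec.voxel_size_um
        spec.event_list = [RemodelingEvent(
            "periosteal", "formation", 0, angular_span_deg=90.0,
            axial_span_um=2 * length, thickness_um=21.0,
            centroid_angle_deg=0.0, centroid_z_um=length / 2)]
        # footprint spans the whole length: validation would flag the grid
        # overflow, so clamp the axial span to the grid instead
        spec.event_list[0] = RemodelingEvent(
            "periosteal", "formation", 0, 90.0, length, 21.0, 0.0, length / 2)
        _, truth = generate_phantom(spec)
        m0 = truth.true_bone_masks[0]
        labels = split_cortical_regions(m0, 42.0, VS)
        surfaces = extract_surfaces(labels)
        rmap = classify_voxels(peel_surface_layer(m0),
                               peel_surface_layer(truth.true_bone_masks[1]),
                               surfaces.peeled_labels)
        ms, _ = dynamic_surfaces(rmap, surfaces, "periosteal")
        assert ms == pytest.approx(25.0, abs=2.0)

    def test_empty_surface_errors(self, cylinder_setup):
        _, _, m0, _, surfaces = cylinder_setup
        import dataclasses
        empty = dataclasses.replace(
            surfaces, periosteal_surface=np.zeros_like(m0))
        p = peel_surface_layer(m0)
        rmap = classify_voxels(p, p, surfaces.peeled_labels)
        with pytest.raises(ValueError, match="empty"):
            dynamic_surfaces(rmap, empty, "periosteal")


class TestThicknessStats:
    def _packages(self, formed_mask):
        m0 = np.zeros_like(formed_mask)
        rmap = _rmap_from_masks(m0, formed_mask)
        return label_packages(rmap, "formed", "endocortical")

    def test_uniform_two_voxel_layer(self):
        result = thickness_stats(self._packages(_slab(2)))
        assert result.value_um == pytest.approx(2 * VS, abs=VS / 2)

    def test_single_voxel_package(self):
        m = np.zeros((6, 6, 6), bool)
        m[3, 3, 3] = True
        result = thickness_stats(self._packages(m))
        assert result.value_um == pytest.approx(VS)

    def test_equal_volume_weighting(self):
        m = np.zeros((30, 40, 40), bool)
        m[5, 2:14, 2:14] = True            # 1 voxel thick, 144 voxels
        m[15:18, 2:10, 2:8] = True         # 3 voxels thick, 144 voxels
        result = thickness_stats(self._packages(m))
        assert result.n_packages == 2
        assert result.value_um == pytest.approx(2 * VS, abs=VS / 2)

    def test_empty_reports_zero_with_flag(self):
        result = thickness_stats(self._packages(np.zeros((5, 5, 5), bool)))
        assert result.value_um == 0.0 and result.empty


class TestRates:
    def test_definitional_identities(self):
        rec = MorphometryRecord(region="periosteal", t_end_day=15.0,
                                MV_BV_pct=7.5, EV_BV_pct=1.2,
                                MTh_um=10.5, ED_um=21.0)
        out = rates(rec, 15.0)
        assert out.MAR3D_um_per_day == pytest.approx(0.7)
        assert out.BFR3D_pct_per_day == pytest.approx(0.5)
        assert out.MAR3D_um_per_day * 15.0 == pytest.approx(out.MTh_um,
                                                            abs=1e-12)
        assert out.BFR3D_pct_per_day * 15.0 == pytest.approx(out.MV_BV_pct,
                                                             abs=1e-12)

    def test_zero_thickness_gives_zero_rate(self):
        rec = MorphometryRecord(region="periosteal", MTh_um=0.0, ED_um=0.0,
                                MV_BV_pct=0.0, EV_BV_pct=0.0)
        out = rates(rec, 15.0)
        assert out.MAR3D_um_per_day == 0.0

    def test_invalid_interval_errors(self):
        with pytest.raises(ValueError):
            rates(MorphometryRecord(region="periosteal"), 0.0)


class TestNetChangeCurves:
    def _rec(self, region, day, mv, ev):
        return MorphometryRecord(region=region, t_start_day=0.0,
                                 t_end_day=day, MV_BV_pct=mv, EV_BV_pct=ev)

    def test_formation_only_is_nondecreasing(self):
        recs = [self._rec("periosteal", d, mv, 0.0)
                for d, mv in [(5, 1.0), (10, 2.5), (15, 4.0)]]
        curve = net_change_curves(recs)
        deltas = curve["delta_BV_pct"].to_numpy()
        assert (np.diff(deltas) >= 0).all()

    def test_balanced_remodeling_nets_zero(self):
        curve = net_change_curves([self._rec("endocortical", 15, 2.0, 2.0)])
        assert curve["delta_BV_pct"].iloc[-1] == 0.0

    def test_requires_day0_anchoring(self):
        rec = MorphometryRecord(region="periosteal", t_start_day=5.0,
                                t_end_day=15.0, MV_BV_pct=1.0, EV_BV_pct=0.0)
        with pytest.raises(ValueError, match="day-0"):
            net_change_curves([rec])


class TestScaleEquivariance:
    def test_voxel_size_scaling(self, clean_cylinder):
        _, _, truth = clean_cylinder
        mask = truth.true_bone_masks[0]
        bv1, ar1, th1 = static_morphometry(mask, VS)
        bv2, ar2, th2 = static_morphometry(mask, 2 * VS)
        assert bv2 == pytest.approx(8 * bv1)
        assert th2 == pytest.approx(2 * th1)
        # normalised quantities are voxel-size independent
        rmap1 = _rmap_from_masks(mask, np.roll(mask, 1, axis=2))
        mv1, _ = dynamic_volumes(rmap1, mask, "endocortical")
        rmap2 = _rmap_from_masks(mask, np.roll(mask, 1, axis=2))
        rmap2.voxel_size_um = 2 * VS
        mv2, _ = dynamic_volumes(rmap2, mask, "endocortical")
        assert mv1 == pytest.approx(mv2)
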