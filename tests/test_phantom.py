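import numpy as np
import pytest

from phantomtract import (
    BundleSpec,
    MaskRecipe,
    PhantomSpec,
    ROISpec,
    SourceSpec,
    bundle_mask,
    demo_spec,
    make_fiber_field,
    make_masks,
    make_roi_atlas,
    make_species_pair,
    straight_tube_spec,
)
from phantomtract.masks import MaskError
from phantomtract.phantom import PhantomError, merged_segment_masks, source_seed_mask


def _single_bundle_spec(bundle, shape=(48, 16, 16), **kw):
    return PhantomSpec(shape=shape, voxel_size_mm=1.0, bundles=(bundle,), **kw)


# ------------------------------------------------------------------ fields


def test_straight_tube_orientations_follow_axis():
    """Zero dispersion on a straight +x tube: every in-tube mean is (1,0,0)."""
    field = make_fiber_field(straight_tube_spec())
    support = field.support
    assert support.any()
    ptr = field.index_volume[support][:, 0]
    assert np.allclose(np.abs(field.means[ptr] @ [1.0, 0.0, 0.0]), 1.0, atol=1e-12)
    # dispersion 0: every sample equals the population mean exactly
    assert np.array_equal(field.samples, np.repeat(field.means[:, None, :],
                                                   field.n_orientation_samples, axis=1))


def test_arc_tangents_match_analytic_circle_tangent():
    """Quarter-circle centerline: in-tube orientations within 5 degrees of the
    closed-form circle tangent at the nearest centerline point."""
    R, cx, cy, z = 20.0, 6.0, 24.0, 8.0
    theta = np.deg2rad(np.arange(0.0, 90.5, 1.0))
    pts = np.stack([cx + R * np.sin(theta), cy - R * np.cos(theta),
                    np.full_like(theta, z)], axis=1)
    spec = _single_bundle_spec(
        BundleSpec("arc", tuple(map(tuple, pts)), radius_mm=2.0, dispersion_deg=0.0),
        shape=(32, 32, 16),
    )
    field = make_fiber_field(spec)
    centers = spec.grid.voxel_centers()[field.support]
    ptr = field.index_volume[field.support][:, 0]
    means = field.means[ptr]
    # analytic tangent at the angle of the nearest *arc* point: the circle
    # projection clamped to the arc's angular range (cap voxels project to
    # the endpoints)
    ang = np.arctan2(centers[:, 0] - cx, -(centers[:, 1] - cy))
    ang = np.clip(ang, 0.0, np.pi / 2)
    tangent = np.stack([np.cos(ang), np.sin(ang), np.zeros_like(ang)], axis=1)
    cosang = np.abs(np.einsum("ij,ij->i", means, tangent))
    assert np.all(cosang >= np.cos(np.deg2rad(5.0)))


def test_orthogonal_crossing_gets_two_populations_with_split_fractions():
    a = BundleSpec("a", ((2.0, 8.0, 8.0), (14.0, 8.0, 8.0)), 2.0, 0.0)
    b = BundleSpec("b", ((8.0, 2.0, 8.0), (8.0, 14.0, 8.0)), 2.0, 0.0)
    spec = PhantomSpec((16, 16, 16), 1.0, (a, b))
    field = make_fiber_field(spec)
    crossing = field.n_populations == 2
    assert crossing.any()
    ptr = field.index_volume[crossing][:, :2]
    assert np.allclose(field.fractions[ptr], 0.5)
    per_voxel_sum = field.fractions[ptr].sum(axis=1)
    assert np.all(per_voxel_sum <= 1.0 + 1e-12)


def test_field_is_deterministic_and_unit_norm():
    spec = demo_spec(rng_seed=21)
    f1, f2 = make_fiber_field(spec), make_fiber_field(spec)
    assert np.array_equal(f1.samples, f2.samples)
    assert np.array_equal(f1.index_volume, f2.index_volume)
    assert np.allclose(np.linalg.norm(f1.samples, axis=-1), 1.0, atol=1e-9)


def test_dispersion_spreads_samples_about_the_mean():
    spec = straight_tube_spec(dispersion_deg=10.0, rng_seed=3)
    field = make_fiber_field(spec)
    cos = np.abs(np.einsum("pkj,pj->pk", field.samples, field.means))
    ang = np.degrees(np.arccos(np.clip(cos, -1, 1)))
    # folded-normal angles: nonzero spread, SD in the right ballpark
    assert ang.std() > 2.0
    assert np.percentile(ang, 99) < 45.0


def test_porosity_interval_reduces_volume_fraction():
    base = straight_tube_spec().bundles[0]
    porous = BundleSpec(base.name, base.control_points_mm, base.radius_mm, 0.0,
                        base.volume_fraction, porosity_interval=(0.4, 0.6),
                        porosity_factor=0.5)
    spec = _single_bundle_spec(porous)
    field = make_fiber_field(spec)
    fr = field.fractions
    assert np.isclose(fr.min(), 0.5 * base.volume_fraction)
    assert np.isclose(fr.max(), base.volume_fraction)


def test_centerline_outside_grid_is_rejected():
    bad = BundleSpec("bad", ((2.0, 8.0, 8.0), (60.0, 8.0, 8.0)), 2.0)
    with pytest.raises(PhantomError, match="leaves the grid"):
        make_fiber_field(_single_bundle_spec(bad))


# ------------------------------------------------------------------ masks


def test_seed_voxels_lie_inside_the_bundle_tube(straight_phantom):
    spec = straight_phantom.spec
    masks = straight_phantom.masks["tube"]
    tube = bundle_mask(spec, "tube")
    assert masks.seed.any()
    assert np.all(tube[masks.seed])


def test_waypoint_is_a_full_coronal_slab(straight_phantom):
    spec = straight_phantom.spec
    w = straight_phantom.masks["tube"].waypoints[0]
    x = spec.grid.voxel_centers()[..., 0]
    lo, hi = spec.recipe("tube").waypoint_x_mm
    assert np.array_equal(w, (x >= lo) & (x <= hi))


def test_posterior_exclusion_disjoint_from_seed(straight_phantom):
    masks = straight_phantom.masks["tube"]
    for e in masks.all_exclusions():
        assert not np.any(masks.seed & e)


def test_empty_seed_slab_errors():
    spec = straight_tube_spec()
    recipe = MaskRecipe("off", "tube", seed_x_mm=(45.0, 47.0), waypoint_x_mm=None)
    with pytest.raises(MaskError, match="seed slab"):
        make_masks(spec, recipe)


# ------------------------------------------------------------------ atlas


def test_roi_rasterization_matches_brute_force():
    spec = PhantomSpec(
        (24, 24, 24), 1.0,
        bundles=(BundleSpec("t", ((4.0, 12.0, 12.0), (20.0, 12.0, 12.0)), 2.0),),
        rois=(ROISpec("ball", (12.0, 12.0, 12.0), 10.0),),
    )
    atlas = make_roi_atlas(spec)
    centers = spec.grid.voxel_centers()
    expected = np.linalg.norm(centers - np.array([12.0, 12.0, 12.0]), axis=-1) <= 10.0
    assert np.array_equal(atlas.labels == 1, expected)


def test_single_voxel_roi():
    spec = PhantomSpec(
        (9, 9, 9), 1.0,
        bundles=(BundleSpec("t", ((1.0, 4.0, 4.0), (7.0, 4.0, 4.0)), 1.5),),
        rois=(ROISpec("dot", (4.0, 4.0, 1.0), 0.5),),
    )
    atlas = make_roi_atlas(spec)
    assert (atlas.labels == 1).sum() == 1


def test_overlapping_rois_error_names_both():
    spec = PhantomSpec(
        (32, 32, 32), 1.0,
        bundles=(BundleSpec("t", ((4.0, 16.0, 16.0), (28.0, 16.0, 16.0)), 2.0),),
        rois=(ROISpec("left", (12.0, 16.0, 16.0), 10.0),
              ROISpec("right", (13.0, 16.0, 16.0), 10.0)),
    )
    with pytest.raises(PhantomError, match="'left' and 'right'"):
        make_roi_atlas(spec)


# ------------------------------------------------------------------ species pair


def test_species_pair_scales_world_coordinates(demo):
    human, macaque = make_species_pair(demo, scale=0.5)
    for hb, mb in zip(human.spec.bundles, macaque.spec.bundles):
        assert mb.name == hb.name
        assert np.allclose(np.asarray(mb.control_points_mm),
                           0.5 * np.asarray(hb.control_points_mm))
        assert np.isclose(mb.radius_mm, 0.5 * hb.radius_mm)
    assert human.tracking.step_size_mm == 0.25
    assert macaque.tracking.step_size_mm == 0.1
    assert set(human.masks) == set(macaque.masks)


def test_sub_voxel_scaled_radius_is_rejected(demo):
    with pytest.raises(PhantomError, match="sub-voxel"):
        make_species_pair(demo, scale=0.5, macaque_voxel_size_mm=2.0)


def test_merged_segment_masks_partition(demo):
    merged, med, lat = merged_segment_masks(demo)
    assert np.array_equal(merged, med | lat)
    assert not np.any(med & lat)
    assert med.any() and lat.any()


def test_source_seed_mask_lies_on_fiber_support(demo):
    field = make_fiber_field(demo)
    for s in demo.sources:
        m = source_seed_mask(demo, s)
        assert m.any()
        assert np.all(field.support[m])
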