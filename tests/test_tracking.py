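from dataclasses import replace

import numpy as np
import pytest

from phantomtract import (
    MaskSet,
    Streamline,
    TrackingConfig,
    filter_streamline,
    propagate,
    sample_direction,
    track_bundle,
    visitation_map,
)
from phantomtract.grid import VoxelGrid
from phantomtract.phantom import junction_arm_mask, mid_exclusion_mask
from phantomtract.tracking import (
    REJECTED_EXCLUSION,
    REJECTED_WAYPOINT,
    RETAINED,
    STOP_CURVATURE,
    TrackingError,
)

from conftest import make_field


# ------------------------------------------------------------ direction draws


def test_single_population_aligns_to_heading(one_voxel_field):
    cfg = TrackingConfig(rng_seed=0)
    rng = np.random.default_rng(0)
    d = sample_direction(one_voxel_field, [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], cfg, rng)
    assert np.allclose(d, [1.0, 0.0, 0.0])
    d = sample_direction(one_voxel_field, [0.0, 0.0, 0.0], [-1.0, 0.0, 0.0], cfg, rng)
    assert np.allclose(d, [-1.0, 0.0, 0.0])  # axial sign alignment


def test_nearest_population_always_wins():
    """Two zero-dispersion populations at 10 and 80 degrees from the heading:
    the 10-degree one is chosen in every one of 1000 draws."""
    m10 = (np.cos(np.deg2rad(10)), np.sin(np.deg2rad(10)), 0.0)
    m80 = (np.cos(np.deg2rad(80)), np.sin(np.deg2rad(80)), 0.0)
    field = make_field((1, 1, 1), {(0, 0, 0): [(m10, 0.4), (m80, 0.4)]})
    cfg = TrackingConfig()
    rng = np.random.default_rng(7)
    for _ in range(1000):
        d = sample_direction(field, [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], cfg, rng)
        assert np.allclose(d, m10)


def test_fraction_threshold_filters_populations(one_voxel_field):
    cfg = TrackingConfig(fraction_threshold=0.9)
    rng = np.random.default_rng(0)
    d = sample_direction(one_voxel_field, [0.0, 0.0, 0.0], [1.0, 0.0, 0.0], cfg, rng)
    assert d is None


def test_seeding_draw_is_fraction_weighted():
    """With fractions 0.75 / 0.25 the seeding choice frequencies match."""
    ma, mb = (1.0, 0.0, 0.0), (0.0, 1.0, 0.0)
    field = make_field((1, 1, 1), {(0, 0, 0): [(ma, 0.75), (mb, 0.25)]})
    cfg = TrackingConfig()
    rng = np.random.default_rng(5)
    n = 4000
    picks = sum(
        np.allclose(
            np.abs(sample_direction(field, [0, 0, 0], None, cfg, rng)), ma
        )
        for _ in range(n)
    )
    assert abs(picks / n - 0.75) < 3 * np.sqrt(0.75 * 0.25 / n)


def test_position_outside_grid_is_contract_violation(one_voxel_field):
    with pytest.raises(TrackingError):
        sample_direction(one_voxel_field, [5.0, 0.0, 0.0], None,
                         TrackingConfig(), np.random.default_rng(0))


# ------------------------------------------------------------ propagation


def test_uniform_field_unidirectional_walk(straight_phantom):
    """Uniform +x tube, zero dispersion, 10 steps: 11 collinear points 0.25 mm apart."""
    cfg = TrackingConfig.human(max_steps=10, bidirectional=False, rng_seed=1)
    s = propagate(straight_phantom.field, [12.0, 8.0, 8.0], cfg)
    assert len(s) == 11
    steps = np.diff(s.points, axis=0)
    assert np.allclose(np.linalg.norm(steps, axis=1), 0.25, atol=1e-9)
    assert np.allclose(steps / 0.25, [1.0, 0.0, 0.0], atol=1e-12)


def test_junction_stops_at_curvature_threshold(junction_phantom):
    cfg = replace(junction_phantom.tracking, curvature_threshold=0.2, rng_seed=4)
    tg, sset = track_bundle(junction_phantom.field, junction_phantom.masks["elbow"], cfg)
    arm = junction_arm_mask(junction_phantom.spec)
    assert tg.counts[arm].sum() == 0
    assert all(s.stop_reason_end == STOP_CURVATURE for s in sset.streamlines)


def test_junction_traversed_with_threshold_disabled(junction_phantom):
    cfg = replace(junction_phantom.tracking, curvature_threshold=-1.0, rng_seed=4)
    tg, _ = track_bundle(junction_phantom.field, junction_phantom.masks["elbow"], cfg)
    assert tg.counts[junction_arm_mask(junction_phantom.spec)].sum() > 0


def test_step_lengths_exact_and_bidirectional_halves_joined(straight_phantom):
    cfg = replace(straight_phantom.tracking, n_samples=20, rng_seed=9)
    _, sset = track_bundle(straight_phantom.field, straight_phantom.masks["tube"], cfg)
    assert len(sset)
    for s in sset.streamlines:
        d = np.linalg.norm(np.diff(s.points, axis=0), axis=1)
        assert np.allclose(d, cfg.step_size_mm, atol=1e-6)


def test_zero_dispersion_streamlines_stay_near_centerline(straight_phantom):
    """Zero dispersion: motion is purely axial, so the off-axis distance never
    exceeds the seeding envelope (tube radius + half a voxel diagonal of
    jitter) plus one step."""
    cfg = replace(straight_phantom.tracking, n_samples=50, rng_seed=2)
    _, sset = track_bundle(straight_phantom.field, straight_phantom.masks["tube"], cfg)
    radius = straight_phantom.spec.bundles[0].radius_mm
    half_diag = np.linalg.norm(straight_phantom.spec.grid.voxel_size_mm[1:]) / 2
    for s in sset.retained():
        off_axis = np.linalg.norm(s.points[:, 1:] - np.array([8.0, 8.0]), axis=1)
        assert np.all(off_axis <= radius + half_diag + cfg.step_size_mm)


# ------------------------------------------------------------ filtering


def _line(p0, p1, n=10):
    return Streamline(np.linspace(p0, p1, n))


def test_filter_streamline_statuses():
    grid = VoxelGrid.isotropic((10, 10, 10), 1.0)
    excl = np.zeros(grid.shape, bool)
    excl[7, :, :] = True
    way = np.zeros(grid.shape, bool)
    way[5, :, :] = True
    seed = np.zeros(grid.shape, bool)
    seed[1, 5, 5] = True
    masks = MaskSet(grid, seed, waypoints=[way], exclusions=[excl])

    through = _line([1.0, 5.0, 5.0], [7.0, 5.0, 5.0])
    assert filter_streamline(through, masks).status == REJECTED_EXCLUSION
    ok = _line([1.0, 5.0, 5.0], [6.0, 5.0, 5.0])
    assert filter_streamline(ok, masks).status == RETAINED
    short = _line([1.0, 5.0, 5.0], [3.0, 5.0, 5.0])
    assert filter_streamline(short, masks).status == REJECTED_WAYPOINT


def test_retained_streamlines_respect_masks_exhaustively(straight_phantom):
    """No retained streamline touches any exclusion voxel; every retained
    streamline intersects every waypoint — asserted point by point."""
    masks = straight_phantom.masks["tube"]
    cfg = replace(straight_phantom.tracking, n_samples=30, rng_seed=3)
    _, sset = track_bundle(straight_phantom.field, masks, cfg)
    assert sset.retained()
    grid = masks.grid
    for s in sset.retained():
        ijk = grid.voxel_index(s.points)
        for e in masks.all_exclusions():
            assert not e[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any()
        for w in masks.waypoints:
            assert w[ijk[:, 0], ijk[:, 1], ijk[:, 2]].any()


def test_exclusion_plane_blocks_everything(straight_phantom):
    spec = straight_phantom.spec
    base = straight_phantom.masks["tube"]
    blocked = MaskSet(
        base.grid, base.seed, base.waypoints,
        base.exclusions + [mid_exclusion_mask(spec)], base.csf, name="blocked",
    )
    cfg = replace(straight_phantom.tracking, n_samples=20, rng_seed=5)
    tg, sset = track_bundle(straight_phantom.field, blocked, cfg)
    assert len(sset.retained()) == 0
    assert tg.empty and tg.counts.sum() == 0


# ------------------------------------------------------------ visitation


def test_visitation_counts_unique_visits_per_streamline():
    grid = VoxelGrid.isotropic((4, 4, 4), 1.0)
    wiggle = Streamline(np.array([[1.0, 1.0, 1.0], [1.2, 1.0, 1.0],
                                  [0.9, 1.0, 1.0], [1.1, 1.0, 1.0]]))
    tg = visitation_map([wiggle], grid)
    assert tg.counts[1, 1, 1] == 1
    three = [_line([0.0, 1.0, 1.0], [3.0, 1.0, 1.0]) for _ in range(3)]
    tg3 = visitation_map(three, grid)
    assert tg3.counts[2, 1, 1] == 3


def test_visitation_matches_brute_force_oracle():
    """Hand-placed polylines against an independent point-in-voxel scan."""
    rng = np.random.default_rng(42)
    grid = VoxelGrid.isotropic((6, 6, 6), 1.0)
    lines = [Streamline(rng.uniform(-0.4, 5.4, size=(rng.integers(2, 30), 3)))
             for _ in range(10)]
    tg = visitation_map(lines, grid)

    expected = np.zeros(grid.shape, dtype=int)
    for s in lines:
        seen = set()
        for p in s.points:
            ijk = tuple(int(round(v)) for v in grid.world_to_voxel(p))
            seen.add(ijk)
        for ijk in seen:
            expected[ijk] += 1
    assert np.array_equal(tg.counts, expected)


def test_empty_input_gives_flagged_zero_map():
    grid = VoxelGrid.isotropic((3, 3, 3), 1.0)
    tg = visitation_map([], grid)
    assert tg.empty and tg.counts.sum() == 0


# ------------------------------------------------------------ reproducibility


def test_tracking_is_bitwise_reproducible(straight_phantom):
    cfg = replace(straight_phantom.tracking, n_samples=25, rng_seed=17)
    tg1, s1 = track_bundle(straight_phantom.field, straight_phantom.masks["tube"], cfg)
    tg2, s2 = track_bundle(straight_phantom.field, straight_phantom.masks["tube"], cfg)
    assert np.array_equal(tg1.counts, tg2.counts)
    assert len(s1) == len(s2)
    for a, b in zip(s1.streamlines, s2.streamlines):
        assert np.array_equal(a.points, b.points)
        assert a.status == b.status


def test_doubling_samples_doubles_retained_in_expectation():
    """Retained totals scale with n_samples (binomial model, 3 SE band)."""
    from phantomtract import build_phantom, straight_tube_spec

    ph = build_phantom(straight_tube_spec(dispersion_deg=12.0, rng_seed=8),
                       TrackingConfig.human())
    cfg1 = replace(ph.tracking, n_samples=40, rng_seed=31)
    cfg2 = replace(cfg1, n_samples=80, rng_seed=32)
    _, s1 = track_bundle(ph.field, ph.masks["tube"], cfg1)
    _, s2 = track_bundle(ph.field, ph.masks["tube"], cfg2)
    n1, n2 = len(s1), len(s2)
    k1, k2 = len(s1.retained()), len(s2.retained())
    p = (k1 + k2) / (n1 + n2)
    se = np.sqrt(p * (1 - p) * (1 / n1 + 1 / n2))
    assert abs(k1 / n1 - k2 / n2) < 3 * se
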