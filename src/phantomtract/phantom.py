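"""Synthetic crossing-fiber phantoms.

This module builds the stand-in for a fitted crossing-fiber diffusion model:
a 3-D grid in which each voxel carries up to three fiber populations, each
with an axial mean orientation, a volume fraction and an angular dispersion,
plus pre-drawn orientation samples emulating posterior draws.  Alongside the
fiber field it rasterizes the mask recipes (seed slab, frontal waypoint
plane, posterior exclusion, CSF rind) and ROI label atlases that the
tractography and fingerprint analyses consume.

Geometry is specified as tubes around parametric centerlines in world mm.
Centerline tangents are taken segment-wise (the direction of the control
segment nearest to a voxel), so a sharp corner in the control polygon is a
genuine abrupt orientation change rather than a smoothed turn — this is what
makes curvature-threshold behaviour testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import cKDTree

from .grid import GridError, VoxelGrid
from .masks import MaskError, MaskSet
from .tracking import TrackingConfig

__all__ = [
    "FiberPopulation",
    "FiberField",
    "BundleSpec",
    "SourceSpec",
    "ROISpec",
    "MaskRecipe",
    "PhantomSpec",
    "ROIAtlas",
    "Phantom",
    "PhantomError",
    "make_fiber_field",
    "make_masks",
    "make_roi_atlas",
    "make_species_pair",
    "build_phantom",
    "demo_spec",
    "straight_tube_spec",
    "junction_spec",
    "merged_segment_masks",
]

MAX_POPULATIONS = 3


class PhantomError(ValueError):
    """Raised for invalid phantom geometry or construction failures."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class FiberPopulation:
    """One fiber population in a voxel.

    ``mean_orientation`` is axial (sign-free) and unit-norm;
    ``dispersion_deg`` is the angular SD of orientation samples about it.
    """

    mean_orientation: tuple[float, float, float]
    volume_fraction: float
    dispersion_deg: float

    def __post_init__(self) -> None:
        m = np.asarray(self.mean_orientation, dtype=float)
        if abs(np.linalg.norm(m) - 1.0) > 1e-9:
            raise PhantomError("mean_orientation must be unit-norm")
        if not 0.0 <= self.volume_fraction <= 1.0:
            raise PhantomError("volume_fraction must be in [0, 1]")
        if self.dispersion_deg < 0:
            raise PhantomError("dispersion_deg must be non-negative")


@dataclass
class FiberField:
    """Per-voxel crossing-fiber populations with pre-drawn orientation samples.

    Populations are stored in flat tables indexed by ``index_volume`` (shape
    ``(*grid.shape, MAX_POPULATIONS)``, -1 where no population), which keeps
    memory proportional to the number of in-bundle voxels and makes the
    tracking inner loop a pure gather.
    """

    grid: VoxelGrid
    index_volume: np.ndarray
    means: np.ndarray  # (P, 3) unit axial orientations
    fractions: np.ndarray  # (P,)
    dispersions_deg: np.ndarray  # (P,)
    samples: np.ndarray  # (P, n_orientation_samples, 3), unit-norm

    def __post_init__(self) -> None:
        if self.index_volume.shape != (*self.grid.shape, MAX_POPULATIONS):
            raise PhantomError("index_volume shape mismatch")
        norms = np.linalg.norm(self.samples, axis=-1)
        if self.samples.size and np.max(np.abs(norms - 1.0)) > 1e-9:
            raise PhantomError("orientation samples must be unit-norm")
        per_voxel = np.where(
            self.index_volume >= 0, self.fractions[self.index_volume], 0.0
        )
        if per_voxel.size and per_voxel.sum(axis=-1).max() > 1.0 + 1e-9:
            raise PhantomError("per-voxel volume fractions sum to > 1")

    @property
    def n_orientation_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def n_populations(self) -> np.ndarray:
        return (self.index_volume >= 0).sum(axis=-1).astype(np.uint8)

    @property
    def support(self) -> np.ndarray:
        """Boolean volume: voxels holding at least one population."""
        return self.index_volume[..., 0] >= 0

    def populations_at(self, ijk) -> list[FiberPopulation]:
        i, j, k = (int(v) for v in ijk)
        out = []
        for p in self.index_volume[i, j, k]:
            if p >= 0:
                out.append(
                    FiberPopulation(
                        tuple(self.means[p]),
                        float(self.fractions[p]),
                        float(self.dispersions_deg[p]),
                    )
                )
        return out


@dataclass(frozen=True)
class BundleSpec:
    """A tube of coherent fibers around a polyline centerline (world mm)."""

    name: str
    control_points_mm: tuple  # ordered (>=2) control points
    radius_mm: float
    dispersion_deg: float = 8.0
    volume_fraction: float = 0.7
    porosity_interval: tuple[float, float] | None = None  # normalized arclength
    porosity_factor: float = 0.5  # multiplies volume fraction inside the interval

    def __post_init__(self) -> None:
        pts = np.asarray(self.control_points_mm, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 3:
            raise PhantomError(f"bundle {self.name!r}: need >=2 control points")
        if self.radius_mm <= 0:
            raise PhantomError(f"bundle {self.name!r}: radius must be positive")
        if not 0.0 < self.volume_fraction <= 1.0:
            raise PhantomError(f"bundle {self.name!r}: volume fraction in (0, 1]")
        if not 0.0 < self.porosity_factor <= 1.0:
            raise PhantomError(f"bundle {self.name!r}: porosity factor in (0, 1]")

    @property
    def points(self) -> np.ndarray:
        return np.asarray(self.control_points_mm, dtype=float)


@dataclass(frozen=True)
class SourceSpec:
    """A gray-matter-analog source region (sphere), feeding one bundle."""

    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float
    bundle: str


@dataclass(frozen=True)
class ROISpec:
    name: str
    center_mm: tuple[float, float, float]
    radius_mm: float


@dataclass(frozen=True)
class MaskRecipe:
    """Placement of seed/waypoint/exclusion volumes for one tract.

    Slabs are intervals on the first world axis (the anterior-posterior
    analog): the seed slab is intersected with the bundle tube, the waypoint
    is a full coronal-plane slab, and the posterior exclusion forbids
    tracking behind the seed region.
    """

    name: str
    bundle: str
    seed_x_mm: tuple[float, float]
    waypoint_x_mm: tuple[float, float] | None
    posterior_exclusion_max_x_mm: float | None = None
    csf_rind: bool = True


@dataclass(frozen=True)
class PhantomSpec:
    shape: tuple[int, int, int]
    voxel_size_mm: float
    bundles: tuple[BundleSpec, ...]
    sources: tuple[SourceSpec, ...] = ()
    rois: tuple[ROISpec, ...] = ()
    recipes: tuple[MaskRecipe, ...] = ()
    rng_seed: int = 0
    n_orientation_samples: int = 32

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise PhantomError("voxel size must be positive")
        if self.n_orientation_samples < 1:
            raise PhantomError("need at least one orientation sample")
        names = [b.name for b in self.bundles]
        if len(set(names)) != len(names):
            raise PhantomError("duplicate bundle names")
        for r in self.recipes:
            if r.bundle not in names:
                raise PhantomError(f"recipe {r.name!r} references unknown bundle")
        for s in self.sources:
            if s.bundle not in names:
                raise PhantomError(f"source {s.name!r} references unknown bundle")

    @property
    def grid(self) -> VoxelGrid:
        return VoxelGrid.isotropic(self.shape, self.voxel_size_mm)

    def bundle(self, name: str) -> BundleSpec:
        for b in self.bundles:
            if b.name == name:
                return b
        raise KeyError(name)

    def recipe(self, name: str) -> MaskRecipe:
        for r in self.recipes:
            if r.name == name:
                return r
        raise KeyError(name)


@dataclass
class ROIAtlas:
    """Integer ROI label volume (0 = background) with a label->name table."""

    grid: VoxelGrid
    labels: np.ndarray
    names: dict[int, str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.shape != self.grid.shape:
            raise PhantomError("atlas label volume shape mismatch")
        present = set(np.unique(self.labels).tolist()) - {0}
        missing = present - set(self.names)
        if missing:
            raise PhantomError(f"labels without names: {sorted(missing)}")

    @property
    def roi_names(self) -> list[str]:
        """Names in canonical (ascending-label) order."""
        return [self.names[l] for l in sorted(self.names)]

    def mask(self, name: str) -> np.ndarray:
        for label, n in self.names.items():
            if n == name:
                return self.labels == label
        raise KeyError(name)


@dataclass
class Phantom:
    """A fully built phantom: fiber field + per-tract masks + atlas + config."""

    species: str
    spec: PhantomSpec
    field: FiberField
    masks: dict[str, MaskSet]
    atlas: ROIAtlas | None
    tracking: TrackingConfig


# --------------------------------------------------------------------------
# centerline machinery


def _densify(bundle: BundleSpec, ds: float):
    """Resample a control polyline at spacing <= ds.

    Returns (points (M,3), tangents (M,3), normalized arclength (M,)).
    Tangents are the unit direction of the control segment each densified
    point lies on — deliberately not smoothed across corners.
    """
    pts = bundle.points
    seg_pts, seg_tan = [], []
    for a, b in zip(pts[:-1], pts[1:]):
        length = np.linalg.norm(b - a)
        if length < 1e-12:
            raise PhantomError(f"bundle {bundle.name!r}: degenerate control segment")
        n = max(2, int(np.ceil(length / ds)) + 1)
        t = np.linspace(0.0, 1.0, n)[:-1]
        seg_pts.append(a[None, :] + t[:, None] * (b - a)[None, :])
        seg_tan.append(np.repeat(((b - a) / length)[None, :], len(t), axis=0))
    seg_pts.append(pts[-1][None, :])
    seg_tan.append(seg_tan[-1][-1:])
    dense = np.concatenate(seg_pts)
    tangents = np.concatenate(seg_tan)
    arc = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(dense, axis=0), axis=1))])
    arc = arc / arc[-1] if arc[-1] > 0 else arc
    return dense, tangents, arc


def _bundle_membership(spec: PhantomSpec, bundle: BundleSpec):
    """Voxels inside the tube, with per-voxel tangent and arclength parameter."""
    grid = spec.grid
    pts = bundle.points
    lo = grid.world_to_voxel(pts.min(axis=0))
    hi = grid.world_to_voxel(pts.max(axis=0))
    if np.any(np.minimum(lo, hi) < -0.5) or np.any(
        np.maximum(lo, hi) > np.asarray(grid.shape) - 0.5
    ):
        raise PhantomError(f"bundle {bundle.name!r}: centerline leaves the grid")
    dense, tangents, arc = _densify(bundle, ds=spec.voxel_size_mm / 4.0)
    centers = grid.voxel_centers().reshape(-1, 3)
    dist, idx = cKDTree(dense).query(centers, workers=-1)
    inside = dist <= bundle.radius_mm
    mask = inside.reshape(grid.shape)
    return mask, tangents[idx[inside]], arc[idx[inside]], np.flatnonzero(inside)


def bundle_mask(spec: PhantomSpec, name: str) -> np.ndarray:
    """Boolean volume of voxels inside the named bundle's tube."""
    return _bundle_membership(spec, spec.bundle(name))[0]


# --------------------------------------------------------------------------
# fiber-field construction


def _draw_samples(means, dispersions_deg, n_samples, rng):
    """Orientation samples: rotate each mean by a folded-normal angle about a
    uniformly random perpendicular axis.  Zero dispersion reproduces the mean
    exactly."""
    P = means.shape[0]
    out = np.repeat(means[:, None, :], n_samples, axis=1)
    disp = np.deg2rad(dispersions_deg)
    active = disp > 0
    if not np.any(active):
        return out
    idx = np.flatnonzero(active)
    m = means[idx]  # (A, 3)
    A = len(idx)
    theta = np.abs(rng.normal(0.0, disp[idx][:, None], size=(A, n_samples)))
    v = rng.normal(size=(A, n_samples, 3))
    v -= np.einsum("asj,aj->as", v, m)[..., None] * m[:, None, :]
    nrm = np.linalg.norm(v, axis=-1, keepdims=True)
    # degenerate draws (numerically parallel to the mean) are re-axised
    bad = nrm[..., 0] < 1e-12
    if np.any(bad):
        fallback = np.cross(m[:, None, :], np.array([1.0, 0.0, 0.0]))
        alt = np.cross(m[:, None, :], np.array([0.0, 1.0, 0.0]))
        small = np.linalg.norm(fallback, axis=-1, keepdims=True) < 1e-6
        fallback = np.where(small, alt, fallback)
        v = np.where(bad[..., None], np.broadcast_to(fallback, v.shape), v)
        nrm = np.linalg.norm(v, axis=-1, keepdims=True)
    axis = v / nrm
    rotated = (
        m[:, None, :] * np.cos(theta)[..., None]
        + np.cross(axis, m[:, None, :]) * np.sin(theta)[..., None]
    )
    rotated /= np.linalg.norm(rotated, axis=-1, keepdims=True)
    out[idx] = rotated
    return out


def make_fiber_field(spec: PhantomSpec) -> FiberField:
    """Rasterize the bundle tubes into a crossing-fiber field.

    Each voxel inside a tube gets a population whose mean orientation is the
    local centerline tangent; voxels inside k tubes get one population per
    bundle with volume fraction 1/k (single-bundle voxels keep the bundle's
    own fraction); a bundle's porosity interval multiplies its fraction by
    the porosity factor.  Orientation samples are drawn deterministically
    from ``spec.rng_seed``.
    """
    grid = spec.grid
    per_bundle = []
    for b in spec.bundles:
        mask, tangents, arc, lin = _bundle_membership(spec, b)
        per_bundle.append((b, tangents, arc, lin))

    counts = np.zeros(int(np.prod(grid.shape)), dtype=np.int8)
    for _, _, _, lin in per_bundle:
        counts[lin] += 1
    if counts.max(initial=0) > MAX_POPULATIONS:
        raise PhantomError(
            f"{int((counts > MAX_POPULATIONS).sum())} voxels fall inside more than "
            f"{MAX_POPULATIONS} bundles"
        )

    entries = []  # (linear voxel, bundle order, mean, fraction, dispersion)
    for bi, (b, tangents, arc, lin) in enumerate(per_bundle):
        k = counts[lin].astype(float)
        frac = np.where(k > 1, 1.0 / k, b.volume_fraction)
        if b.porosity_interval is not None:
            t0, t1 = b.porosity_interval
            frac = np.where((arc >= t0) & (arc <= t1), frac * b.porosity_factor, frac)
        tangents = tangents / np.linalg.norm(tangents, axis=-1, keepdims=True)
        entries.append((lin, np.full(len(lin), bi), tangents, frac,
                        np.full(len(lin), float(b.dispersion_deg))))

    if entries:
        lin = np.concatenate([e[0] for e in entries])
        order = np.concatenate([e[1] for e in entries])
        means = np.concatenate([e[2] for e in entries])
        fracs = np.concatenate([e[3] for e in entries])
        disps = np.concatenate([e[4] for e in entries])
        perm = np.lexsort((order, lin))
        lin, means, fracs, disps = lin[perm], means[perm], fracs[perm], disps[perm]
    else:
        lin = np.empty(0, dtype=int)
        means = np.empty((0, 3))
        fracs = disps = np.empty(0)

    index_volume = np.full((*grid.shape, MAX_POPULATIONS), -1, dtype=np.int32)
    slot = np.zeros_like(counts, dtype=np.int8)
    flat = index_volume.reshape(-1, MAX_POPULATIONS)
    for p, v in enumerate(lin):
        flat[v, slot[v]] = p
        slot[v] += 1

    rng = np.random.default_rng(spec.rng_seed)
    samples = _draw_samples(means, disps, spec.n_orientation_samples, rng)
    return FiberField(grid, index_volume, means, fracs, disps, samples)


# --------------------------------------------------------------------------
# masks, atlas, species pair


def _x_slab(grid: VoxelGrid, lo: float | None, hi: float | None) -> np.ndarray:
    """Coronal-plane slab: voxels whose world x lies in [lo, hi]."""
    x = grid.voxel_centers()[..., 0]
    mask = np.ones(grid.shape, dtype=bool)
    if lo is not None:
        mask &= x >= lo
    if hi is not None:
        mask &= x <= hi
    return mask


def _rind(grid: VoxelGrid) -> np.ndarray:
    """One-voxel boundary shell: the CSF-analog surrounding the tissue block."""
    m = np.zeros(grid.shape, dtype=bool)
    m[0, :, :] = m[-1, :, :] = True
    m[:, 0, :] = m[:, -1, :] = True
    m[:, :, 0] = m[:, :, -1] = True
    return m


def _sphere(grid: VoxelGrid, center_mm, radius_mm: float) -> np.ndarray:
    d = np.linalg.norm(grid.voxel_centers() - np.asarray(center_mm), axis=-1)
    return d <= radius_mm


def make_masks(spec: PhantomSpec, recipe: str | MaskRecipe) -> MaskSet:
    """Rasterize one tract recipe into a :class:`MaskSet`.

    The seed slab is intersected with the bundle tube (the phantom analog of
    seeding in coherent high-anisotropy white matter); the waypoint is a full
    coronal slab; exclusions are the posterior slab behind the seed plus the
    CSF rind.
    """
    if isinstance(recipe, str):
        recipe = spec.recipe(recipe)
    grid = spec.grid
    tube = bundle_mask(spec, recipe.bundle)
    seed = tube & _x_slab(grid, *recipe.seed_x_mm)
    if not seed.any():
        raise MaskError(
            f"recipe {recipe.name!r}: seed slab does not intersect bundle "
            f"{recipe.bundle!r}"
        )
    waypoints = []
    if recipe.waypoint_x_mm is not None:
        waypoints.append(_x_slab(grid, *recipe.waypoint_x_mm))
    exclusions = []
    if recipe.posterior_exclusion_max_x_mm is not None:
        exclusions.append(_x_slab(grid, None, recipe.posterior_exclusion_max_x_mm))
    csf = _rind(grid) if recipe.csf_rind else None
    return MaskSet(grid, seed, waypoints, exclusions, csf, name=recipe.name)


def source_seed_mask(spec: PhantomSpec, source: str | SourceSpec) -> np.ndarray:
    """Seed mask for a gray-matter-analog source: its sphere restricted to the
    fed bundle's tube (seeding needs fiber support under it)."""
    if isinstance(source, str):
        source = next(s for s in spec.sources if s.name == source)
    m = _sphere(spec.grid, source.center_mm, source.radius_mm)
    m &= bundle_mask(spec, source.bundle)
    if not m.any():
        raise MaskError(f"source {source.name!r}: sphere misses bundle {source.bundle!r}")
    return m


def make_roi_atlas(spec: PhantomSpec) -> ROIAtlas:
    """Rasterize ROI spheres into a label volume; overlaps are an error."""
    if not spec.rois:
        raise PhantomError("no ROIs requested")
    grid = spec.grid
    labels = np.zeros(grid.shape, dtype=np.int16)
    names: dict[int, str] = {}
    for label, roi in enumerate(spec.rois, start=1):
        ball = _sphere(grid, roi.center_mm, roi.radius_mm)
        if not ball.any():
            raise PhantomError(f"ROI {roi.name!r} rasterizes to no voxels")
        clash = labels[ball]
        if np.any(clash):
            other = names[int(clash[clash > 0][0])]
            raise PhantomError(f"ROIs {other!r} and {roi.name!r} overlap")
        labels[ball] = label
        names[label] = roi.name
    return ROIAtlas(grid, labels, names)


def _scale_spec(spec: PhantomSpec, scale: float, voxel_size_mm: float,
                rng_seed: int) -> PhantomSpec:
    def spt(p):
        return tuple(float(c) * scale for c in p)

    bundles = tuple(
        replace(
            b,
            control_points_mm=tuple(spt(p) for p in b.control_points_mm),
            radius_mm=b.radius_mm * scale,
        )
        for b in spec.bundles
    )
    sources = tuple(
        replace(s, center_mm=spt(s.center_mm), radius_mm=s.radius_mm * scale)
        for s in spec.sources
    )
    rois = tuple(
        replace(r, center_mm=spt(r.center_mm), radius_mm=r.radius_mm * scale)
        for r in spec.rois
    )
    recipes = tuple(
        replace(
            r,
            seed_x_mm=(r.seed_x_mm[0] * scale, r.seed_x_mm[1] * scale),
            waypoint_x_mm=None
            if r.waypoint_x_mm is None
            else (r.waypoint_x_mm[0] * scale, r.waypoint_x_mm[1] * scale),
            posterior_exclusion_max_x_mm=None
            if r.posterior_exclusion_max_x_mm is None
            else r.posterior_exclusion_max_x_mm * scale,
        )
        for r in spec.recipes
    )
    return replace(
        spec,
        voxel_size_mm=voxel_size_mm,
        bundles=bundles,
        sources=sources,
        rois=rois,
        recipes=recipes,
        rng_seed=rng_seed,
    )


def make_species_pair(
    spec: PhantomSpec,
    scale: float = 0.5,
    macaque_voxel_size_mm: float | None = None,
) -> tuple["Phantom", "Phantom"]:
    """Build a human-analog / macaque-analog phantom pair.

    The macaque-analog shares the bundle topology but is scaled down in world
    mm (default half extent) with a proportionally finer grid, its own RNG
    seed, and the macaque tracking step size (0.1 mm vs 0.25 mm).
    """
    if macaque_voxel_size_mm is None:
        macaque_voxel_size_mm = spec.voxel_size_mm * scale
    mspec = _scale_spec(spec, scale, macaque_voxel_size_mm, spec.rng_seed + 1)
    for b in mspec.bundles:
        if b.radius_mm < macaque_voxel_size_mm:
            raise PhantomError(
                f"scaled bundle {b.name!r} has sub-voxel tube radius "
                f"({b.radius_mm:g} mm < {macaque_voxel_size_mm:g} mm voxels)"
            )
    human = build_phantom(spec, TrackingConfig.human(), species="human")
    macaque = build_phantom(mspec, TrackingConfig.macaque(), species="macaque")
    return human, macaque


def build_phantom(spec: PhantomSpec, tracking: TrackingConfig,
                  species: str = "human") -> Phantom:
    field = make_fiber_field(spec)
    masks = {r.name: make_masks(spec, r) for r in spec.recipes}
    atlas = make_roi_atlas(spec) if spec.rois else None
    return Phantom(species, spec, field, masks, atlas, tracking)


# --------------------------------------------------------------------------
# canonical geometries


def straight_tube_spec(dispersion_deg: float = 0.0, rng_seed: int = 0) -> PhantomSpec:
    """A single straight tube along +x with a downstream waypoint.

    :func:`mid_exclusion_mask` supplies an extra exclusion slab separating
    seed from waypoint, which must reject every streamline.
    """
    return PhantomSpec(
        shape=(48, 16, 16),
        voxel_size_mm=1.0,
        bundles=(
            BundleSpec(
                name="tube",
                control_points_mm=((6.0, 8.0, 8.0), (42.0, 8.0, 8.0)),
                radius_mm=2.5,
                dispersion_deg=dispersion_deg,
                volume_fraction=0.8,
            ),
        ),
        recipes=(
            MaskRecipe(
                name="tube",
                bundle="tube",
                seed_x_mm=(10.0, 13.0),
                waypoint_x_mm=(36.0, 38.0),
                posterior_exclusion_max_x_mm=2.0,
            ),
        ),
        rng_seed=rng_seed,
    )


def mid_exclusion_mask(spec: PhantomSpec, x_lo: float = 24.0,
                       x_hi: float = 26.0) -> np.ndarray:
    """An exclusion slab separating seed from waypoint on the straight tube."""
    return _x_slab(spec.grid, x_lo, x_hi)


def junction_spec(dispersion_deg: float = 0.0, rng_seed: int = 0) -> PhantomSpec:
    """An L-shaped bundle with a genuine 90-degree orientation flip.

    Streamlines entering the corner propose an orthogonal step (cosine 0), so
    any curvature threshold above 0 stops them there; disabling the threshold
    (-1) lets them round the corner into the vertical arm.
    """
    return PhantomSpec(
        shape=(40, 40, 12),
        voxel_size_mm=1.0,
        bundles=(
            BundleSpec(
                name="elbow",
                control_points_mm=((6.0, 8.0, 6.0), (26.0, 8.0, 6.0), (26.0, 32.0, 6.0)),
                radius_mm=2.5,
                dispersion_deg=dispersion_deg,
                volume_fraction=0.8,
            ),
        ),
        recipes=(
            MaskRecipe(
                name="elbow",
                bundle="elbow",
                seed_x_mm=(8.0, 11.0),
                waypoint_x_mm=None,
                posterior_exclusion_max_x_mm=None,
                csf_rind=False,
            ),
        ),
        rng_seed=rng_seed,
    )


def junction_arm_mask(spec: PhantomSpec, y_min: float = 14.0) -> np.ndarray:
    """Voxels in the vertical arm beyond the junction (world y >= y_min)."""
    y = spec.grid.voxel_centers()[..., 1]
    return y >= y_min


def demo_spec(rng_seed: int = 0, dispersion_deg: float = 8.0) -> PhantomSpec:
    """The two-source merged-bundle phantom used throughout the examples.

    Two ventral tubes — a medial bundle fed by an amygdala-analog source and
    a lateral bundle fed by a temporal-pole-analog source — run anteriorly
    and converge rostrally into a merged segment, with a dorsal control
    bundle and four prefrontal-analog ROI spheres at the rostral end.
    """
    bundles = (
        BundleSpec(
            name="medial",
            control_points_mm=((8.0, 18.0, 16.0), (36.0, 18.0, 16.0), (58.0, 21.0, 16.0)),
            radius_mm=3.0,
            dispersion_deg=dispersion_deg,
        ),
        BundleSpec(
            name="lateral",
            control_points_mm=((8.0, 30.0, 16.0), (36.0, 30.0, 16.0), (58.0, 25.0, 16.0)),
            radius_mm=3.0,
            dispersion_deg=dispersion_deg,
        ),
        BundleSpec(
            name="dorsal",
            control_points_mm=((8.0, 24.0, 26.0), (58.0, 24.0, 26.0)),
            radius_mm=2.5,
            dispersion_deg=dispersion_deg,
        ),
    )
    sources = (
        SourceSpec("amygdala", (10.0, 18.0, 16.0), 2.5, bundle="medial"),
        SourceSpec("temporal_pole", (10.0, 30.0, 16.0), 2.5, bundle="lateral"),
    )
    rois = (
        ROISpec("pfc_medial", (58.0, 18.0, 16.0), 2.0),
        ROISpec("pfc_mid", (58.0, 23.0, 16.0), 2.0),
        ROISpec("pfc_lateral", (58.0, 28.0, 16.0), 2.0),
        ROISpec("pfc_dorsal", (58.0, 24.0, 26.0), 2.0),
    )
    recipes = tuple(
        MaskRecipe(
            name=b,
            bundle=b,
            seed_x_mm=(18.0, 22.0),
            waypoint_x_mm=(44.0, 46.0),
            posterior_exclusion_max_x_mm=2.0,
        )
        for b in ("medial", "lateral", "dorsal")
    )
    return PhantomSpec(
        shape=(64, 48, 32),
        voxel_size_mm=1.0,
        bundles=bundles,
        sources=sources,
        rois=rois,
        recipes=recipes,
        rng_seed=rng_seed,
    )


def merged_segment_masks(spec: PhantomSpec, x_fraction: float = 0.75):
    """Masks for the rostral merged segment of the two ventral bundles.

    Returns ``(merged, medial_half, lateral_half)``: the union of the medial
    and lateral tubes restricted to world x beyond ``x_fraction`` of the grid
    extent, split into halves at the mask's mean y coordinate.
    """
    union = bundle_mask(spec, "medial") | bundle_mask(spec, "lateral")
    xmax = spec.shape[0] * spec.voxel_size_mm
    merged = union & _x_slab(spec.grid, x_fraction * xmax, None)
    if not merged.any():
        raise PhantomError("merged segment is empty")
    y = spec.grid.voxel_centers()[..., 1]
    y_split = y[merged].mean()
    medial_half = merged & (y < y_split)
    lateral_half = merged & (y >= y_split)
    return merged, medial_half, lateral_half
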