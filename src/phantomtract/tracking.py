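"""Probabilistic streamline propagation under seed/waypoint/exclusion masks.

The tracker walks a :class:`~phantomtract.phantom.FiberField` with a fixed
step size.  At each step it looks up the populations of the voxel containing
the current position (nearest-voxel, no interpolation), keeps those whose
volume fraction passes the threshold, picks the population angularly closest
to the current heading (axially, i.e. by ``|cos|``), draws one of its stored
orientation samples and sign-aligns it to the heading.  A proposed direction
whose cosine against the previous direction falls below the curvature
threshold terminates that end; so does leaving the grid or entering a voxel
with no passing population.

Streamlines are seeded from uniformly jittered positions inside each seed
voxel and, by default, propagated bidirectionally: a second pass starts from
the seed with the initial direction negated and the two half-paths are
concatenated (the seed point appears once).  Mask filtering applies to the
full concatenated path: touching any exclusion (or CSF) voxel rejects the
streamline; otherwise every waypoint volume must be intersected.

Reproducibility: all randomness flows from ``TrackingConfig.rng_seed``
through one generator, and every per-step draw is made for the whole batch
of streamlines whether or not each is still active — so a streamline's
trajectory does not depend on when its neighbours terminated.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import TYPE_CHECKING

import numpy as np

from .grid import VoxelGrid, grids_equal
from .masks import MaskError, MaskSet

if TYPE_CHECKING:  # pragma: no cover
    from .phantom import FiberField

__all__ = [
    "TrackingConfig",
    "Streamline",
    "StreamlineSet",
    "Tractogram",
    "TrackingError",
    "sample_direction",
    "propagate",
    "filter_streamline",
    "visitation_map",
    "track_bundle",
]

#: stop reasons for a streamline end
STOP_BOUNDS = "bounds"
STOP_CURVATURE = "curvature"
STOP_MAX_STEPS = "max_steps"
STOP_NO_FIBER = "no_fiber"

RETAINED = "retained"
REJECTED_EXCLUSION = "rejected_exclusion"
REJECTED_WAYPOINT = "rejected_waypoint"


class TrackingError(ValueError):
    pass


@dataclass(frozen=True)
class TrackingConfig:
    """Tracking parameters.

    Defaults are the human protocol: 10,000 samples per seed voxel, at most
    3200 steps per sample, 0.25 mm steps, curvature threshold 0.2 (minimum
    cosine between successive step directions).  The macaque protocol differs
    only in its 0.1 mm step size.
    """

    n_samples: int = 10_000
    max_steps: int = 3200
    step_size_mm: float = 0.25
    curvature_threshold: float = 0.2
    fraction_threshold: float = 0.01
    bidirectional: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.max_steps < 1:
            raise TrackingError("n_samples and max_steps must be positive")
        if self.step_size_mm <= 0:
            raise TrackingError("step size must be positive")
        if not -1.0 <= self.curvature_threshold <= 1.0:
            raise TrackingError("curvature threshold is a cosine in [-1, 1]")
        if not 0.0 <= self.fraction_threshold <= 1.0:
            raise TrackingError("fraction threshold must be in [0, 1]")

    @classmethod
    def human(cls, **overrides) -> "TrackingConfig":
        return cls(**{"step_size_mm": 0.25, **overrides})

    @classmethod
    def macaque(cls, **overrides) -> "TrackingConfig":
        return cls(**{"step_size_mm": 0.1, **overrides})

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class Streamline:
    """One propagated sample: an ordered polyline in world mm."""

    points: np.ndarray  # (m >= 2, 3)
    status: str = RETAINED
    stop_reason_start: str = STOP_NO_FIBER
    stop_reason_end: str = STOP_NO_FIBER

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[0] < 2 or self.points.shape[1] != 3:
            raise TrackingError("a streamline needs >= 2 finite 3-D points")
        if not np.all(np.isfinite(self.points)):
            raise TrackingError("streamline contains non-finite points")

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass
class StreamlineSet:
    streamlines: list[Streamline]
    tract: str = "tract"
    config_hash: str = ""
    rng_seed: int = 0

    def __len__(self) -> int:
        return len(self.streamlines)

    def retained(self) -> list[Streamline]:
        return [s for s in self.streamlines if s.status == RETAINED]


@dataclass
class Tractogram:
    """Per-voxel streamline visitation counts, with optional normalized form."""

    grid: VoxelGrid
    counts: np.ndarray
    normalized: np.ndarray | None = None
    name: str = "tract"
    empty: bool = False

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != self.grid.shape:
            raise TrackingError("count volume shape does not match grid")
        if np.any(self.counts < 0):
            raise TrackingError("visitation counts must be non-negative")


# --------------------------------------------------------------------------
# direction sampling


def _sample_batch(field: "FiberField", pos, heading, threshold, u_pop, u_samp):
    """Vectorized direction draw for a batch of positions.

    ``heading`` is ``(n, 3)`` unit vectors or ``None`` (seeding).  Returns
    ``(directions (n, 3), ok (n,))``; rows with ``ok == False`` found no
    population at/above the fraction threshold (or are outside the grid).
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    n = pos.shape[0]
    ijk = field.grid.voxel_index(pos)
    inb = field.grid.inside(ijk)
    ijk_safe = np.clip(ijk, 0, np.asarray(field.grid.shape) - 1)
    ptr = field.index_volume[ijk_safe[:, 0], ijk_safe[:, 1], ijk_safe[:, 2]]  # (n, 3)
    exists = (ptr >= 0) & inb[:, None]
    frac = np.where(exists, field.fractions[np.clip(ptr, 0, None)], 0.0)
    passing = exists & (frac >= threshold)
    ok = passing.any(axis=1)

    if heading is None:
        w = np.where(passing, frac, 0.0)
        tot = w.sum(axis=1)
        cum = np.cumsum(w, axis=1)
        pick = (u_pop[:, None] * np.where(tot > 0, tot, 1.0)[:, None] >= cum).sum(axis=1)
        pick = np.minimum(pick, ptr.shape[1] - 1)
    else:
        means = field.means[np.clip(ptr, 0, None)]  # (n, 3, 3)
        score = np.abs(np.einsum("npj,nj->np", means, heading))
        score = np.where(passing, score, -1.0)
        pick = np.argmax(score, axis=1)

    chosen = ptr[np.arange(n), pick]
    chosen = np.clip(chosen, 0, None)
    k = np.minimum(
        (u_samp * field.n_orientation_samples).astype(np.int64),
        field.n_orientation_samples - 1,
    )
    d = field.samples[chosen, k].copy()
    if heading is not None:
        flip = np.einsum("nj,nj->n", d, heading) < 0.0
        d[flip] *= -1.0
    d[~ok] = 0.0
    return d, ok


def sample_direction(field: "FiberField", position, heading, cfg: TrackingConfig, rng):
    """Draw one propagation direction at a world position.

    With a heading, the population angularly closest to it (axially) among
    those passing the fraction threshold is used and the returned sample is
    sign-aligned so its dot product with the heading is >= 0.  Without a
    heading (seeding), the population is chosen at random weighted by volume
    fraction.  Returns ``None`` when no population passes.
    """
    position = np.asarray(position, dtype=float)
    if not field.grid.contains_world(position):
        raise TrackingError("position outside the grid")
    u_pop = np.asarray([rng.random()])
    u_samp = np.asarray([rng.random()])
    h = None if heading is None else np.atleast_2d(np.asarray(heading, dtype=float))
    d, ok = _sample_batch(field, position[None, :], h, cfg.fraction_threshold,
                          u_pop, u_samp)
    return d[0] if ok[0] else None


# --------------------------------------------------------------------------
# propagation


def _march(field, start, d0, alive0, cfg, rng):
    """Propagate a batch one direction from ``start`` along initial dirs ``d0``.

    Returns (history (steps, n, 3), active-history (steps, n), stop (n,)).
    ``history[t]`` is the position after step t+1 for streamlines that were
    still active.
    """
    n = start.shape[0]
    stop = np.array([STOP_NO_FIBER] * n, dtype=object)
    pos = start.copy()
    direction = d0.copy()
    active = alive0.copy()

    # first step: along the seeding direction itself
    hist, act_hist = [], []
    nxt = pos + cfg.step_size_mm * direction
    off = ~field.grid.contains_world(nxt)
    stop[active & off] = STOP_BOUNDS
    active = active & ~off
    pos = np.where(active[:, None], nxt, pos)
    hist.append(pos.copy())
    act_hist.append(active.copy())

    for step in range(1, cfg.max_steps):
        if not active.any():
            break
        u_pop = rng.random(n)
        u_samp = rng.random(n)
        d_new, ok = _sample_batch(field, pos, direction, cfg.fraction_threshold,
                                  u_pop, u_samp)
        no_fiber = active & ~ok
        stop[no_fiber] = STOP_NO_FIBER
        cos = np.einsum("nj,nj->n", d_new, direction)
        too_curved = active & ok & (cos < cfg.curvature_threshold)
        stop[too_curved] = STOP_CURVATURE
        active = active & ok & ~too_curved
        nxt = pos + cfg.step_size_mm * d_new
        off = active & ~field.grid.contains_world(nxt)
        stop[off] = STOP_BOUNDS
        active = active & ~off
        pos = np.where(active[:, None], nxt, pos)
        direction = np.where(active[:, None], d_new, direction)
        hist.append(pos.copy())
        act_hist.append(active.copy())
    stop[active] = STOP_MAX_STEPS
    return np.asarray(hist), np.asarray(act_hist), stop


def _propagate_batch(field, seeds, cfg: TrackingConfig, rng):
    """Propagate a batch of seed points; returns a list of
    (points, stop_start, stop_end) or None for seeds with no fiber support."""
    n = seeds.shape[0]
    u_pop = rng.random(n)
    u_samp = rng.random(n)
    d0, ok0 = _sample_batch(field, seeds, None, cfg.fraction_threshold, u_pop, u_samp)

    fwd_hist, fwd_act, fwd_stop = _march(field, seeds, d0, ok0, cfg, rng)
    if cfg.bidirectional:
        bwd_hist, bwd_act, bwd_stop = _march(field, seeds, -d0, ok0, cfg, rng)
    else:
        bwd_hist = bwd_act = None
        bwd_stop = np.array([STOP_NO_FIBER] * n, dtype=object)

    out = []
    for i in range(n):
        if not ok0[i]:
            out.append(None)
            continue
        fwd_pts = fwd_hist[fwd_act[:, i], i]
        if bwd_hist is not None:
            bwd_pts = bwd_hist[bwd_act[:, i], i][::-1]
        else:
            bwd_pts = np.empty((0, 3))
        pts = np.concatenate([bwd_pts, seeds[i][None, :], fwd_pts])
        if pts.shape[0] < 2:
            out.append(None)
            continue
        out.append((pts, str(bwd_stop[i]), str(fwd_stop[i])))
    return out


def propagate(field: "FiberField", seed_point, cfg: TrackingConfig, rng=None) -> Streamline:
    """Propagate a single streamline from ``seed_point``.

    Steps are exactly ``cfg.step_size_mm`` long; see the module docstring for
    termination semantics.  Raises if the seed voxel holds no passing fiber
    population (a contract violation — seeds lie inside seed masks, which lie
    on fiber support).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    seed = np.asarray(seed_point, dtype=float)
    res = _propagate_batch(field, seed[None, :], cfg, rng)[0]
    if res is None:
        raise TrackingError("no fiber population at the seed point")
    pts, stop_start, stop_end = res
    return Streamline(pts, status=RETAINED, stop_reason_start=stop_start,
                      stop_reason_end=stop_end)


# --------------------------------------------------------------------------
# filtering and visitation


def _voxel_linear(grid: VoxelGrid, points: np.ndarray) -> np.ndarray:
    ijk = grid.voxel_index(points)
    ijk = np.clip(ijk, 0, np.asarray(grid.shape) - 1)
    return np.ravel_multi_index((ijk[:, 0], ijk[:, 1], ijk[:, 2]), grid.shape)


def filter_streamline(s: Streamline, masks: MaskSet) -> Streamline:
    """Set a streamline's status from the mask semantics.

    Rejected if any point lies in an exclusion or CSF voxel; otherwise
    rejected unless every waypoint volume is intersected; otherwise retained.
    The test applies to the full (concatenated bidirectional) path.
    """
    lin = _voxel_linear(masks.grid, s.points)
    for e in masks.all_exclusions():
        if e.reshape(-1)[lin].any():
            s.status = REJECTED_EXCLUSION
            return s
    for w in masks.waypoints:
        if not w.reshape(-1)[lin].any():
            s.status = REJECTED_WAYPOINT
            return s
    s.status = RETAINED
    return s


def visitation_map(streamlines, grid: VoxelGrid, name: str = "tract") -> Tractogram:
    """Count, per voxel, the number of distinct streamlines visiting it.

    Each streamline contributes at most 1 to any voxel regardless of how many
    of its points fall there.  An empty input yields an all-zero map flagged
    ``empty``.
    """
    counts = np.zeros(int(np.prod(grid.shape)), dtype=np.int32)
    n = 0
    for s in streamlines:
        counts[np.unique(_voxel_linear(grid, s.points))] += 1
        n += 1
    return Tractogram(grid, counts.reshape(grid.shape), name=name, empty=(n == 0))


def track_bundle(
    field: "FiberField",
    masks: MaskSet,
    cfg: TrackingConfig,
    name: str | None = None,
) -> tuple[Tractogram, StreamlineSet]:
    """Seed, propagate and filter a whole bundle.

    Launches ``cfg.n_samples`` streamlines per seed voxel from uniformly
    jittered positions within the voxel, filters them against the masks, and
    returns the visitation map of retained streamlines together with the full
    streamline set (statuses preserved).  Zero retained streamlines is an
    explicit empty result, not an error.
    """
    masks.check_grid(field.grid)
    name = name or masks.name
    rng = np.random.default_rng(cfg.rng_seed)
    seed_vox = np.argwhere(masks.seed)
    n = seed_vox.shape[0] * cfg.n_samples

    jitter = rng.random((n, 3)) - 0.5
    base = np.repeat(seed_vox, cfg.n_samples, axis=0).astype(float)
    seeds = field.grid.voxel_to_world(base + jitter)

    results = _propagate_batch(field, seeds, cfg, rng)
    streamlines: list[Streamline] = []
    for res in results:
        if res is None:
            continue
        pts, stop_start, stop_end = res
        s = Streamline(pts, stop_reason_start=stop_start, stop_reason_end=stop_end)
        streamlines.append(filter_streamline(s, masks))

    retained = [s for s in streamlines if s.status == RETAINED]
    tractogram = visitation_map(retained, field.grid, name=name)
    sset = StreamlineSet(
        streamlines, tract=name, config_hash=cfg.config_hash(), rng_seed=cfg.rng_seed
    )
    return tractogram, sset
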