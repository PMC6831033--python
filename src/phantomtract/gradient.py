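"""Within-bundle connectivity-gradient analysis.

Given two source regions (the amygdala-analog and temporal-pole-analog), we
track from each source using the bundle's core (its original seed mask) as a
waypoint, normalize the two visitation maps, and form the voxelwise ratio

    ratio[v] = (A[v] - B[v]) / (A[v] + B[v])        in [-1, 1]

inside the bundle mask, where A is the amygdala-source map and B the
temporal-pole-source map.  Positive values mark voxels whose streamlines
predominantly originate in the amygdala-analog, negative values the
temporal-pole-analog.  Voxels where A + B = 0 are invalid and carry NaN —
never 0, because 0 is a meaningful "balanced" value — and are excluded from
all summaries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grid import VoxelGrid, grids_equal
from .masks import MaskError, MaskSet
from .normalize import log_normalize
from .tracking import Tractogram, TrackingConfig, track_bundle

__all__ = ["GradientMap", "source_tractograms", "gradient_ratio", "GradientError"]


class GradientError(ValueError):
    pass


@dataclass
class GradientMap:
    """Voxelwise origin ratio in [-1, 1]; NaN where invalid."""

    grid: VoxelGrid
    ratio: np.ndarray
    valid: np.ndarray
    name: str = "bundle"

    def __post_init__(self) -> None:
        if self.ratio.shape != self.grid.shape or self.valid.shape != self.grid.shape:
            raise GradientError("ratio/valid volume shape mismatch")
        vals = self.ratio[self.valid]
        if vals.size and np.max(np.abs(vals)) > 1.0 + 1e-9:
            raise GradientError("gradient ratio out of [-1, 1] on valid voxels")

    def mean_over(self, mask: np.ndarray) -> float:
        """Mean ratio over the valid voxels of ``mask`` (NaN if none)."""
        sel = self.valid & np.asarray(mask, dtype=bool)
        return float(self.ratio[sel].mean()) if sel.any() else float("nan")


def source_tractograms(
    field,
    source_roi: np.ndarray,
    bundle_core_waypoint: np.ndarray,
    cfg: TrackingConfig,
    name: str = "source",
    exclusions: list[np.ndarray] | None = None,
    csf: np.ndarray | None = None,
) -> Tractogram:
    """Track from a source region through a bundle core and normalize.

    Seeds in ``source_roi``, requires passage through ``bundle_core_waypoint``
    (the bundle's original seed mask), and log-normalizes the retained-
    streamline visitation map.  A run that retains nothing returns an
    all-zero normalized map flagged ``empty`` rather than raising.
    """
    source_roi = np.asarray(source_roi, dtype=bool)
    if not source_roi.any():
        raise MaskError(f"source ROI for {name!r} is empty")
    masks = MaskSet(
        field.grid,
        seed=source_roi,
        waypoints=[np.asarray(bundle_core_waypoint, dtype=bool)],
        exclusions=exclusions or [],
        csf=csf,
        name=name,
    )
    tractogram, _ = track_bundle(field, masks, cfg, name=name)
    if not (tractogram.counts > 0).any():
        zero = np.zeros(field.grid.shape, dtype=np.float32)
        return Tractogram(field.grid, tractogram.counts, normalized=zero,
                          name=name, empty=True)
    return log_normalize(tractogram)


def gradient_ratio(tA: Tractogram, tB: Tractogram, bundle_mask: np.ndarray,
                   name: str = "bundle") -> GradientMap:
    """(A - B) / (A + B) of two normalized source tractograms within a bundle."""
    grids_equal(tA.grid, tB.grid, what="gradient inputs")
    if tA.normalized is None or tB.normalized is None:
        raise GradientError("gradient inputs must be normalized tractograms")
    bundle_mask = np.asarray(bundle_mask, dtype=bool)
    if bundle_mask.shape != tA.grid.shape:
        raise GradientError("bundle mask shape mismatch")
    a = np.asarray(tA.normalized, dtype=np.float64)
    b = np.asarray(tB.normalized, dtype=np.float64)
    total = a + b
    valid = bundle_mask & (total > 0)
    ratio = np.full(tA.grid.shape, np.nan)
    np.divide(a - b, total, out=ratio, where=valid)
    return GradientMap(tA.grid, ratio, valid, name=name)
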