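"""Mask sets encoding a tract "recipe": seed, waypoints, exclusions, CSF.

Semantics (enforced downstream in :mod:`phantomtract.tracking`):

* **seed** — voxels from which streamlines are launched;
* **waypoints** — every waypoint volume must be intersected by a streamline
  for it to be retained;
* **exclusions** — a streamline touching any exclusion voxel is discarded
  entirely;
* **csf** — treated exactly like an exclusion (kept separate only for
  provenance); prevents streamlines from leaving the tissue compartment.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grid import VoxelGrid, grids_equal

__all__ = ["MaskSet", "MaskError"]


class MaskError(ValueError):
    """Raised for inconsistent mask recipes."""


@dataclass
class MaskSet:
    grid: VoxelGrid
    seed: np.ndarray
    waypoints: list[np.ndarray] = field(default_factory=list)
    exclusions: list[np.ndarray] = field(default_factory=list)
    csf: np.ndarray | None = None
    name: str = "tract"

    def __post_init__(self) -> None:
        self.seed = np.asarray(self.seed, dtype=bool)
        if self.seed.shape != self.grid.shape:
            raise MaskError("seed mask shape does not match grid")
        if not self.seed.any():
            raise MaskError(f"recipe {self.name!r}: empty seed mask")
        self.waypoints = [self._check(w, "waypoint") for w in self.waypoints]
        self.exclusions = [self._check(e, "exclusion") for e in self.exclusions]
        if self.csf is not None:
            self.csf = self._check(self.csf, "csf")
        for e in self.all_exclusions():
            if np.any(self.seed & e):
                raise MaskError(
                    f"recipe {self.name!r}: seed intersects an exclusion mask"
                )

    def _check(self, m, what: str) -> np.ndarray:
        m = np.asarray(m, dtype=bool)
        if m.shape != self.grid.shape:
            raise MaskError(f"{what} mask shape does not match grid")
        return m

    def all_exclusions(self) -> list[np.ndarray]:
        """Exclusion volumes plus CSF; touching any of these rejects a streamline."""
        out = list(self.exclusions)
        if self.csf is not None:
            out.append(self.csf)
        return out

    def check_grid(self, grid: VoxelGrid) -> None:
        grids_equal(self.grid, grid, what=f"masks {self.name!r} and field")
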