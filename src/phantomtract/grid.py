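"""Voxel grids: the shared spatial frame for fields, masks, and tractograms.

World coordinates are RAS-like millimetres.  A voxel's world position is the
affine image of its integer (0-based) index, i.e. the voxel-*center*
convention.  All volumes in the package live on a :class:`VoxelGrid` and two
volumes are only combined when their grids match.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VoxelGrid", "GridError", "grids_equal"]


class GridError(ValueError):
    """Raised for invalid grid definitions or grid mismatches."""


@dataclass(frozen=True)
class VoxelGrid:
    """A 3-D voxel lattice with an affine index->world(mm) mapping.

    Parameters
    ----------
    shape
        Number of voxels along each axis; all strictly positive.
    affine
        4x4 matrix mapping homogeneous voxel indices to world mm.  Must be
        invertible.  The derived voxel sizes are the column norms of the
        linear 3x3 part.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s <= 0 for s in shape):
            raise GridError(f"shape must be 3 positive integers, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise GridError(f"affine must be 4x4, got {affine.shape}")
        if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise GridError("affine is singular")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "_inv", np.linalg.inv(affine))

    @classmethod
    def isotropic(cls, shape, voxel_size_mm: float) -> "VoxelGrid":
        aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
        return cls(tuple(shape), aff)

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel size: column norms of the affine's linear part."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk) -> np.ndarray:
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz) -> np.ndarray:
        """Continuous voxel coordinates of world points."""
        xyz = np.asarray(xyz, dtype=float)
        inv = self._inv
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_index(self, xyz) -> np.ndarray:
        """Nearest-voxel integer index of world points (may be out of bounds)."""
        return np.rint(self.world_to_voxel(xyz)).astype(np.int64)

    def inside(self, ijk) -> np.ndarray:
        """Boundedness test for integer indices (broadcasts over leading axes)."""
        ijk = np.asarray(ijk)
        shp = np.asarray(self.shape)
        return np.all((ijk >= 0) & (ijk < shp), axis=-1)

    def contains_world(self, xyz) -> np.ndarray:
        return self.inside(self.voxel_index(xyz))

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape ``(*shape, 3)``."""
        ii, jj, kk = np.meshgrid(*(np.arange(s) for s in self.shape), indexing="ij")
        ijk = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
        return self.voxel_to_world(ijk).reshape(*self.shape, 3)

    def __eq__(self, other) -> bool:
        if not isinstance(other, VoxelGrid):
            return NotImplemented
        return self.shape == other.shape and np.allclose(
            self.affine, other.affine, atol=1e-6
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.affine.round(6).tobytes()))


def grids_equal(a: VoxelGrid, b: VoxelGrid, what: str = "volumes") -> None:
    """Raise :class:`GridError` unless two grids agree (shape and affine)."""
    if a != b:
        raise GridError(f"grid mismatch between {what}: {a.shape} vs {b.shape}")
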