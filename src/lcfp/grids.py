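"""Standard-space voxel grids.

A :class:`Grid` couples a 3-D voxel array shape with a 4x4 voxel-to-world
affine (mm).  All volumes handled by this package are kept in a canonical
axis order (ascending x toward the right, y toward anterior, z toward
superior) so that voxel-index ordering is anatomically meaningful and
storage-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid"]


@dataclass(frozen=True)
class Grid:
    """A 3-D voxel grid with a voxel-to-world affine in mm."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(s) <= 0 for s in self.shape):
            raise ValueError(f"grid shape must be three positive ints, got {self.shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))
        object.__setattr__(self, "affine", aff)

    @property
    def voxel_size(self) -> np.ndarray:
        """Edge length of a voxel along each axis (mm)."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        """Map voxel indices (..., 3) to world coordinates in mm."""
        ijk = np.asarray(ijk, dtype=float)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (..., 3) to (fractional) voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    def voxel_coordinates(self) -> np.ndarray:
        """All voxel index triplets, shape (nx*ny*nz, 3), C order."""
        idx = np.indices(self.shape).reshape(3, -1).T
        return idx

    def same_as(self, other: "Grid", atol: float = 1e-6) -> bool:
        return self.shape == other.shape and np.allclose(self.affine, other.affine, atol=atol)
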