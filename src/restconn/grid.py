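"""Axis-aligned voxel grids and world-coordinate conversion.

The grid models a scanner volume as an axis-aligned box of isotropic or
anisotropic voxels.  World coordinates are millimetres; voxel ``(0, 0, 0)``
maps to ``origin_mm`` and voxel ``v`` to ``origin_mm + v * voxel_size_mm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError


@dataclass(frozen=True)
class VolumeGrid:
    """Geometry of a 3-D voxel grid.

    Parameters
    ----------
    dims : tuple of int
        Number of voxels along each axis (all >= 1).
    voxel_size_mm : tuple of float
        Voxel edge length along each axis in millimetres (all > 0).
    origin_mm : tuple of float
        World coordinate of voxel (0, 0, 0).
    """

    dims: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.dims) != 3 or any(int(d) < 1 for d in self.dims):
            raise ValidationError(f"grid dims must be three integers >= 1, got {self.dims}")
        if len(self.voxel_size_mm) != 3 or any(s <= 0 for s in self.voxel_size_mm):
            raise ValidationError(f"voxel sizes must be positive, got {self.voxel_size_mm}")
        object.__setattr__(self, "dims", tuple(int(d) for d in self.dims))
        object.__setattr__(self, "voxel_size_mm", tuple(float(s) for s in self.voxel_size_mm))
        object.__setattr__(self, "origin_mm", tuple(float(o) for o in self.origin_mm))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.dims))

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-world affine (diagonal scaling plus translation)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    def voxel_to_mm(self, voxel: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel index triples (..., 3)."""
        v = np.asarray(voxel, dtype=float)
        return np.asarray(self.origin_mm) + v * np.asarray(self.voxel_size_mm)

    def mm_to_voxel(self, mm: np.ndarray) -> np.ndarray:
        """Fractional voxel coordinates of world points (..., 3)."""
        p = np.asarray(mm, dtype=float)
        return (p - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def contains_mm(self, mm) -> bool:
        """True if a world point falls inside the grid's voxel index range."""
        v = self.mm_to_voxel(mm)
        return bool(np.all(v >= 0) and np.all(v <= np.asarray(self.dims) - 1))

    def voxel_centers_mm(self) -> np.ndarray:
        """(nx, ny, nz, 3) array of world coordinates of every voxel center."""
        axes = [
            self.origin_mm[a] + np.arange(self.dims[a]) * self.voxel_size_mm[a]
            for a in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def flat_index(self, voxel: tuple[int, int, int]) -> int:
        return int(np.ravel_multi_index(voxel, self.dims))

    def unflatten(self, idx: int) -> tuple[int, int, int]:
        return tuple(int(i) for i in np.unravel_index(idx, self.dims))
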