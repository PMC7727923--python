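"""Regular-grid containers for scalar and vector volumes.

All geometry is axis-aligned: world coordinates (mm) of the voxel with
integer index ``(i, j, k)`` are ``origin + index * spacing``.  Array axes
are ordered ``(x, y, z)``; the axial (slice) axis is the last one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Grid", "ImageVolume", "DisplacementField", "same_grid"]


@dataclass(frozen=True)
class Grid:
    """Axis-aligned lattice geometry: shape, spacing (mm) and origin (mm)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))
        if len(self.shape) != 3 or any(n < 1 for n in self.shape):
            raise ValueError(f"invalid grid shape {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"non-positive spacing {self.spacing}")

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.spacing))

    @property
    def extent_mm(self) -> np.ndarray:
        """Physical size of the field of view along each axis."""
        return np.asarray(self.shape) * np.asarray(self.spacing)

    @property
    def center_mm(self) -> np.ndarray:
        """World coordinates of the centroid of all voxel centers."""
        return np.asarray(self.origin) + (np.asarray(self.shape) - 1) / 2.0 * np.asarray(self.spacing)

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices (n,3) to world mm."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin) + index * np.asarray(self.spacing)

    def world_to_index(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm coordinates (n,3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def voxel_centers(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates of voxel centers, optionally restricted to a mask.

        Returned in C order of the flattened grid (matching ``np.argwhere``).
        """
        if mask is None:
            idx = np.indices(self.shape).reshape(3, -1).T
        else:
            idx = np.argwhere(mask)
        return self.index_to_world(idx)

    def contains_index(self, index: np.ndarray) -> np.ndarray:
        """Boolean membership of integer indices (n,3) in the lattice."""
        index = np.asarray(index)
        return np.all((index >= 0) & (index < np.asarray(self.shape)), axis=-1)


@dataclass
class ImageVolume:
    """A 3-D scalar lattice (HU, density, ventilation, counts) with geometry."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.shape != tuple(self.grid.shape):
            raise ValueError(
                f"data shape {self.data.shape} does not match grid {self.grid.shape}"
            )

    @classmethod
    def from_array(cls, data, spacing, origin=(0.0, 0.0, 0.0)) -> "ImageVolume":
        data = np.asarray(data)
        return cls(data, Grid(data.shape, tuple(spacing), tuple(origin)))

    def like(self, data: np.ndarray) -> "ImageVolume":
        """A new volume with the same geometry and different values."""
        return ImageVolume(data, self.grid)

    def copy(self) -> "ImageVolume":
        return ImageVolume(self.data.copy(), self.grid)


@dataclass
class DisplacementField:
    """Inverse-transformation samples on the target grid.

    ``data`` has shape ``(*grid.shape, 3)`` and stores world-mm offsets
    ``u(y)`` such that the reference-frame position of target voxel center
    ``y`` is ``phi_inv(y) = y + u(y)``.
    """

    data: np.ndarray
    grid: Grid

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != tuple(self.grid.shape) + (3,):
            raise ValueError(
                f"displacement shape {self.data.shape} incompatible with grid {self.grid.shape}"
            )

    def phi_inv(self, mask: np.ndarray | None = None) -> np.ndarray:
        """World coordinates phi_inv(y) at (masked) target voxel centers."""
        centers = self.grid.voxel_centers(mask)
        if mask is None:
            u = self.data.reshape(-1, 3)
        else:
            u = self.data[mask]
        return centers + u


def same_grid(a: Grid, b: Grid, tol: float = 1e-6) -> bool:
    """Whether two grids share shape and geometry to within ``tol`` mm."""
    return (
        a.shape == b.shape
        and np.allclose(a.spacing, b.spacing, atol=tol)
        and np.allclose(a.origin, b.origin, atol=tol)
    )
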