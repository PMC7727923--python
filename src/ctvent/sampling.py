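"""Knot / subdomain placement and tolerance-driven subregion growth.

Dart throwing visits every mask voxel center in a seeded random order and
accepts a candidate iff it lies at least the nominal spacing from every
previously accepted point — a maximal-style Poisson-disk sample that is
deterministic given the seed.

Subregions start as a single seed voxel and are "dilated" with a box
structuring element until a tolerance predicate passes: after k dilations
with a (2a+1, 2b+1, 2c+1) box the seed's dilation is the Chebyshev box of
radius (ka, kb, kc), which is intersected with the lung mask and restricted
to the seed's 26-connected component.  Predicates only need sums of voxelwise
fields over the candidate region, so candidates are screened in O(1) with
3-D summed-area tables and the exact connected region is only materialized
(and the predicate re-verified on it) when the screen passes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import ndimage

from .grid import Grid, ImageVolume

__all__ = ["PointSet", "Subregion", "dart_throw", "grow_subregion", "RegionGrower"]


@dataclass
class PointSet:
    """Approximately uniformly spaced points inside a mask."""

    points: np.ndarray            # (n, 3) world mm
    nominal_spacing_mm: float
    seed: int

    def __len__(self):
        return len(self.points)


@dataclass
class Subregion:
    """A connected voxel set grown from a seed inside the reference mask."""

    voxel_indices: np.ndarray     # flat C-order indices into the grid
    seed_index: tuple[int, int, int]
    dilation_count: int
    valid: bool
    grid_shape: tuple[int, int, int] = None

    @property
    def size(self) -> int:
        return int(self.voxel_indices.size)


def dart_throw(mask: ImageVolume, spacing_mm: float, seed: int) -> PointSet:
    """Seeded maximal-style Poisson-disk sample of mask voxel centers.

    Every pairwise distance in the result is >= ``spacing_mm``; every mask
    voxel center was considered, so no further candidate can be added.
    """
    m = np.asarray(mask.data, dtype=bool)
    if not m.any():
        raise ValueError("dart throwing requires a non-empty mask")
    if spacing_mm <= 0:
        raise ValueError("spacing must be positive")

    centers = mask.grid.voxel_centers(m)
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(centers))

    # uniform cell hash; cell edge = spacing/sqrt(3) guarantees any conflict
    # lies within +-2 cells along each axis
    cell = spacing_mm / np.sqrt(3.0)
    lo = centers.min(axis=0)
    cells: dict[tuple[int, int, int], list[int]] = {}
    accepted: list[int] = []
    pts = centers
    sp2 = spacing_mm ** 2

    for ci in order:
        p = pts[ci]
        key = tuple(((p - lo) // cell).astype(int))
        ok = True
        for dx in range(-2, 3):
            for dy in range(-2, 3):
                for dz in range(-2, 3):
                    bucket = cells.get((key[0] + dx, key[1] + dy, key[2] + dz))
                    if not bucket:
                        continue
                    d2 = ((pts[bucket] - p) ** 2).sum(axis=1)
                    if (d2 < sp2).any():
                        ok = False
                        break
                if not ok:
                    break
            if not ok:
                break
        if ok:
            accepted.append(ci)
            cells.setdefault(key, []).append(ci)

    return PointSet(points=pts[accepted], nominal_spacing_mm=float(spacing_mm), seed=int(seed))


# ---------------------------------------------------------------------------
# subregion growth
# ---------------------------------------------------------------------------

class _SummedFields:
    """3-D summed-area tables for O(1) box sums of masked voxel fields."""

    def __init__(self, mask: np.ndarray, fields: Sequence[np.ndarray]):
        mask = np.asarray(mask, dtype=bool)
        stack = [mask.astype(np.float64)]
        for f in fields:
            stack.append(np.where(mask, np.asarray(f, dtype=np.float64), 0.0))
        self.tables = []
        for arr in stack:
            t = np.zeros(tuple(n + 1 for n in arr.shape))
            t[1:, 1:, 1:] = arr.cumsum(0).cumsum(1).cumsum(2)
            self.tables.append(t)

    def box(self, lo, hi):
        """Sums over the inclusive index box [lo, hi]; first entry = voxel count."""
        i0, j0, k0 = lo
        i1, j1, k1 = (hi[0] + 1, hi[1] + 1, hi[2] + 1)
        out = np.empty(len(self.tables))
        for n, t in enumerate(self.tables):
            out[n] = (
                t[i1, j1, k1] - t[i0, j1, k1] - t[i1, j0, k1] - t[i1, j1, k0]
                + t[i0, j0, k1] + t[i0, j1, k0] + t[i1, j0, k0] - t[i0, j0, k0]
            )
        return out


class RegionGrower:
    """Grows tolerance-satisfying subregions for many seeds on one mask.

    ``fields`` are voxelwise arrays on the mask's grid whose region sums the
    predicate consumes.  The predicate receives ``(nvox, sums)`` where
    ``sums[i]`` is the sum of ``fields[i]`` over the candidate region, and
    returns True when the tolerance criterion is met.
    """

    def __init__(self, mask: ImageVolume, fields: Sequence[np.ndarray] = (),
                 structure: tuple[int, int, int] = (3, 3, 3)):
        self.mask = np.asarray(mask.data, dtype=bool)
        self.grid = mask.grid
        self.fields = [np.asarray(f) for f in fields]
        if any(s % 2 == 0 or s < 1 for s in structure):
            raise ValueError("structuring element sizes must be odd and >= 1")
        self.radii = tuple(s // 2 for s in structure)
        self._sums = _SummedFields(self.mask, self.fields)
        self._full_counts = {}

    def _exact_region(self, seed, k):
        """Connected component of (Chebyshev box ∩ mask) containing the seed."""
        shape = self.mask.shape
        lo = [max(0, seed[d] - k * self.radii[d]) for d in range(3)]
        hi = [min(shape[d] - 1, seed[d] + k * self.radii[d]) for d in range(3)]
        window = self.mask[lo[0]:hi[0] + 1, lo[1]:hi[1] + 1, lo[2]:hi[2] + 1]
        labels, _ = ndimage.label(window, structure=np.ones((3, 3, 3), dtype=int))
        seed_local = tuple(seed[d] - lo[d] for d in range(3))
        comp = labels == labels[seed_local]
        idx_local = np.argwhere(comp)
        idx = idx_local + np.asarray(lo)
        flat = np.ravel_multi_index(idx.T, shape)
        return np.sort(flat)

    def _region_sums(self, flat):
        idx = np.unravel_index(flat, self.mask.shape)
        out = np.empty(len(self.fields))
        for n, f in enumerate(self.fields):
            out[n] = f[idx].sum()
        return out

    def grow(self, seed_index, predicate: Callable[[int, np.ndarray], bool],
             max_dilations: int = 20) -> Subregion:
        seed = tuple(int(i) for i in seed_index)
        if not self.mask[seed]:
            raise ValueError(f"seed index {seed} lies outside the mask")
        shape = self.mask.shape

        for k in range(max_dilations + 1):
            lo = [max(0, seed[d] - k * self.radii[d]) for d in range(3)]
            hi = [min(shape[d] - 1, seed[d] + k * self.radii[d]) for d in range(3)]
            sums = self._sums.box(lo, hi)
            nvox = sums[0]
            if nvox <= 0 or not predicate(int(round(nvox)), sums[1:]):
                continue
            # screen passed on box ∩ mask: verify on the connected region
            box_full = all(hi[d] - lo[d] + 1 == 2 * k * self.radii[d] + 1 for d in range(3))
            if box_full and int(round(nvox)) == int(np.prod([h - l + 1 for l, h in zip(lo, hi)])):
                # box entirely inside the mask: connected by construction
                ii, jj, kk = np.meshgrid(*[np.arange(l, h + 1) for l, h in zip(lo, hi)],
                                         indexing="ij")
                flat = np.ravel_multi_index(
                    (ii.ravel(), jj.ravel(), kk.ravel()), shape)
                return Subregion(np.sort(flat), seed, k, True, shape)
            flat = self._exact_region(seed, k)
            if flat.size == int(round(nvox)):
                return Subregion(flat, seed, k, True, shape)
            exact = self._region_sums(flat)
            if flat.size > 0 and predicate(flat.size, exact):
                return Subregion(flat, seed, k, True, shape)

        return Subregion(np.empty(0, dtype=np.int64), seed, max_dilations, False, shape)


def grow_subregion(seed_index, mask: ImageVolume,
                   predicate: Callable[[int, np.ndarray], bool],
                   max_dilations: int = 20,
                   structure: tuple[int, int, int] = (3, 3, 3),
                   fields: Sequence[np.ndarray] = ()) -> Subregion:
    """One-shot convenience wrapper around :class:`RegionGrower`.

    When several seeds share one mask and field set, build a single
    ``RegionGrower`` instead (the summed-area tables are reused).
    """
    return RegionGrower(mask, fields, structure).grow(seed_index, predicate, max_dilations)
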