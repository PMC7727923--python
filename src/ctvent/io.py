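"""Volume I/O: NIfTI-1 (nibabel) and MetaImage (SimpleITK).

Only axis-aligned geometry is supported: spacing and origin round-trip;
oriented (rotated) volumes are rejected rather than silently mangled.
Displacement fields are stored as 4-D volumes with 3 components in world-mm
offsets on the target grid (component axis last in memory).
"""

from __future__ import annotations

import os

import nibabel as nib
import numpy as np
import SimpleITK as sitk

from .grid import DisplacementField, Grid, ImageVolume, same_grid

__all__ = ["read_volume", "write_volume", "read_displacement",
           "write_displacement", "check_same_grid"]

_NIFTI_EXT = (".nii", ".nii.gz")
_META_EXT = (".mha", ".mhd")


def _format_of(path: str) -> str:
    lower = str(path).lower()
    if lower.endswith(".nii.gz") or lower.endswith(".nii"):
        return "nifti"
    if lower.endswith(_META_EXT):
        return "metaimage"
    raise ValueError(f"unsupported volume format: {path} (use .nii[.gz], .mha, .mhd)")


def _grid_from_nifti(img) -> Grid:
    affine = np.asarray(img.affine)
    rot = affine[:3, :3]
    if not np.allclose(rot - np.diag(np.diag(rot)), 0.0, atol=1e-6):
        raise ValueError("oriented (non-axis-aligned) NIfTI volumes are unsupported")
    spacing = np.abs(np.diag(rot))
    if np.any(spacing <= 0):
        raise ValueError("NIfTI header lacks usable voxel spacing")
    shape = img.shape[:3]
    return Grid(tuple(shape), tuple(spacing), tuple(affine[:3, 3]))


def read_volume(path: str) -> ImageVolume:
    """Read a 3-D scalar volume with its grid geometry."""
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj)
        if data.ndim != 3:
            raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
        return ImageVolume(np.asarray(data, dtype=float), _grid_from_nifti(img))
    img = sitk.ReadImage(str(path))
    if img.GetDimension() != 3:
        raise ValueError(f"{path}: expected a 3-D volume")
    data = sitk.GetArrayFromImage(img)        # (z, y, x)
    data = np.ascontiguousarray(data.transpose(2, 1, 0)).astype(float)
    grid = Grid(tuple(data.shape), tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return ImageVolume(data, grid)


def write_volume(volume: ImageVolume, path: str) -> None:
    """Write a volume; format chosen from the file extension."""
    fmt = _format_of(path)
    grid = volume.grid
    data = np.asarray(volume.data, dtype=np.float64)
    if fmt == "nifti":
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        nib.save(nib.Nifti1Image(data, affine), str(path))
        return
    img = sitk.GetImageFromArray(np.ascontiguousarray(data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def read_displacement(path: str) -> DisplacementField:
    """Read a 3-component displacement field (world-mm offsets)."""
    fmt = _format_of(path)
    if fmt == "nifti":
        img = nib.load(path)
        data = np.asarray(img.dataobj, dtype=float)
        data = np.squeeze(data)
        if data.ndim != 4 or data.shape[-1] != 3:
            raise ValueError(f"{path}: expected a 4-D field with 3 components")
        return DisplacementField(data, _grid_from_nifti(img))
    img = sitk.ReadImage(str(path))
    data = sitk.GetArrayFromImage(img)        # (z, y, x, 3)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise ValueError(f"{path}: expected a vector field with 3 components")
    data = np.ascontiguousarray(data.transpose(2, 1, 0, 3)).astype(float)
    grid = Grid(tuple(data.shape[:3]), tuple(img.GetSpacing()), tuple(img.GetOrigin()))
    return DisplacementField(data, grid)


def write_displacement(field: DisplacementField, path: str) -> None:
    fmt = _format_of(path)
    grid = field.grid
    data = np.asarray(field.data, dtype=np.float64)
    if fmt == "nifti":
        affine = np.diag(list(grid.spacing) + [1.0])
        affine[:3, 3] = grid.origin
        img = nib.Nifti1Image(data, affine)
        img.header["descrip"] = b"phi_inv offsets, world mm, target grid"
        nib.save(img, str(path))
        return
    img = sitk.GetImageFromArray(
        np.ascontiguousarray(data.transpose(2, 1, 0, 3)), isVector=True)
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    sitk.WriteImage(img, str(path))


def check_same_grid(a, b, what: str = "volumes") -> None:
    if not same_grid(a.grid, b.grid):
        raise ValueError(
            f"grid mismatch between {what}: {a.grid.shape}@{a.grid.spacing} vs "
            f"{b.grid.shape}@{b.grid.spacing}"
        )
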