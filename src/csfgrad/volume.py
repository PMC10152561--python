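"""Aligned 3D volumes and NIfTI I/O.

All analysis stages operate on a common axis-aligned voxel grid: the upstream
study co-registers every map to the diffusion (ADC) space, and the synthetic
phantom emits already-aligned volumes.  Accordingly :class:`VolumeGrid` keeps
only the scalar array, per-axis voxel spacing in mm and an informational
origin; oblique orientations are rejected at load rather than resampled.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "VolumeGrid",
    "VolumeFormatError",
    "ObliqueOrientationError",
    "GridMismatchError",
    "load_volume",
    "save_volume",
    "validate_same_grid",
]


class VolumeFormatError(ValueError):
    """The file is not a readable NIfTI volume."""


class ObliqueOrientationError(ValueError):
    """The volume's affine is not axis-aligned (rotation/shear present)."""


class GridMismatchError(ValueError):
    """Volumes that must share one grid have different shapes or spacings."""


@dataclass
class VolumeGrid:
    """A 3D scalar field with per-axis voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.values.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


def load_volume(path) -> VolumeGrid:
    """Read a NIfTI volume into a :class:`VolumeGrid`.

    Distinct errors for a missing file, an unreadable header and an oblique
    (non-axis-aligned) orientation; the latter must be resolved upstream by
    resampling, which is deliberately out of scope here.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(f"volume file not found: {path}")
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
        affine = img.affine
    except Exception as exc:  # nibabel raises various types for corrupt input
        raise VolumeFormatError(f"{path}: not a readable NIfTI volume ({exc})") from exc
    if data.ndim != 3:
        raise VolumeFormatError(f"{path}: expected 3D data, got shape {data.shape}")
    rot = affine[:3, :3]
    off_diag = rot - np.diag(np.diag(rot))
    if np.max(np.abs(off_diag)) > 1e-4 * max(1.0, np.max(np.abs(rot))):
        raise ObliqueOrientationError(
            f"{path}: oblique orientation (non-diagonal affine); "
            "resample to an axis-aligned grid before analysis"
        )
    spacing = tuple(float(abs(rot[i, i])) for i in range(3))
    origin = tuple(float(v) for v in affine[:3, 3])
    return VolumeGrid(values=data, spacing=spacing, origin=origin)


def save_volume(vol: VolumeGrid, path) -> None:
    """Write a :class:`VolumeGrid` as NIfTI with spacing in the header."""
    affine = np.diag(list(vol.spacing) + [1.0])
    affine[:3, 3] = vol.origin
    values = vol.values
    if values.dtype == bool:
        values = values.astype(np.uint8)
    img = nib.Nifti1Image(values, affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, os.fspath(path))


def validate_same_grid(named_volumes: dict) -> None:
    """Check that all volumes share one shape and spacing.

    ``named_volumes`` maps a display name (e.g. a file path) to a VolumeGrid
    or bare array; the error message names the offending pair.
    """
    ref_name = None
    ref_shape = ref_spacing = None
    for name, vol in named_volumes.items():
        shape = vol.shape if not isinstance(vol, VolumeGrid) else vol.values.shape
        spacing = vol.spacing if isinstance(vol, VolumeGrid) else None
        if ref_name is None:
            ref_name, ref_shape, ref_spacing = name, shape, spacing
            continue
        if shape != ref_shape:
            raise GridMismatchError(
                f"shape mismatch: {ref_name} has {ref_shape}, {name} has {shape}"
            )
        if spacing is not None and ref_spacing is not None and not np.allclose(
            spacing, ref_spacing
        ):
            raise GridMismatchError(
                f"spacing mismatch: {ref_name} has {ref_spacing}, {name} has {spacing}"
            )
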