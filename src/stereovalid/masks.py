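"""Binary segmentation masks with physical voxel geometry.

A :class:`SegmentationMask` is the central in-memory container: a 3D boolean
array plus the physical size of each voxel in millimetres.  Voxels are modelled
as half-open axis-aligned boxes ``[origin + i*spacing, origin + (i+1)*spacing)``
so that every point in space belongs to exactly one voxel — the property the
point-counting estimator relies on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class SegmentationMask:
    """3D binary mask with voxel spacing (mm) and world origin (mm).

    Parameters
    ----------
    data
        Boolean (or 0/1) array of shape (nx, ny, nz).
    spacing
        Physical edge lengths of one voxel along each axis, in mm.
    origin
        World coordinate of the corner of voxel (0, 0, 0), in mm.
    """

    data: np.ndarray
    spacing: np.ndarray
    origin: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError(f"mask must be 3D, got ndim={self.data.ndim}")
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise ValueError(f"voxel spacing must be positive, got {self.spacing}")
        if self.origin is None:
            self.origin = np.zeros(3)
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def voxel_volume(self) -> float:
        """Volume of a single voxel in mm^3."""
        return float(np.prod(self.spacing))

    def volume(self) -> float:
        """Voxel-count volume in mm^3 (foreground voxels x voxel volume)."""
        return float(self.data.sum()) * self.voxel_volume

    def physical_extent(self) -> np.ndarray:
        """(3, 2) array of [min, max) world coordinates covered by the array."""
        lo = self.origin
        hi = self.origin + self.data.shape * self.spacing
        return np.stack([lo, hi], axis=1)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Vectorised point-in-foreground test for an (n, 3) array of world points.

        A point lies in the foreground iff the half-open voxel box containing it
        is foreground; points outside the array are background.
        """
        points = np.atleast_2d(points)
        idx = np.floor((points - self.origin) / self.spacing).astype(int)
        inside = np.all((idx >= 0) & (idx < self.data.shape), axis=1)
        out = np.zeros(len(points), dtype=bool)
        if inside.any():
            ii = idx[inside]
            out[inside] = self.data[ii[:, 0], ii[:, 1], ii[:, 2]]
        return out


def read_mask(path) -> SegmentationMask:
    """Load a NIfTI-1 file as a binary :class:`SegmentationMask`.

    Non-binary volumes are binarised (nonzero -> foreground) with a warning.
    Voxel spacing is taken from the header; the affine translation becomes the
    world origin (voxel corner convention: NIfTI places coordinates at voxel
    centres, so half a voxel is subtracted).
    """
    try:
        img = nib.load(str(path))
    except Exception as exc:  # pragma: no cover - nibabel error text varies
        raise IOError(f"cannot read NIfTI mask at {path!s}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise IOError(f"{path!s}: expected a 3D volume, got shape {data.shape}")
    values = np.unique(data)
    if not np.all(np.isin(values, [0, 1])):
        warnings.warn(
            f"{path!s}: non-binary values {values[:5]}... binarised as nonzero -> 1",
            stacklevel=2,
        )
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    centre0 = img.affine[:3, 3]
    origin = centre0 - spacing / 2.0
    return SegmentationMask(data != 0, spacing=spacing, origin=origin)


def write_mask(mask: SegmentationMask, path) -> None:
    """Write a mask as NIfTI-1 (uint8), preserving spacing and origin."""
    affine = np.diag(list(mask.spacing) + [1.0])
    affine[:3, 3] = mask.origin + mask.spacing / 2.0
    img = nib.Nifti1Image(mask.data.astype(np.uint8), affine)
    img.header.set_zooms(tuple(mask.spacing))
    nib.save(img, str(path))
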