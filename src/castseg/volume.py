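"""3D image volume container with world-coordinate bookkeeping.

Volumes hold scalar CT data in Hounsfield units (HU) on an isotropic grid.
Axes of ``data`` are ordered (x, y, z); voxel ``(i, j, k)`` is node-centered
at world position ``origin + voxel_size * (i, j, k)`` (mm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import SimpleITK as sitk


@dataclass
class ImageVolume:
    """Scalar image on a cubic-voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Scalar values (HU for CT volumes).
    voxel_size : float
        Isotropic voxel edge length in mm.
    origin : ndarray, shape (3,)
        World position (mm) of voxel (0, 0, 0).
    """

    data: np.ndarray
    voxel_size: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("ImageVolume data must be 3D")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_extent(self) -> np.ndarray:
        """(3, 2) array of [min, max] world coordinates spanned by voxel centers."""
        hi = self.origin + self.voxel_size * (np.array(self.shape) - 1)
        return np.stack([self.origin, hi], axis=1)

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map world coordinates (mm) to fractional voxel indices."""
        return (np.asarray(points, dtype=float) - self.origin) / self.voxel_size


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write a volume as MetaImage (.mha/.mhd) or NIfTI (.nii/.nii.gz)."""
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.T))
    img.SetSpacing((volume.voxel_size,) * 3)
    img.SetOrigin(tuple(volume.origin))
    sitk.WriteImage(img, str(path))


def read_volume(path: str | Path) -> ImageVolume:
    """Read a MetaImage or NIfTI volume written by :func:`write_volume`."""
    img = sitk.ReadImage(str(path))
    spacing = img.GetSpacing()
    if not np.allclose(spacing, spacing[0]):
        raise ValueError(f"anisotropic voxels not supported: {spacing}")
    data = sitk.GetArrayFromImage(img).T
    return ImageVolume(data=data, voxel_size=float(spacing[0]),
                       origin=np.array(img.GetOrigin(), dtype=float))
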