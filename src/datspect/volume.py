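"""The 3-D count volume container and its NIfTI-1 round trip."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A reconstructed SPECT-like count grid with isotropic voxel spacing.

    Axes are ordered (x: left->right, y: posterior->anterior, z:
    inferior->superior); indexing is 0-based and the physical origin sits at
    the grid centre.
    """

    data: np.ndarray
    voxel_mm: float

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("volume data must be 3-D")
        if not np.isfinite(self.data).all():
            raise ValueError("volume contains non-finite values")
        if (self.data < 0).any():
            raise ValueError("volume contains negative counts")
        if self.voxel_mm <= 0:
            raise ValueError("voxel_mm must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_mm**3 / 1000.0

    def affine(self) -> np.ndarray:
        """RAS-style affine placing the physical origin at the grid centre."""
        aff = np.diag([self.voxel_mm] * 3 + [1.0])
        aff[:3, 3] = -(np.array(self.data.shape) - 1) / 2.0 * self.voxel_mm
        return aff

    def flipped_lr(self) -> "Volume":
        """Mirror the volume about the midsagittal plane."""
        return Volume(self.data[::-1].copy(), self.voxel_mm)


def save_volume(volume: Volume, path: str | Path) -> None:
    img = nib.Nifti1Image(volume.data.astype(np.float32), volume.affine())
    img.header.set_zooms((volume.voxel_mm,) * 3)
    nib.save(img, str(path))


def load_volume(path: str | Path) -> Volume:
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    if not np.allclose(zooms, zooms[0], rtol=1e-4):
        raise ValueError(f"anisotropic voxels {zooms} are not supported")
    return Volume(np.asarray(img.dataobj, dtype=float), float(zooms[0]))
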