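"""Voxel volume container with physical spacing and NIfTI I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidInputError

__all__ = ["VoxelVolume", "save_nifti", "load_nifti"]


@dataclass
class VoxelVolume:
    """A 3D scalar intensity grid in physical (mm) coordinates.

    ``values[i, j, k]`` samples the point ``origin_mm + (i, j, k) * spacing_mm``
    (voxel-centre convention, 0-based indices).  ``sagittal_axis`` names the
    grid axis whose fixed values define sagittal planes for slice-wise
    segmentation.
    """

    values: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray = field(default_factory=lambda: np.zeros(3))
    sagittal_axis: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float)
        if self.values.ndim != 3 or self.values.size == 0:
            raise InvalidInputError("values must be a non-empty 3D grid")
        if self.spacing_mm.shape != (3,) or np.any(self.spacing_mm <= 0):
            raise InvalidInputError("spacing must be three positive reals")
        if self.sagittal_axis not in (0, 1, 2):
            raise InvalidInputError("sagittal_axis must be 0, 1 or 2")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def slice(self, index: int) -> np.ndarray:
        """The 2D sagittal slice at the given index along ``sagittal_axis``."""
        if not 0 <= index < self.shape[self.sagittal_axis]:
            raise IndexError(
                f"slice index {index} out of range for axis {self.sagittal_axis} "
                f"of length {self.shape[self.sagittal_axis]}"
            )
        return np.take(self.values, index, axis=self.sagittal_axis)

    def index_to_mm(self, idx: np.ndarray) -> np.ndarray:
        """Map (possibly fractional) voxel indices to mm coordinates."""
        return self.origin_mm + np.asarray(idx, dtype=float) * self.spacing_mm


def save_nifti(volume: VoxelVolume, path: str | Path) -> None:
    import nibabel as nib

    affine = np.diag(np.append(volume.spacing_mm, 1.0))
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.values.astype(np.float32), affine), str(path))


def load_nifti(path: str | Path, sagittal_axis: int = 0) -> VoxelVolume:
    import nibabel as nib

    img = nib.load(str(path))
    affine = img.affine
    spacing = np.abs(np.diag(affine)[:3])
    return VoxelVolume(
        np.asarray(img.dataobj, dtype=float),
        spacing,
        affine[:3, 3].copy(),
        sagittal_axis,
    )
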