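"""3-D scalar volume container and NIfTI-1 input/output.

Every image in the pipeline lives on a single common grid (the template
grid); :class:`VolumeImage` couples the voxel array with its physical
voxel size so that all spatial operations (PSF blurring, deconvolution,
cluster coordinates) can work in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "read_volume", "write_volume"]


@dataclass(frozen=True)
class VolumeImage:
    """A 3-D scalar grid (uptake or SUVR units) with physical voxel size.

    Parameters
    ----------
    values
        3-D float array of voxel values. Must be finite everywhere.
    voxel_size_mm
        Positive (x, y, z) voxel edge lengths in millimetres.
    """

    values: np.ndarray
    voxel_size_mm: tuple[float, float, float]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError(f"expected a 3-D array, got ndim={values.ndim}")
        if not np.all(np.isfinite(values)):
            raise ValueError("image contains non-finite voxel values")
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size_mm must be a positive triple, got {self.voxel_size_mm}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "voxel_size_mm", vox)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def with_values(self, values: np.ndarray) -> "VolumeImage":
        """Return a new image on the same grid with replaced voxel values."""
        return VolumeImage(values, self.voxel_size_mm)


def read_volume(path: str | Path) -> VolumeImage:
    """Load a 3-D NIfTI-1 image (.nii or .nii.gz).

    Raises
    ------
    ValueError
        If the image is not 3-D (4-D time series are not supported).
    """
    img = nib.load(str(path))
    shape = img.shape
    if len(shape) != 3:
        raise ValueError(f"only 3-D volumes are supported, got shape {shape}")
    values = np.asarray(img.dataobj, dtype=float)
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(values, zooms)  # type: ignore[arg-type]


def write_volume(image: VolumeImage, path: str | Path) -> None:
    """Write a :class:`VolumeImage` as float32 NIfTI-1 with a diagonal affine."""
    affine = np.diag([*image.voxel_size_mm, 1.0])
    nifti = nib.Nifti1Image(image.values.astype(np.float32), affine)
    nifti.header.set_zooms(image.voxel_size_mm)
    nib.save(nifti, str(path))
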