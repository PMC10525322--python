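"""NIfTI volume I/O and alignment validation.

Inputs are assumed already co-registered to a common space; this module
never resamples.  Reading returns the raw data array plus a header record
(shape, affine, voxel spacing, dtype); writing round-trips those fields.
A shape or affine disagreement between two volumes that must share a grid
raises instead of silently proceeding.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeHeader", "read_volume", "write_volume", "check_aligned"]


@dataclass(frozen=True)
class VolumeHeader:
    shape: tuple[int, ...]
    affine: np.ndarray
    spacing: tuple[float, ...]
    dtype: np.dtype

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"voxel spacing must be positive: {self.spacing}")
        if abs(np.linalg.det(np.asarray(self.affine)[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")

    @classmethod
    def identity(cls, shape, dtype=np.float64) -> "VolumeHeader":
        return cls(shape=tuple(shape), affine=np.eye(4),
                   spacing=(1.0,) * len(shape), dtype=np.dtype(dtype))


def read_volume(path) -> tuple[np.ndarray, VolumeHeader]:
    """Load a NIfTI-1 volume (.nii or .nii.gz)."""
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:
        raise IOError(f"cannot read volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    header = VolumeHeader(
        shape=tuple(data.shape),
        affine=np.asarray(img.affine, dtype=np.float64),
        spacing=tuple(float(z) for z in img.header.get_zooms()[:data.ndim]),
        dtype=data.dtype,
    )
    return data, header


def write_volume(volume: np.ndarray, header: VolumeHeader | None, path) -> None:
    """Write a NIfTI-1 volume; ``header=None`` uses the identity affine."""
    volume = np.asarray(volume)
    if header is None:
        header = VolumeHeader.identity(volume.shape, volume.dtype)
    if tuple(volume.shape) != tuple(header.shape):
        raise ValueError(
            f"volume shape {volume.shape} != header shape {header.shape}"
        )
    img = nib.Nifti1Image(volume, np.asarray(header.affine))
    img.header.set_zooms(header.spacing[:3])
    nib.save(img, str(path))


def check_aligned(a: VolumeHeader, b: VolumeHeader,
                  names: tuple[str, str] = ("first", "second")) -> None:
    """Raise if two volumes do not share a voxel grid (shape and affine)."""
    if tuple(a.shape) != tuple(b.shape):
        raise ValueError(
            f"{names[0]} shape {tuple(a.shape)} != {names[1]} shape "
            f"{tuple(b.shape)}; inputs must be co-registered"
        )
    if not np.allclose(a.affine, b.affine, atol=1e-6):
        raise ValueError(
            f"{names[0]} and {names[1]} have different affines; "
            "inputs must be co-registered"
        )
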