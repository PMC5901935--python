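"""Core domain types shared across the pipeline.

A :class:`BoldSeries` is the masked 4D BOLD record of one subject stored as a
``(n_voxels, n_timepoints)`` matrix together with the grid metadata needed to
reconstruct volumes (mask, affine, voxel coordinates).  All pipeline stages
consume and produce this type.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import nibabel as nib
import numpy as np

__all__ = [
    "BoldSeries",
    "SubjectRecord",
    "embed_to_volume",
    "load_bold_nifti",
    "save_bold_nifti",
    "save_map_nifti",
]


@dataclass
class BoldSeries:
    """Masked BOLD time series of one subject.

    Parameters
    ----------
    data
        Array of shape ``(n_voxels, n_timepoints)``; one row per masked voxel.
    tr
        Repetition time in seconds.
    mask
        3D boolean brain mask; ``mask.sum() == n_voxels``.
    affine
        4x4 voxel-index -> mm mapping; must be invertible.
    voxel_coords
        ``(n_voxels, 3)`` integer grid indices of the masked voxels, in the
        same row order as ``data``.
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray
    voxel_coords: np.ndarray
    latents: Optional[dict] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        self.affine = np.asarray(self.affine, dtype=float)
        self.voxel_coords = np.asarray(self.voxel_coords)
        if self.data.ndim != 2:
            raise ValueError("data must be 2D (n_voxels, n_timepoints)")
        if self.data.shape[1] < 2:
            raise ValueError("need at least 2 timepoints")
        if self.mask.ndim != 3 or not self.mask.any():
            raise ValueError("mask must be a nonempty 3D boolean array")
        if int(self.mask.sum()) != self.data.shape[0]:
            raise ValueError(
                f"mask has {int(self.mask.sum())} voxels but data has "
                f"{self.data.shape[0]} rows"
            )
        if self.affine.shape != (4, 4) or abs(np.linalg.det(self.affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        if self.voxel_coords.shape != (self.data.shape[0], 3):
            raise ValueError("voxel_coords must be (n_voxels, 3)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple:
        return self.mask.shape

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """Copy of this series with a new data matrix (metadata preserved)."""
        return replace(self, data=np.asarray(data, dtype=float))

    def voxel_mm(self, row: int) -> np.ndarray:
        """mm coordinate of the voxel stored at ``row``."""
        ijk = np.append(self.voxel_coords[row], 1.0)
        return (self.affine @ ijk)[:3]


@dataclass
class SubjectRecord:
    """Group label, demographics and clinical covariates for one subject."""

    subject_id: str
    group: str  # "patient" | "control"
    age: float
    gender: str  # "F" | "M"
    bdi: int
    psqi: int
    isi: int
    age_of_onset: Optional[float] = None
    duration: Optional[float] = None
    motion: Optional[np.ndarray] = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.group not in ("patient", "control"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.gender not in ("F", "M"):
            raise ValueError(f"unknown gender {self.gender!r}")
        if not 0 <= self.bdi <= 63:
            raise ValueError("bdi out of range [0, 63]")
        if not 0 <= self.psqi <= 21:
            raise ValueError("psqi out of range [0, 21]")
        if not 0 <= self.isi <= 28:
            raise ValueError("isi out of range [0, 28]")
        if self.age_of_onset is not None:
            if self.age_of_onset > self.age:
                raise ValueError("age_of_onset must not exceed age")
            if self.duration is not None:
                if abs((self.age - self.age_of_onset) - self.duration) > 1e-9:
                    raise ValueError("duration must equal age - age_of_onset")


def embed_to_volume(values: np.ndarray, mask: np.ndarray, fill: float = 0.0) -> np.ndarray:
    """Scatter per-voxel values back into a 3D (or 4D) volume."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        vol = np.full(mask.shape, fill, dtype=float)
        vol[mask] = values
        return vol
    vol = np.full(mask.shape + (values.shape[1],), fill, dtype=float)
    vol[mask, :] = values
    return vol


def save_bold_nifti(series: BoldSeries, path: str) -> None:
    """Write a BoldSeries as a 4D NIfTI image."""
    vol = embed_to_volume(series.data, series.mask)
    img = nib.Nifti1Image(vol.astype(np.float32), series.affine)
    img.header["pixdim"][4] = series.tr
    nib.save(img, path)


def load_bold_nifti(path: str, mask: np.ndarray, tr: Optional[float] = None) -> BoldSeries:
    """Read a 4D NIfTI into a BoldSeries under the given brain mask."""
    img = nib.load(path)
    vol = np.asarray(img.get_fdata(), dtype=float)
    if vol.ndim != 4:
        raise ValueError(f"{path}: expected 4D image, got {vol.ndim}D")
    mask = np.asarray(mask, dtype=bool)
    if vol.shape[:3] != mask.shape:
        raise ValueError("mask shape does not match image grid")
    if tr is None:
        tr = float(img.header["pixdim"][4])
    coords = np.array(np.nonzero(mask)).T
    return BoldSeries(
        data=vol[mask, :],
        tr=tr,
        mask=mask,
        affine=np.asarray(img.affine),
        voxel_coords=coords,
    )


def save_map_nifti(values: np.ndarray, mask: np.ndarray, affine: np.ndarray, path: str) -> None:
    """Write a per-voxel statistic vector as a 3D NIfTI map."""
    vol = embed_to_volume(values, mask)
    nib.save(nib.Nifti1Image(vol.astype(np.float32), affine), path)
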