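"""Core in-memory containers shared across the pipeline.

A :class:`BoldSeries` is a subject's 4D BOLD grid together with its voxel
geometry and sampling interval; a :class:`VolumeMask` is the boolean 3D
analysis domain (typically gray matter) defined on the same grid.  All
spatial arrays are indexed ``(x, y, z)`` and time is the last axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np

__all__ = ["BoldSeries", "VolumeMask", "load_bold", "save_volume", "save_bold"]


def _affine(voxel_size_mm: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


@dataclass
class BoldSeries:
    """4D BOLD signal grid with voxel geometry and sampling interval.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
        BOLD signal values; ``t >= 2`` and all values finite.
    voxel_size_mm : tuple of 3 floats
        Voxel edge lengths in millimetres (all positive).
    tr_s : float
        Repetition time (sampling interval) in seconds.
    space_tag : str
        Label of the coordinate space, e.g. ``"MNI"`` or ``"synthetic"``.
    """

    data: np.ndarray
    voxel_size_mm: tuple[float, float, float]
    tr_s: float
    space_tag: str = "synthetic"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError(f"BOLD data must be 4D (x,y,z,t), got ndim={self.data.ndim}")
        if self.data.shape[-1] < 2:
            raise ValueError("BOLD series needs at least 2 time points")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if len(self.voxel_size_mm) != 3 or any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel sizes must be 3 positive reals, got {self.voxel_size_mm}")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("BOLD data contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape[:3]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[-1]

    @property
    def nyquist_hz(self) -> float:
        return 1.0 / (2.0 * self.tr_s)

    def with_data(self, data: np.ndarray) -> "BoldSeries":
        """New series on the same grid with replaced signal values."""
        return BoldSeries(data, self.voxel_size_mm, self.tr_s, self.space_tag)


@dataclass
class VolumeMask:
    """Boolean 3D analysis domain sharing a grid with a :class:`BoldSeries`."""

    mask: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())

    def indices(self) -> np.ndarray:
        """(n, 3) integer coordinates of in-mask voxels, C order."""
        return np.argwhere(self.mask)


def load_bold(path, tr_s: float | None = None, space_tag: str = "MNI") -> BoldSeries:
    """Read a 4D NIfTI-1 file into a :class:`BoldSeries`.

    TR is taken from the header zooms unless given explicitly.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata())
    zooms = img.header.get_zooms()
    if tr_s is None:
        if len(zooms) < 4 or zooms[3] <= 0:
            raise ValueError(f"{path}: no TR in header; pass tr_s explicitly")
        tr_s = float(zooms[3])
    return BoldSeries(data, tuple(float(z) for z in zooms[:3]), tr_s, space_tag)


def save_bold(bold: BoldSeries, path) -> None:
    img = nib.Nifti1Image(np.asarray(bold.data, dtype=np.float32), _affine(bold.voxel_size_mm))
    img.header.set_zooms((*bold.voxel_size_mm, bold.tr_s))
    nib.save(img, str(path))


def save_volume(vol: np.ndarray, voxel_size_mm, path) -> None:
    """Write a 3D map (float) or mask (uint8) as NIfTI-1."""
    arr = np.asarray(vol)
    dtype = np.uint8 if arr.dtype == bool else np.float32
    nib.save(nib.Nifti1Image(arr.astype(dtype), _affine(tuple(voxel_size_mm))), str(path))
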