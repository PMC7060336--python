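"""Gridded image containers and NIfTI I/O.

All volumes in this package live on axis-aligned regular grids with a
voxel-center convention: voxel index ``i`` along an axis sits at physical
coordinate ``i * spacing`` millimetres from the first voxel center.
Orientation metadata beyond spacing is not modelled; synthetic cohorts are
generated pre-aligned and real-data entry points are expected to supply
co-registered volumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = [
    "ImageVolume",
    "DwiPair",
    "DscSeries",
    "NawmRoiSpec",
    "load_volume",
    "save_volume",
]


@dataclass
class ImageVolume:
    """A 3D scalar image with per-axis voxel spacing in millimetres.

    ``valid`` optionally marks voxels carrying meaningful values; voxels
    outside it are excluded from downstream statistics rather than filled
    with a numeric sentinel.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    valid: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got shape {self.data.shape}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)
            if self.valid.shape != self.data.shape:
                raise ValueError("valid mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def valid_mask(self) -> np.ndarray:
        if self.valid is None:
            return np.ones(self.data.shape, dtype=bool)
        return self.valid

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Physical coordinates of all voxel centers, one array per axis."""
        axes = [np.arange(n) * s for n, s in zip(self.data.shape, self.spacing)]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class DwiPair:
    """Diffusion-weighted signal pair S(0), S(b) on a shared grid."""

    s0: ImageVolume
    sb: ImageVolume
    b_value: float  # s/mm^2

    def __post_init__(self) -> None:
        if self.s0.shape != self.sb.shape:
            raise ValueError("S0 and Sb volumes must share a grid")
        if self.s0.spacing != self.sb.spacing:
            raise ValueError("S0 and Sb volumes must share voxel spacing")
        if self.b_value <= 0:
            raise ValueError(f"b_value must be positive, got {self.b_value}")


@dataclass
class DscSeries:
    """4D dynamic susceptibility contrast signal series.

    ``signal`` is indexed (x, y, z, t).  ``baseline_index_range`` gives the
    half-open range of pre-bolus timepoints used to define the baseline
    signal level.
    """

    signal: np.ndarray
    te_s: float
    tr_s: float
    baseline_index_range: tuple[int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 4:
            raise ValueError("DSC signal must be 4D (x, y, z, t)")
        if self.te_s <= 0:
            raise ValueError(f"TE must be positive, got {self.te_s}")
        if self.tr_s <= 0:
            raise ValueError(f"TR must be positive, got {self.tr_s}")
        lo, hi = self.baseline_index_range
        if not (0 <= lo < hi <= self.signal.shape[3]):
            raise ValueError(f"invalid baseline index range {self.baseline_index_range}")
        if hi - lo < 2:
            raise ValueError("need at least 2 baseline timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.signal.shape[3]


@dataclass
class NawmRoiSpec:
    """Spherical normal-appearing white matter ROI used for CBV normalization.

    The ROI is realized as all voxels whose centers lie within
    ``diameter_mm / 2`` of ``center_mm``.
    """

    center_mm: tuple[float, float, float]
    diameter_mm: float = 4.0

    def voxel_mask(self, volume: ImageVolume) -> np.ndarray:
        cx, cy, cz = self.center_mm
        gx, gy, gz = volume.voxel_centers_mm()
        r2 = (gx - cx) ** 2 + (gy - cy) ** 2 + (gz - cz) ** 2
        return r2 <= (self.diameter_mm / 2.0) ** 2


def load_volume(path) -> ImageVolume:
    """Read a 3D NIfTI volume; spacing is taken from the header zooms."""
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    zooms = img.header.get_zooms()[:3]
    return ImageVolume(data=data, spacing=tuple(float(z) for z in zooms))


def save_volume(volume: ImageVolume, path) -> None:
    affine = np.diag(list(volume.spacing) + [1.0])
    nib.save(nib.Nifti1Image(volume.data.astype(np.float32), affine), str(path))
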