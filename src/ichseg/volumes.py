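"""Volumetric containers and NIfTI I/O.

A head CT is represented as a :class:`CTVolume` — a 3-D grid of Hounsfield
Unit (HU) intensities plus per-axis voxel spacing in millimetres.  Expert or
predicted hemorrhage annotations live in :class:`LabelVolume` objects that
are voxel-aligned with their CT.  Axis order is (x, y, z) with z the axial
slice index; volumes read from disk are reoriented to the closest canonical
(RAS) orientation so every downstream stage sees one consistent layout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "CTVolume",
    "LabelVolume",
    "StandardSpec",
    "read_volume",
    "read_label",
    "write_volume",
    "write_label",
]


def _check_spacing(spacing: tuple[float, float, float]) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"spacing must be three strictly positive floats, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3-D scalar intensity grid in Hounsfield Units.

    Parameters
    ----------
    intensities
        3-D float array of HU values, axis order (x, y, z).
    spacing
        Voxel edge lengths ``(sx, sy, sz)`` in mm; all strictly positive.
    """

    intensities: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=np.float64)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3-D intensity grid, got ndim={self.intensities.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical size of the grid per axis (shape x spacing)."""
        return tuple(n * s for n, s in zip(self.shape, self.spacing))


@dataclass
class LabelVolume:
    """A binary hemorrhage mask aligned voxel-for-voxel with a CT grid.

    Every voxel is exactly 0 (background) or 1 (hemorrhage).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        vals = np.unique(arr)
        if not np.isin(vals, (0, 1)).all():
            bad = vals[~np.isin(vals, (0, 1))]
            raise ValueError(f"label volume must be binary, found values {bad[:5]}")
        self.labels = arr.astype(np.uint8)
        if self.labels.ndim != 3:
            raise ValueError(f"expected a 3-D label grid, got ndim={self.labels.ndim}")
        self.spacing = _check_spacing(self.spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def voxel_volume_mm3(self) -> float:
        sx, sy, sz = self.spacing
        return sx * sy * sz


@dataclass
class StandardSpec:
    """The fixed standard space every scan is resampled into.

    Defaults follow the clinical convention of a 128 x 128 in-plane by 64
    axial-slice grid with HU intensities windowed to (0, 100); smaller grids
    are first-class so CPU-scale experiments use the same code path.
    """

    grid: tuple[int, int, int] = (128, 128, 64)
    hu_window: tuple[float, float] = (0.0, 100.0)

    def __post_init__(self) -> None:
        self.grid = tuple(int(n) for n in self.grid)
        if len(self.grid) != 3 or any(n < 8 for n in self.grid):
            raise ValueError(f"standard grid components must be >= 8, got {self.grid}")
        lo, hi = self.hu_window
        if not lo < hi:
            raise ValueError(f"HU window must satisfy lo < hi, got {self.hu_window}")
        self.hu_window = (float(lo), float(hi))


def _affine_from_spacing(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.diag(list(spacing) + [1.0])
    return aff


def _load_canonical(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such volume: {path}")
    img = nib.load(str(path))
    img = nib.as_closest_canonical(img)
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D payload, got shape {data.shape}")
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(data, dtype=np.float64), spacing


def read_volume(path: str | Path) -> CTVolume:
    """Read a CT volume from NIfTI, reoriented to canonical axes."""
    data, spacing = _load_canonical(path)
    if not np.isfinite(data).all():
        raise ValueError(f"{path}: non-finite intensities in CT volume")
    return CTVolume(intensities=data, spacing=spacing)


def read_label(path: str | Path) -> LabelVolume:
    """Read a binary mask from NIfTI; rejects any non-{0,1} payload."""
    data, spacing = _load_canonical(path)
    return LabelVolume(labels=data, spacing=spacing)


def write_volume(vol: CTVolume, path: str | Path) -> Path:
    """Write a CT volume to NIfTI with a diagonal spacing affine."""
    path = Path(path)
    img = nib.Nifti1Image(vol.intensities.astype(np.float64), _affine_from_spacing(vol.spacing))
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
    return path


def write_label(mask: LabelVolume, path: str | Path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), _affine_from_spacing(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, str(path))
    return path
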