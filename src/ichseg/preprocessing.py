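"""Standard-space preprocessing: resampling and HU windowing.

Every scan entering the network is first resampled onto the fixed standard
grid (linear interpolation for intensities, nearest-neighbour for masks so
they stay binary) and then intensity-windowed by clamping HU values into
(lo, hi).  Windowing to (0, 100) suppresses bone and air while keeping the
full soft-tissue/blood contrast: acute blood sits around 50-90 HU, well
above parenchyma (~30 HU), which is the contrast the segmenter exploits.

Interpolation uses the half-pixel-centred convention: output voxel centres
are placed at ``(i + 0.5) / zoom - 0.5`` in input index space, so the
physical extent of the grid is preserved.  Clamping is applied after
resampling, so interpolation operates on native HU values.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volumes import CTVolume, LabelVolume, StandardSpec

__all__ = ["clamp_hu", "resample_to_standard", "standardize", "normalize_intensities"]


def clamp_hu(vol: CTVolume, window: tuple[float, float] | None = None) -> CTVolume:
    """Clamp HU intensities into a window (default (0, 100)).

    Values below the window floor map to the floor, values above the
    ceiling to the ceiling; in-window voxels are unchanged.  Idempotent.
    """
    lo, hi = window if window is not None else (0.0, 100.0)
    if not lo < hi:
        raise ValueError(f"window must satisfy lo < hi, got ({lo}, {hi})")
    if not np.isfinite(vol.intensities).all():
        raise ValueError("cannot clamp a volume with non-finite intensities")
    return CTVolume(intensities=np.clip(vol.intensities, lo, hi), spacing=vol.spacing)


def _zoom_factors(shape: tuple[int, int, int], grid: tuple[int, int, int]) -> tuple[float, ...]:
    if any(n < 2 for n in shape):
        raise ValueError(f"cannot resample a degenerate (single-voxel-axis) grid of shape {shape}")
    return tuple(g / n for g, n in zip(grid, shape))


def resample_to_standard(
    vol: CTVolume,
    labels: LabelVolume | None = None,
    spec: StandardSpec | None = None,
) -> tuple[CTVolume, LabelVolume | None]:
    """Resample a CT (and optionally its mask) onto the standard grid.

    Intensities are interpolated linearly, masks with nearest-neighbour so
    the output stays in {0, 1}.  The output spacing is the input physical
    extent divided by the target grid, so extent is preserved.
    """
    spec = spec or StandardSpec()
    if labels is not None and labels.shape != vol.shape:
        raise ValueError(f"labels shape {labels.shape} does not match volume shape {vol.shape}")
    factors = _zoom_factors(vol.shape, spec.grid)
    out_spacing = tuple(e / g for e, g in zip(vol.extent_mm, spec.grid))

    intens = ndimage.zoom(
        vol.intensities, factors, order=1, grid_mode=True, mode="nearest", prefilter=False
    )
    # zoom can be off by one voxel on awkward ratios; enforce the contract
    if intens.shape != spec.grid:  # pragma: no cover - scipy honors round(n*zoom)
        raise RuntimeError(f"resampled shape {intens.shape} != requested grid {spec.grid}")
    out_vol = CTVolume(intensities=intens, spacing=out_spacing)

    out_labels = None
    if labels is not None:
        lab = ndimage.zoom(
            labels.labels, factors, order=0, grid_mode=True, mode="nearest", prefilter=False
        )
        out_labels = LabelVolume(labels=lab, spacing=out_spacing)
    return out_vol, out_labels


def standardize(
    vol: CTVolume,
    labels: LabelVolume | None = None,
    spec: StandardSpec | None = None,
) -> tuple[CTVolume, LabelVolume | None]:
    """Full preprocessing: resample to the standard grid, then clamp HU."""
    spec = spec or StandardSpec()
    out_vol, out_labels = resample_to_standard(vol, labels, spec)
    return clamp_hu(out_vol, spec.hu_window), out_labels


def normalize_intensities(vol: CTVolume, window: tuple[float, float]) -> np.ndarray:
    """Map windowed HU values linearly onto [0, 1] for network input."""
    lo, hi = window
    return (np.clip(vol.intensities, lo, hi) - lo) / (hi - lo)
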