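"""Prediction and hematoma volume quantification.

The probability map is binarized at a threshold (default 0.5, strict
``>``; a voxel exactly at the threshold is background) and the hemorrhage
volume is the voxel count times the voxel size.  Quantification is done in
standard space by default; optionally the mask is resampled back to the
native grid with nearest-neighbour interpolation and quantified there too,
since the two voxel sizes differ slightly after resampling.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

from scipy import ndimage

import numpy as np

from .model import SegmentationModel, load_model
from .preprocessing import standardize
from .volumes import CTVolume, LabelVolume, StandardSpec, read_volume, write_label

__all__ = ["VolumeMeasurement", "predict_mask", "quantify_volume", "run_pipeline"]


@dataclass
class VolumeMeasurement:
    """A hematoma volume: voxel count times per-voxel volume."""

    voxel_count: int
    voxel_volume_mm3: float

    @property
    def volume_ml(self) -> float:
        return self.voxel_count * self.voxel_volume_mm3 / 1000.0


def predict_mask(
    model: SegmentationModel, vol: CTVolume, threshold: float = 0.5
) -> LabelVolume:
    """Binarize the model's probability map at ``threshold`` (strict >)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    prob = model.predict_proba(vol)
    return LabelVolume(labels=(prob.values > threshold).astype(np.uint8), spacing=vol.spacing)


def quantify_volume(mask: LabelVolume) -> VolumeMeasurement:
    """Exact voxel count and volume in mL from the mask's own voxel size."""
    if mask.spacing is None:  # defensive; LabelVolume validates spacing
        raise ValueError("mask has no spacing metadata")
    return VolumeMeasurement(
        voxel_count=int(mask.labels.sum()), voxel_volume_mm3=mask.voxel_volume_mm3
    )


def _mask_to_native(mask: LabelVolume, native_shape, native_spacing) -> LabelVolume:
    factors = tuple(n / m for n, m in zip(native_shape, mask.shape))
    lab = ndimage.zoom(mask.labels, factors, order=0, grid_mode=True, mode="nearest", prefilter=False)
    return LabelVolume(labels=lab, spacing=native_spacing)


def run_pipeline(
    volume_path: str | Path,
    checkpoint_path: str | Path,
    spec: StandardSpec | None = None,
    threshold: float = 0.5,
    mask_out: str | Path | None = None,
    report_out: str | Path | None = None,
    native_quantification: bool = True,
) -> tuple[LabelVolume, VolumeMeasurement, dict]:
    """Full inference: read -> resample -> clamp -> forward -> threshold ->
    quantify.

    Returns the standard-space mask, its measurement, and a JSON-ready
    report carrying the threshold, grids, spacings, checkpoint identity and
    (when ``native_quantification``) the native-space volume as well.
    Errors from any stage propagate with stage-labelled context.
    """
    spec = spec or StandardSpec()

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    vol = _stage("read", read_volume, volume_path)
    model = _stage("load-checkpoint", load_model, checkpoint_path)
    std_vol, _ = _stage("standardize", standardize, vol, None, spec)
    mask = _stage("predict", predict_mask, model, std_vol, threshold)
    measurement = _stage("quantify", quantify_volume, mask)

    report = {
        "input": str(volume_path),
        "checkpoint": str(checkpoint_path),
        "checkpoint_sha256": hashlib.sha256(Path(checkpoint_path).read_bytes()).hexdigest(),
        "threshold": threshold,
        "native_grid": list(vol.shape),
        "native_spacing_mm": list(vol.spacing),
        "standard_grid": list(spec.grid),
        "standard_spacing_mm": list(std_vol.spacing),
        "hu_window": list(spec.hu_window),
        "voxel_count": measurement.voxel_count,
        "voxel_volume_mm3": measurement.voxel_volume_mm3,
        "volume_ml": measurement.volume_ml,
    }
    if native_quantification:
        native_mask = _stage("native-resample", _mask_to_native, mask, vol.shape, vol.spacing)
        native_meas = quantify_volume(native_mask)
        report["native_voxel_count"] = native_meas.voxel_count
        report["native_volume_ml"] = native_meas.volume_ml

    if mask_out is not None:
        _stage("write-mask", write_label, mask, mask_out)
        report["mask"] = str(mask_out)
    if report_out is not None:
        Path(report_out).write_text(json.dumps(report, indent=2))
    return mask, measurement, report
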