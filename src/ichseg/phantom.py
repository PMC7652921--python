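"""Synthetic head-CT phantoms with ground-truth hematomas and noisy raters.

The generator builds a head-like volume — an ellipsoidal skull shell around
brain parenchyma with hypodense ventricles — and places one or more
hyperdense, irregularly shaped hematoma lobes inside the parenchyma.  Tissue
HU statistics are chosen so the phantom behaves like a clinical scan under
the (0, 100) HU window: parenchyma ~30 HU, ventricular CSF ~8 HU, acute
blood ~65 HU, skull far above the window (it clamps to the ceiling).
An optional calcification decoy adds a small bright non-hemorrhagic focus,
the classic false-positive trap for intensity-driven segmenters.

Simulated raters perturb the true mask only in a band around its boundary,
mirroring how real inter-expert disagreement concentrates at lesion margins,
plus an optional systematic dilation/erosion bias per rater.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import CTVolume, LabelVolume, write_label, write_volume

__all__ = [
    "PhantomSpec",
    "RaterNoiseSpec",
    "AnnotationSet",
    "generate_phantom",
    "simulate_raters",
    "generate_cohort",
]


@dataclass
class PhantomSpec:
    """Parameters of one synthetic head CT.

    Geometry is expressed in millimetres; the default grid emulates a
    moderately downsampled native scan.  ``seed`` fully determines the
    generated volume and mask.
    """

    grid: tuple[int, int, int] = (96, 96, 48)
    spacing: tuple[float, float, float] = (2.0, 2.0, 3.0)
    # tissue HU (mean, sd)
    hu_air: tuple[float, float] = (-1000.0, 20.0)
    hu_skull: tuple[float, float] = (1000.0, 100.0)
    hu_parenchyma: tuple[float, float] = (30.0, 5.0)
    hu_ventricle: tuple[float, float] = (8.0, 4.0)
    hu_hematoma: tuple[float, float] = (65.0, 10.0)
    hu_calcification: tuple[float, float] = (95.0, 3.0)
    # hematoma geometry
    lobe_count: int = 2
    lobe_radius_mm: tuple[float, float] = (8.0, 18.0)
    irregularity: float = 0.3
    # acquisition noise added on top of tissue draws
    noise_sd: float = 2.0
    calcification_prob: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hu_hematoma[0] <= self.hu_parenchyma[0]:
            raise ValueError(
                "hematoma mean HU must exceed parenchyma mean HU "
                f"({self.hu_hematoma[0]} <= {self.hu_parenchyma[0]}): the method "
                "relies on hyperdensity of acute blood"
            )
        if self.lobe_count < 0:
            raise ValueError("lobe_count must be >= 0")
        lo, hi = self.lobe_radius_mm
        if not 0 < lo <= hi:
            raise ValueError(f"lobe_radius_mm must be 0 < lo <= hi, got {self.lobe_radius_mm}")


@dataclass
class RaterNoiseSpec:
    """Annotation-noise model for one simulated rater.

    ``flip_prob`` is the per-voxel label-flip probability inside a band of
    ``band_width`` voxels around the true boundary.  ``morph_radius`` draws
    a systematic bias: a uniformly chosen integer in the closed range,
    applied as dilation (positive) or erosion (negative) of the true mask
    before boundary flips.
    """

    flip_prob: float = 0.1
    band_width: int = 2
    morph_radius: tuple[int, int] = (0, 0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.flip_prob < 0.5:
            raise ValueError(f"flip_prob must lie in [0, 0.5), got {self.flip_prob}")
        if self.band_width < 1:
            raise ValueError("band_width must be >= 1")


@dataclass
class AnnotationSet:
    """Per-case collection of aligned binary rater masks."""

    case_id: str
    masks: dict[str, LabelVolume]

    def __post_init__(self) -> None:
        shapes = {m.shape for m in self.masks.values()}
        if len(shapes) > 1:
            raise ValueError(f"rater masks are not shape-aligned: {shapes}")

    @property
    def rater_ids(self) -> list[str]:
        return list(self.masks)


def _coord_grids(grid, spacing):
    # voxel-centre coordinates in mm, origin at the grid centre
    axes = [(np.arange(n) - (n - 1) / 2.0) * s for n, s in zip(grid, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix gives a Haar-random orthogonal matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    return q * np.sign(np.diag(r))


def _lobe_mask(coords, center, radii, rot, irregularity, rng):
    x = np.stack([c - mu for c, mu in zip(coords, center)], axis=-1)  # (..., 3)
    local = x @ rot.T
    q = np.sqrt(np.sum((local / radii) ** 2, axis=-1))
    if irregularity > 0:
        # low-frequency multiplicative boundary perturbation
        pert = np.zeros(q.shape)
        for _ in range(3):
            k = rng.normal(scale=0.15, size=3)  # cycles per ~7 mm
            phase = rng.uniform(0, 2 * np.pi)
            pert += np.cos(sum(ki * ci for ki, ci in zip(k, coords)) + phase)
        pert /= 3.0
        thresh = 1.0 + irregularity * pert
    else:
        thresh = 1.0
    return q <= thresh


def generate_phantom(spec: PhantomSpec) -> tuple[CTVolume, LabelVolume]:
    """Generate one synthetic head CT and its exact hematoma mask."""
    rng = np.random.default_rng(spec.seed)
    coords = _coord_grids(spec.grid, spec.spacing)
    half_extent = np.array([n * s for n, s in zip(spec.grid, spec.spacing)]) / 2.0
    head_radii = 0.85 * half_extent

    # normalised head radius; skull is a thin shell at the head boundary
    r = np.sqrt(sum((c / a) ** 2 for c, a in zip(coords, head_radii)))
    head = r <= 1.0
    brain = r <= 0.90
    skull = head & ~brain

    # two para-midline ventricles
    ventricles = np.zeros(spec.grid, dtype=bool)
    for sx in (-1.0, 1.0):
        center = (sx * 0.12 * half_extent[0], 0.0, 0.08 * half_extent[2])
        radii = np.array([0.08, 0.25, 0.12]) * half_extent
        vx = np.stack([c - mu for c, mu in zip(coords, center)], axis=-1)
        ventricles |= (np.sqrt(np.sum((vx / radii) ** 2, axis=-1)) <= 1.0) & brain

    # hematoma: union of irregular ellipsoidal lobes inside the parenchyma
    hematoma = np.zeros(spec.grid, dtype=bool)
    if spec.lobe_count > 0:
        for attempt in range(10):
            hematoma[:] = False
            first_center = None
            for _ in range(spec.lobe_count):
                if first_center is None:
                    center = rng.uniform(-0.45, 0.45, size=3) * head_radii
                    first_center = center
                else:
                    # keep lobes near each other so the lesion is one complex
                    center = first_center + rng.uniform(-0.5, 0.5, size=3) * np.mean(
                        spec.lobe_radius_mm
                    )
                radii = rng.uniform(*spec.lobe_radius_mm, size=3)
                lobe = _lobe_mask(coords, center, radii, _random_rotation(rng), spec.irregularity, rng)
                hematoma |= lobe
            hematoma &= brain & ~ventricles
            if hematoma.sum() >= 8:
                break
        else:
            raise RuntimeError("hematoma geometry sampling produced an empty lesion 10 times")

    tissue_mean = np.full(spec.grid, spec.hu_air[0])
    tissue_sd = np.full(spec.grid, spec.hu_air[1])
    for mask, (mu, sd) in (
        (brain, spec.hu_parenchyma),
        (ventricles, spec.hu_ventricle),
        (hematoma, spec.hu_hematoma),
        (skull, spec.hu_skull),
    ):
        tissue_mean[mask] = mu
        tissue_sd[mask] = sd

    # optional calcification decoy: bright non-hemorrhagic focus in brain
    if spec.calcification_prob > 0 and rng.uniform() < spec.calcification_prob:
        for _ in range(20):
            center = rng.uniform(-0.5, 0.5, size=3) * head_radii
            cx = np.stack([c - mu for c, mu in zip(coords, center)], axis=-1)
            decoy = (np.sqrt(np.sum((cx / 4.0) ** 2, axis=-1)) <= 1.0) & brain
            if decoy.any() and not (decoy & hematoma).any():
                tissue_mean[decoy] = spec.hu_calcification[0]
                tissue_sd[decoy] = spec.hu_calcification[1]
                break

    intensities = tissue_mean + tissue_sd * rng.standard_normal(spec.grid)
    if spec.noise_sd > 0:
        intensities += spec.noise_sd * rng.standard_normal(spec.grid)

    vol = CTVolume(intensities=intensities, spacing=spec.spacing)
    mask = LabelVolume(labels=hematoma.astype(np.uint8), spacing=spec.spacing)
    return vol, mask


def simulate_raters(truth: LabelVolume, specs: list[RaterNoiseSpec]) -> AnnotationSet:
    """Produce one perturbed binary mask per rater from the true mask.

    Noise is confined to a band around the mask boundary: the expected
    voxel disagreement with truth grows monotonically with ``flip_prob``.
    """
    masks: dict[str, LabelVolume] = {}
    for k, spec in enumerate(specs, start=1):
        rng = np.random.default_rng(spec.seed)
        mask = truth.labels.astype(bool)

        lo, hi = spec.morph_radius
        radius = int(rng.integers(lo, hi + 1)) if hi >= lo and (lo, hi) != (0, 0) else 0
        if radius > 0:
            mask = ndimage.binary_dilation(mask, iterations=radius)
        elif radius < 0:
            eroded = ndimage.binary_erosion(mask, iterations=-radius)
            if eroded.any():  # never let bias erase the lesion entirely
                mask = eroded

        if spec.flip_prob > 0 and mask.any():
            band = ndimage.binary_dilation(mask, iterations=spec.band_width) & ~ndimage.binary_erosion(
                mask, iterations=spec.band_width
            )
            flips = band & (rng.random(mask.shape) < spec.flip_prob)
            mask = mask ^ flips

        masks[f"E{k}"] = LabelVolume(labels=mask.astype(np.uint8), spacing=truth.spacing)
    return AnnotationSet(case_id="", masks=masks)


def _split_cases(case_ids: list[str], split: tuple[int, int, int], rng: np.random.Generator):
    n_train, n_val, n_test = split
    if n_train + n_val + n_test != len(case_ids):
        raise ValueError(f"split {split} does not sum to {len(case_ids)} cases")
    order = list(rng.permutation(case_ids))
    return {
        "train": sorted(order[:n_train]),
        "val": sorted(order[n_train : n_train + n_val]),
        "test": sorted(order[n_train + n_val :]),
    }


def generate_cohort(
    n: int,
    out_dir: str | Path,
    spec: PhantomSpec | None = None,
    rater_specs: list[RaterNoiseSpec] | None = None,
    split: tuple[int, int, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Write ``n`` phantom cases with rater masks and a CSV manifest.

    Each case gets its own child seed derived from ``seed``; the train/
    validation/test split is a seeded permutation.  Returns the manifest
    (also written to ``out_dir/manifest.csv``) with one row per case and
    columns for the image, truth and per-rater mask paths.
    """
    if n < 2:
        raise ValueError("a cohort needs at least 2 cases")
    spec = spec or PhantomSpec()
    if rater_specs is None:
        rater_specs = [
            RaterNoiseSpec(flip_prob=0.08, morph_radius=(0, 1)),
            RaterNoiseSpec(flip_prob=0.10),
            RaterNoiseSpec(flip_prob=0.12, morph_radius=(-1, 0)),
        ]
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    case_seeds = ss.generate_state(n * (len(rater_specs) + 1)).reshape(n, -1) % (2**31)
    rows = []
    for i in range(n):
        case_id = f"case{i:03d}"
        case_spec = PhantomSpec(**{**asdict(spec), "seed": int(case_seeds[i, 0])})
        vol, truth = generate_phantom(case_spec)
        r_specs = [
            RaterNoiseSpec(**{**asdict(rs), "seed": int(case_seeds[i, 1 + j])})
            for j, rs in enumerate(rater_specs)
        ]
        ann = simulate_raters(truth, r_specs)

        row = {"case_id": case_id}
        row["image"] = str(write_volume(vol, out_dir / f"{case_id}_image.nii.gz"))
        row["truth"] = str(write_label(truth, out_dir / f"{case_id}_truth.nii.gz"))
        for rid, m in ann.masks.items():
            row[f"rater_{rid}"] = str(write_label(m, out_dir / f"{case_id}_{rid}.nii.gz"))
        row["truth_voxels"] = int(truth.labels.sum())
        rows.append(row)

    manifest = pd.DataFrame(rows)
    if split is None:
        n_test = max(1, n // 5)
        n_val = max(1, n // 5)
        split = (n - n_val - n_test, n_val, n_test)
    assignment = _split_cases(list(manifest["case_id"]), split, np.random.default_rng(seed))
    manifest["split"] = [
        next(s for s, ids in assignment.items() if cid in ids) for cid in manifest["case_id"]
    ]
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    with open(out_dir / "cohort_config.json", "w") as fh:
        json.dump({"n": n, "seed": seed, "split": split, "phantom": asdict(spec)}, fh, indent=2)
    return manifest
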