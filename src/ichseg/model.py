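"""The deeply supervised 3-D U-Net (CNN-DS) for hemorrhage segmentation.

The network maps a standardized, HU-windowed head CT volume to a voxel-wise
hemorrhage probability map of identical spatial size.  The contracting path
stacks residual *context modules* (two 3x3x3 convolutions with dropout in
between, plus an identity skip) connected by stride-2 3x3x3 convolutions;
channel width doubles at every level.  The expansive path mirrors it with
*upscaling modules* (upsampling, a 3x3x3 and a 1x1x1 convolution),
concatenation with the matching contracting feature map, and *localization
modules* (a 3x3x3 followed by a 1x1x1 convolution).  With deep supervision
enabled, 3x3x3 segmentation layers at the decoder levels are upsampled to
full resolution and merged by element-wise summation of their logits before
the output sigmoid; without it only the finest-level segmentation layer is
used, leaving the encoder-decoder otherwise identical — the controlled
comparison the ablation harness relies on.

Parameter initialization is He-normal, seeded per parameter name, so two
builds with the same seed share identical values for every parameter they
have in common (in particular across the deep-supervision ablation arms).
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .volumes import CTVolume

__all__ = [
    "NetworkConfig",
    "SegmentationModel",
    "ProbabilityMap",
    "build_model",
    "count_parameters",
    "save_weights",
    "load_model",
    "load_weights",
]

GRID_SEARCH_DEPTHS = (3, 4, 5, 6)


@dataclass
class NetworkConfig:
    """Architecture hyper-parameters.

    ``depth`` counts resolution levels (the tuned domain is {3,4,5,6});
    the input grid must be divisible by ``2**(depth-1)`` per axis.  Channel
    width at level ``l`` is ``base_channels * 2**l``.
    """

    depth: int = 4
    base_channels: int = 16
    dropout_rate: float = 0.3
    use_deep_supervision: bool = True
    in_grid: tuple[int, int, int] = (128, 128, 64)
    hu_window: tuple[float, float] = (0.0, 100.0)
    upsample_mode: str = "nearest"  # or "transposed" (zero-stuffing + conv)
    use_instance_norm: bool = True
    deep_supervision_levels: tuple[int, ...] | None = None
    relu_after_1x1: bool = True

    def __post_init__(self) -> None:
        if self.depth not in GRID_SEARCH_DEPTHS:
            raise ValueError(f"depth must be one of {GRID_SEARCH_DEPTHS}, got {self.depth}")
        if self.base_channels < 1:
            raise ValueError("base_channels must be >= 1")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError(f"dropout_rate must be in [0, 1), got {self.dropout_rate}")
        if self.upsample_mode not in ("nearest", "transposed"):
            raise ValueError(f"unknown upsample_mode {self.upsample_mode!r}")
        self.in_grid = tuple(int(n) for n in self.in_grid)
        div = 2 ** (self.depth - 1)
        for axis, n in zip("xyz", self.in_grid):
            if n % div:
                raise ValueError(
                    f"in_grid axis {axis} (={n}) not divisible by 2**(depth-1) = {div}"
                )
        if self.deep_supervision_levels is None:
            # every expansive level except the coarsest (the bottleneck)
            self.deep_supervision_levels = tuple(range(self.depth - 1))
        else:
            self.deep_supervision_levels = tuple(sorted(set(int(l) for l in self.deep_supervision_levels)))
            if any(l < 0 or l > self.depth - 2 for l in self.deep_supervision_levels):
                raise ValueError(
                    f"deep_supervision_levels must lie in [0, depth-2], got {self.deep_supervision_levels}"
                )
            if 0 not in self.deep_supervision_levels:
                raise ValueError("level 0 must carry a segmentation layer")

    def channels(self, level: int) -> int:
        return self.base_channels * 2**level

    @property
    def seg_levels(self) -> tuple[int, ...]:
        return self.deep_supervision_levels if self.use_deep_supervision else (0,)


@dataclass
class ProbabilityMap:
    """Voxel-wise hemorrhage probabilities on the standard grid."""

    values: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if not np.isfinite(v).all():
            raise ValueError("probability map contains non-finite values")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("probability map values must lie in [0, 1]")
        self.values = v


def _he_init(shape: tuple[int, ...], fan_in: int, rng: np.random.Generator) -> np.ndarray:
    return rng.normal(scale=np.sqrt(2.0 / fan_in), size=shape)


def _param_rng(seed: int, name: str) -> np.random.Generator:
    # a parameter's init depends only on (seed, name): builds sharing a seed
    # share values for every parameter name they have in common
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


class SegmentationModel:
    """A configured CNN-DS with its trainable weights.

    Use :func:`build_model` to construct one; :meth:`forward` runs a
    deterministic evaluation-mode pass, :meth:`forward_tensor` a
    differentiable pass for training.
    """

    def __init__(self, config: NetworkConfig, params: dict[str, Tensor], seed: int):
        self.config = config
        self.params = params
        self.seed = seed

    # ----- plumbing -------------------------------------------------------

    def _conv_params(self, name: str) -> tuple[Tensor, Tensor]:
        return self.params[f"{name}.w"], self.params[f"{name}.b"]

    def _conv(self, x: Tensor, name: str, stride: int = 1) -> Tensor:
        w, b = self._conv_params(name)
        return nn.conv3d(x, w, b, stride=stride)

    def _norm(self, x: Tensor, name: str) -> Tensor:
        if not self.config.use_instance_norm:
            return x
        return nn.instance_norm(x, self.params[f"{name}.g"], self.params[f"{name}.b"])

    def _context(self, x: Tensor, level: int, training: bool, rng) -> Tensor:
        # pre-activation residual block with dropout between the two convs;
        # zero-initialized closing conv makes the block start as the identity
        h = self._conv(nn.relu(self._norm(x, f"enc{level}.n1")), f"enc{level}.ctx1")
        h = nn.dropout(h, self.config.dropout_rate, rng, training)
        h = self._conv(nn.relu(self._norm(h, f"enc{level}.n2")), f"enc{level}.ctx2")
        return nn.add(x, h)

    def _upscale(self, x: Tensor, level: int) -> Tensor:
        if self.config.upsample_mode == "nearest":
            u = nn.upsample_nearest(x, 2)
        else:
            u = nn.upsample_zeros(x, 2)
        u = nn.relu(self._norm(self._conv(u, f"dec{level}.up3"), f"dec{level}.nu"))
        u = self._conv(u, f"dec{level}.up1")
        return nn.relu(u) if self.config.relu_after_1x1 else u

    def _localize(self, x: Tensor, level: int) -> Tensor:
        h = nn.relu(self._norm(self._conv(x, f"dec{level}.loc3"), f"dec{level}.nl"))
        h = self._conv(h, f"dec{level}.loc1")
        return nn.relu(h) if self.config.relu_after_1x1 else h

    # ----- forward passes -------------------------------------------------

    def forward_tensor(
        self, x01: np.ndarray, training: bool = False, rng: np.random.Generator | None = None
    ) -> Tensor:
        """Differentiable pass on a [0,1]-scaled volume; returns the
        probability tensor."""
        if x01.shape != self.config.in_grid:
            raise ValueError(f"input shape {x01.shape} != configured grid {self.config.in_grid}")
        if training and rng is None:
            raise ValueError("training-mode forward needs a dropout rng")
        cfg = self.config
        x = Tensor(x01[None])  # (1, X, Y, Z)

        feats = []
        h = self._conv(x, "enc0.in")
        h = self._context(h, 0, training, rng)
        feats.append(h)
        for l in range(1, cfg.depth):
            h = self._conv(h, f"enc{l}.down", stride=2)
            h = self._context(h, l, training, rng)
            feats.append(h)

        seg_logits: dict[int, Tensor] = {}
        d = feats[-1]
        for l in range(cfg.depth - 2, -1, -1):
            d = self._upscale(d, l)
            d = nn.concat(d, feats[l])
            d = self._localize(d, l)
            if l in self.config.seg_levels:
                seg_logits[l] = self._conv(d, f"seg{l}")

        # merge segmentation logits at full resolution by element-wise sum
        merged: Tensor | None = None
        for l, s in sorted(seg_logits.items()):
            for _ in range(l):
                s = nn.upsample_nearest(s, 2)
            merged = s if merged is None else nn.add(merged, s)
        p = nn.sigmoid(merged)
        return Tensor(p.data[0], parents=(p,), backward=lambda g: p._accumulate(g[None]))

    def forward(self, x01: np.ndarray) -> np.ndarray:
        """Deterministic evaluation-mode pass (dropout disabled)."""
        return self.forward_tensor(x01, training=False).data

    def predict_proba(self, vol: CTVolume) -> ProbabilityMap:
        """Probability map for a standardized, HU-windowed CT volume."""
        lo, hi = self.config.hu_window
        v = vol.intensities
        if v.min() < lo - 1e-9 or v.max() > hi + 1e-9:
            raise ValueError(
                f"intensities outside the HU window ({lo}, {hi}); clamp before inference"
            )
        x01 = (v - lo) / (hi - lo)
        return ProbabilityMap(values=self.forward(x01), spacing=vol.spacing)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.zero_grad()


def _parameter_shapes(cfg: NetworkConfig) -> dict[str, tuple[tuple[int, ...], int]]:
    """Name -> (shape, fan_in) for every trainable parameter, in a fixed order."""
    shapes: dict[str, tuple[tuple[int, ...], int]] = {}

    def conv(name: str, cin: int, cout: int, k: int) -> None:
        shapes[f"{name}.w"] = ((cout, cin, k, k, k), cin * k**3)
        shapes[f"{name}.b"] = ((cout,), cin * k**3)

    def norm(name: str, c: int) -> None:
        if cfg.use_instance_norm:
            shapes[f"{name}.g"] = ((c,), 0)
            shapes[f"{name}.b"] = ((c,), 0)

    conv("enc0.in", 1, cfg.channels(0), 3)
    for l in range(cfg.depth):
        c = cfg.channels(l)
        norm(f"enc{l}.n1", c)
        conv(f"enc{l}.ctx1", c, c, 3)
        norm(f"enc{l}.n2", c)
        conv(f"enc{l}.ctx2", c, c, 3)
        if l >= 1:
            conv(f"enc{l}.down", cfg.channels(l - 1), c, 3)
    for l in range(cfg.depth - 2, -1, -1):
        c = cfg.channels(l)
        conv(f"dec{l}.up3", cfg.channels(l + 1), c, 3)
        norm(f"dec{l}.nu", c)
        conv(f"dec{l}.up1", c, c, 1)
        conv(f"dec{l}.loc3", 2 * c, c, 3)
        norm(f"dec{l}.nl", c)
        conv(f"dec{l}.loc1", c, c, 1)
    for l in cfg.seg_levels:
        conv(f"seg{l}", cfg.channels(l), 1, 3)
    return shapes


def build_model(config: NetworkConfig, seed: int = 0) -> SegmentationModel:
    """Assemble a CNN-DS with He-normal, seed-deterministic initialization."""
    params: dict[str, Tensor] = {}
    for name, (shape, fan_in) in _parameter_shapes(config).items():
        rng = _param_rng(seed, name)
        if name.endswith(".g"):
            data = np.ones(shape)
        elif name.endswith(".b"):
            data = np.zeros(shape)
        elif name.startswith("seg") or ".ctx2" in name:
            # zero-init: residual blocks start as the identity and the merged
            # segmentation logit starts at 0 (p = 0.5 everywhere).  Without
            # normalization layers, activation variance would otherwise double
            # at every residual level and the initial logits would be large
            # enough for the first optimizer steps to saturate the sigmoid.
            data = np.zeros(shape)
        else:
            data = _he_init(shape, fan_in, rng)
        params[name] = Tensor(data, requires_grad=True)
    return SegmentationModel(config, params, seed)


def count_parameters(model: SegmentationModel) -> int:
    return int(sum(p.data.size for p in model.params.values()))


def save_weights(model: SegmentationModel, path: str | Path) -> Path:
    """Checkpoint weights together with the embedded NetworkConfig."""
    path = Path(path)
    if path.suffix != ".npz":
        path = Path(str(path) + ".npz")
    cfg_json = json.dumps(asdict(model.config))
    np.savez(
        path,
        __config__=np.frombuffer(cfg_json.encode(), dtype=np.uint8),
        __seed__=np.array([model.seed]),
        **{name: p.data for name, p in model.params.items()},
    )
    return path


def _read_checkpoint(path: str | Path):
    with np.load(Path(path)) as archive:
        cfg_dict = json.loads(bytes(archive["__config__"].tobytes()).decode())
        seed = int(archive["__seed__"][0])
        weights = {k: archive[k] for k in archive.files if not k.startswith("__")}
    cfg_dict["in_grid"] = tuple(cfg_dict["in_grid"])
    cfg_dict["hu_window"] = tuple(cfg_dict["hu_window"])
    if cfg_dict.get("deep_supervision_levels") is not None:
        cfg_dict["deep_supervision_levels"] = tuple(cfg_dict["deep_supervision_levels"])
    return NetworkConfig(**cfg_dict), seed, weights


def load_model(path: str | Path) -> SegmentationModel:
    """Rebuild a model entirely from a checkpoint."""
    config, seed, weights = _read_checkpoint(path)
    model = build_model(config, seed)
    for name, p in model.params.items():
        p.data = weights[name].astype(np.float64)
    return model


def load_weights(model: SegmentationModel, path: str | Path) -> SegmentationModel:
    """Load weights into an existing model; the checkpoint's config must
    match the model's exactly."""
    config, _, weights = _read_checkpoint(path)
    if config != model.config:
        raise ValueError(
            f"checkpoint config {config} does not match model config {model.config}"
        )
    for name, p in model.params.items():
        p.data = weights[name].astype(np.float64)
    return model
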