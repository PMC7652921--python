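"""Dice-loss training with plateau LR-halving, early stopping, grid search
and the deep-supervision ablation harness.

The loss is the negated two-class soft Dice: with ``g`` the binary
reference, ``p`` the predicted foreground probability, and the background
class realized as ``(1-g, 1-p)``,

    loss = -(1/|L|) * sum_{l in L} [ 2 * sum_i g_l^i p_l^i
                                     / sum_i (g_l^i + p_l^i) ],   L = {0, 1}

so a perfect prediction scores -1 and the loss lives in [-1, 0].  A small
epsilon (1e-5) is added to each denominator so the expression stays defined
when a class is absent from both ``g`` and ``p``.

Optimization follows the reference schedule: Adam (betas 0.9/0.999), batch
size one, initial learning rate 0.005; the learning rate is divided by two
whenever the validation loss fails to improve for ten consecutive epochs,
and training stops after fifty consecutive epochs without improvement.
The schedule is a pure function of the validation-loss sequence and is
unit-testable without any network.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .model import NetworkConfig, SegmentationModel, build_model
from .nn import Adam
from .preprocessing import standardize
from .volumes import StandardSpec, read_label, read_volume

__all__ = [
    "DICE_EPS",
    "TrainConfig",
    "TrainState",
    "GridSpec",
    "PlateauScheduler",
    "dice_loss",
    "dice_loss_grad",
    "replay_schedule",
    "train",
    "grid_search",
    "ablate_ds",
    "epochs_to_loss",
    "prepare_cases",
]

DICE_EPS = 1e-5


# ----------------------------------------------------------------------------
# loss


def _check_loss_inputs(g: np.ndarray, p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.asarray(g, dtype=np.float64)
    p = np.asarray(p, dtype=np.float64)
    if g.shape != p.shape:
        raise ValueError(f"label/prediction shape mismatch: {g.shape} vs {p.shape}")
    if not np.isin(np.unique(g), (0.0, 1.0)).all():
        raise ValueError("reference labels must be binary")
    if p.min() < 0.0 or p.max() > 1.0:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    return g, p


def dice_loss(g: np.ndarray, p: np.ndarray, eps: float = DICE_EPS) -> float:
    """Negated class-averaged soft Dice over L = {0, 1}; in [-1, 0]."""
    g, p = _check_loss_inputs(g, p)
    total = 0.0
    for gl, pl in ((g, p), (1.0 - g, 1.0 - p)):
        total += 2.0 * float((gl * pl).sum()) / (float((gl + pl).sum()) + eps)
    return -total / 2.0


def dice_loss_grad(
    g: np.ndarray, p: np.ndarray, eps: float = DICE_EPS
) -> tuple[float, np.ndarray]:
    """Loss value and its analytic gradient with respect to ``p``."""
    g, p = _check_loss_inputs(g, p)
    s1 = float((g * p).sum())
    d1 = float((g + p).sum()) + eps
    s0 = float(((1.0 - g) * (1.0 - p)).sum())
    d0 = float((2.0 - g - p).sum()) + eps
    loss = -(2.0 * s1 / d1 + 2.0 * s0 / d0) / 2.0
    grad = -(
        (g * d1 - s1) / d1**2  # foreground term
        + (s0 - (1.0 - g) * d0) / d0**2  # background term (dp0/dp = -1)
    )
    return loss, grad


# ----------------------------------------------------------------------------
# schedule


class PlateauScheduler:
    """Plateau LR-halving plus early stopping.

    An epoch *improves* when its validation loss is strictly below the best
    seen so far.  After ``plateau_patience`` consecutive non-improving
    epochs the learning rate is multiplied by ``lr_factor`` (and the
    plateau counter restarts); after ``early_stop_patience`` consecutive
    non-improving epochs ``should_stop`` becomes true.
    """

    def __init__(
        self,
        initial_lr: float,
        plateau_patience: int = 10,
        lr_factor: float = 0.5,
        early_stop_patience: int = 50,
    ):
        if not 0.0 < lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        if plateau_patience < 1 or early_stop_patience < 1:
            raise ValueError("patience values must be positive integers")
        self.lr = float(initial_lr)
        self.plateau_patience = int(plateau_patience)
        self.lr_factor = float(lr_factor)
        self.early_stop_patience = int(early_stop_patience)
        self.best = math.inf
        self.best_epoch = 0
        self.epoch = 0
        self._stagnant = 0  # consecutive non-improving epochs (early stop)
        self._stagnant_lr = 0  # consecutive non-improving epochs since last LR event
        self.should_stop = False

    def step(self, val_loss: float) -> None:
        self.epoch += 1
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = self.epoch
            self._stagnant = 0
            self._stagnant_lr = 0
            return
        self._stagnant += 1
        self._stagnant_lr += 1
        if self._stagnant_lr >= self.plateau_patience:
            self.lr *= self.lr_factor
            self._stagnant_lr = 0
        if self._stagnant >= self.early_stop_patience:
            self.should_stop = True


def replay_schedule(
    val_losses: list[float],
    initial_lr: float,
    plateau_patience: int = 10,
    lr_factor: float = 0.5,
    early_stop_patience: int = 50,
) -> tuple[list[float], int | None]:
    """Replay the schedule over a scripted validation-loss sequence.

    Returns the learning rate in effect *after* each epoch and the 1-based
    epoch at which training would stop (None if it never would).
    """
    sched = PlateauScheduler(initial_lr, plateau_patience, lr_factor, early_stop_patience)
    lrs: list[float] = []
    stop_epoch: int | None = None
    for v in val_losses:
        sched.step(v)
        lrs.append(sched.lr)
        if sched.should_stop and stop_epoch is None:
            stop_epoch = sched.epoch
    return lrs, stop_epoch


# ----------------------------------------------------------------------------
# configuration and state


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults follow the tuned schedule)."""

    initial_lr: float = 0.005
    adam_beta1: float = 0.9
    adam_beta2: float = 0.999
    batch_size: int = 1
    max_epochs: int = 500
    plateau_patience: int = 10
    lr_factor: float = 0.5
    early_stop_patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size != 1:
            raise ValueError("the training procedure uses a batch of size one")
        if not 0.0 < self.lr_factor < 1.0:
            raise ValueError("lr_factor must lie in (0, 1)")
        if self.plateau_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be positive integers")


@dataclass
class TrainState:
    """Per-epoch loss curves and schedule trace of one training run."""

    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)
    best_val_loss: float = math.inf
    best_epoch: int = 0
    stopped_early: bool = False
    seed: int = 0

    @property
    def epochs_completed(self) -> int:
        return len(self.train_loss)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(1, self.epochs_completed + 1),
                "train_loss": self.train_loss,
                "val_loss": self.val_loss,
                "lr": self.lr,
            }
        )

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        return path


@dataclass
class GridSpec:
    """The hyper-parameter grid searched over the validation set."""

    depths: tuple[int, ...] = (3, 4, 5, 6)
    learning_rates: tuple[float, ...] = (1e-2, 5e-3, 1e-3, 5e-4, 1e-4)
    dropout_rates: tuple[float, ...] = (0.3, 0.4, 0.5)

    def cells(self):
        """Cartesian product in declaration order (ties break first-wins)."""
        return itertools.product(self.depths, self.learning_rates, self.dropout_rates)

    @property
    def n_cells(self) -> int:
        return len(self.depths) * len(self.learning_rates) * len(self.dropout_rates)


# ----------------------------------------------------------------------------
# training loop


def _as_pairs(cases) -> list[tuple[np.ndarray, np.ndarray]]:
    pairs = []
    for c in cases:
        x, g = c
        pairs.append((np.asarray(x, dtype=np.float64), np.asarray(g, dtype=np.float64)))
    return pairs


def train(
    model: SegmentationModel,
    train_cases,
    val_cases,
    cfg: TrainConfig | None = None,
) -> tuple[SegmentationModel, TrainState]:
    """Optimize ``model`` in place; returns it with the recorded TrainState.

    ``train_cases`` and ``val_cases`` are sequences of ``(image01, labels)``
    pairs on the model's input grid, with image intensities already scaled
    to [0, 1] and labels binary.  One optimizer step per case per epoch
    (batch size one); validation loss is the same Dice loss in evaluation
    mode (dropout off).
    """
    cfg = cfg or TrainConfig()
    train_pairs = _as_pairs(train_cases)
    val_pairs = _as_pairs(val_cases)
    if not train_pairs or not val_pairs:
        raise ValueError("training and validation sets must both be non-empty")

    ss = np.random.SeedSequence(cfg.seed)
    order_rng, dropout_rng = (np.random.default_rng(s) for s in ss.spawn(2))
    opt = Adam(model.params, lr=cfg.initial_lr, beta1=cfg.adam_beta1, beta2=cfg.adam_beta2)
    sched = PlateauScheduler(
        cfg.initial_lr, cfg.plateau_patience, cfg.lr_factor, cfg.early_stop_patience
    )
    state = TrainState(seed=cfg.seed)

    for _epoch in range(cfg.max_epochs):
        losses = []
        for idx in order_rng.permutation(len(train_pairs)):
            x, g = train_pairs[idx]
            opt.zero_grad()
            p = model.forward_tensor(x, training=True, rng=dropout_rng)
            loss, grad = dice_loss_grad(g, np.clip(p.data, 0.0, 1.0))
            if not math.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {sched.epoch + 1} "
                    f"(case index {idx}); last lr {opt.lr}"
                )
            p.backward(grad)
            opt.step()
            losses.append(loss)
        val = float(np.mean([dice_loss(g, model.forward(x)) for x, g in val_pairs]))
        if not math.isfinite(val):
            raise RuntimeError(f"non-finite validation loss at epoch {sched.epoch + 1}")

        sched.step(val)
        opt.lr = sched.lr
        state.train_loss.append(float(np.mean(losses)))
        state.val_loss.append(val)
        state.lr.append(sched.lr)
        state.best_val_loss = sched.best
        state.best_epoch = sched.best_epoch
        if sched.should_stop:
            state.stopped_early = True
            break
    return model, state


def grid_search(
    grid: GridSpec,
    train_cases,
    val_cases,
    network_cfg: NetworkConfig | None = None,
    train_cfg: TrainConfig | None = None,
    max_epochs_per_cell: int = 20,
) -> tuple[dict, pd.DataFrame]:
    """Exhaustive search over the (depth, lr, dropout) grid.

    Every cell trains a freshly initialized network under the given budget
    and is scored by its best validation loss; ties break in favour of the
    first cell in enumeration order.  Returns the winning cell and the full
    per-cell results table.
    """
    if max_epochs_per_cell < 1:
        raise ValueError("the budget must allow at least one epoch per cell")
    network_cfg = network_cfg or NetworkConfig()
    train_cfg = train_cfg or TrainConfig()
    records = []
    best: dict | None = None
    for depth, lr, dropout in grid.cells():
        cell_net = replace(
            network_cfg, depth=depth, dropout_rate=dropout, deep_supervision_levels=None
        )
        cell_train = replace(train_cfg, initial_lr=lr, max_epochs=max_epochs_per_cell)
        model = build_model(cell_net, seed=train_cfg.seed)
        _, state = train(model, train_cases, val_cases, cell_train)
        rec = {
            "depth": depth,
            "learning_rate": lr,
            "dropout_rate": dropout,
            "best_val_loss": state.best_val_loss,
            "epochs": state.epochs_completed,
        }
        records.append(rec)
        if best is None or rec["best_val_loss"] < best["best_val_loss"]:
            best = rec
    return best, pd.DataFrame(records)


def ablate_ds(
    train_cases,
    val_cases,
    network_cfg: NetworkConfig,
    train_cfg: TrainConfig,
    seeds,
) -> list[tuple[TrainState, TrainState]]:
    """Paired with/without-deep-supervision runs, identical otherwise.

    For each seed, the two arms share data order, dropout stream and the
    initial values of every parameter they have in common; only the
    deep-supervision branches differ.  Returns ``(with_ds, without_ds)``
    TrainState pairs, one per seed.
    """
    results = []
    for seed in seeds:
        pair = []
        for use_ds in (True, False):
            cfg_net = replace(network_cfg, use_deep_supervision=use_ds)
            cfg_train = replace(train_cfg, seed=int(seed))
            model = build_model(cfg_net, seed=int(seed))
            _, state = train(model, train_cases, val_cases, cfg_train)
            pair.append(state)
        results.append((pair[0], pair[1]))
    return results


def epochs_to_loss(state: TrainState, threshold: float) -> float:
    """First 1-based epoch whose training loss is <= threshold (inf if never)."""
    for i, loss in enumerate(state.train_loss, start=1):
        if loss <= threshold:
            return float(i)
    return math.inf


# ----------------------------------------------------------------------------
# data loading


def prepare_cases(
    manifest: pd.DataFrame | str | Path,
    split: str | None = None,
    spec: StandardSpec | None = None,
    reference: str = "truth",
) -> tuple[list[tuple[np.ndarray, np.ndarray]], list[str]]:
    """Load cohort cases as network-ready ``(image01, labels)`` pairs.

    Reads the image and reference mask of every manifest row (optionally
    restricted to one split), standardizes both, and scales intensities by
    the HU window onto [0, 1].  ``reference`` selects the ``truth`` column
    or a rater column (e.g. ``rater_E1``).
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    if split is not None:
        manifest = manifest[manifest["split"] == split]
    spec = spec or StandardSpec()
    lo, hi = spec.hu_window
    pairs, ids = [], []
    for _, row in manifest.iterrows():
        vol = read_volume(row["image"])
        mask = read_label(row[reference if reference in row else f"rater_{reference}"])
        std_vol, std_mask = standardize(vol, mask, spec)
        x01 = (std_vol.intensities - lo) / (hi - lo)
        pairs.append((x01, std_mask.labels.astype(np.float64)))
        ids.append(str(row["case_id"]))
    return pairs, ids
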