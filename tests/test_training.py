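import numpy as np
import pytest

from ichseg import (
    GridSpec,
    NetworkConfig,
    TrainConfig,
    build_model,
    dice_loss,
    dice_loss_grad,
    grid_search,
    replay_schedule,
    train,
)
from ichseg.training import PlateauScheduler, prepare_cases


def dice_loss_oracle(g, p):
    """Naive voxel-loop evaluation of the printed two-class formula."""
    total = 0.0
    for label in (0, 1):
        num = den = 0.0
        for gi, pi in zip(np.ravel(g), np.ravel(p)):
            gl = gi if label == 1 else 1 - gi
            pl = pi if label == 1 else 1 - pi
            num += gl * pl
            den += gl + pl
        total += 2 * num / den
    return -total / 2


class TestDiceLoss:
    def test_hand_worked_example(self):
        # g=(1,1,0,0), p=(1,0,0,0): fg 2/3, bg 4/5 -> -(2/3+4/5)/2 = -11/15
        g = np.array([1.0, 1.0, 0.0, 0.0])
        p = np.array([1.0, 0.0, 0.0, 0.0])
        assert dice_loss(g, p) == pytest.approx(-11 / 15, abs=1e-5)

    def test_perfect_prediction_scores_minus_one(self, rng):
        g = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert dice_loss(g, g) == pytest.approx(-1.0, abs=1e-5)

    def test_total_miss_approaches_zero(self, rng):
        g = (rng.random((6, 6, 6)) > 0.5).astype(float)
        assert dice_loss(g, 1.0 - g) == pytest.approx(0.0, abs=1e-4)

    def test_gradient_matches_finite_differences(self, rng):
        g = (rng.random((4, 4, 4)) > 0.6).astype(float)
        p = rng.uniform(0.05, 0.95, (4, 4, 4))
        _, grad = dice_loss_grad(g, p)
        eps = 1e-7
        for idx in [(0, 0, 0), (1, 2, 3), (3, 3, 3)]:
            orig = p[idx]
            p[idx] = orig + eps
            fp = dice_loss(g, p)
            p[idx] = orig - eps
            fm = dice_loss(g, p)
            p[idx] = orig
            assert grad[idx] == pytest.approx((fp - fm) / (2 * eps), rel=1e-5)

    def test_input_validation(self):
        with pytest.raises(ValueError, match="shape"):
            dice_loss(np.zeros(3), np.zeros(4))
        with pytest.raises(ValueError, match="binary"):
            dice_loss(np.array([0.5]), np.array([0.5]))
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            dice_loss(np.array([1.0]), np.array([1.5]))


class TestSchedule:
    def test_lr_halves_after_ten_stagnant_epochs(self):
        # one improving epoch, then flat: the 10th stagnant epoch halves
        lrs, _ = replay_schedule([1.0] + [1.0] * 10, initial_lr=0.005)
        assert lrs[9] == 0.005  # 9 stagnant epochs: unchanged
        assert lrs[10] == 0.0025  # 10th stagnant epoch: halved

    def test_stop_after_fifty_stagnant_epochs(self):
        _, stop = replay_schedule([1.0] + [1.0] * 50, initial_lr=0.005)
        assert stop == 51  # the 50th stagnant epoch
        _, no_stop = replay_schedule([1.0] + [1.0] * 49, initial_lr=0.005)
        assert no_stop is None

    def test_improvement_resets_both_counters(self):
        seq = [1.0] + [1.0] * 9 + [0.5] + [0.5] * 10
        lrs, stop = replay_schedule(seq, initial_lr=0.004)
        assert lrs[9] == 0.004  # reset before reaching patience
        assert lrs[-1] == 0.002  # 10 stagnant epochs after the improvement
        assert stop is None

    def test_repeated_halving_on_long_plateau(self):
        lrs, _ = replay_schedule([1.0] + [1.0] * 20, initial_lr=0.008)
        assert lrs[-1] == 0.002  # two halvings at stagnant epochs 10 and 20

    def test_validation(self):
        with pytest.raises(ValueError):
            PlateauScheduler(0.005, lr_factor=1.5)
        with pytest.raises(ValueError):
            PlateauScheduler(0.005, plateau_patience=0)


class TestTrainConfig:
    def test_defaults_match_tuned_schedule(self):
        cfg = TrainConfig()
        assert (cfg.initial_lr, cfg.adam_beta1, cfg.adam_beta2, cfg.batch_size) == (
            0.005,
            0.9,
            0.999,
            1,
        )
        assert (cfg.plateau_patience, cfg.lr_factor, cfg.early_stop_patience) == (10, 0.5, 50)

    def test_rejects_other_batch_sizes(self):
        with pytest.raises(ValueError, match="batch"):
            TrainConfig(batch_size=4)


def _toy_cases(rng, n=2, grid=(16, 16, 8)):
    cases = []
    for _ in range(n):
        g = np.zeros(grid)
        g[4:9, 4:9, 2:5] = 1
        x = 0.3 + 0.4 * g + 0.02 * rng.standard_normal(grid)
        cases.append((np.clip(x, 0, 1), g))
    return cases


class TestTrainLoop:
    def test_records_curves_and_is_seed_deterministic(self, rng):
        cases = _toy_cases(rng)
        cfg = NetworkConfig(depth=3, base_channels=2, in_grid=(16, 16, 8))
        out = []
        for _ in range(2):
            model = build_model(cfg, seed=1)
            _, state = train(model, cases, cases, TrainConfig(seed=1, max_epochs=3))
            out.append(state)
        assert out[0].epochs_completed == 3
        assert len(out[0].train_loss) == len(out[0].val_loss) == len(out[0].lr) == 3
        assert out[0].train_loss == out[1].train_loss
        assert out[0].val_loss == out[1].val_loss

    def test_rejects_empty_sets(self):
        model = build_model(NetworkConfig(depth=3, base_channels=2, in_grid=(16, 16, 8)), 0)
        with pytest.raises(ValueError, match="non-empty"):
            train(model, [], [], TrainConfig())


class TestGridSearch:
    def test_printed_candidate_sets_give_60_cells(self):
        grid = GridSpec()
        assert grid.depths == (3, 4, 5, 6)
        assert grid.learning_rates == (1e-2, 5e-3, 1e-3, 5e-4, 1e-4)
        assert grid.dropout_rates == (0.3, 0.4, 0.5)
        assert grid.n_cells == 60
        assert len(list(grid.cells())) == 60

    def test_single_cell_grid_returns_that_cell(self, rng):
        cases = _toy_cases(rng)
        grid = GridSpec(depths=(3,), learning_rates=(5e-3,), dropout_rates=(0.3,))
        best, table = grid_search(
            grid,
            cases,
            cases,
            NetworkConfig(depth=3, base_channels=2, in_grid=(16, 16, 8)),
            TrainConfig(seed=0),
            max_epochs_per_cell=1,
        )
        assert (best["depth"], best["learning_rate"], best["dropout_rate"]) == (3, 5e-3, 0.3)
        assert len(table) == 1

    def test_enumeration_order_and_tie_breaking(self, rng):
        cases = _toy_cases(rng, n=1)
        grid = GridSpec(depths=(3,), learning_rates=(5e-3, 5e-3), dropout_rates=(0.3,))
        best, table = grid_search(
            grid,
            cases,
            cases,
            NetworkConfig(depth=3, base_channels=2, in_grid=(16, 16, 8)),
            TrainConfig(seed=0),
            max_epochs_per_cell=1,
        )
        # identical cells tie exactly; the first in enumeration order wins
        assert table.iloc[0]["best_val_loss"] == table.iloc[1]["best_val_loss"]
        assert best == table.iloc[0].to_dict() | {"depth": 3, "learning_rate": 5e-3, "dropout_rate": 0.3}

    def test_budget_validation(self, rng):
        with pytest.raises(ValueError, match="budget"):
            grid_search(GridSpec(), [], [], max_epochs_per_cell=0)


def test_prepare_cases_reads_manifest(small_cohort):
    from ichseg import StandardSpec

    _, manifest = small_cohort
    cases, ids = prepare_cases(manifest, "train", StandardSpec(grid=(16, 16, 8)))
    assert len(cases) == 4 and len(ids) == 4
    for x, g in cases:
        assert x.shape == (16, 16, 8) and g.shape == (16, 16, 8)
        assert 0.0 <= x.min() and x.max() <= 1.0
        assert set(np.unique(g)) <= {0.0, 1.0}
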