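import numpy as np
import pytest

from ichseg import (
    AnnotationSet,
    LabelVolume,
    RaterNoiseSpec,
    cohen_kappa,
    disagreement,
    kappa_group_test,
    majority_vote,
    overlap_metrics,
    simulate_raters,
    volume_regression,
)
from ichseg.training import dice_loss


def _mask(arr, spacing=(1.0, 1.0, 1.0)):
    return LabelVolume(labels=np.asarray(arr), spacing=spacing)


class TestOverlapMetrics:
    def test_perfect_overlap(self, rng):
        m = rng.random((5, 5, 5)) > 0.5
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0)

    def test_complement_scores_zero(self, rng):
        m = rng.random((5, 5, 5)) > 0.5
        assert overlap_metrics(~m, m) == (0.0, 0.0, 0.0)

    def test_confusion_toy_example(self):
        # TP=2, FP=1, FN=2 -> dice 4/7, precision 2/3, recall 1/2
        ref = np.array([1, 1, 1, 1, 0, 0])
        pred = np.array([1, 1, 0, 0, 1, 0])
        d, p, r = overlap_metrics(pred, ref)
        assert d == pytest.approx(4 / 7)
        assert p == pytest.approx(2 / 3)
        assert r == pytest.approx(1 / 2)

    def test_empty_conventions(self):
        empty = np.zeros((3, 3, 3), dtype=bool)
        some = np.zeros((3, 3, 3), dtype=bool)
        some[0, 0, 0] = True
        assert overlap_metrics(empty, empty) == (1.0, 1.0, 1.0)
        d, p, r = overlap_metrics(some, empty)
        assert p == 0.0
        d, p, r = overlap_metrics(empty, some)
        assert r == 0.0

    def test_foreground_dice_consistent_with_loss(self, rng):
        """On hard labels the foreground soft-Dice term equals the overlap
        Dice, so -loss averages it with the background term."""
        g = (rng.random((6, 6, 6)) > 0.6).astype(float)
        p = (rng.random((6, 6, 6)) > 0.6).astype(float)
        dice_fg, _, _ = overlap_metrics(p.astype(bool), g.astype(bool))
        dice_bg, _, _ = overlap_metrics(~p.astype(bool), ~g.astype(bool))
        assert -dice_loss(g, p) == pytest.approx((dice_fg + dice_bg) / 2, abs=1e-4)


class TestMajorityVote:
    def test_two_of_three_wins(self):
        out = majority_vote([_mask([[[1]]]), _mask([[[1]]]), _mask([[[0]]])])
        assert out.labels[0, 0, 0] == 1
        out = majority_vote([_mask([[[0]]]), _mask([[[0]]]), _mask([[[1]]])])
        assert out.labels[0, 0, 0] == 0

    def test_identical_masks_pass_through(self, rng):
        m = rng.random((4, 4, 4)) > 0.5
        out = majority_vote([_mask(m)] * 3)
        np.testing.assert_array_equal(out.labels, m.astype(np.uint8))

    def test_rejects_even_count(self):
        with pytest.raises(ValueError, match="odd"):
            majority_vote([_mask([[[1]]]), _mask([[[0]]])])

    def test_consensus_is_central(self, rng):
        """The consensus is no farther from any rater than that rater's most
        distant peer (checked on 3-rater sets)."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            masks = [r.random((6, 6, 6)) > 0.5 for _ in range(3)]
            cons = majority_vote([_mask(m) for m in masks]).labels.astype(bool)
            for i in range(3):
                d_cons = (cons ^ masks[i]).sum()
                d_far = max((masks[i] ^ masks[j]).sum() for j in range(3) if j != i)
                assert d_cons <= d_far


class TestCohenKappa:
    def test_identical_masks(self, rng):
        m = rng.random((5, 5, 5)) > 0.5
        assert cohen_kappa(m, m) == pytest.approx(1.0)

    def test_hand_computed_marginals(self):
        # a: 40 yes / 60 no; b: 50/50; agreement 70% with 30 yes-yes
        # kappa = (0.70 - 0.50) / 0.50 = 0.40
        a = np.array([1] * 40 + [0] * 60)
        b = np.concatenate([np.ones(30), np.zeros(10), np.ones(20), np.zeros(40)])
        assert float((a == b).mean()) == pytest.approx(0.70)
        assert cohen_kappa(a, b) == pytest.approx(0.40)

    def test_independent_masks_near_zero(self):
        kappas = []
        for seed in range(30):
            r = np.random.default_rng(seed)
            kappas.append(cohen_kappa(r.random(4000) > 0.5, r.random(4000) > 0.5))
        assert abs(np.mean(kappas)) < 0.02

    def test_constant_identical_masks(self):
        ones = np.ones((3, 3, 3), dtype=bool)
        assert cohen_kappa(ones, ones) == 1.0


@pytest.fixture(scope="module")
def annotations():
    # the "method" is a fourth simulated rater with the same noise level
    # as the experts, so both kappa groups come from one distribution
    rng = np.random.default_rng(0)
    sets = []
    for n in range(10):
        truth = _mask(rng.random((12, 12, 6)) > 0.8)
        ann = simulate_raters(
            truth, [RaterNoiseSpec(flip_prob=0.1, seed=100 * n + k) for k in range(4)]
        )
        masks = {k: v for k, v in ann.masks.items() if k != "E4"}
        masks["M"] = ann.masks["E4"]
        sets.append(AnnotationSet(case_id=f"c{n}", masks=masks))
    return sets


class TestKappaGroups:
    def test_group_sizes_are_r_times_n(self, annotations):
        report = kappa_group_test(annotations, ["E1", "E2", "E3"], "M")
        assert len(report.human_human) == 30  # R=3 pairs x N=10 images
        assert len(report.method_human) == 30

    def test_expert_level_method_is_indistinguishable(self, annotations):
        report = kappa_group_test(annotations, ["E1", "E2", "E3"], "M")
        assert report.mwu_p > 0.05

    def test_identical_groups_give_p_one(self):
        rng = np.random.default_rng(1)
        sets = []
        for n in range(4):
            m = _mask(rng.random((8, 8, 4)) > 0.7)
            sets.append(AnnotationSet(case_id=f"c{n}", masks={"E1": m, "E2": m, "M": m}))
        report = kappa_group_test(sets, ["E1", "E2"], "M")
        assert report.mwu_p == pytest.approx(1.0)

    def test_requires_two_cases(self):
        with pytest.raises(ValueError, match="2 cases"):
            kappa_group_test([], ["E1"], "M")


class TestDisagreement:
    def test_identical_volumes_zero(self):
        assert disagreement([10.0, 20.0], [10.0, 20.0]) == 0.0

    def test_printed_formula_single_case(self):
        # (30 - 20) / ((30 + 20)/2) = 0.4
        assert disagreement([30.0], [20.0]) == pytest.approx(0.4)

    def test_antisymmetry(self, rng):
        a = rng.uniform(5, 50, 8)
        b = rng.uniform(5, 50, 8)
        assert disagreement(a, b) == pytest.approx(-disagreement(b, a))

    def test_zero_pairs_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero total volume"):
            d = disagreement([0.0, 30.0], [0.0, 20.0])
        assert d == pytest.approx(0.4)


class TestVolumeRegression:
    def test_identity_line(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        beta, alpha, p_beta, _ = volume_regression(x, x)
        assert beta == pytest.approx(1.0)
        assert alpha == pytest.approx(0.0, abs=1e-10)
        assert p_beta < 1e-6

    def test_noiseless_affine_recovery(self):
        x = np.array([1.0, 2.0, 5.0, 7.0, 11.0])
        beta, alpha, _, _ = volume_regression(x, 2 * x + 1)
        assert beta == pytest.approx(2.0)
        assert alpha == pytest.approx(1.0)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 60, 25)
        y = 1.2 * x - 3.0 + rng.normal(0, 2.0, 25)
        beta, alpha, _, _ = volume_regression(x, y)
        xc = x - x.mean()
        beta_cf = float((xc * (y - y.mean())).sum() / (xc**2).sum())
        alpha_cf = float(y.mean() - beta_cf * x.mean())
        assert beta == pytest.approx(beta_cf, abs=1e-8)
        assert alpha == pytest.approx(alpha_cf, abs=1e-8)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="3 paired"):
            volume_regression([1.0, 2.0], [1.0, 2.0])
        with pytest.raises(ValueError, match="variance"):
            volume_regression([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])
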