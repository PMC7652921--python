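"""Accuracy and inter-rater agreement statistics.

Segmentation accuracy against the consensus reference uses the Dice
similarity coefficient, precision and recall of the foreground class.  The
reference standard itself is the voxel-wise majority vote of an odd number
of raters.

Rater reliability follows the two-group protocol: for every test image and
every pair of human raters a Cohen's kappa is computed over all voxels of
that image, giving the "human-human" group {K(Ei,Ej)_n}; kappas of the
automated method against each human give the "method-human" group
{K(M,Ei)_n}.  With R raters and N images each group holds R x N values
(R=3, N=10 in the reference protocol), and the two unpaired groups are
compared with a two-sided Mann-Whitney U test at the 0.05 level.  Volume
reliability uses the signed mean relative volume difference ("disagreement
measure") and an ordinary least-squares fit y = beta*x + alpha between the
paired per-case volumes of two raters.

Kappa is computed over all voxels of each image (no cropping); background
dominance therefore pushes kappas upward, which is inherent to the
protocol and worth remembering when reading absolute values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .phantom import AnnotationSet
from .volumes import LabelVolume

__all__ = [
    "MetricsReport",
    "AgreementReport",
    "overlap_metrics",
    "majority_vote",
    "cohen_kappa",
    "kappa_group_test",
    "disagreement",
    "volume_regression",
    "evaluate_accuracy",
]


# ----------------------------------------------------------------------------
# overlap metrics


def _confusion(pred: np.ndarray, ref: np.ndarray) -> tuple[int, int, int]:
    pred = pred.astype(bool)
    ref = ref.astype(bool)
    if pred.shape != ref.shape:
        raise ValueError(f"mask shape mismatch: {pred.shape} vs {ref.shape}")
    tp = int((pred & ref).sum())
    fp = int((pred & ~ref).sum())
    fn = int((~pred & ref).sum())
    return tp, fp, fn


def overlap_metrics(
    pred: LabelVolume | np.ndarray, ref: LabelVolume | np.ndarray
) -> tuple[float, float, float]:
    """(dice, precision, recall) of the foreground class.

    Conventions for empty masks: when a denominator is zero, the metric is
    1.0 if prediction and reference are both empty and 0.0 otherwise.
    """
    p = pred.labels if isinstance(pred, LabelVolume) else np.asarray(pred)
    r = ref.labels if isinstance(ref, LabelVolume) else np.asarray(ref)
    tp, fp, fn = _confusion(p, r)
    both_empty = (tp + fp + fn) == 0

    def _ratio(num: int, den: int) -> float:
        if den == 0:
            return 1.0 if both_empty else 0.0
        return num / den

    dice = _ratio(2 * tp, 2 * tp + fp + fn)
    precision = _ratio(tp, tp + fp)
    recall = _ratio(tp, tp + fn)
    return dice, precision, recall


def majority_vote(masks: list[LabelVolume]) -> LabelVolume:
    """Voxel-wise majority over an odd number of aligned binary masks."""
    if len(masks) % 2 == 0 or len(masks) < 3:
        raise ValueError(f"majority voting needs an odd number (>= 3) of masks, got {len(masks)}")
    shapes = {m.shape for m in masks}
    if len(shapes) > 1:
        raise ValueError(f"masks are not shape-aligned: {shapes}")
    votes = np.sum([m.labels for m in masks], axis=0)
    consensus = (votes > len(masks) / 2).astype(np.uint8)
    return LabelVolume(labels=consensus, spacing=masks[0].spacing)


# ----------------------------------------------------------------------------
# agreement


def cohen_kappa(a: LabelVolume | np.ndarray, b: LabelVolume | np.ndarray) -> float:
    """Cohen's kappa between two binary masks over all voxels of the image.

    kappa = (p_o - p_e) / (1 - p_e), with observed agreement p_o and chance
    agreement p_e from the two raters' marginal label frequencies.  When
    both raters are constant with the same label (p_e = 1), identical masks
    score 1 by convention.
    """
    x = (a.labels if isinstance(a, LabelVolume) else np.asarray(a)).astype(bool).ravel()
    y = (b.labels if isinstance(b, LabelVolume) else np.asarray(b)).astype(bool).ravel()
    if x.shape != y.shape:
        raise ValueError("masks must be shape-aligned")
    n = x.size
    po = float((x == y).sum()) / n
    pa1, pb1 = float(x.sum()) / n, float(y.sum()) / n
    pe = pa1 * pb1 + (1.0 - pa1) * (1.0 - pb1)
    if pe >= 1.0:
        if po == 1.0:
            return 1.0
        raise ValueError("degenerate marginals: chance agreement is 1 but masks differ")
    return (po - pe) / (1.0 - pe)


@dataclass
class MetricsReport:
    """Per-case and aggregate segmentation accuracy."""

    per_case: pd.DataFrame
    dice_mean: float
    dice_sd: float
    precision_mean: float
    precision_sd: float
    recall_mean: float
    recall_sd: float
    f1: float

    def summary(self) -> dict:
        return {
            "dice": [self.dice_mean, self.dice_sd],
            "precision": [self.precision_mean, self.precision_sd],
            "recall": [self.recall_mean, self.recall_sd],
            "f1": self.f1,
        }


@dataclass
class AgreementReport:
    """Kappa groups, their Mann-Whitney comparison, and per-pair volume
    agreement."""

    kappa_per_pair: pd.DataFrame  # columns: case_id, rater_i, rater_j, group, kappa
    human_human: np.ndarray
    method_human: np.ndarray
    mwu_statistic: float
    mwu_p: float
    disagreement_per_pair: pd.DataFrame | None = None
    regression_per_pair: pd.DataFrame | None = None

    @property
    def human_human_mean(self) -> float:
        return float(np.mean(self.human_human))

    @property
    def human_human_sd(self) -> float:
        return float(np.std(self.human_human, ddof=1))

    @property
    def method_human_mean(self) -> float:
        return float(np.mean(self.method_human))

    @property
    def method_human_sd(self) -> float:
        return float(np.std(self.method_human, ddof=1))


def evaluate_accuracy(predictions: dict[str, LabelVolume], references: dict[str, LabelVolume]) -> MetricsReport:
    """Dice/precision/recall per case plus mean +/- SD and aggregate F1.

    The aggregate F1 pools true/false positives and negatives over cases.
    """
    rows = []
    tp_all = fp_all = fn_all = 0
    for case_id, pred in predictions.items():
        ref = references[case_id]
        d, p, r = overlap_metrics(pred, ref)
        tp, fp, fn = _confusion(pred.labels, ref.labels)
        tp_all, fp_all, fn_all = tp_all + tp, fp_all + fp, fn_all + fn
        rows.append({"case_id": case_id, "dice": d, "precision": p, "recall": r})
    per_case = pd.DataFrame(rows)
    f1 = 2 * tp_all / (2 * tp_all + fp_all + fn_all) if (2 * tp_all + fp_all + fn_all) else 1.0
    sd = lambda s: float(s.std(ddof=1)) if len(s) > 1 else 0.0
    return MetricsReport(
        per_case=per_case,
        dice_mean=float(per_case["dice"].mean()),
        dice_sd=sd(per_case["dice"]),
        precision_mean=float(per_case["precision"].mean()),
        precision_sd=sd(per_case["precision"]),
        recall_mean=float(per_case["recall"].mean()),
        recall_sd=sd(per_case["recall"]),
        f1=float(f1),
    )


def kappa_group_test(
    annotations: list[AnnotationSet],
    human_raters: list[str],
    method: str = "M",
    with_volume_agreement: bool = True,
) -> AgreementReport:
    """Build the human-human and method-human kappa groups and compare them.

    Every AnnotationSet must contain a mask per human rater and one for the
    method.  Pairs are evaluated per image; with R human raters and N
    images each group holds R x N kappas (all unordered human pairs for
    R = 3 give exactly 3 pairs).  Groups are compared with a two-sided
    Mann-Whitney U test (normal approximation with tie correction).
    """
    if len(annotations) < 2:
        raise ValueError("kappa group comparison needs at least 2 cases")
    rows = []
    vol_rows = []
    for ann in annotations:
        for i, j in itertools.combinations(human_raters, 2):
            rows.append(
                {
                    "case_id": ann.case_id,
                    "rater_i": i,
                    "rater_j": j,
                    "group": "human-human",
                    "kappa": cohen_kappa(ann.masks[i], ann.masks[j]),
                }
            )
        for i in human_raters:
            rows.append(
                {
                    "case_id": ann.case_id,
                    "rater_i": method,
                    "rater_j": i,
                    "group": "method-human",
                    "kappa": cohen_kappa(ann.masks[method], ann.masks[i]),
                }
            )
    table = pd.DataFrame(rows)
    hh = table.loc[table["group"] == "human-human", "kappa"].to_numpy()
    mh = table.loc[table["group"] == "method-human", "kappa"].to_numpy()
    mwu = stats.mannwhitneyu(hh, mh, alternative="two-sided", method="asymptotic")

    dis_table = reg_table = None
    if with_volume_agreement:
        all_raters = list(human_raters) + [method]
        volumes = {
            r: np.array(
                [
                    ann.masks[r].labels.sum() * ann.masks[r].voxel_volume_mm3 / 1000.0
                    for ann in annotations
                ]
            )
            for r in all_raters
        }
        dis_rows, reg_rows = [], []
        for i, j in itertools.combinations(all_raters, 2):
            group = "human-human" if method not in (i, j) else "method-human"
            dis_rows.append(
                {
                    "rater_i": i,
                    "rater_j": j,
                    "group": group,
                    "disagreement": disagreement(volumes[i], volumes[j]),
                }
            )
            if len(annotations) >= 3:
                beta, alpha, p_beta, p_alpha = volume_regression(volumes[i], volumes[j])
                reg_rows.append(
                    {
                        "rater_i": i,
                        "rater_j": j,
                        "group": group,
                        "beta": beta,
                        "alpha": alpha,
                        "p_beta": p_beta,
                        "p_alpha": p_alpha,
                    }
                )
        dis_table = pd.DataFrame(dis_rows)
        reg_table = pd.DataFrame(reg_rows) if reg_rows else None

    return AgreementReport(
        kappa_per_pair=table,
        human_human=hh,
        method_human=mh,
        mwu_statistic=float(mwu.statistic),
        mwu_p=float(mwu.pvalue),
        disagreement_per_pair=dis_table,
        regression_per_pair=reg_table,
    )


def disagreement(volumes_i, volumes_j) -> float:
    """Signed mean relative volume difference between two raters.

    d(i, j) = (1/N) * sum_k (V_ik - V_jk) / ((V_ik + V_jk) / 2); cases
    where both volumes are zero are excluded (with a warning) since the
    relative difference is undefined there.  Antisymmetric in (i, j).
    """
    vi = np.asarray(volumes_i, dtype=np.float64)
    vj = np.asarray(volumes_j, dtype=np.float64)
    if vi.shape != vj.shape or vi.ndim != 1:
        raise ValueError("volume lists must be 1-D and equally long")
    keep = (vi + vj) > 0
    if not keep.all():
        warnings.warn(
            f"excluding {int((~keep).sum())} case(s) with zero total volume from the "
            "disagreement mean",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no cases with positive volume to compare")
    num = vi[keep] - vj[keep]
    den = (vi[keep] + vj[keep]) / 2.0
    return float(np.mean(num / den))


def volume_regression(x, y) -> tuple[float, float, float, float]:
    """OLS fit y = beta*x + alpha between two raters' per-case volumes.

    Returns (beta, alpha, p_beta, p_alpha) with two-sided p-values for
    beta != 0 and alpha != 0.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("regression needs >= 3 paired cases")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x: slope is unidentifiable")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    alpha, beta = res.params
    p_alpha, p_beta = res.pvalues
    return float(beta), float(alpha), float(p_beta), float(p_alpha)
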