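"""Evaluation metrics for enhancement and segmentation quality.

Image-quality side: MSE / PSNR between an image pair, noise standard
deviation (NSD) and equivalent number of looks (ENL = (mean/std)^2) over a
homogeneous region, the linear index of fuzziness and normalized fuzzy
entropy of a membership plane, and target-to-background contrast based on
either standard deviation or histogram entropy.

Segmentation side: pixel-level confusion statistics (sensitivity,
specificity, PPV, NPV, accuracy), trapezoidal ROC AUC, region-overlap
acceptance (IoU against a threshold, default k = 0.75), the asymmetric
local refinement error E(A,B,p) = |R(A,p) \\ R(B,p)| / |R(A,p)|, and
boundary agreement by minimum-cost bipartite edgel matching (precision /
recall / F-measure with a distance gate d_max).

Conventions fixed for reproducibility: population (biased) standard
deviations throughout; base-2 entropies; infinities as float('inf')
sentinels where a denominator vanishes (PSNR of identical images, ENL of a
constant region); undefined confusion statistics become NaN with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np
from scipy.optimize import linear_sum_assignment
from scipy.spatial import cKDTree
from scipy.stats import rankdata
from skimage.segmentation import find_boundaries

from .fuzzy_enhancement import FuzzyPlane
from .image_io import BinaryMask, GrayImage

__all__ = [
    "ConfusionCounts",
    "EvaluationReport",
    "mse_psnr",
    "nsd_enl",
    "index_of_fuzziness",
    "fuzzy_entropy",
    "target_background_contrast",
    "local_refinement_error",
    "mean_local_refinement_error",
    "overlap_accept",
    "iou",
    "dice",
    "boundary_pixels",
    "edgel_match_f",
    "confusion_from_masks",
    "confusion_stats",
    "roc_auc",
    "evaluate_masks",
]

_EPS = 1e-12
_CAP = 1e12  # sentinel cap when a contrast denominator is (near) zero


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class EvaluationReport:
    """All metric values for one (prediction, ground-truth) pair."""

    iou: float
    dice: float
    overlap_accepted: bool
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    boundary_precision: float
    boundary_recall: float
    f_measure: float
    refinement_error_pred_vs_truth: float
    refinement_error_truth_vs_pred: float

    def as_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# image-quality metrics


def mse_psnr(a: GrayImage, b: GrayImage) -> tuple[float, float]:
    """Mean squared error and PSNR (dB) between two same-shape images.

    PSNR = 10*log10(max_level^2 / MSE); identical images give (0, inf).
    """
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    diff = a.pixels.astype(float) - b.pixels.astype(float)
    mse = float(np.mean(diff**2))
    if mse == 0.0:
        return 0.0, float("inf")
    peak = float(max(a.max_level, b.max_level))
    return mse, float(10.0 * np.log10(peak**2 / mse))


def nsd_enl(img: GrayImage, region: BinaryMask | None = None) -> tuple[float, float]:
    """Noise standard deviation and equivalent number of looks over a region.

    With no region given, a border strip of width 5% of the smaller image
    dimension serves as the homogeneous-background proxy.  ENL = (mean/std)^2;
    a constant region gives (0, inf).
    """
    if region is None:
        h, w = img.shape
        strip = max(1, int(round(0.05 * min(h, w))))
        m = np.zeros((h, w), dtype=bool)
        m[:strip, :] = m[-strip:, :] = True
        m[:, :strip] = m[:, -strip:] = True
        region = BinaryMask(m)
    if region.shape != img.shape or not region.pixels.any():
        raise ValueError("region must be non-empty and match the image shape")
    vals = img.pixels[region.pixels].astype(float)
    std = float(vals.std())  # population std
    if std == 0.0:
        return 0.0, float("inf")
    return std, float((vals.mean() / std) ** 2)


def index_of_fuzziness(plane: FuzzyPlane) -> float:
    """Linear index of fuzziness (2/N) * sum(min(P, 1-P)); 0 crisp, 1 maximal."""
    p = np.asarray(plane.values, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("membership values must lie in [0, 1]")
    return float(2.0 * np.minimum(p, 1.0 - p).mean())


def fuzzy_entropy(plane: FuzzyPlane) -> float:
    """Normalized fuzzy entropy H = (1/(N ln 2)) * sum(S(P)), S the Shannon pair term."""
    p = np.asarray(plane.values, dtype=float)
    if p.min() < 0 or p.max() > 1:
        raise ValueError("membership values must lie in [0, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        s = -p * np.log(p) - (1.0 - p) * np.log(1.0 - p)
    s = np.nan_to_num(s, nan=0.0, posinf=0.0)  # S(0) = S(1) = 0
    return float(s.mean() / np.log(2.0))


def _hist_entropy(vals: np.ndarray, max_level: int) -> float:
    """Base-2 Shannon entropy of the normalized gray-level histogram."""
    counts = np.bincount(vals, minlength=max_level + 1).astype(float)
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log2(p)).sum())


def target_background_contrast(
    img: GrayImage, target: BinaryMask
) -> tuple[float, float]:
    """Target-to-background contrast by standard deviation and by entropy.

    tbc_std = |mu_T - mu_B| / (sigma_T + sigma_B + eps);
    tbc_entropy = |H_T - H_B| / (H_T + H_B + eps) with H the base-2 entropy
    of each side's gray-level histogram.  Values are capped at 1e12 when a
    denominator degenerates to the eps guard.
    """
    if target.shape != img.shape:
        raise ValueError("target mask must match the image shape")
    t = target.pixels
    if not t.any() or t.all():
        raise ValueError("target and background must both be non-empty")
    tv = img.pixels[t].astype(float)
    bv = img.pixels[~t].astype(float)
    tbc_std = abs(tv.mean() - bv.mean()) / (tv.std() + bv.std() + _EPS)
    h_t = _hist_entropy(img.pixels[t], img.max_level)
    h_b = _hist_entropy(img.pixels[~t], img.max_level)
    tbc_ent = abs(h_t - h_b) / (h_t + h_b + _EPS)
    return float(min(tbc_std, _CAP)), float(min(tbc_ent, _CAP))


# ---------------------------------------------------------------------------
# region-based segmentation metrics


def iou(a: BinaryMask, b: BinaryMask) -> float:
    """Intersection over union of two masks (1.0 when both are empty)."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    union = np.logical_or(a.pixels, b.pixels).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a.pixels, b.pixels).sum() / union)


def dice(a: BinaryMask, b: BinaryMask) -> float:
    """Dice coefficient 2|A∩B|/(|A|+|B|) (1.0 when both are empty)."""
    if a.shape != b.shape:
        raise ValueError("mask shapes differ")
    s = int(a.pixels.sum()) + int(b.pixels.sum())
    if s == 0:
        return 1.0
    return float(2.0 * np.logical_and(a.pixels, b.pixels).sum() / s)


def overlap_accept(machine: BinaryMask, truth: BinaryMask, k: float = 0.75) -> bool:
    """Region-overlap acceptance: IoU >= k (boundary inclusive), default k = 0.75."""
    if not machine.pixels.any() or not truth.pixels.any():
        raise ValueError("both regions must be non-empty")
    return iou(machine, truth) >= k


def local_refinement_error(
    labels_a: np.ndarray, labels_b: np.ndarray, pixel: tuple[int, int]
) -> float:
    """E(A,B,p) = |R(A,p) \\ R(B,p)| / |R(A,p)| at one pixel.

    Asymmetric: zero whenever A's region at p is contained in B's, so a
    strict refinement of B scores 0 everywhere against B.
    """
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images must share a shape")
    ra = labels_a == labels_a[pixel]
    rb = labels_b == labels_b[pixel]
    return float(np.logical_and(ra, ~rb).sum() / ra.sum())


def mean_local_refinement_error(labels_a: np.ndarray, labels_b: np.ndarray) -> float:
    """Mean of E(A,B,p) over all pixels, computed from region-pair overlap counts."""
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label images must share a shape")
    a = labels_a.ravel()
    b = labels_b.ravel()
    n = a.size
    # contingency counts n_ab; per pixel in cell (a,b): E = 1 - n_ab / n_a
    pairs = a.astype(np.int64) * (b.max() + 1) + b
    cell, n_ab = np.unique(pairs, return_counts=True)
    n_a = np.bincount(a)
    cell_a = cell // (b.max() + 1)
    per_cell = n_ab * (1.0 - n_ab / n_a[cell_a])
    return float(per_cell.sum() / n)


# ---------------------------------------------------------------------------
# boundary metrics


def boundary_pixels(mask: BinaryMask) -> np.ndarray:
    """(k, 2) array of 8-connected inner-border pixel coordinates of a mask."""
    edge = find_boundaries(mask.pixels, mode="inner", connectivity=2)
    return np.argwhere(edge)


def edgel_match_f(
    a_boundary: np.ndarray,
    b_boundary: np.ndarray,
    d_max: float = 2.0,
) -> tuple[float, float, float]:
    """Boundary agreement by min-cost bipartite edgel assignment.

    Edgels of A and B form a bipartite graph with Euclidean-distance costs,
    edges admissible only within ``d_max``.  A maximum-cardinality,
    minimum-cost assignment is solved exactly (Hungarian); precision =
    matched/|A|, recall = matched/|B|, F = 2PR/(P+R) (0 when P + R = 0).
    Empty boundaries yield zeros with a warning.
    """
    a = np.asarray(a_boundary, dtype=float).reshape(-1, 2)
    b = np.asarray(b_boundary, dtype=float).reshape(-1, 2)
    if a.size == 0 or b.size == 0:
        warnings.warn("empty boundary: precision/recall/F set to 0")
        return 0.0, 0.0, 0.0
    # restrict the assignment to edgels that have any admissible partner
    tree_b = cKDTree(b)
    pairs = tree_b.query_ball_point(a, r=d_max)
    a_idx = np.array([i for i, js in enumerate(pairs) if js], dtype=int)
    if a_idx.size == 0:
        return 0.0, 0.0, 0.0
    b_idx = np.unique(np.concatenate([pairs[i] for i in a_idx])).astype(int)
    sub_a, sub_b = a[a_idx], b[b_idx]
    cost = np.linalg.norm(sub_a[:, None, :] - sub_b[None, :, :], axis=2)
    big = d_max * (cost.shape[0] + cost.shape[1] + 1) + 1.0
    cost_gated = np.where(cost <= d_max, cost, big)
    ri, ci = linear_sum_assignment(cost_gated)
    matched = int((cost[ri, ci] <= d_max).sum())
    precision = matched / a.shape[0]
    recall = matched / b.shape[0]
    f = 0.0 if precision + recall == 0 else 2 * precision * recall / (precision + recall)
    return float(precision), float(recall), float(f)


# ---------------------------------------------------------------------------
# confusion statistics and ROC


def confusion_from_masks(pred: BinaryMask, truth: BinaryMask) -> ConfusionCounts:
    """Pixel-level confusion counts of a predicted mask against ground truth."""
    if pred.shape != truth.shape:
        raise ValueError("mask shapes differ")
    p, t = pred.pixels, truth.pixels
    return ConfusionCounts(
        tp=int(np.sum(p & t)),
        fp=int(np.sum(p & ~t)),
        tn=int(np.sum(~p & ~t)),
        fn=int(np.sum(~p & t)),
    )


def confusion_stats(c: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, PPV, NPV and accuracy; NaN where undefined."""

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return float("nan")
        return num / den

    return {
        "sensitivity": ratio(c.tp, c.tp + c.fn, "sensitivity"),
        "specificity": ratio(c.tn, c.tn + c.fp, "specificity"),
        "ppv": ratio(c.tp, c.tp + c.fp, "ppv"),
        "npv": ratio(c.tn, c.tn + c.fn, "npv"),
        "accuracy": ratio(c.tp + c.tn, c.total, "accuracy"),
    }


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Trapezoidal ROC AUC via the rank (Mann-Whitney) formula, ties counted 1/2."""
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels, dtype=bool).ravel()
    if scores.size != labels.size:
        raise ValueError("scores and labels differ in length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(scores)  # average ranks handle ties as 1/2
    r_pos = ranks[labels].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# convenience report


def evaluate_masks(
    pred: BinaryMask,
    truth: BinaryMask,
    k: float = 0.75,
    d_max: float = 2.0,
) -> EvaluationReport:
    """Full region + boundary + confusion report for one mask pair."""
    c = confusion_from_masks(pred, truth)
    stats = confusion_stats(c)
    p_prec, p_rec, f = edgel_match_f(boundary_pixels(pred), boundary_pixels(truth), d_max)
    la = pred.pixels.astype(np.int64)
    lb = truth.pixels.astype(np.int64)
    j = iou(pred, truth)
    return EvaluationReport(
        iou=j,
        dice=dice(pred, truth),
        overlap_accepted=bool(j >= k),
        sensitivity=stats["sensitivity"],
        specificity=stats["specificity"],
        ppv=stats["ppv"],
        npv=stats["npv"],
        accuracy=stats["accuracy"],
        boundary_precision=p_prec,
        boundary_recall=p_rec,
        f_measure=f,
        refinement_error_pred_vs_truth=mean_local_refinement_error(la, lb),
        refinement_error_truth_vs_pred=mean_local_refinement_error(lb, la),
    )
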