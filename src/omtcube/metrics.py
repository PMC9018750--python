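"""Ensemble voting over models/orientations and segmentation metrics."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "orientation_variants",
    "inverse_orientation",
    "ensemble_vote",
    "confusion_metrics",
    "hd95",
    "dice_ce_loss",
    "MetricsReport",
]

N_ORIENTATIONS = 5
DICE_INCLUSION_THRESHOLD = 0.8


def _check_cubic(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 3 or len(set(a.shape)) != 1:
        raise ValueError("orientation variants require a cubic tensor")
    return a


def _apply(a: np.ndarray, mu: int) -> np.ndarray:
    # R0 identity; R1 90deg counterclockwise in the axial (first two axes)
    # plane; R2 left-right mirror (first axis); R3 top-bottom mirror (second
    # axis); R4 mirror then rotation.
    if mu == 0:
        return a
    if mu == 1:
        return np.rot90(a, k=1, axes=(0, 1))
    if mu == 2:
        return a[::-1]
    if mu == 3:
        return a[:, ::-1]
    if mu == 4:
        return np.rot90(a[::-1], k=1, axes=(0, 1))
    raise ValueError("orientation index must be 0..4")


def _invert(a: np.ndarray, mu: int) -> np.ndarray:
    if mu == 0:
        return a
    if mu == 1:
        return np.rot90(a, k=-1, axes=(0, 1))
    if mu == 2:
        return a[::-1]
    if mu == 3:
        return a[:, ::-1]
    if mu == 4:
        return np.rot90(a, k=-1, axes=(0, 1))[::-1]
    raise ValueError("orientation index must be 0..4")


def orientation_variants(cube: np.ndarray) -> list[np.ndarray]:
    """The 5 test-time orientations R0..R4 of a cubic tensor."""
    cube = _check_cubic(cube)
    return [np.ascontiguousarray(_apply(cube, mu)) for mu in range(N_ORIENTATIONS)]


def inverse_orientation(cube: np.ndarray, mu: int) -> np.ndarray:
    """Map a prediction made in the R_mu frame back to the R0 frame."""
    return np.ascontiguousarray(_invert(_check_cubic(cube), mu))


def _dice_binary(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def ensemble_vote(
    prob_sets: dict | list,
    threshold: float = DICE_INCLUSION_THRESHOLD,
) -> tuple[np.ndarray, dict]:
    """Dice-gated mean of probability grids, all in the R0 frame.

    ``prob_sets`` maps (mu, nu) -> probability grid (or is a flat list; the
    first entry is then the reference).  Each grid is binarized at 1/2 and
    compared with the reference (mu, nu) = (0, 1); grids with Dice below the
    inclusion threshold are excluded, and the vote is the mean of the rest.
    The reference always passes (Dice 1), so the vote is well defined.
    """
    if isinstance(prob_sets, dict):
        keys = sorted(prob_sets.keys(), key=lambda k: (k[1], k[0]))
        ref_key = (0, 1)
        if ref_key not in prob_sets:
            raise ValueError("reference prediction (mu, nu) = (0, 1) is missing")
        grids = {k: np.asarray(prob_sets[k], dtype=float) for k in keys}
    else:
        grids = {(i, 1): np.asarray(g, dtype=float) for i, g in enumerate(prob_sets)}
        ref_key = (0, 1)
        keys = list(grids.keys())
    ref_bin = grids[ref_key] >= 0.5
    alpha = {}
    for k in keys:
        d = _dice_binary(ref_bin, grids[k] >= 0.5)
        alpha[k] = 1 if d >= threshold else 0
    n = sum(alpha.values())
    voted = sum(alpha[k] * grids[k] for k in keys) / n
    return voted, {"alpha": alpha, "N": n}


@dataclass
class MetricsReport:
    tp: int
    fp: int
    fn: int
    tn: int
    dice: float | None
    sensitivity: float | None
    specificity: float | None
    precision: float | None
    hd95: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def confusion_metrics(gt: np.ndarray, pd: np.ndarray) -> MetricsReport:
    """Dice / Sensitivity / Specificity / Precision from voxel counts.

    Dice is 1 when both sets are empty; rates with a zero denominator are
    reported as None (missing), never as 0.
    """
    gt = np.asarray(gt).astype(bool)
    pd = np.asarray(pd).astype(bool)
    if gt.shape != pd.shape:
        raise ValueError("shape mismatch between GT and PD")
    tp = int((gt & pd).sum())
    fp = int((~gt & pd).sum())
    fn = int((gt & ~pd).sum())
    tn = int((~gt & ~pd).sum())

    def rate(num, den):
        return num / den if den > 0 else None

    dice = 1.0 if (tp + fp + fn) == 0 else 2 * tp / (2 * tp + fp + fn)
    return MetricsReport(
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        dice=dice,
        sensitivity=rate(tp, tp + fn),
        specificity=rate(tn, tn + fp),
        precision=rate(tp, tp + fp),
    )


def _surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Voxels of the set with at least one 6-neighbor outside it."""
    m = np.asarray(mask).astype(bool)
    interior = np.ones_like(m)
    for axis in range(3):
        shifted = np.roll(m, 1, axis=axis)
        shifted[(slice(None),) * axis + (0,)] = False
        interior &= shifted
        shifted = np.roll(m, -1, axis=axis)
        shifted[(slice(None),) * axis + (-1,)] = False
        interior &= shifted
    return np.argwhere(m & ~interior)


def hd95(gt: np.ndarray, pd: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Symmetric 95th-percentile surface distance (max of the two directed
    95th percentiles) in physical units."""
    gt = np.asarray(gt).astype(bool)
    pd = np.asarray(pd).astype(bool)
    if not gt.any() or not pd.any():
        raise ValueError("HD95 undefined: empty segmentation")
    spacing = np.asarray(spacing, dtype=float)
    sg = _surface_voxels(gt) * spacing
    sp = _surface_voxels(pd) * spacing
    d_g = cKDTree(sp).query(sg)[0]
    d_p = cKDTree(sg).query(sp)[0]
    return float(max(np.percentile(d_g, 95), np.percentile(d_p, 95)))


def dice_ce_loss(gt_p: np.ndarray, pd_p: np.ndarray, eps: float = 1e-7) -> float:
    """Dice loss plus cross-entropy of probability tensors,
    (1 - 2 sum(GT.PD)/sum(GT+PD)) - sum(GT log PD), with PD clipped to
    [eps, 1] before the logarithm."""
    gt_p = np.asarray(gt_p, dtype=float)
    pd_p = np.asarray(pd_p, dtype=float)
    pd_c = np.clip(pd_p, eps, 1.0)
    denom = (gt_p + pd_p).sum()
    dice_loss = 1.0 - (2.0 * (gt_p * pd_p).sum() / denom if denom > 0 else 1.0)
    ce = -(gt_p * np.log(pd_c)).sum()
    return float(dice_loss + ce)
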