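"""Training objectives of the dual-branch pipeline.

The total loss is the unweighted sum of the two branch losses,

    L = L_sem + L_ins,

where the semantic branch is supervised with a soft Dice loss on the
fragment probability map,

    L_dice = 1 - 2 TP / (FP + 2 TP + FN)

with soft confusion counts (TP = sum p*g, FP = sum p*(1-g),
FN = sum (1-p)*g) and a smoothing constant added to numerator and
denominator, and the instance branch sums, over the prompted instances,

    L_ins = sum_i [ focal(p_i, g_i) + dice(p_i, g_i)
                    + (iou_pred_i - iou_i)^2 ],

with the predicted-IoU head regressed onto the actual IoU between the
*binarized* predicted mask and its ground truth.  No inter-term or
inter-branch weights are applied.  Focal loss is averaged over pixels so
that instance count, not instance area, drives the outer sum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn.tensor import Tensor, astensor

__all__ = ["LossBreakdown", "dice_loss", "focal_loss", "iou_mse_loss",
           "instance_loss", "total_loss"]

DICE_SMOOTH = 1.0
_CLAMP = 1e-6


@dataclass
class LossBreakdown:
    total: Tensor
    sem: Tensor
    ins: Tensor
    focal: float
    dice: float
    mse: float


def _check_shapes(pred, gt):
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs gt {gt.shape}")


def dice_loss(pred_prob, gt, smooth: float = DICE_SMOOTH) -> Tensor:
    """Soft Dice loss 1 - (2TP + s) / (FP + 2TP + FN + s) on probabilities."""
    pred_prob = astensor(pred_prob)
    g = np.asarray(gt, dtype=np.float32)
    _check_shapes(pred_prob, g)
    tp = (pred_prob * g).sum()
    fp = (pred_prob * (1.0 - g)).sum()
    fn = ((1.0 - pred_prob) * g).sum()
    return 1.0 - (2.0 * tp + smooth) / (fp + 2.0 * tp + fn + smooth)


def focal_loss(pred_prob, gt, alpha: float = 0.25, gamma: float = 2.0) -> Tensor:
    """Pixel-mean focal loss, -alpha_t (1-p_t)^gamma log p_t."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if gamma < 0.0:
        raise ValueError("gamma must be >= 0")
    pred_prob = astensor(pred_prob)
    g = np.asarray(gt, dtype=np.float32)
    _check_shapes(pred_prob, g)
    p = pred_prob.clamp(_CLAMP, 1.0 - _CLAMP)
    pt = p * g + (1.0 - p) * (1.0 - g)
    alpha_t = alpha * g + (1.0 - alpha) * (1.0 - g)
    loss = -1.0 * alpha_t * (1.0 - pt) ** gamma * pt.log()
    return loss.mean()


def mask_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Hard IoU of two boolean masks; 0 when the union is empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def iou_mse_loss(iou_pred, mask_pred: np.ndarray, gt: np.ndarray) -> Tensor:
    """(predicted IoU - actual IoU of the binarized mask)^2."""
    _check_shapes(np.asarray(mask_pred), np.asarray(gt))
    nu = mask_iou(mask_pred, gt)
    iou_pred = astensor(iou_pred)
    return (iou_pred - nu) ** 2.0


def _instance_terms(preds, gts, alpha: float, gamma: float
                    ) -> tuple[Tensor, Tensor, Tensor]:
    if len(preds) != len(gts):
        raise ValueError(f"{len(preds)} predictions vs {len(gts)} ground truths")
    focal_t: Tensor = Tensor(0.0)
    dice_t: Tensor = Tensor(0.0)
    mse_t: Tensor = Tensor(0.0)
    for pred, gt in zip(preds, gts):
        logits = pred.logits_t if pred.logits_t is not None else Tensor(pred.logits)
        prob = logits.sigmoid()
        iou_pred = (pred.iou_pred_t if pred.iou_pred_t is not None
                    else Tensor(pred.iou_pred))
        focal_t = focal_t + focal_loss(prob, gt, alpha=alpha, gamma=gamma)
        dice_t = dice_t + dice_loss(prob, gt)
        mse_t = mse_t + iou_mse_loss(iou_pred, pred.mask, gt)
    return focal_t, dice_t, mse_t


def instance_loss(preds, gts, alpha: float = 0.25, gamma: float = 2.0
                  ) -> Tensor:
    """Sum over instances of focal + dice + IoU-MSE.

    ``preds`` are InstancePrediction objects (or anything exposing
    ``logits_t``/``logits``, ``mask`` and ``iou_pred_t``/``iou_pred``);
    ``gts`` the aligned ground-truth boolean masks.  Training prompts
    are ground-truth boxes, so alignment is by construction.
    """
    focal_t, dice_t, mse_t = _instance_terms(preds, gts, alpha, gamma)
    return focal_t + dice_t + mse_t


def total_loss(sem_pred_prob, frag_gt, ins_preds, ins_gts,
               alpha: float = 0.25, gamma: float = 2.0) -> LossBreakdown:
    """L = L_sem + L_ins with per-term components for logging."""
    sem = dice_loss(sem_pred_prob, frag_gt)
    focal_t, dice_t, mse_t = _instance_terms(ins_preds, ins_gts, alpha, gamma)
    ins = focal_t + dice_t + mse_t
    return LossBreakdown(total=sem + ins, sem=sem, ins=ins,
                         focal=float(focal_t.data), dice=float(dice_t.data),
                         mse=float(mse_t.data))
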