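"""Fine-tuning regime for the dual-branch network.

Per step the padded image is encoded once; every ground-truth blastomere
box (optionally jittered) is encoded as a prompt and decoded into a
mask; the semantic decoder consumes the same embedding; and the summed
branch loss is optimized with AdamW under cosine decay.  The prompt
decoder is frozen by default — it only consumes box coordinates — while
the encoder and both decoders are trained.  Both branches are optimized
jointly from the first step.

The seed in TrainConfig fixes initialization, data order and box
jitter, so a training run is reproducible end to end.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .dataset_io import AnnotatedFrame, Box, pad_to_model_size
from .losses import total_loss
from .metrics import dice_coefficient, evaluate_dataset
from .network import DualBranchNet, NetworkConfig, save_checkpoint
from .nn import AdamW, cosine_lr
from .losses import mask_iou
from . import pipeline as pl

__all__ = ["TrainConfig", "train", "validate"]


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 8
    learning_rate: float = 3e-3
    optimizer: str = "adamw"
    weight_decay: float = 1e-4
    seed: int = 0
    freeze_prompt_decoder: bool = True
    box_jitter_px: float = 0.0
    target_size: int = 128
    checkpoint_dir: str | None = None
    log_path: str | None = None


def _jitter_box(box: Box, jitter: float, rng, h: int, w: int) -> Box:
    if jitter <= 0:
        return box
    d = rng.uniform(-jitter, jitter, size=4)
    return Box(min(box.x_min + d[0], box.x_max - 1.0),
               min(box.y_min + d[1], box.y_max - 1.0),
               max(box.x_max + d[2], box.x_min + 1.0),
               max(box.y_max + d[3], box.y_min + 1.0)).clip(h, w)


def train(frames: list[AnnotatedFrame], cfg: TrainConfig,
          net_cfg: NetworkConfig | None = None) -> DualBranchNet:
    """Train on annotated frames; returns the trained network.

    Checkpoints (one per epoch plus ``final.npz``) are written to
    ``cfg.checkpoint_dir`` when set; per-step loss components go to the
    JSONL training log when ``cfg.log_path`` is set.
    """
    if not frames:
        raise ValueError("empty training set")
    net_cfg = net_cfg or NetworkConfig(
        target_size=cfg.target_size, seed=cfg.seed,
        freeze_prompt_decoder=cfg.freeze_prompt_decoder)
    if net_cfg.freeze_prompt_decoder != cfg.freeze_prompt_decoder:
        net_cfg = NetworkConfig(**{**asdict(net_cfg),
                                   "freeze_prompt_decoder":
                                       cfg.freeze_prompt_decoder})
    net = DualBranchNet(net_cfg)
    opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    rng = np.random.default_rng(cfg.seed)
    padded = [pad_to_model_size(f, net_cfg.target_size) for f in frames]
    total_steps = cfg.epochs * len(frames)
    log_fh = open(cfg.log_path, "w") if cfg.log_path else None
    step = 0
    t0 = time.time()
    try:
        for epoch in range(cfg.epochs):
            order = rng.permutation(len(padded))
            epoch_losses = []
            for idx in order:
                frame, _t = padded[idx]
                h, w = frame.image.shape
                opt.lr = cosine_lr(cfg.learning_rate, step, total_steps)
                emb = net.encode_image(frame.image)
                prompts = []
                gts = []
                for mask, box, _cat in frame.instances:
                    b = _jitter_box(box, cfg.box_jitter_px, rng, h, w)
                    prompts.append(net.encode_box_prompt(b))
                    gts.append(mask)
                preds = net.decode_instance_masks(emb, prompts)
                sem_prob = net.decode_semantic(emb).sigmoid()
                breakdown = total_loss(sem_prob, frame.fragment_mask,
                                       preds, gts)
                value = float(breakdown.total.data)
                if not np.isfinite(value):
                    raise FloatingPointError(
                        f"non-finite loss at step {step}: "
                        f"sem={float(breakdown.sem.data)} "
                        f"focal={breakdown.focal} dice={breakdown.dice} "
                        f"mse={breakdown.mse}")
                opt.zero_grad()
                breakdown.total.backward()
                opt.step()
                epoch_losses.append(value)
                if log_fh:
                    log_fh.write(json.dumps({
                        "step": step, "epoch": epoch, "total": value,
                        "sem": float(breakdown.sem.data),
                        "ins": float(breakdown.ins.data),
                        "focal": breakdown.focal, "dice": breakdown.dice,
                        "mse": breakdown.mse, "lr": opt.lr,
                        "elapsed_s": round(time.time() - t0, 2)}) + "\n")
                step += 1
            if cfg.checkpoint_dir:
                ckpt_dir = Path(cfg.checkpoint_dir)
                save_checkpoint(net, ckpt_dir / f"epoch{epoch:03d}.npz")
            if log_fh:
                log_fh.write(json.dumps({
                    "epoch": epoch,
                    "mean_total": float(np.mean(epoch_losses))}) + "\n")
                log_fh.flush()
    finally:
        if log_fh:
            log_fh.close()
    if cfg.checkpoint_dir:
        save_checkpoint(net, Path(cfg.checkpoint_dir) / "final.npz")
    return net


def epoch_mean_losses(log_path: str | Path) -> list[float]:
    """Mean total loss per epoch from a JSONL training log."""
    means = []
    with open(log_path) as fh:
        for line in fh:
            rec = json.loads(line)
            if "mean_total" in rec:
                means.append(rec["mean_total"])
    return means


def _gt_condition_results(frames, net, jitter_px: float, seed: int):
    """Run the pipeline on every frame; returns (results, gt) dicts for
    evaluate_dataset plus per-frame mean instance IoU under GT prompts."""
    frames_by_id = {f.image.id: f for f in frames}
    detector = pl.make_oracle_detector(frames_by_id, jitter_px=jitter_px,
                                       seed=seed)
    results, gt = {}, {}
    per_instance_ious = []
    for frame in frames:
        seg_boxes = detector(frame.image)
        preds = pl.segment_instances(frame.image, seg_boxes, net)
        frag = pl.segment_fragments(frame.image, net)
        # detection metrics are scored on the tight boxes of the predicted
        # masks (the segmentation output), not on the prompt boxes
        # masks are ranked by detector confidence times the predicted-IoU
        # head, so the mask-quality estimate informs the PR curve
        scored = []
        for p, sb in zip(preds, seg_boxes):
            if p.mask.any():
                from .dataset_io import ScoredBox, mask_tight_box
                scored.append(ScoredBox(mask_tight_box(p.mask),
                                        sb.score * max(p.iou_pred, 1e-3),
                                        sb.category))
        results[frame.image.id] = {"boxes": scored, "fragment_mask": frag}
        gt[frame.image.id] = {
            "boxes": [(b, c) for _, b, c in frame.instances],
            "fragment_mask": frame.fragment_mask,
        }
        if jitter_px == 0.0:
            for p, (m, _b, _c) in zip(preds, frame.instances):
                per_instance_ious.append(mask_iou(p.mask, m))
    return results, gt, per_instance_ious


def validate(frames: list[AnnotatedFrame], net: DualBranchNet,
             detector_jitter_px: float = 5.0, seed: int = 0) -> dict:
    """Evaluate a checkpointed network under the ground-truth-prompt
    condition and under a jittered-detector condition.

    Returns a dict with keys ``gt_prompt`` and ``detector``, each holding
    the dataset metric report plus fragment Dice, and (for the GT
    condition) the mean per-instance mask IoU.
    """
    out = {}
    for name, jitter in (("gt_prompt", 0.0), ("detector", detector_jitter_px)):
        results, gt, ious = _gt_condition_results(frames, net, jitter, seed)
        report = evaluate_dataset(results, gt)
        entry = {
            "map": report.mean_ap,
            "blastomere_ap": report.per_class.get("blastomere", {}).get("ap", 0.0),
            "fragment_dice": report.mean_dice,
            "fragment_hausdorff": report.mean_hausdorff,
        }
        if name == "gt_prompt":
            entry["mean_instance_iou"] = float(np.mean(ious)) if ious else 0.0
        out[name] = entry
    return out


def untrained_baseline(frames: list[AnnotatedFrame],
                       net_cfg: NetworkConfig) -> dict:
    """Fragment Dice and instance IoU of a freshly initialized network."""
    net = DualBranchNet(net_cfg)
    dices, ious = [], []
    for frame in frames:
        frag = pl.segment_fragments(frame.image, net)
        dices.append(dice_coefficient(frag, frame.fragment_mask))
        boxes = [pl.ScoredBox(b, 1.0, c) for _, b, c in frame.instances]
        preds = pl.segment_instances(frame.image, boxes, net)
        for p, (m, _b, _c) in zip(preds, frame.instances):
            ious.append(mask_iou(p.mask, m))
    return {"fragment_dice": float(np.mean(dices)) if dices else 0.0,
            "mean_instance_iou": float(np.mean(ious)) if ious else 0.0}
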