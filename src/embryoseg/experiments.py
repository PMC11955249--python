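"""Desk-scale benchmark experiments used by the acceptance checks.

Everything here runs from scratch on synthetic data: generate the study
conditions, train the dual-branch network, and measure held-out
performance under the ground-truth-prompt and jittered-detector
conditions, the semantic-branch ablation, and detector-degradation
sweeps.  Problem sizes are chosen so the full battery runs in minutes on
one CPU; the methods note discusses what these desk-scale numbers do and
do not show.
"""

from __future__ import annotations

import numpy as np

from . import pipeline as pl
from .metrics import dice_coefficient, evaluate_dataset
from .network import NetworkConfig
from .synthdata import DatasetConfig, generate_frames
from .training import TrainConfig, train, untrained_baseline, validate

__all__ = ["DESK_TRAIN_FRAMES", "DESK_VAL_FRAMES", "DESK_EPOCHS",
           "desk_net_config", "desk_frames", "run_desk_experiment",
           "detector_degradation_map"]

# desk-scale study conditions: 128 px frames, embed dim 32,
# 200 training / 50 validation scenes, 20 epochs
DESK_TRAIN_FRAMES = 200
DESK_VAL_FRAMES = 50
DESK_EPOCHS = 20
DESK_LR = 2e-3


def desk_net_config(seed: int = 0) -> NetworkConfig:
    return NetworkConfig(embed_dim=32, encoder_width=8, target_size=128,
                         upblock_channels=(16, 8, 8, 4), seed=seed)


def desk_frames(seed: int = 0):
    """Generate the train/val splits for the desk-scale benchmark."""
    train_frames = generate_frames(DatasetConfig(
        n_images=DESK_TRAIN_FRAMES, image_size=128, seed=seed * 7919 + 11))
    val_frames = generate_frames(DatasetConfig(
        n_images=DESK_VAL_FRAMES, image_size=128, seed=seed * 7919 + 99))
    return train_frames, val_frames


def run_desk_experiment(seed: int = 0, epochs: int = DESK_EPOCHS,
                        log_path: str | None = None) -> dict:
    """Train the dual-branch network at desk scale and evaluate it.

    Returns a flat dict of the headline quantities: untrained baselines,
    held-out fragment Dice/Hausdorff, mean per-instance mask IoU under
    ground-truth box prompts, blastomere mAP under ground-truth-prompt
    and jittered-detector conditions, and the fragment Dice of the full
    pipeline versus its no-semantic-branch ablation.
    """
    train_frames, val_frames = desk_frames(seed)
    ncfg = desk_net_config(seed)
    base = untrained_baseline(val_frames, ncfg)
    tcfg = TrainConfig(epochs=epochs, seed=seed, learning_rate=DESK_LR,
                       target_size=128, log_path=log_path)
    net = train(train_frames, tcfg, ncfg)
    rep = validate(val_frames, net, detector_jitter_px=5.0, seed=seed)

    # ablation: fragment quality with and without the semantic branch
    frames_by_id = {f.image.id: f for f in val_frames}
    det = pl.make_oracle_detector(frames_by_id, include_fragments=True,
                                  seed=seed)
    d_full, d_nosem = [], []
    for f in val_frames:
        seg_full = pl.run_pipeline(f.image, det, net, mode="full")
        seg_nosem = pl.run_pipeline(f.image, det, net, mode="no_semantic")
        d_full.append(dice_coefficient(seg_full.fragment_mask,
                                       f.fragment_mask))
        d_nosem.append(dice_coefficient(seg_nosem.fragment_mask,
                                        f.fragment_mask))

    return {
        "net": net,
        "val_frames": val_frames,
        "untrained_fragment_dice": base["fragment_dice"],
        "untrained_instance_iou": base["mean_instance_iou"],
        "fragment_dice": rep["gt_prompt"]["fragment_dice"],
        "fragment_hausdorff": rep["gt_prompt"]["fragment_hausdorff"],
        "instance_iou_gt_prompt": rep["gt_prompt"]["mean_instance_iou"],
        "map_gt_prompt": rep["gt_prompt"]["map"],
        "map_detector": rep["detector"]["map"],
        "fragment_dice_full_mode": float(np.mean(d_full)),
        "fragment_dice_no_semantic": float(np.mean(d_nosem)),
    }


def detector_degradation_map(frames, jitters=(0.0, 2.0, 5.0, 10.0),
                             n_seeds: int = 10, seed: int = 0) -> dict:
    """Detection mAP at IoU 0.5 of the oracle detector under box jitter,
    averaged over seeds.  No network involved: this isolates how prompt
    quality degrades with localization error."""
    out = {}
    gt = {f.image.id: {"boxes": [(b, c) for _, b, c in f.instances],
                       "fragment_mask": None}
          for f in frames}
    for jit in jitters:
        maps = []
        for s in range(n_seeds):
            frames_by_id = {f.image.id: f for f in frames}
            det = pl.make_oracle_detector(frames_by_id, jitter_px=jit,
                                          seed=seed * 1013 + s)
            results = {f.image.id: {"boxes": det(f.image)} for f in frames}
            rep = evaluate_dataset(results, gt)
            maps.append(rep.per_class["blastomere"]["ap"])
        out[jit] = float(np.mean(maps))
    return out
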