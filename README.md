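# embryoseg

Dual-branch segmentation of cleavage-stage embryo micrographs.

## Who this is for

Assessing a cleavage-stage embryo (day 1–3 of in-vitro fertilization)
means counting its blastomeres, measuring their sizes, and estimating
how much of the embryo is covered by cytoplasmic fragments — work that
embryologists currently do by eye on time-lapse video. This package
implements an automated segmentation pipeline for that task, together
with everything needed to develop and evaluate it without clinical
data: a synthetic embryo-scene generator with pixel-perfect ground
truth, COCO-format I/O, training code, the full metric suite, and
time-lapse morphology reporting.

## The method

Blastomeres overlap heavily as the embryo cleaves, so they are
segmented as **instances**: a detector (or ground-truth boxes during
training) proposes one bounding box per blastomere, a frozen prompt
decoder encodes each box, and a promptable mask decoder combines the
prompt with a shared image embedding to produce one mask `M_i` and a
predicted mask-quality score ν̃_i per blastomere. Fragments matter only
in aggregate, so they are segmented **semantically**: a stack of four
upsampling blocks decodes the same image embedding into a single
fragment-coverage mask `M_f`. The two outputs are fused by pixel-wise
union,

    M_final = ∪_i M_i  ∪  M_f,

with every per-instance mask kept individually (no suppression —
overlaps are the biology, not an error). Training minimizes

    L = L_sem + L_ins,
    L_sem = 1 − 2TP / (FP + 2TP + FN)                       (soft Dice)
    L_ins = Σ_i [ Focal(Õ_i, O_i) + Dice(Õ_i, O_i) + (ν̃_i − ν_i)² ]

where `O_i`/`Õ_i` are the ground-truth and predicted masks of instance
`i` and ν_i is the IoU of the binarized prediction. Evaluation uses
detection precision/recall/F1 and mAP at box IoU ≥ 0.5, pixel Dice, and
Hausdorff distance. See `docs/methods.md` for the full model and
design-decision account.

The neural components run on a small in-repo numpy autodiff engine
(gradient-checked against finite differences), so the package trains at
desk scale on one CPU with no GPU frameworks installed.

## Worked example

Generate a synthetic dataset, train, segment and evaluate:

```bash
embryoseg generate --n-images 50 --image-size 128 --seed 0 --out data/
embryoseg train --data data/ --out run/
embryoseg segment --dir data/ --split val --checkpoint run/final.npz \
    --detector oracle --mode full --out seg/
embryoseg evaluate --pred seg/results.json \
    --gt data/annotations/val.json --images data/images --out report
```

The same flow through the library, at the benchmark's scale
(200 training / 50 validation scenes, 20 epochs, a few minutes on one
CPU):

```python
from embryoseg.experiments import run_desk_experiment
res = run_desk_experiment(seed=1)
print({k: round(v, 3) for k, v in res.items()
       if isinstance(v, float)})
```

prints

```
{'untrained_fragment_dice': 0.075, 'untrained_instance_iou': 0.041,
 'fragment_dice': 0.915, 'fragment_hausdorff': 5.008,
 'instance_iou_gt_prompt': 0.79, 'map_gt_prompt': 0.978,
 'map_detector': 0.872, 'fragment_dice_full_mode': 0.915,
 'fragment_dice_no_semantic': 0.471}
```

Reading these numbers: starting from an untrained network (fragment
Dice 0.08, instance IoU 0.04), twenty epochs of joint training recover
held-out fragment Dice 0.91 and mean per-blastomere mask IoU 0.79 under
ground-truth box prompts. Blastomere mAP with ground-truth prompts
(0.98) exceeds mAP with a jittered detector (0.87) — better detection
means better segmentation — and the semantic branch's fragment Dice
(0.91) far exceeds what detector-driven instance segmentation of
fragments achieves (0.47), which is the reason the fragment branch is
semantic. Exact values vary a little with the seed.

For time-lapse sequences, `embryoseg video-report` segments every
frame, writes a per-frame morphology timeline (blastomere count,
relative areas, fragment ratio, dominant fragment quadrant), extracts
cleavage keyframes where the smoothed blastomere count changes, and
renders overlays (red blastomere boundaries, green fragment
boundaries).

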