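"""Neural components of the dual-branch pipeline.

Four parts share one image embedding:

* **ImageEncoder** — a small convolutional backbone with total stride 16
  producing a C x (T/16) x (T/16) embedding grid of the padded T x T
  input.  An adapter slot (``NetworkConfig.checkpoint``) accepts
  externally pretrained weights with the same state-dict layout.
* **PromptDecoder** — encodes one bounding box as two corner tokens:
  random-Fourier positional encoding of the normalized corner
  coordinates plus learned corner-type embeddings.  Frozen by default:
  it only consumes box coordinates.
* **MaskDecoder** — per-prompt two-way attention between (mask token,
  IoU token, corner tokens) and the positionally-encoded image tokens,
  a small upscaling head, and a hypernetwork dot-product producing one
  mask logit map and one predicted-IoU scalar per prompt.
* **SemanticDecoder** — four stacked UpBlocks (bilinear 2x upsample +
  four 3x3 convolutions with instance norm and ReLU) taking the embedding
  grid back to full resolution, then a 1x1 projection to a single
  fragment-vs-background logit channel.

All randomness in initialization flows from ``NetworkConfig.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from . import nn
from .dataset_io import Box, Image
from .nn import functional as F
from .nn.tensor import Tensor, concat

__all__ = ["NetworkConfig", "ImageEmbedding", "InstancePrediction",
           "DualBranchNet", "save_checkpoint", "load_checkpoint"]

STRIDE = 16  # embedding stride; 4 UpBlocks of 2x recover full resolution


@dataclass(frozen=True)
class NetworkConfig:
    embed_dim: int = 32
    encoder_width: int = 8
    target_size: int = 128
    upblock_channels: tuple[int, int, int, int] = (16, 8, 8, 4)
    freeze_prompt_decoder: bool = True
    seed: int = 0
    checkpoint: str | None = None

    def __post_init__(self):
        if self.target_size % STRIDE != 0:
            raise ValueError(f"target_size must be divisible by {STRIDE}")
        if len(self.upblock_channels) != 4:
            raise ValueError("exactly 4 UpBlocks are required")

    @property
    def grid_size(self) -> int:
        return self.target_size // STRIDE


@dataclass
class ImageEmbedding:
    grid: Tensor            # (1, C, h, w)
    stride: int
    target_size: int

    @property
    def h(self) -> int:
        return self.grid.shape[2]


@dataclass
class InstancePrediction:
    logits: np.ndarray      # (H', W') at model size (or unpadded size)
    mask: np.ndarray        # boolean, thresholded at p >= 0.5
    iou_pred: float
    score: float = 1.0
    logits_t: Tensor | None = None   # kept for the training graph
    iou_pred_t: Tensor | None = None


def _fourier_features(coords: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """SAM-style random Fourier positional encoding of [0,1]^2 coords."""
    proj = (2.0 * coords - 1.0) @ matrix  # (..., C/2)
    return np.concatenate([np.sin(2 * np.pi * proj),
                           np.cos(2 * np.pi * proj)], axis=-1)


class ImageEncoder(nn.Module):
    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        w, c = cfg.encoder_width, cfg.embed_dim
        chans = [3, w, 2 * w, c, c]
        self.stages = [
            nn.Sequential(nn.Conv2d(rng, chans[i], chans[i + 1], 3, stride=2),
                          nn.InstanceNorm2d(chans[i + 1]), nn.ReLU())
            for i in range(4)
        ]
        self.neck = nn.Conv2d(rng, c, c, 3, stride=1)

    def forward(self, x: Tensor) -> Tensor:
        for stage in self.stages:
            x = stage(x)
        return self.neck(x)


class PromptDecoder(nn.Module):
    """Box -> two corner tokens.

    SAM calls this component the prompt *encoder*; this pipeline keeps
    the name PromptDecoder used throughout its own architecture, where
    it sits decoder-side next to the mask decoder."""

    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        c = cfg.embed_dim
        # fixed random projection (buffer, never trained)
        self.pe_matrix = rng.normal(0.0, 1.0, size=(2, c // 2)).astype(np.float32)
        self.corner_embed = nn.layers._trainable(
            rng.normal(0.0, 0.02, size=(2, c)))
        self.target_size = cfg.target_size

    def encode_box(self, box: Box) -> Tensor:
        if box.area <= 0:
            raise ValueError("degenerate box prompt")
        t = float(self.target_size)
        corners = np.array([[box.x_min / t, box.y_min / t],
                            [box.x_max / t, box.y_max / t]], dtype=np.float32)
        pe = _fourier_features(corners, self.pe_matrix)  # (2, C)
        return Tensor(pe) + self.corner_embed

    def dense_pe(self, h: int, w: int) -> np.ndarray:
        """Positional encoding of embedding-cell centres, (h*w, C)."""
        ys = (np.arange(h) + 0.5) / h
        xs = (np.arange(w) + 0.5) / w
        grid = np.stack(np.meshgrid(xs, ys), axis=-1).reshape(-1, 2)
        return _fourier_features(grid.astype(np.float32), self.pe_matrix)


class _TwoWayBlock(nn.Module):
    """One decoder layer of the two-way transformer: token self-attention,
    token->image cross-attention, MLP, then image->token cross-attention so
    the image features become prompt-dependent.  Single-head scaled
    dot-product throughout; positional encodings are re-added to the image
    queries/keys at every layer."""

    def __init__(self, rng, c: int):
        super().__init__()
        self.q1 = nn.Linear(rng, c, c)
        self.k1 = nn.Linear(rng, c, c)
        self.v1 = nn.Linear(rng, c, c)
        self.n1 = nn.LayerNorm(c)
        self.q2 = nn.Linear(rng, c, c)
        self.k2 = nn.Linear(rng, c, c)
        self.v2 = nn.Linear(rng, c, c)
        self.n2 = nn.LayerNorm(c)
        self.fc1 = nn.Linear(rng, c, 2 * c)
        self.fc2 = nn.Linear(rng, 2 * c, c)
        self.n3 = nn.LayerNorm(c)
        self.q3 = nn.Linear(rng, c, c)
        self.k3 = nn.Linear(rng, c, c)
        self.v3 = nn.Linear(rng, c, c)
        self.n4 = nn.LayerNorm(c)
        self.scale = 1.0 / np.sqrt(c)

    @staticmethod
    def _attend(q, k, v, scale):
        att = (q @ k.transpose(0, 2, 1)) * scale
        return att.softmax(axis=-1) @ v

    def forward(self, tokens: Tensor, img: Tensor, img_pe: Tensor
                ) -> tuple[Tensor, Tensor]:
        # tokens: (N, T, C); img: (N, L, C); img_pe: (1, L, C)
        t = self.n1(tokens + self._attend(self.q1(tokens), self.k1(tokens),
                                          self.v1(tokens), self.scale))
        kv = img + img_pe
        t = self.n2(t + self._attend(self.q2(t), self.k2(kv),
                                     self.v2(kv), self.scale))
        t = self.n3(t + self.fc2(self.fc1(t).relu()))
        img = self.n4(img + self._attend(self.q3(img + img_pe), self.k3(t),
                                         self.v3(t), self.scale))
        return t, img


class MaskDecoder(nn.Module):
    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        c = cfg.embed_dim
        self.mask_token = nn.layers._trainable(rng.normal(0, 0.02, size=(1, c)))
        self.iou_token = nn.layers._trainable(rng.normal(0, 0.02, size=(1, c)))
        self.block1 = _TwoWayBlock(rng, c)
        self.block2 = _TwoWayBlock(rng, c)
        # upscaling head: embedding grid -> mask features at 4x resolution
        self.up1 = nn.Sequential(nn.Conv2d(rng, c, c // 2, 3),
                                 nn.InstanceNorm2d(c // 2), nn.ReLU())
        self.up2 = nn.Sequential(nn.Conv2d(rng, c // 2, c // 4, 3),
                                 nn.InstanceNorm2d(c // 4), nn.ReLU())
        self.hyper = nn.Sequential(nn.Linear(rng, c, c), nn.ReLU(),
                                   nn.Linear(rng, c, c // 4))
        self.iou_head = nn.Sequential(nn.Linear(rng, c, c), nn.ReLU(),
                                      nn.Linear(rng, c, 1))

    def forward(self, emb_grid: Tensor, dense_pe: np.ndarray,
                prompts: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Returns (mask logits (N, T, T), iou predictions (N,))."""
        n = len(prompts)
        _, c, h, w = emb_grid.shape
        img_pe = Tensor(dense_pe).reshape(1, h * w, c)
        img_1 = emb_grid.reshape(c, h * w).transpose(1, 0).reshape(1, h * w, c)
        # one copy of the image tokens per prompt: image features become
        # prompt-dependent through the image->token attention
        img = concat([img_1] * n, axis=0) if n > 1 else img_1

        toks = concat([
            concat([self.mask_token, self.iou_token, p],
                   axis=0).reshape(1, -1, c)
            for p in prompts], axis=0)                      # (N, 4, C)
        toks, img = self.block1(toks, img, img_pe)
        toks, img = self.block2(toks, img, img_pe)
        mask_tok = toks[:, 0, :]                            # (N, C)
        iou_tok = toks[:, 1, :]

        grid = img.transpose(0, 2, 1).reshape(n, c, h, w)
        feats = F.upsample2x(grid)
        feats = self.up1(feats)
        feats = F.upsample2x(feats)
        feats = self.up2(feats)                             # (N, C/4, 4h, 4w)
        cq = feats.shape[1]
        flat = feats.reshape(n, cq, 16 * h * w)             # (N, C/4, L4)
        hyper = self.hyper(mask_tok).reshape(n, 1, cq)      # (N, 1, C/4)
        lowres = (hyper @ flat).reshape(n, 4 * h, 4 * w)
        iou = self.iou_head(iou_tok).reshape(n).sigmoid()
        return lowres, iou


class SemanticDecoder(nn.Module):
    """Four UpBlocks of (bilinear 2x + four 3x3 convs), then 1x1 to 1 ch."""

    def __init__(self, rng, cfg: NetworkConfig):
        super().__init__()
        chans = [cfg.embed_dim, *cfg.upblock_channels]
        blocks = []
        for i in range(4):
            convs: list[nn.Module] = []
            cin = chans[i]
            for j in range(4):
                cout = chans[i + 1]
                convs += [nn.Conv2d(rng, cin if j == 0 else cout, cout, 3),
                          nn.InstanceNorm2d(cout), nn.ReLU()]
            blocks.append(nn.Sequential(*convs))
        self.blocks = blocks
        self.head = nn.Conv2d(rng, chans[-1], 1, 1, padding=0)

    def forward(self, emb_grid: Tensor) -> Tensor:
        x = emb_grid
        for block in self.blocks:
            x = F.upsample2x(x)
            x = block(x)
        return self.head(x)  # (1, 1, T, T)


class DualBranchNet(nn.Module):
    """Shared encoder + prompt decoder + mask decoder + semantic decoder."""

    def __init__(self, cfg: NetworkConfig):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        self.encoder = ImageEncoder(rng, cfg)
        self.prompt_decoder = PromptDecoder(rng, cfg)
        self.mask_decoder = MaskDecoder(rng, cfg)
        self.semantic_decoder = SemanticDecoder(rng, cfg)
        if cfg.freeze_prompt_decoder:
            self.prompt_decoder.freeze()
        if cfg.checkpoint:
            state, _ = _read_checkpoint(cfg.checkpoint)
            self.load_state_dict(state)

    # -- public operations ----------------------------------------------
    def encode_image(self, image: Image) -> ImageEmbedding:
        h, w = image.shape
        t = self.cfg.target_size
        if (h, w) != (t, t):
            raise ValueError(
                f"image is {h}x{w} but the model expects {t}x{t}; pad it "
                "first with dataset_io.pad_to_model_size")
        px = image.pixels
        if px.ndim == 2:
            px = np.repeat(px[None, :, :], 3, axis=0)  # grayscale -> 3ch
        else:
            px = px.transpose(2, 0, 1)
        x = Tensor(px[None])
        grid = self.encoder(x)
        return ImageEmbedding(grid=grid, stride=STRIDE, target_size=t)

    def encode_box_prompt(self, box: Box) -> Tensor:
        return self.prompt_decoder.encode_box(box)

    def decode_instance_masks(self, emb: ImageEmbedding,
                              prompts: list[Tensor]
                              ) -> list[InstancePrediction]:
        if emb.target_size != self.cfg.target_size:
            raise ValueError("embedding produced under a different config")
        if not prompts:
            return []
        h = emb.grid.shape[2]
        dense_pe = self.prompt_decoder.dense_pe(h, h)
        lowres, iou = self.mask_decoder(emb.grid, dense_pe, prompts)
        # upsample the low-res (T/4) logit maps to full model resolution
        full = F.upsample2x(F.upsample2x(
            lowres.reshape(len(prompts), 1, 4 * h, 4 * h)))
        preds = []
        for i in range(len(prompts)):
            logits_t = full[i, 0, :, :]
            iou_t = iou[i].clamp(0.0, 1.0)
            logits = logits_t.data
            preds.append(InstancePrediction(
                logits=logits,
                mask=1.0 / (1.0 + np.exp(-logits)) >= 0.5,
                iou_pred=float(iou_t.data),
                logits_t=logits_t, iou_pred_t=iou_t))
        return preds

    def decode_semantic(self, emb: ImageEmbedding) -> Tensor:
        if emb.stride != STRIDE:
            raise ValueError("semantic decoder requires stride-16 embeddings")
        return self.semantic_decoder(emb.grid)[0, 0, :, :]  # (T, T)


# ---------------------------------------------------------------------------
# checkpointing: weights + config + seed in one npz

def save_checkpoint(net: DualBranchNet, path: str | Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    state = net.state_dict()
    state["__pe_matrix__"] = net.prompt_decoder.pe_matrix
    np.savez(path, __config__=json.dumps(asdict(net.cfg)), **state)


def _read_checkpoint(path: str | Path):
    with np.load(Path(path), allow_pickle=False) as data:
        cfg_dict = json.loads(str(data["__config__"]))
        state = {k: data[k] for k in data.files
                 if k not in ("__config__",)}
    cfg_dict["upblock_channels"] = tuple(cfg_dict["upblock_channels"])
    cfg_dict["checkpoint"] = None
    return state, NetworkConfig(**cfg_dict)


def load_checkpoint(path: str | Path) -> DualBranchNet:
    state, cfg = _read_checkpoint(path)
    net = DualBranchNet(cfg)
    net.prompt_decoder.pe_matrix = state.pop("__pe_matrix__")
    net.load_state_dict(state)
    if cfg.freeze_prompt_decoder:
        net.prompt_decoder.freeze()
    return net
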