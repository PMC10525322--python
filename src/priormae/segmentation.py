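"""Downstream tumor segmentation: labels, network surface, loss, metrics.

Label composition follows the BraTS convention for the nested evaluation
classes (raw codes 1 = necrotic core NCR, 2 = edema ED, 4 = enhancing tumor
ET):

    WT = NCR ∪ ED ∪ ET,   TC = NCR ∪ ET,   ET = ET,

so ET ⊆ TC ⊆ WT voxelwise.  The segmentation network reuses the pre-trained
patch tokenizer and transformer encoder, taps token features after selected
blocks plus an image-level convolutional feature z_0, and fuses them in a
lightweight convolutional decoder that emits 3-channel logits at four
resolutions (full, 1/2, 1/4, 1/8 per axis).  Deep supervision weights the
per-stage (binary cross-entropy + soft Dice) losses by 1, 1/2, 1/4, 1/8.

Evaluation metrics are the Dice similarity coefficient and the 95th
percentile of the symmetric surface distance (HD95), with surfaces taken as
mask voxels that have a background face-neighbor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import nn, model
from .nn import Tensor

__all__ = [
    "BRATS_CODES",
    "SegLabelVolume",
    "compose_brats_channels",
    "SegConfig",
    "SegmentationNetwork",
    "deep_supervision_loss",
    "DEEP_SUPERVISION_WEIGHTS",
    "dice_score",
    "dice_loss",
    "hd95",
    "finetune",
]

BRATS_CODES = {"background": 0, "ncr": 1, "ed": 2, "et": 4}
DEEP_SUPERVISION_WEIGHTS = (1.0, 0.5, 0.25, 0.125)
N_STAGES = 4


@dataclass(frozen=True)
class SegLabelVolume:
    """Raw integer label volume plus the composed nested binary channels."""

    raw: np.ndarray
    wt: np.ndarray
    tc: np.ndarray
    et: np.ndarray

    @property
    def channels(self) -> np.ndarray:
        """(3, D, H, W) binary array in (WT, TC, ET) order."""
        return np.stack([self.wt, self.tc, self.et]).astype(np.float64)


def compose_brats_channels(raw: np.ndarray,
                           codes: dict[str, int] = BRATS_CODES) -> SegLabelVolume:
    """Compose the nested WT/TC/ET channels from raw subregion codes."""
    raw = np.asarray(raw)
    valid = set(codes.values())
    present = set(np.unique(raw).tolist())
    unknown = sorted(present - valid)
    if unknown:
        raise ValueError(f"unknown label codes {unknown}; expected {sorted(valid)}")
    ncr = raw == codes["ncr"]
    ed = raw == codes["ed"]
    et = raw == codes["et"]
    return SegLabelVolume(raw=raw, wt=(ncr | ed | et), tc=(ncr | et), et=et)


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SegConfig:
    """Segmentation-head configuration around a (pre-trained) encoder."""

    model: model.EmbeddingConfig = field(
        default_factory=lambda: model.EmbeddingConfig(in_channels=4))
    input_size: int = 128
    tap_layers: tuple[int, ...] = (2, 4, 6, 8, 12)
    decoder_channels: int = 16
    n_classes: int = 3

    def __post_init__(self):
        bad = [t for t in self.tap_layers if t > self.model.encoder_layers or t < 1]
        if bad:
            raise ValueError(
                f"tap layers {bad} beyond encoder depth "
                f"{self.model.encoder_layers}"
            )
        if self.model.patch_size not in (2, 4, 8):
            raise ValueError("decoder supports patch sizes 2, 4, 8")
        if self.input_size % self.model.patch_size:
            raise ValueError("patch size must divide input size")
        if self.input_size % 8 or self.input_size < 16:
            raise ValueError(
                "input size must be a multiple of 8 and at least 16 for the "
                "four-stage decoder"
            )

    @classmethod
    def tiny(cls, **overrides) -> "SegConfig":
        base = dict(model=model.EmbeddingConfig.tiny(in_channels=4),
                    input_size=16, tap_layers=(1, 2), decoder_channels=8)
        base.update(overrides)
        return cls(**base)


class _ResBlock(nn.Module):
    """Two k=3 convolutions with a (projected) residual connection."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = nn.Conv3d(in_ch, out_ch, 3, rng, padding=1)
        self.conv2 = nn.Conv3d(out_ch, out_ch, 3, rng, padding=1)
        self.skip = nn.Conv3d(in_ch, out_ch, 1, rng) if in_ch != out_ch else None

    def forward(self, x: Tensor) -> Tensor:
        h = self.conv2(self.conv1(x).leaky_relu(0.1))
        s = x if self.skip is None else self.skip(x)
        return (h + s).leaky_relu(0.1)


class _UpBlock(nn.Module):
    """Transposed-convolution upsampler followed by two residual convs."""

    def __init__(self, in_ch: int, skip_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.up = nn.ConvTranspose3d(in_ch, out_ch, rng)
        self.res1 = _ResBlock(out_ch + skip_ch, out_ch, rng)
        self.res2 = _ResBlock(out_ch, out_ch, rng)

    def forward(self, x: Tensor, skip: Tensor | None) -> Tensor:
        x = self.up(x)
        if skip is not None:
            x = nn.concatenate([x, skip], axis=1)
        return self.res2(self.res1(x))


class SegmentationNetwork(nn.Module):
    """Encoder (tokenizer + transformer) with a convolutional fusion decoder.

    Token features from the tapped transformer blocks are projected to the
    decoder width and fused at the patch-grid resolution; an image-level
    feature z_0 supplies full-resolution detail.  The decoder walks the
    resolution ladder input/8 -> input and emits class logits at each of the
    four deep-supervision stages (finest first).
    """

    def __init__(self, config: SegConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        cfg = config.model
        c = config.decoder_channels
        self.grid_dims = (config.input_size // cfg.patch_size,) * 3
        n_pos = int(np.prod(self.grid_dims))
        self.embed = model.PatchEmbedding(cfg, n_pos, rng)
        self.encoder = model.Encoder(cfg, rng)
        # z_0: image-level feature at full resolution, plus its down pyramid
        self.stem = nn.Conv3d(cfg.in_channels, c, 3, rng, padding=1)
        self.z_down2 = nn.Conv3d(c, c, 3, rng, stride=2, padding=1)
        self.z_down4 = nn.Conv3d(c, c, 3, rng, stride=2, padding=1)
        self.tap_proj = [nn.Linear(cfg.feature_dim, c, rng)
                         for _ in config.tap_layers]
        self.fuse = _ResBlock(c * len(config.tap_layers), c, rng)
        # stride-2 convs taking the fused grid feature down to input/8
        n_pre = int(np.log2(8 // cfg.patch_size))
        self.pre_downs = [nn.Conv3d(c, c, 3, rng, stride=2, padding=1)
                          for _ in range(n_pre)]
        # upsampling ladder input/8 -> input/4 -> input/2 -> input
        self.up4 = _UpBlock(c, c, c, rng)
        self.up2 = _UpBlock(c, c, c, rng)
        self.up1 = _UpBlock(c, c, c, rng)
        self.heads = [nn.Conv3d(c, config.n_classes, 1, rng) for _ in range(4)]

    def _tokens_to_grid(self, tokens: Tensor, proj: nn.Linear) -> Tensor:
        gx, gy, gz = self.grid_dims
        t = proj(tokens)  # (n, c)
        return t.reshape(gx, gy, gz, t.shape[-1]).transpose(3, 0, 1, 2) \
                .reshape(1, t.shape[-1], gx, gy, gz)

    def forward(self, volume) -> list[Tensor]:
        """volume: (C, L, L, L) -> logits at [full, 1/2, 1/4, 1/8] resolution."""
        vol = nn.as_tensor(volume)
        cfg = self.config.model
        L = self.config.input_size
        if vol.shape != (cfg.in_channels, L, L, L):
            raise ValueError(
                f"expected volume of shape {(cfg.in_channels, L, L, L)}, "
                f"got {vol.shape}"
            )
        # tokenize every patch (no masking downstream)
        s = cfg.patch_size
        gx, gy, gz = self.grid_dims
        n = gx * gy * gz
        patches = vol.reshape(cfg.in_channels, gx, s, gy, s, gz, s) \
                     .transpose(1, 3, 5, 0, 2, 4, 6).reshape(n, cfg.patch_voxels)
        tokens = self.embed(patches, np.arange(n))
        _, taps = self.encoder(tokens, return_taps=self.config.tap_layers)
        grids = [self._tokens_to_grid(taps[l], proj)
                 for l, proj in zip(self.config.tap_layers, self.tap_proj)]
        fg = self.fuse(nn.concatenate(grids, axis=1))  # (1,c,...) at L/s

        z0 = self.stem(vol.reshape((1,) + vol.shape)).leaky_relu(0.1)
        z_pyr = {1: z0}
        z_pyr[2] = self.z_down2(z0).leaky_relu(0.1)
        z_pyr[4] = self.z_down4(z_pyr[2]).leaky_relu(0.1)

        x = fg
        for conv in self.pre_downs:
            x = conv(x).leaky_relu(0.1)
        feats = {8: x}  # coarsest stage at input/8
        for f_to, up in ((4, self.up4), (2, self.up2), (1, self.up1)):
            skip = fg if f_to == s else z_pyr[f_to]
            x = up(x, skip)
            feats[f_to] = x
        return [self.heads[i](feats[f])[0]
                for i, f in enumerate((1, 2, 4, 8))]


# ---------------------------------------------------------------------------
# Losses and metrics
# ---------------------------------------------------------------------------

def _bce_with_logits(logits: Tensor, targets: Tensor) -> Tensor:
    """Numerically stable mean binary cross-entropy on logits."""
    # log(1+exp(x)) = relu(x) + log(1+exp(-|x|))
    x = logits
    softplus = x.relu() + ((-1.0 * x.abs()).exp() + 1.0).log()
    return (softplus - x * targets).mean()


def dice_loss(probs: Tensor, targets: Tensor, eps: float = 1e-6) -> Tensor:
    """Soft Dice loss 1 - 2|PG|/(|P|+|G|), averaged over channels."""
    axes = tuple(range(1, len(probs.shape)))
    inter = (probs * targets).sum(axis=axes)
    denom = probs.sum(axis=axes) + targets.sum(axis=axes)
    dice = (2.0 * inter + eps) / (denom + eps)
    return 1.0 - dice.mean()


def _resize_nearest(gt: np.ndarray, factor: int) -> np.ndarray:
    """Nearest-neighbor downsampling of a (C,D,H,W) binary array by 2^k."""
    return gt[:, ::factor, ::factor, ::factor]


def deep_supervision_loss(predictions, ground_truth,
                          weights=DEEP_SUPERVISION_WEIGHTS) -> Tensor:
    """Σ_i 1/2^(i-1) · (BCE(S_i, Ŝ_i) + Dice(S_i, Ŝ_i)) over 4 stages.

    ``predictions``: logits per stage, finest first, shapes halving per axis;
    ``ground_truth``: full-resolution (C,D,H,W) binary array, resized by
    nearest-neighbor to each stage.
    """
    if len(predictions) != N_STAGES:
        raise ValueError(f"expected {N_STAGES} stages, got {len(predictions)}")
    gt_full = np.asarray(ground_truth, dtype=np.float64)
    total = None
    for i, (pred, w) in enumerate(zip(predictions, weights)):
        pred = nn.as_tensor(pred)
        gt = Tensor(_resize_nearest(gt_full, 2**i))
        if pred.shape != gt.shape:
            raise ValueError(
                f"stage {i + 1}: prediction shape {pred.shape} != "
                f"resized ground truth {gt.shape}"
            )
        stage = _bce_with_logits(pred, gt) + dice_loss(pred.sigmoid(), gt)
        term = w * stage
        total = term if total is None else total + term
    return total


def dice_score(pred_binary: np.ndarray, gt_binary: np.ndarray) -> float:
    """DSC = 2|A∩B| / (|A|+|B|); both-empty pairs score 1 by convention."""
    a = np.asarray(pred_binary).astype(bool)
    b = np.asarray(gt_binary).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def _surface(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with a background face-neighbor (array border counts)."""
    struct = ndimage.generate_binary_structure(mask.ndim, 1)
    eroded = ndimage.binary_erosion(mask, structure=struct, border_value=0)
    return mask & ~eroded


def hd95(pred: np.ndarray, gt: np.ndarray,
         spacing=(1.0, 1.0, 1.0), empty_value: float = float("nan")) -> float:
    """95th percentile of the symmetric surface-to-surface distances.

    Distances from every predicted-surface voxel to the nearest ground-truth
    surface voxel and vice versa are pooled; the 95th percentile of the pool
    is returned (physical units via ``spacing``).  If either mask is empty
    the percentile is undefined and ``empty_value`` is returned.
    """
    a = np.asarray(pred).astype(bool)
    b = np.asarray(gt).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        return empty_value
    sa, sb = _surface(a), _surface(b)
    # distance transforms of the complement of each surface
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    d_ab = dt_b[sa]
    d_ba = dt_a[sb]
    return float(np.percentile(np.hstack([d_ab, d_ba]), 95))


def hausdorff(pred: np.ndarray, gt: np.ndarray, spacing=(1.0, 1.0, 1.0)) -> float:
    """Exact (maximum) symmetric surface distance; shares hd95's conventions."""
    a = np.asarray(pred).astype(bool)
    b = np.asarray(gt).astype(bool)
    sa, sb = _surface(a), _surface(b)
    dt_b = ndimage.distance_transform_edt(~sb, sampling=spacing)
    dt_a = ndimage.distance_transform_edt(~sa, sampling=spacing)
    return float(max(dt_b[sa].max(), dt_a[sb].max()))


# ---------------------------------------------------------------------------
# Fine-tuning
# ---------------------------------------------------------------------------

def finetune(
    config: SegConfig,
    volumes,
    label_channels,
    n_steps: int = 100,
    learning_rate: float = 1e-3,
    weight_decay: float = 5e-2,
    seed: int = 0,
    encoder_extract: dict | None = None,
    log=None,
):
    """Supervised fine-tuning of the segmentation network.

    ``volumes``: (C, L, L, L) arrays; ``label_channels``: matching
    (n_classes, L, L, L) binary arrays.  Optionally warm-starts from an
    encoder extract (see :mod:`priormae.pretrain`).  Returns the trained
    network and the per-step loss history.
    """
    from .nn import AdamW
    from .pretrain import load_encoder_into

    if len(volumes) != len(label_channels) or not volumes:
        raise ValueError("need matching, nonempty volumes and labels")
    rng = np.random.default_rng([seed, 20])
    net = SegmentationNetwork(config, rng)
    if encoder_extract is not None:
        load_encoder_into(encoder_extract, net.embed, net.encoder)
    opt = AdamW(net.parameters(), lr=learning_rate, weight_decay=weight_decay)
    order = np.random.default_rng([seed, 21])
    history = []
    for step in range(n_steps):
        i = int(order.integers(0, len(volumes)))
        preds = net(volumes[i])
        loss = deep_supervision_loss(preds, label_channels[i])
        opt.zero_grad()
        loss.backward()
        opt.step()
        history.append(float(loss))
        if log is not None:
            log({"step": step, "l_seg": float(loss)})
    return net, history
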