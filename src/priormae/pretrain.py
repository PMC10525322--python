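"""Self-supervised pre-training with anatomical prior-informed masking.

Each step center-crops an intensity volume and the sampling weight map,
patchifies both, forms the patch probability vector, draws a fresh visible
set (prior-informed or uniform), encodes the visible tokens, decodes all
positions, and optimizes the reconstruction + adversarial objective with
strictly alternating discriminator / autoencoder AdamW updates.

Checkpoints are written as a single ``.npz`` archive holding every named
parameter tensor plus a JSON configuration block, sufficient for exact
reload; :func:`extract_encoder` keeps only the tokenizer and encoder blocks
for downstream transfer.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from . import masking, model
from .nn import AdamW
from .occurrence import SamplingWeightMap

__all__ = [
    "PretrainConfig",
    "pretrain",
    "save_checkpoint",
    "load_checkpoint",
    "extract_encoder",
    "load_encoder_into",
]


@dataclass(frozen=True)
class PretrainConfig:
    """Pre-training hyperparameters (defaults: the full-scale recipe)."""

    masking_ratio: float = 0.75
    batch_size: int = 12
    epochs: int = 300
    learning_rate: float = 1e-3
    weight_decay: float = 5e-2
    adv_weight: float = 1.0
    seed: int = 0
    strategy: str = "prior"          # {prior, random}
    crop_size: int = 128
    steps_per_epoch: int | None = None  # None: one pass over the images
    tiny: bool = False
    model: model.EmbeddingConfig = field(default_factory=model.EmbeddingConfig)

    def __post_init__(self):
        if not 0.0 < self.masking_ratio < 1.0:
            raise ValueError("masking_ratio must be in (0,1)")
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.strategy not in ("prior", "random"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.tiny:
            object.__setattr__(self, "crop_size", min(self.crop_size, 16))
            object.__setattr__(self, "model", model.EmbeddingConfig.tiny())

    @property
    def grid(self) -> masking.PatchGrid:
        return masking.PatchGrid(
            input_shape=(self.crop_size,) * 3,
            patch_size=self.model.patch_size,
        )


def _prepare(volume: np.ndarray, crop: int) -> np.ndarray:
    return masking.center_crop(np.asarray(volume, dtype=np.float64),
                               (crop,) * 3)


def pretrain(
    config: PretrainConfig,
    images: Sequence[np.ndarray],
    weight_map: SamplingWeightMap | np.ndarray | None,
    log: Callable[[dict], None] | None = None,
) -> dict:
    """Run the pre-training loop; returns a checkpoint dictionary.

    ``images`` are raw 3D intensity volumes (center-cropped here).  A weight
    map is required for the ``prior`` strategy and ignored by ``random``.
    The checkpoint holds ``state`` (name → array), ``config``, and the
    per-epoch loss ``history``.
    """
    if not images:
        raise ValueError("no images given")
    grid = config.grid
    crop = config.crop_size
    vols = [_prepare(im, crop) for im in images]
    patches_per_image = [masking.patchify(v, grid.patch_size) for v in vols]

    if config.strategy == "prior":
        if weight_map is None:
            raise ValueError("prior strategy requires a sampling weight map")
        w = weight_map.weights if isinstance(weight_map, SamplingWeightMap) \
            else np.asarray(weight_map, dtype=np.float64)
        w = _prepare(w, crop)
        pvec = masking.patch_probabilities(w, grid)
    else:
        pvec = masking.PatchProbabilityVector(p=np.full(grid.n, 1.0 / grid.n))

    rng = np.random.default_rng(config.seed)
    mae = model.MaskedAutoencoder(config.model, grid.n,
                                  np.random.default_rng([config.seed, 10]))
    disc = model.PatchDiscriminator(config.model,
                                    np.random.default_rng([config.seed, 11]))
    opt_ae = AdamW(mae.parameters(), lr=config.learning_rate,
                   weight_decay=config.weight_decay)
    opt_d = AdamW(disc.parameters(), lr=config.learning_rate,
                  weight_decay=config.weight_decay)

    n_img = len(vols)
    steps = config.steps_per_epoch or max(1, n_img // config.batch_size)
    history = []
    for epoch in range(config.epochs):
        ep = {"epoch": epoch, "l_rec": 0.0, "l_adv_d": 0.0, "l_adv_g": 0.0}
        for _ in range(steps):
            batch_idx = rng.integers(0, n_img, size=min(config.batch_size, n_img))
            b_rec = b_d = b_g = 0.0
            # --- discriminator step (reconstructions detached) ---------
            d_losses = []
            samples = []
            for bi in batch_idx:
                sel_seed = int(rng.integers(0, 2**31 - 1))
                sel = masking.sample_visible(pvec, config.masking_ratio, sel_seed)
                patches = patches_per_image[bi]
                pred = mae(patches, sel.visible, sel.masked)
                samples.append((patches, sel, pred))
                l_d, _ = model.adversarial_losses(patches, pred, disc)
                d_losses.append(l_d)
            loss_d = sum(d_losses[1:], d_losses[0]) * (1.0 / len(d_losses))
            opt_d.zero_grad()
            loss_d.backward()
            opt_d.step()
            b_d = float(loss_d)
            # --- autoencoder step -------------------------------------
            ae_losses, rec_vals, g_vals = [], [], []
            for patches, sel, pred in samples:
                l_rec = model.reconstruction_loss(pred, patches, sel.masked)
                _, l_g = model.adversarial_losses(patches, pred, disc)
                ae_losses.append(model.total_loss(l_rec, l_g, config.adv_weight))
                rec_vals.append(float(l_rec))
                g_vals.append(float(l_g))
            loss_ae = sum(ae_losses[1:], ae_losses[0]) * (1.0 / len(ae_losses))
            opt_ae.zero_grad()
            loss_ae.backward()
            opt_ae.step()
            b_rec = float(np.mean(rec_vals))
            b_g = float(np.mean(g_vals))
            ep["l_rec"] += b_rec / steps
            ep["l_adv_d"] += b_d / steps
            ep["l_adv_g"] += b_g / steps
        history.append(ep)
        if log is not None:
            log(ep)

    state = {f"mae.{k}": v for k, v in mae.state_dict().items()}
    state.update({f"disc.{k}": v for k, v in disc.state_dict().items()})
    return {
        "state": state,
        "config": {"pretrain": _config_dict(config), "n_positions": grid.n},
        "history": history,
    }


def _config_dict(config: PretrainConfig) -> dict:
    d = asdict(config)
    d["model"] = config.model.to_dict()
    return d


def save_checkpoint(checkpoint: dict, path) -> None:
    """Single-archive checkpoint: parameter arrays + a JSON config block."""
    path = Path(path)
    meta = json.dumps({"config": checkpoint["config"],
                       "history": checkpoint.get("history", [])})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **checkpoint["state"])


def load_checkpoint(path) -> dict:
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as archive:
        meta = json.loads(archive["__meta__"].tobytes().decode())
        state = {k: archive[k] for k in archive.files if k != "__meta__"}
    return {"state": state, "config": meta["config"],
            "history": meta.get("history", [])}


_ENCODER_PREFIXES = ("mae.embed.", "mae.encoder.")


def extract_encoder(checkpoint: dict) -> dict:
    """Keep only tokenizer + encoder tensors (decoder/discriminator dropped)."""
    state = {k: np.asarray(v).copy() for k, v in checkpoint["state"].items()
             if k.startswith(_ENCODER_PREFIXES)}
    if not state:
        raise ValueError("checkpoint contains no encoder tensors")
    return {"state": state, "config": checkpoint["config"]}


def load_encoder_into(encoder_extract: dict, embed: model.PatchEmbedding,
                      encoder: model.Encoder) -> list[str]:
    """Load transferred weights; returns the names that were skipped.

    If the target tokenizer's input channel count differs from the
    pre-trained one (1-channel pre-training vs multi-channel fine-tuning),
    the tokenizer keeps its fresh initialization and only the transformer
    blocks (and their norms) are transferred.
    """
    state = encoder_extract["state"]
    skipped: list[str] = []
    emb_state = {k[len("mae.embed."):]: v for k, v in state.items()
                 if k.startswith("mae.embed.")}
    own = dict(embed.named_parameters())
    compatible = all(
        k in own and own[k].data.shape == np.asarray(v).shape
        for k, v in emb_state.items()
    )
    if compatible:
        embed.load_state_dict(emb_state)
    else:
        skipped.extend("mae.embed." + k for k in emb_state)
    enc_state = {k[len("mae.encoder."):]: v for k, v in state.items()
                 if k.startswith("mae.encoder.")}
    encoder.load_state_dict(enc_state)
    return skipped
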