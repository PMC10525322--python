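"""Masked-autoencoder model components and losses.

Patch embedding maps each flattened patch through a learnable linear
tokenizer and adds a sinusoidal positional encoding at the patch's original
grid position:

    x_enc = g(x_i) + PE,   PE(pos, 2i) = sin(pos / 10000^(2i/D)),
                           PE(pos, 2i+1) = cos(pos / 10000^(2i/D)).

The encoder is a stack of pre-norm transformer blocks over the visible
tokens (optionally with windowed attention).  The decoder inserts one shared
learnable mask token at every masked position, adds positional encodings,
runs a shallow transformer, and predicts raw voxel intensities for all n
patches.  Losses:

    L_Rec = 1/2 sum_{masked i} ||y_hat_i - x_i||^2          (masked only)
    L_Adv(D) = 1/2 sum_i (||D(x_i) - 1||^2 + ||D(y_hat_i)||^2)
    L_Adv(G) = 1/2 sum_i ||D(y_hat_i) - 1||^2
    L_total = L_Rec + adv_weight * L_Adv(G)

The least-squares discriminator scores individual patches with five
convolutional layers (four k=3 blocks, one k=1 head, spatial average).
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "EmbeddingConfig",
    "positional_encoding",
    "PatchEmbedding",
    "Encoder",
    "Decoder",
    "PatchDiscriminator",
    "MaskedAutoencoder",
    "reconstruction_loss",
    "adversarial_losses",
    "total_loss",
]


@dataclass(frozen=True)
class EmbeddingConfig:
    """Architecture hyperparameters (defaults: the full-scale configuration)."""

    patch_size: int = 8
    feature_dim: int = 384
    decoder_dim: int = 384
    encoder_layers: int = 12
    decoder_layers: int = 8
    n_heads: int = 6
    in_channels: int = 1
    mlp_ratio: float = 4.0
    window_size: int | None = None  # None = full attention over tokens
    pe_one_origin: bool = False     # position index origin (0 default)
    disc_channels: int = 16

    def __post_init__(self):
        if self.feature_dim % self.n_heads:
            raise ValueError(
                f"feature_dim {self.feature_dim} not divisible by "
                f"n_heads {self.n_heads}"
            )
        for name in ("patch_size", "feature_dim", "decoder_dim",
                     "encoder_layers", "decoder_layers", "n_heads",
                     "in_channels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")

    @property
    def patch_voxels(self) -> int:
        return self.patch_size**3 * self.in_channels

    @property
    def out_voxels(self) -> int:
        return self.patch_size**3 * self.in_channels

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def tiny(cls, **overrides) -> "EmbeddingConfig":
        """Desk-scale configuration for tests and smoke runs."""
        base = dict(patch_size=4, feature_dim=32, decoder_dim=32,
                    encoder_layers=2, decoder_layers=2, n_heads=4,
                    in_channels=1, mlp_ratio=2.0, disc_channels=4)
        base.update(overrides)
        return cls(**base)


def positional_encoding(T: int, D: int, one_origin: bool = False) -> np.ndarray:
    """Sinusoidal positional encoding table of shape (T, D).

    Even dimensions carry sin(pos / 10000^(2i/D)), odd dimensions the
    matching cos.  Positions index tokens 0..T-1 by default; ``one_origin``
    shifts to 1..T.
    """
    if T < 1 or D < 1:
        raise ValueError("T and D must be >= 1")
    if D % 2:
        raise ValueError(f"feature dimension must be even, got {D}")
    pos = np.arange(T, dtype=np.float64) + (1.0 if one_origin else 0.0)
    i = np.arange(D // 2, dtype=np.float64)
    angles = pos[:, None] / (10000.0 ** (2.0 * i / D))[None, :]
    pe = np.empty((T, D), dtype=np.float64)
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles)
    return pe


class PatchEmbedding(nn.Module):
    """Learnable linear tokenizer g(.) plus positional encoding."""

    def __init__(self, config: EmbeddingConfig, n_positions: int,
                 rng: np.random.Generator, zero_init: bool = False):
        super().__init__()
        self.config = config
        self.n_positions = n_positions
        self.tokenizer = nn.Linear(config.patch_voxels, config.feature_dim, rng,
                                   zero_init=zero_init)
        self.pe = positional_encoding(n_positions, config.feature_dim,
                                      config.pe_one_origin)

    def forward(self, patches, positions) -> Tensor:
        """patches: (k, patch_voxels); positions: (k,) original grid indices."""
        x = nn.as_tensor(patches)
        if x.shape[-1] != self.config.patch_voxels:
            raise ValueError(
                f"patch vector length {x.shape[-1]} != "
                f"{self.config.patch_voxels} (patch_size^3 * in_channels)"
            )
        positions = np.asarray(positions, dtype=np.int64)
        if positions.min() < 0 or positions.max() >= self.n_positions:
            raise ValueError("positions outside the patch grid")
        return self.tokenizer(x) + Tensor(self.pe[positions])


class Encoder(nn.Module):
    """Stack of pre-norm transformer blocks with a final layer norm."""

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator):
        super().__init__()
        self.blocks = [
            nn.TransformerBlock(config.feature_dim, config.n_heads, rng,
                                config.mlp_ratio, config.window_size)
            for _ in range(config.encoder_layers)
        ]
        self.norm = nn.LayerNorm(config.feature_dim)

    def forward(self, tokens: Tensor, return_taps: tuple[int, ...] = ()) -> Tensor:
        """``return_taps`` requests the (1-based) block outputs z_l as well."""
        taps = {}
        x = tokens
        for l, block in enumerate(self.blocks, start=1):
            x = block(x)
            if l in return_taps:
                taps[l] = x
        out = self.norm(x)
        if return_taps:
            bad = sorted(set(return_taps) - set(taps))
            if bad:
                raise ValueError(
                    f"tap layers {bad} beyond encoder depth {len(self.blocks)}"
                )
            return out, taps
        return out


class Decoder(nn.Module):
    """Shallow transformer decoder reconstructing all n patches."""

    def __init__(self, config: EmbeddingConfig, n_positions: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.n_positions = n_positions
        # explicit projection encoder dim -> decoder dim (identity-shaped
        # when the dims agree, but always present)
        self.proj = nn.Linear(config.feature_dim, config.decoder_dim, rng)
        self.mask_token = Tensor(
            rng.normal(0.0, 0.02, size=config.decoder_dim), requires_grad=True
        )
        self.pe = positional_encoding(n_positions, config.decoder_dim,
                                      config.pe_one_origin)
        self.blocks = [
            nn.TransformerBlock(config.decoder_dim, config.n_heads, rng,
                                config.mlp_ratio)
            for _ in range(config.decoder_layers)
        ]
        self.norm = nn.LayerNorm(config.decoder_dim)
        self.head = nn.Linear(config.decoder_dim, config.out_voxels, rng)

    def forward(self, encoded: Tensor, visible_positions, masked_positions) -> Tensor:
        """Returns predictions (n, patch_voxels) aligned to grid order 0..n-1."""
        vis = np.asarray(visible_positions, dtype=np.int64)
        msk = np.asarray(masked_positions, dtype=np.int64)
        if np.intersect1d(vis, msk).size:
            raise ValueError("visible and masked positions overlap")
        n = vis.size + msk.size
        if not np.array_equal(np.union1d(vis, msk), np.arange(n)):
            raise ValueError("visible ∪ masked must partition the patch grid")
        if n > self.n_positions:
            raise ValueError("more positions than the decoder was built for")

        enc = self.proj(encoded)  # (k, D_dec)
        order = np.concatenate([vis, msk])
        inv = np.argsort(order)  # scatter back to grid order
        if msk.size:
            mask_tokens = nn.stack([self.mask_token] * msk.size, axis=0)
            full = nn.concatenate([enc, mask_tokens], axis=0)
        else:
            full = enc
        full = full[inv] + Tensor(self.pe[np.arange(n)])
        x = full
        for block in self.blocks:
            x = block(x)
        return self.head(self.norm(x))


class PatchDiscriminator(nn.Module):
    """Five-layer convolutional least-squares discriminator on single patches.

    Four k=3 convolution blocks (LeakyReLU) followed by a k=1 convolution and
    a spatial average producing one scalar score per patch.
    """

    def __init__(self, config: EmbeddingConfig, rng: np.random.Generator):
        super().__init__()
        c = config.disc_channels
        self.patch_size = config.patch_size
        self.in_channels = config.in_channels
        self.convs = [
            nn.Conv3d(config.in_channels, c, 3, rng, padding=1),
            nn.Conv3d(c, c, 3, rng, padding=1),
            nn.Conv3d(c, c, 3, rng, padding=1),
            nn.Conv3d(c, c, 3, rng, padding=1),
        ]
        self.head = nn.Conv3d(c, 1, 1, rng)

    @property
    def n_conv_layers(self) -> int:
        return len(self.convs) + 1

    def forward(self, patches) -> Tensor:
        """patches: (N, patch_voxels) or (N, C, s, s, s) -> (N,) scores."""
        x = nn.as_tensor(patches)
        s, c = self.patch_size, self.in_channels
        if x.ndim == 2:
            if x.shape[1] != c * s**3:
                raise ValueError(
                    f"patch vector length {x.shape[1]} != {c * s**3}"
                )
            x = x.reshape(x.shape[0], c, s, s, s)
        elif x.shape[1:] != (c, s, s, s):
            raise ValueError(f"expected (N,{c},{s},{s},{s}), got {x.shape}")
        for conv in self.convs:
            x = conv(x).leaky_relu(0.2)
        x = self.head(x)  # (N,1,s,s,s)
        return x.mean(axis=(1, 2, 3, 4))


class MaskedAutoencoder(nn.Module):
    """Tokenizer + encoder + decoder bundle for pre-training."""

    def __init__(self, config: EmbeddingConfig, n_positions: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.n_positions = n_positions
        self.embed = PatchEmbedding(config, n_positions, rng)
        self.encoder = Encoder(config, rng)
        self.decoder = Decoder(config, n_positions, rng)

    def forward(self, patches, visible_positions, masked_positions) -> Tensor:
        vis = np.asarray(visible_positions, dtype=np.int64)
        tokens = self.embed(np.asarray(patches)[vis], vis)
        encoded = self.encoder(tokens)
        return self.decoder(encoded, vis, masked_positions)


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def reconstruction_loss(predicted, target, masked_positions) -> Tensor:
    """L_Rec = 1/2 * sum of squared errors over masked positions only."""
    msk = np.asarray(masked_positions, dtype=np.int64)
    if msk.size == 0:
        raise ValueError("masked position set is empty; L_Rec is undefined")
    pred = nn.as_tensor(predicted)
    tgt = nn.as_tensor(target)
    if pred.shape != tgt.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {tgt.shape}")
    diff = pred[msk] - tgt[msk]
    return 0.5 * (diff * diff).sum()


def adversarial_losses(real_patches, reconstructed, disc: PatchDiscriminator):
    """Least-squares GAN losses over all n patches.

    Returns ``(l_adv_d, l_adv_g)``: the discriminator objective
    1/2 Σ(||D(x)-1||² + ||D(ŷ)||²) with reconstructions detached, and the
    generator's fool term 1/2 Σ ||D(ŷ)-1||².
    """
    real = nn.as_tensor(real_patches)
    fake = nn.as_tensor(reconstructed)
    if real.shape != fake.shape:
        raise ValueError(f"shape mismatch {real.shape} vs {fake.shape}")
    d_real = disc(real.detach() if real.requires_grad else real)
    d_fake_detached = disc(fake.detach())
    l_adv_d = 0.5 * (((d_real - 1.0) ** 2).sum() + (d_fake_detached**2).sum())
    d_fake = disc(fake)
    l_adv_g = 0.5 * ((d_fake - 1.0) ** 2).sum()
    return l_adv_d, l_adv_g


def total_loss(l_rec, l_adv_g, adv_weight: float = 1.0):
    """Combined objective: L_Rec + adv_weight * L_Adv(G) (default weight 1)."""
    return l_rec + adv_weight * l_adv_g
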