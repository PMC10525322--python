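"""Neural-network layers on top of the autograd engine.

Provides the building blocks for the masked autoencoder and the
segmentation network: linear maps, layer normalization, multi-head
self-attention, pre-norm transformer blocks, and 3D (transposed)
convolutions.  Modules register parameters recursively so models can be
serialized as flat name → array dictionaries.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .autograd import Tensor

__all__ = [
    "Module",
    "Linear",
    "LayerNorm",
    "MultiHeadSelfAttention",
    "TransformerBlock",
    "Conv3d",
    "ConvTranspose3d",
    "conv3d",
    "conv_transpose3d_2x",
]


class Module:
    """Base class: tracks parameters and submodules by attribute name."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_mods", {})

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._mods[name] = value
        elif isinstance(value, (list, tuple)) and value and all(
            isinstance(v, Module) for v in value
        ):
            for i, v in enumerate(value):
                self._mods[f"{name}.{i}"] = v
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, mod in self._mods.items():
            yield from mod.named_parameters(prefix + name + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        extra = set(state) - set(own)
        if strict and (missing or extra):
            raise KeyError(
                f"state mismatch: missing={sorted(missing)} unexpected={sorted(extra)}"
            )
        for name, p in own.items():
            if name in state:
                arr = np.asarray(state[name], dtype=np.float64)
                if arr.shape != p.data.shape:
                    raise ValueError(
                        f"shape mismatch for {name}: {arr.shape} vs {p.data.shape}"
                    )
                p.data = arr.copy()

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 zero_init: bool = False):
        super().__init__()
        if zero_init:
            w = np.zeros((in_dim, out_dim))
        else:
            # Xavier-uniform
            bound = np.sqrt(6.0 / (in_dim + out_dim))
            w = rng.uniform(-bound, bound, size=(in_dim, out_dim))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x.layer_norm(self.eps) * self.gamma + self.beta


class MultiHeadSelfAttention(Module):
    """Full self-attention over a (T, D) token sequence.

    ``window_size`` restricts attention to contiguous chunks of the token
    sequence (a simple windowed mode); ``None`` means global attention.
    """

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 window_size: int | None = None):
        super().__init__()
        if dim % n_heads:
            raise ValueError(f"dim {dim} not divisible by n_heads {n_heads}")
        self.dim = dim
        self.n_heads = n_heads
        self.head_dim = dim // n_heads
        self.window_size = window_size
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def _attend(self, x: Tensor) -> Tensor:
        T = x.shape[0]
        h, dh = self.n_heads, self.head_dim
        qkv = self.qkv(x).reshape(T, 3, h, dh).transpose(1, 2, 0, 3)  # (3,h,T,dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 2, 1)) * (1.0 / np.sqrt(dh))
        attn = scores.softmax(axis=-1)
        out = (attn @ v).transpose(1, 0, 2).reshape(T, self.dim)
        return self.proj(out)

    def forward(self, x: Tensor) -> Tensor:
        T = x.shape[0]
        w = self.window_size
        if w is None or w >= T:
            return self._attend(x)
        # contiguous windows; remainder forms a final short window
        from .autograd import concatenate

        chunks = [self._attend(x[i:min(i + w, T)]) for i in range(0, T, w)]
        return concatenate(chunks, axis=0)


class TransformerBlock(Module):
    """Pre-norm transformer block: MSA + MLP, both with residuals."""

    def __init__(self, dim: int, n_heads: int, rng: np.random.Generator,
                 mlp_ratio: float = 4.0, window_size: int | None = None):
        super().__init__()
        hidden = int(dim * mlp_ratio)
        self.norm1 = LayerNorm(dim)
        self.attn = MultiHeadSelfAttention(dim, n_heads, rng, window_size)
        self.norm2 = LayerNorm(dim)
        self.fc1 = Linear(dim, hidden, rng)
        self.fc2 = Linear(hidden, dim, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.fc2(self.fc1(self.norm2(x)).gelu())
        return x


# ---------------------------------------------------------------------------
# 3D convolutions
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """3D cross-correlation.  x: (N,C,D,H,W); weight: (O,C,k,k,k)."""
    k = weight.shape[-1]
    s = stride
    xp = np.pad(x.data, ((0, 0), (0, 0)) + ((padding, padding),) * 3)
    view = sliding_window_view(xp, (k, k, k), axis=(2, 3, 4))[:, :, ::s, ::s, ::s]
    y = np.einsum("ncdhwijk,ocijk->nodhw", view, weight.data, optimize=True)
    if bias is not None:
        y = y + bias.data[None, :, None, None, None]
    Do, Ho, Wo = y.shape[2:]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        if weight.requires_grad:
            gw = np.einsum("ncdhwijk,nodhw->ocijk", view, g, optimize=True)
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            gxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    for l in range(k):
                        gxp[:, :, i:i + s * Do:s, j:j + s * Ho:s, l:l + s * Wo:s] += (
                            np.einsum("nodhw,oc->ncdhw", g, weight.data[:, :, i, j, l],
                                      optimize=True)
                        )
            if padding:
                gxp = gxp[:, :, padding:-padding, padding:-padding, padding:-padding]
            x._accumulate(gxp)

    return Tensor._make(y, parents, bw)


def conv_transpose3d_2x(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Transposed 3D convolution with kernel 2, stride 2 (exact ×2 upsampling).

    x: (N,C,D,H,W); weight: (C,O,2,2,2); output (N,O,2D,2H,2W).
    """
    N, C, D, H, W = x.shape
    O = weight.shape[1]
    y8 = np.einsum("nidhw,ioabc->nodahbwc", x.data, weight.data, optimize=True)
    y = y8.reshape(N, O, 2 * D, 2 * H, 2 * W)
    if bias is not None:
        y = y + bias.data[None, :, None, None, None]

    parents = (x, weight) if bias is None else (x, weight, bias)

    def bw(g):
        gr = g.reshape(N, O, D, 2, H, 2, W, 2)
        if x.requires_grad:
            x._accumulate(
                np.einsum("nodahbwc,ioabc->nidhw", gr, weight.data, optimize=True)
            )
        if weight.requires_grad:
            weight._accumulate(
                np.einsum("nidhw,nodahbwc->ioabc", x.data, gr, optimize=True)
            )
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3, 4)))

    return Tensor._make(y, parents, bw)


class Conv3d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int,
                 rng: np.random.Generator, stride: int = 1, padding: int = 0):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_ch * kernel**3
        # He-normal initialization
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(out_ch, in_ch) + (kernel,) * 3)
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, self.stride, self.padding)


class ConvTranspose3d(Module):
    """Kernel-2 stride-2 transposed convolution (the ×2 upsampler)."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_ch * 8
        w = rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(in_ch, out_ch, 2, 2, 2))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return conv_transpose3d_2x(x, self.weight, self.bias)
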