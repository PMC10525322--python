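"""Prior-informed patch masking.

A 3D volume of side L with patch size s yields an n = (L/s)^3 token grid;
patches are enumerated in row-major order over the grid axes (axis 0 varies
slowest), the same order used for positional encodings downstream.  The
per-patch sampling probability is the normalized sum of sampling-map weights
inside the patch,

    p_i = sum_j w_ij / sum_ij w_ij ,

and the k = round((1 - masking_ratio) * n) visible patches are drawn by
sequential weighted draws *without replacement* (the weight vector is
renormalized over the remaining indices after every draw).  Zero-probability
patches — background under the anatomical prior — can never become visible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .occurrence import SamplingWeightMap

__all__ = [
    "PatchGrid",
    "PatchProbabilityVector",
    "MaskSelection",
    "patchify",
    "unpatchify",
    "center_crop",
    "patch_probabilities",
    "sample_visible",
    "random_mask",
    "apply_mask",
]


@dataclass(frozen=True)
class PatchGrid:
    """Non-overlapping cubic patch tiling of a 3D volume."""

    input_shape: tuple[int, int, int] = (128, 128, 128)
    patch_size: int = 8
    grid_dims: tuple[int, int, int] = field(init=False)
    n: int = field(init=False)

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be positive")
        for s in self.input_shape:
            if s % self.patch_size:
                raise ValueError(
                    f"patch size {self.patch_size} does not divide shape "
                    f"{self.input_shape}; center_crop the input first"
                )
        dims = tuple(s // self.patch_size for s in self.input_shape)
        object.__setattr__(self, "grid_dims", dims)
        object.__setattr__(self, "n", int(np.prod(dims)))

    @property
    def voxels_per_patch(self) -> int:
        return self.patch_size**3


@dataclass(frozen=True)
class PatchProbabilityVector:
    """Normalized per-patch sampling probabilities p (length n, sum 1)."""

    p: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.p, dtype=np.float64)
        if p.ndim != 1:
            raise ValueError("p must be a vector")
        if (p < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if not np.isclose(p.sum(), 1.0, atol=1e-9):
            raise ValueError(f"probabilities must sum to 1, got {p.sum()}")
        object.__setattr__(self, "p", p)

    @property
    def n(self) -> int:
        return len(self.p)


@dataclass(frozen=True)
class MaskSelection:
    """Disjoint visible/masked patch index sets over a grid of n patches."""

    visible: np.ndarray
    masked: np.ndarray
    ratio: float
    seed: int

    def __post_init__(self):
        vis = np.sort(np.asarray(self.visible, dtype=np.int64))
        msk = np.sort(np.asarray(self.masked, dtype=np.int64))
        if np.intersect1d(vis, msk).size:
            raise ValueError("visible and masked sets overlap")
        n = vis.size + msk.size
        if not np.array_equal(np.union1d(vis, msk), np.arange(n)):
            raise ValueError("visible ∪ masked must cover all patch indices")
        object.__setattr__(self, "visible", vis)
        object.__setattr__(self, "masked", msk)

    @property
    def n(self) -> int:
        return self.visible.size + self.masked.size

    @property
    def k(self) -> int:
        return self.visible.size

    @property
    def m(self) -> int:
        return self.masked.size


def n_visible(n: int, masking_ratio: float) -> int:
    """k = round((1 - ratio) * n)."""
    if not 0.0 <= masking_ratio < 1.0:
        raise ValueError(f"masking_ratio must be in [0, 1), got {masking_ratio}")
    return int(round((1.0 - masking_ratio) * n))


def patchify(volume: np.ndarray, patch_size: int) -> np.ndarray:
    """Tile a 3D volume into (n, patch_size^3) flattened patches.

    Patches are ordered row-major over grid axes; voxels within a patch are
    row-major over the local axes.  Exact inverse: :func:`unpatchify`.
    """
    vol = np.asarray(volume)
    if vol.ndim != 3:
        raise ValueError("volume must be 3D")
    grid = PatchGrid(input_shape=vol.shape, patch_size=patch_size)
    gx, gy, gz = grid.grid_dims
    s = patch_size
    arr = vol.reshape(gx, s, gy, s, gz, s).transpose(0, 2, 4, 1, 3, 5)
    return arr.reshape(grid.n, s**3)


def unpatchify(patches: np.ndarray, grid: PatchGrid) -> np.ndarray:
    """Inverse of :func:`patchify` for the given grid."""
    s = grid.patch_size
    gx, gy, gz = grid.grid_dims
    arr = np.asarray(patches).reshape(gx, gy, gz, s, s, s)
    return arr.transpose(0, 3, 1, 4, 2, 5).reshape(grid.input_shape)


def center_crop(volume: np.ndarray, target_shape: tuple[int, ...]) -> np.ndarray:
    """Symmetric center crop; on odd differences the extra voxel is trimmed
    from the high side (low offset = diff // 2)."""
    vol = np.asarray(volume)
    if vol.ndim != len(target_shape):
        raise ValueError("target rank mismatch")
    for have, want in zip(vol.shape, target_shape):
        if have < want:
            raise ValueError(
                f"cannot crop shape {vol.shape} to larger {tuple(target_shape)}"
            )
    slices = tuple(
        slice((have - want) // 2, (have - want) // 2 + want)
        for have, want in zip(vol.shape, target_shape)
    )
    return vol[slices]


def patch_probabilities(
    weight_map: SamplingWeightMap | np.ndarray, grid: PatchGrid
) -> PatchProbabilityVector:
    """p_i proportional to the summed voxel weights inside patch i."""
    w = weight_map.weights if isinstance(weight_map, SamplingWeightMap) else \
        np.asarray(weight_map, dtype=np.float64)
    if w.shape != grid.input_shape:
        raise ValueError(
            f"weight map shape {w.shape} != grid input shape {grid.input_shape}"
        )
    sums = patchify(w, grid.patch_size).sum(axis=1)
    total = sums.sum()
    if total <= 0:
        raise ValueError("degenerate sampling weights: all patch weights are zero")
    return PatchProbabilityVector(p=sums / total)


def _sequential_draws(p: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """k distinct indices by weighted draws without replacement."""
    w = p.astype(np.float64).copy()
    chosen = np.empty(k, dtype=np.int64)
    for t in range(k):
        c = np.cumsum(w)
        u = rng.random() * c[-1]
        idx = int(np.searchsorted(c, u, side="right"))
        idx = min(idx, len(w) - 1)
        chosen[t] = idx
        w[idx] = 0.0
    return chosen


def sample_visible(
    p: PatchProbabilityVector | np.ndarray,
    masking_ratio: float,
    seed: int,
) -> MaskSelection:
    """Draw the visible patch set under the anatomical prior.

    Sequential weighted draws without replacement from ``p``; deterministic
    per seed.  Raises if fewer than k patches have positive probability.
    """
    pv = p if isinstance(p, PatchProbabilityVector) else PatchProbabilityVector(
        p=np.asarray(p, dtype=np.float64) / np.asarray(p, dtype=np.float64).sum()
    )
    n = pv.n
    k = n_visible(n, masking_ratio)
    n_pos = int((pv.p > 0).sum())
    if n_pos < k:
        raise ValueError(
            f"cannot sample {k} visible patches: only {n_pos} have positive "
            f"probability (deficit {k - n_pos})"
        )
    rng = np.random.default_rng(seed)
    chosen = _sequential_draws(pv.p, k, rng)
    masked = np.setdiff1d(np.arange(n), chosen)
    return MaskSelection(visible=chosen, masked=masked,
                         ratio=masking_ratio, seed=seed)


def random_mask(n: int, masking_ratio: float, seed: int) -> MaskSelection:
    """Uniform masking baseline: visible set drawn uniformly without
    replacement (the prior-informed sampler with a flat probability vector)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    uniform = PatchProbabilityVector(p=np.full(n, 1.0 / n))
    return sample_visible(uniform, masking_ratio, seed)


def apply_mask(
    volume: np.ndarray,
    selection: MaskSelection,
    grid: PatchGrid,
    fill_value: float = 0.0,
) -> np.ndarray:
    """Replace masked patches by ``fill_value``; visible patches unchanged."""
    vol = np.asarray(volume)
    if vol.shape != grid.input_shape:
        raise ValueError(f"volume shape {vol.shape} != grid {grid.input_shape}")
    if selection.n != grid.n:
        raise ValueError(f"selection over {selection.n} patches, grid has {grid.n}")
    if selection.masked.size and selection.masked.max() >= grid.n:
        raise ValueError("masked index out of range")
    patches = patchify(vol, grid.patch_size).astype(np.float64, copy=True)
    patches[selection.masked] = fill_value
    return unpatchify(patches, grid)
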