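"""Synthetic study fixtures: atlases, tumor labels, intensity volumes.

Desk-scale stand-ins for a co-registered neuroimaging cohort: a multi-region
parcellation inside a brain mask (seeded Voronoi partition), per-region
Bernoulli tumor occurrence with known rates, and noisy region-mean intensity
volumes.  Everything is deterministic per seed; per-operation randomness is
drawn from fixed sub-streams of the root seed (offset 0 = atlas, 1 = tumor
labels, 2 = intensities) so the three generators never share draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .occurrence import ParcellationAtlas

__all__ = [
    "SyntheticStudyConfig",
    "make_brain_mask",
    "make_atlas",
    "simulate_tumor_labels",
    "make_intensity_volume",
    "make_study",
]

# sub-stream offsets of the root seed
_ATLAS_STREAM = 0
_TUMOR_STREAM = 1
_INTENSITY_STREAM = 2
_RATES_STREAM = 3


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream)])


@dataclass(frozen=True)
class SyntheticStudyConfig:
    """Parameters of one synthetic cohort."""

    grid_shape: tuple[int, int, int] = (32, 32, 32)
    n_regions: int = 8
    brain_mask_kind: str = "ellipsoid"
    region_rates: Mapping[int, float] | None = None
    n_cases: int = 200
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 3 or any(s < 1 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive ints: {self.grid_shape}")
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.brain_mask_kind not in ("ellipsoid", "full"):
            raise ValueError(f"unknown brain_mask_kind {self.brain_mask_kind!r}")
        if self.n_cases < 1:
            raise ValueError("n_cases must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.region_rates is not None:
            for rid, rate in self.region_rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"rate for region {rid} outside [0,1]: {rate}")


def make_brain_mask(grid_shape: tuple[int, int, int], kind: str) -> np.ndarray:
    """Boolean mask: full grid, or an axis-aligned ellipsoid at 90% half-extent."""
    if kind == "full":
        return np.ones(grid_shape, dtype=bool)
    if kind != "ellipsoid":
        raise ValueError(f"unknown brain_mask_kind {kind!r}")
    centers = [(s - 1) / 2.0 for s in grid_shape]
    semi = [0.9 * s / 2.0 for s in grid_shape]
    grids = np.ogrid[tuple(slice(0, s) for s in grid_shape)]
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, centers, semi))
    return q <= 1.0


def make_atlas(config: SyntheticStudyConfig) -> ParcellationAtlas:
    """Seeded Voronoi parcellation of the brain mask.

    ``n_regions`` seed voxels are drawn uniformly from the mask; every mask
    voxel is assigned to the nearest seed (Euclidean distance on voxel
    indices, ties to the lowest region id).  Labels are 1..n_regions,
    background 0.
    """
    mask = make_brain_mask(config.grid_shape, config.brain_mask_kind)
    coords = np.argwhere(mask)
    n_vox = len(coords)
    if config.n_regions > n_vox:
        raise ValueError(
            f"infeasible partition: n_regions={config.n_regions} exceeds "
            f"{n_vox} mask voxels"
        )
    rng = _rng(config.seed, _ATLAS_STREAM)
    seed_idx = rng.choice(n_vox, size=config.n_regions, replace=False)
    seeds = coords[seed_idx].astype(np.float32)

    labels = np.zeros(config.grid_shape, dtype=np.int32)
    # chunked distance computation; argmin takes the lowest seed index on ties
    pts = coords.astype(np.float32)
    chunk = 65536
    assignments = np.empty(n_vox, dtype=np.int32)
    for lo in range(0, n_vox, chunk):
        block = pts[lo:lo + chunk]  # (B,3)
        d2 = ((block[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
        assignments[lo:lo + chunk] = np.argmin(d2, axis=1)
    labels[tuple(coords.T)] = assignments + 1
    return ParcellationAtlas(labels=labels)


def simulate_tumor_labels(
    atlas: ParcellationAtlas,
    region_rates: Mapping[int, float],
    n_cases: int,
    seed: int,
    class_multipliers: Mapping[str, float] | None = None,
) -> list[np.ndarray] | dict[str, list[np.ndarray]]:
    """Per-region Bernoulli tumor occurrence.

    Each voxel of region i is tumor-positive independently with probability
    ``region_rates[i]``; background is always 0.  With ``class_multipliers``
    (e.g. ``{"et": 1.0, "tc": 1.3, "wt": 1.6}``) a nested family of masks is
    produced per case by thresholding a single uniform draw per voxel against
    each class's (clipped) rate, so larger multipliers strictly contain
    smaller ones.  Default returns a flat list for the single binary class.
    """
    if n_cases < 1:
        raise ValueError("n_cases must be positive")
    missing = sorted(set(atlas.region_ids) - set(region_rates))
    if missing:
        raise ValueError(f"rates missing for atlas regions: {missing}")
    for rid, rate in region_rates.items():
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"rate for region {rid} outside [0,1]: {rate}")

    max_label = int(atlas.labels.max())
    base = np.zeros(max_label + 1, dtype=np.float64)
    for rid in atlas.region_ids:
        base[rid] = region_rates[rid]
    rate_vol = base[atlas.labels]
    fg = atlas.mask

    rng = _rng(seed, _TUMOR_STREAM)
    multipliers = class_multipliers or {"_single": 1.0}
    out: dict[str, list[np.ndarray]] = {c: [] for c in multipliers}
    for _ in range(n_cases):
        u = rng.random(atlas.shape)
        for cls, mult in multipliers.items():
            thresh = np.clip(rate_vol * mult, 0.0, 1.0)
            vol = ((u < thresh) & fg).astype(np.uint8)
            out[cls].append(vol)
    if class_multipliers is None:
        return out["_single"]
    return out


def make_intensity_volume(
    atlas: ParcellationAtlas, noise_sd: float, seed: int
) -> np.ndarray:
    """Region-mean intensities plus iid Gaussian noise; background 0.

    Per-region means are drawn once from the intensity sub-stream, uniform in
    [0.5, 1.5] — fixed for a given (atlas label set, seed) pair.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    rng = _rng(seed, _INTENSITY_STREAM)
    max_label = int(atlas.labels.max())
    means = np.zeros(max_label + 1)
    means[list(atlas.region_ids)] = rng.uniform(0.5, 1.5, size=len(atlas.region_ids))
    vol = means[atlas.labels]
    if noise_sd > 0:
        vol = vol + rng.normal(0.0, noise_sd, size=atlas.shape)
    vol[~atlas.mask] = 0.0
    return vol


def make_study(config: SyntheticStudyConfig):
    """Convenience: atlas, tumor label volumes, and one intensity volume."""
    atlas = make_atlas(config)
    rates = config.region_rates
    if rates is None:
        rng = _rng(config.seed, _RATES_STREAM)
        rates = {rid: float(r) for rid, r in
                 zip(atlas.region_ids,
                     rng.uniform(0.05, 0.6, size=len(atlas.region_ids)))}
    labels = simulate_tumor_labels(atlas, rates, config.n_cases, config.seed)
    intensity = make_intensity_volume(atlas, config.noise_sd, config.seed)
    return atlas, rates, labels, intensity
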