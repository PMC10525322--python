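"""Patch grids, weighted visible-set sampling, and masking application."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from priormae import masking
from priormae.masking import (
    MaskSelection,
    PatchGrid,
    PatchProbabilityVector,
    apply_mask,
    center_crop,
    patch_probabilities,
    patchify,
    random_mask,
    sample_visible,
    unpatchify,
)


def inclusion_probabilities(p, k):
    """Exact inclusion probabilities of sequential weighted draws without
    replacement, by enumeration of all ordered k-tuples (oracle)."""
    p = np.asarray(p, dtype=float)
    n = len(p)
    incl = np.zeros(n)
    for perm in itertools.permutations(range(n), k):
        prob = 1.0
        rem = 1.0
        for idx in perm:
            prob *= p[idx] / rem
            rem -= p[idx]
        for idx in perm:
            incl[idx] += prob
    return incl


class TestPatchify:
    def test_default_grid_counts(self):
        vol = np.zeros((128, 128, 128))
        patches = patchify(vol, 8)
        assert patches.shape == (4096, 512)
        grid = PatchGrid()
        assert grid.n == 4096 and grid.grid_dims == (16, 16, 16)

    def test_single_patch_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        patches = patchify(vol, 8)
        assert patches.shape == (1, 512)
        np.testing.assert_array_equal(patches[0], vol.ravel())

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 10_000), patch=st.sampled_from([2, 4, 8]))
    def test_round_trip_identity(self, seed, patch):
        vol = np.random.default_rng(seed).normal(size=(16, 16, 16))
        grid = PatchGrid(input_shape=(16, 16, 16), patch_size=patch)
        np.testing.assert_array_equal(unpatchify(patchify(vol, patch), grid), vol)

    def test_enumeration_order_is_row_major(self):
        """Patch i must cover the block at grid coordinate unravel(i)."""
        vol = np.arange(16**3).reshape(16, 16, 16)
        patches = patchify(vol, 4)
        gx = 4
        for i in (0, 1, 5, 37):
            cx, cy, cz = np.unravel_index(i, (gx, gx, gx))
            block = vol[cx * 4:(cx + 1) * 4, cy * 4:(cy + 1) * 4,
                        cz * 4:(cz + 1) * 4]
            np.testing.assert_array_equal(patches[i], block.ravel())

    def test_non_divisible_shape_suggests_crop(self):
        with pytest.raises(ValueError, match="center_crop"):
            patchify(np.zeros((10, 10, 10)), 4)


class TestCenterCrop:
    def test_even_difference_symmetric(self):
        vol = np.arange(130**3).reshape(130, 130, 130)
        out = center_crop(vol, (128, 128, 128))
        np.testing.assert_array_equal(out, vol[1:129, 1:129, 1:129])

    def test_equal_shape_identity(self, rng):
        vol = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(center_crop(vol, (8, 8, 8)), vol)

    def test_odd_difference_trims_high_side(self):
        vol = np.arange(9**3).reshape(9, 9, 9)
        out = center_crop(vol, (8, 8, 8))
        np.testing.assert_array_equal(out, vol[0:8, 0:8, 0:8])

    def test_too_small_raises(self):
        with pytest.raises(ValueError, match="cannot crop"):
            center_crop(np.zeros((4, 4, 4)), (8, 8, 8))


class TestPatchProbabilities:
    def test_uniform_weights(self):
        grid = PatchGrid(input_shape=(16, 16, 16), patch_size=8)
        p = patch_probabilities(np.ones((16, 16, 16)), grid)
        np.testing.assert_allclose(p.p, 1 / 8)

    def test_two_patch_toy(self):
        grid = PatchGrid(input_shape=(16, 16, 16), patch_size=8)
        w = np.zeros((16, 16, 16))
        w[:8, :8, :8] = 3.0   # patch 0
        w[:8, :8, 8:] = 1.0   # patch 1
        p = patch_probabilities(w, grid)
        np.testing.assert_allclose(p.p[:2], [0.75, 0.25])
        assert (p.p[2:] == 0).all()

    def test_scaling_invariance(self, tiny_weight_map):
        grid = PatchGrid(input_shape=(16, 16, 16), patch_size=4)
        p1 = patch_probabilities(tiny_weight_map, grid)
        p2 = patch_probabilities(tiny_weight_map.weights * 1000.0, grid)
        np.testing.assert_allclose(p1.p, p2.p, rtol=1e-12)

    def test_all_zero_weights_rejected(self):
        grid = PatchGrid(input_shape=(8, 8, 8), patch_size=4)
        with pytest.raises(ValueError, match="degenerate sampling weights"):
            patch_probabilities(np.zeros((8, 8, 8)), grid)


class TestSampleVisible:
    def test_default_masking_arithmetic(self):
        """128-cube, patch 8, 75% masking: 1024 visible of 4096."""
        grid = PatchGrid()
        p = PatchProbabilityVector(p=np.full(grid.n, 1 / grid.n))
        sel = sample_visible(p, 0.75, seed=0)
        assert (sel.n, sel.k, sel.m) == (4096, 1024, 3072)

    def test_deterministic_and_partition(self):
        p = np.array([0.5, 0.3, 0.2, 0.0])
        a = sample_visible(p, 0.5, seed=9)
        b = sample_visible(p, 0.5, seed=9)
        np.testing.assert_array_equal(a.visible, b.visible)
        assert a.k == 2 and a.m == 2
        assert not np.intersect1d(a.visible, a.masked).size

    def test_zero_probability_never_visible(self):
        p = np.array([0.4, 0.0, 0.3, 0.3, 0.0])
        for seed in range(200):
            sel = sample_visible(p, 0.4, seed)  # k = 3
            assert 1 not in sel.visible and 4 not in sel.visible

    def test_deficit_reported(self):
        p = np.array([1.0, 0.0, 0.0, 0.0])
        with pytest.raises(ValueError, match="deficit 2"):
            sample_visible(p, 0.25, seed=0)  # k = 3 but one positive

    def test_single_draw_matches_p(self):
        p = np.array([0.5, 0.3, 0.2])
        hits = np.zeros(3)
        n_draws = 30_000
        for seed in range(n_draws):
            hits[sample_visible(p, 2 / 3, seed).visible[0]] += 1
        freq = hits / n_draws
        se = np.sqrt(p * (1 - p) / n_draws)
        assert (np.abs(freq - p) < 3 * se).all()

    def test_inclusion_probabilities_match_enumeration_oracle(self):
        """n=3, k=2, p=(0.5,0.3,0.2): exact inclusion probabilities are
        (0.8392857, 0.675, 0.4857143); empirical frequencies over 1e5 seeded
        draws agree within 3 binomial standard errors."""
        p = np.array([0.5, 0.3, 0.2])
        exact = inclusion_probabilities(p, 2)
        np.testing.assert_allclose(
            exact, [0.8392857142857143, 0.675, 0.4857142857142857], atol=1e-12)
        n_draws = 100_000
        hits = np.zeros(3)
        for seed in range(n_draws):
            hits[sample_visible(p, 1 / 3, seed).visible] += 1
        freq = hits / n_draws
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert (np.abs(freq - exact) < 3 * se).all()

    @pytest.mark.parametrize("n,k,seed", [(4, 2, 0), (5, 3, 1), (6, 2, 2)])
    def test_oracle_agreement_random_weights(self, n, k, seed):
        rng = np.random.default_rng(seed)
        p = rng.dirichlet(np.ones(n))
        exact = inclusion_probabilities(p, k)
        n_draws = 20_000
        hits = np.zeros(n)
        for s in range(n_draws):
            hits[sample_visible(p, 1 - k / n, s).visible] += 1
        freq = hits / n_draws
        se = np.sqrt(exact * (1 - exact) / n_draws)
        assert (np.abs(freq - exact) < 3.5 * se).all()

    def test_monotonicity_of_inclusion_by_enumeration(self):
        """Raising one patch's weight cannot lower its inclusion probability
        (exact, no sampling)."""
        rng = np.random.default_rng(4)
        for n, k in [(4, 2), (5, 2), (6, 3)]:
            w = rng.uniform(0.5, 2.0, size=n)
            base = inclusion_probabilities(w / w.sum(), k)
            w2 = w.copy()
            w2[0] *= 1.5
            boosted = inclusion_probabilities(w2 / w2.sum(), k)
            assert boosted[0] >= base[0]


class TestRandomMask:
    def test_ratio_zero_all_visible(self):
        sel = random_mask(10, 0.0, seed=0)
        assert sel.k == 10 and sel.m == 0

    def test_one_masked_patch(self):
        sel = random_mask(8, 1 / 8, seed=3)
        assert sel.m == 1

    def test_uniform_inclusion_frequency(self):
        n, ratio = 64, 0.75
        hits = np.zeros(n)
        n_draws = 4000
        for seed in range(n_draws):
            hits[random_mask(n, ratio, seed).visible] += 1
        freq = hits / n_draws
        se = np.sqrt(0.25 * 0.75 / n_draws)
        assert (np.abs(freq - 0.25) < 4 * se).all()

    def test_uniform_prior_identical_to_random(self):
        """Prior-informed sampling with flat weights is the uniform baseline,
        draw for draw under the same seed."""
        n = 27
        flat = PatchProbabilityVector(p=np.full(n, 1 / n))
        for seed in range(20):
            a = sample_visible(flat, 0.7, seed)
            b = random_mask(n, 0.7, seed)
            np.testing.assert_array_equal(a.visible, b.visible)


class TestApplyMask:
    def test_empty_masked_set_is_identity(self, rng):
        grid = PatchGrid(input_shape=(8, 8, 8), patch_size=4)
        vol = rng.normal(size=(8, 8, 8))
        sel = MaskSelection(visible=np.arange(8), masked=np.array([], dtype=int),
                            ratio=0.0, seed=0)
        np.testing.assert_array_equal(apply_mask(vol, sel, grid), vol)

    def test_all_masked_constant(self, rng):
        grid = PatchGrid(input_shape=(8, 8, 8), patch_size=4)
        vol = rng.normal(size=(8, 8, 8))
        sel = MaskSelection(visible=np.array([], dtype=int), masked=np.arange(8),
                            ratio=1.0, seed=0)
        out = apply_mask(vol, sel, grid, fill_value=7.5)
        assert (out == 7.5).all()

    def test_fill_count_equals_masked_patches(self, rng):
        grid = PatchGrid(input_shape=(16, 16, 16), patch_size=4)
        vol = rng.uniform(1.0, 2.0, size=(16, 16, 16))  # never equals fill
        sel = random_mask(grid.n, 0.75, seed=5)
        out = apply_mask(vol, sel, grid, fill_value=0.0)
        n_zero_patches = int((patchify(out, 4) == 0).all(axis=1).sum())
        assert n_zero_patches == sel.m

    def test_selection_grid_size_mismatch(self, rng):
        grid = PatchGrid(input_shape=(8, 8, 8), patch_size=4)
        sel = random_mask(27, 0.5, seed=1)
        with pytest.raises(ValueError, match="grid has 8"):
            apply_mask(rng.normal(size=(8, 8, 8)), sel, grid)
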