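"""Model components: positional encoding, embedding, MAE parts, losses."""

import numpy as np
import pytest

from priormae import model, nn
from priormae.model import (
    Decoder,
    EmbeddingConfig,
    Encoder,
    MaskedAutoencoder,
    PatchDiscriminator,
    PatchEmbedding,
    adversarial_losses,
    positional_encoding,
    reconstruction_loss,
    total_loss,
)
from priormae.nn import Tensor

TINY = EmbeddingConfig.tiny()


class TestPositionalEncoding:
    def test_position_zero_alternates_zero_one(self):
        pe = positional_encoding(4, 10)
        np.testing.assert_array_equal(pe[0], [0, 1] * 5)

    def test_values_bounded(self):
        pe = positional_encoding(64, 32)
        assert (np.abs(pe) <= 1).all()

    def test_sin_of_one_at_pos1_dim0(self):
        pe = positional_encoding(8, 384)
        assert pe[1, 0] == pytest.approx(np.sin(1.0), abs=1e-12)
        assert pe[1, 1] == pytest.approx(np.cos(1.0), abs=1e-12)

    def test_one_origin_shifts_positions(self):
        pe0 = positional_encoding(4, 8)
        pe1 = positional_encoding(4, 8, one_origin=True)
        np.testing.assert_allclose(pe1[0], pe0[1])

    def test_odd_dimension_rejected(self):
        with pytest.raises(ValueError, match="even"):
            positional_encoding(4, 7)


class TestPatchEmbedding:
    def test_zero_tokenizer_yields_pe_rows(self, rng):
        emb = PatchEmbedding(TINY, n_positions=27, rng=rng, zero_init=True)
        patches = np.zeros((3, TINY.patch_voxels))
        positions = np.array([0, 5, 26])
        out = emb(patches, positions)
        np.testing.assert_allclose(out.data, emb.pe[positions])

    def test_full_scale_dimension_mapping(self, rng):
        """An 8-cube single-channel patch maps 512 -> 384."""
        cfg = EmbeddingConfig()
        emb = PatchEmbedding(cfg, n_positions=16, rng=rng)
        out = emb(np.zeros((2, 512)), np.array([0, 1]))
        assert out.shape == (2, 384)

    def test_permutation_equivariance(self, rng):
        emb = PatchEmbedding(TINY, n_positions=27, rng=rng)
        patches = rng.normal(size=(4, TINY.patch_voxels))
        positions = np.array([3, 7, 11, 20])
        perm = np.array([2, 0, 3, 1])
        a = emb(patches, positions).data
        b = emb(patches[perm], positions[perm]).data
        np.testing.assert_allclose(a[perm], b, atol=1e-12)

    def test_wrong_patch_length_rejected(self, rng):
        emb = PatchEmbedding(TINY, n_positions=8, rng=rng)
        with pytest.raises(ValueError, match="patch vector length"):
            emb(np.zeros((2, 99)), np.array([0, 1]))


class TestEncoderDecoder:
    def test_shape_preserving_and_deterministic(self, rng):
        enc = Encoder(TINY, rng)
        x = Tensor(np.random.default_rng(0).normal(size=(1, TINY.feature_dim)))
        a = enc(x).data
        b = enc(x).data
        assert a.shape == (1, TINY.feature_dim)
        np.testing.assert_array_equal(a, b)

    def test_gradient_reaches_every_block(self, rng):
        enc = Encoder(TINY, rng)
        x = Tensor(rng.normal(size=(5, TINY.feature_dim)), requires_grad=True)
        (enc(x) ** 2).sum().backward()
        for name, p in enc.named_parameters():
            assert p.grad is not None, name

    def test_decoder_emits_all_positions(self, rng):
        dec = Decoder(TINY, n_positions=8, rng=rng)
        enc_tokens = Tensor(rng.normal(size=(3, TINY.feature_dim)))
        out = dec(enc_tokens, np.array([0, 2, 5]), np.array([1, 3, 4, 6, 7]))
        assert out.shape == (8, TINY.out_voxels)

    def test_decoder_nothing_masked_still_emits_all(self, rng):
        dec = Decoder(TINY, n_positions=4, rng=rng)
        enc_tokens = Tensor(rng.normal(size=(4, TINY.feature_dim)))
        out = dec(enc_tokens, np.arange(4), np.array([], dtype=int))
        assert out.shape == (4, TINY.out_voxels)

    def test_decoder_rejects_overlap(self, rng):
        dec = Decoder(TINY, n_positions=4, rng=rng)
        enc_tokens = Tensor(rng.normal(size=(2, TINY.feature_dim)))
        with pytest.raises(ValueError, match="overlap"):
            dec(enc_tokens, np.array([0, 1]), np.array([1, 2, 3]))

    def test_windowed_attention_config(self, rng):
        cfg = EmbeddingConfig.tiny(window_size=4)
        enc = Encoder(cfg, rng)
        out = enc(Tensor(rng.normal(size=(10, cfg.feature_dim))))
        assert out.shape == (10, cfg.feature_dim)


class TestReconstructionLoss:
    def test_perfect_reconstruction_is_zero(self, rng):
        x = rng.normal(size=(6, 64))
        assert float(reconstruction_loss(x, x, np.array([1, 3]))) == 0.0

    def test_unit_residual_on_one_masked_patch(self):
        """One masked 512-voxel patch with residual 1 everywhere: 1/2*512."""
        target = np.zeros((4, 512))
        pred = target.copy()
        pred[2] = 1.0
        assert float(reconstruction_loss(pred, target, np.array([2]))) == 256.0

    def test_visible_positions_do_not_contribute(self, rng):
        target = rng.normal(size=(5, 64))
        pred = target + rng.normal(size=(5, 64))
        masked = np.array([0, 4])
        base = float(reconstruction_loss(pred, target, masked))
        pred2 = pred.copy()
        pred2[[1, 2, 3]] += 100.0  # perturb visible positions only
        assert float(reconstruction_loss(pred2, target, masked)) == base

    def test_gradient_zero_at_visible_positions(self, rng):
        target = rng.normal(size=(5, 8))
        pred = Tensor(rng.normal(size=(5, 8)), requires_grad=True)
        reconstruction_loss(pred, target, np.array([1, 3])).backward()
        np.testing.assert_array_equal(pred.grad[[0, 2, 4]], 0.0)
        assert np.abs(pred.grad[[1, 3]]).sum() > 0

    def test_quadratic_scaling(self, rng):
        target = np.zeros((3, 16))
        resid = rng.normal(size=(3, 16))
        masked = np.arange(3)
        l1 = float(reconstruction_loss(resid, target, masked))
        l2 = float(reconstruction_loss(2 * resid, target, masked))
        assert l2 == pytest.approx(4 * l1, rel=1e-12)

    def test_empty_masked_set_rejected(self, rng):
        x = rng.normal(size=(3, 8))
        with pytest.raises(ValueError, match="empty"):
            reconstruction_loss(x, x, np.array([], dtype=int))


class _ConstantDisc(nn.Module):
    """Stub discriminator returning a fixed score for every patch."""

    def __init__(self, value):
        super().__init__()
        self.value = value

    def forward(self, patches):
        x = nn.as_tensor(patches)
        return x.sum(axis=tuple(range(1, x.ndim))) * 0.0 + self.value


class TestAdversarialLosses:
    def test_perfect_discriminator_zero_loss(self, rng):
        x = rng.normal(size=(4, 8))

        class Perfect(nn.Module):
            def forward(self, patches):
                arr = np.asarray(patches.data if isinstance(patches, Tensor)
                                 else patches)
                is_real = np.array([np.allclose(row, x[i]) for i, row in
                                    enumerate(arr)])
                return Tensor(is_real.astype(float))

        l_d, _ = adversarial_losses(x, x + 10.0, Perfect())
        assert float(l_d) == 0.0

    def test_constant_half_scorer_gives_one(self, rng):
        """D = 0.5 on 4 patches: 1/2 * 4 * (0.25 + 0.25) = 1."""
        x = rng.normal(size=(4, 8))
        l_d, _ = adversarial_losses(x, x + 1.0, _ConstantDisc(0.5))
        assert float(l_d) == pytest.approx(1.0, abs=1e-12)

    def test_fooled_discriminator_zero_generator_loss(self, rng):
        x = rng.normal(size=(3, 8))
        _, l_g = adversarial_losses(x, x + 1.0, _ConstantDisc(1.0))
        assert float(l_g) == pytest.approx(0.0, abs=1e-12)

    def test_objective_minimized_at_one_zero(self, rng):
        """Eq-style least-squares objective: any deviation from scores
        (real, fake) = (1, 0) increases the discriminator loss from 0."""
        x = rng.normal(size=(2, 8))
        for real_s, fake_s in [(1.0, 0.0), (0.9, 0.0), (1.0, 0.2), (0.5, 0.5)]:
            value = 0.5 * 2 * ((real_s - 1) ** 2 + fake_s**2)
            assert value >= 0
            if (real_s, fake_s) == (1.0, 0.0):
                assert value == 0.0
            else:
                assert value > 0.0

    def test_discriminator_step_does_not_touch_generator(self, rng):
        """Reconstructions enter the discriminator loss detached."""
        fake = Tensor(rng.normal(size=(2, TINY.patch_voxels)),
                      requires_grad=True)
        disc = PatchDiscriminator(TINY, rng)
        l_d, l_g = adversarial_losses(
            rng.normal(size=(2, TINY.patch_voxels)), fake, disc)
        l_d.backward()
        assert fake.grad is None
        l_g.backward()
        assert fake.grad is not None


class TestDiscriminator:
    def test_scalar_score_per_patch_and_determinism(self, rng):
        disc = PatchDiscriminator(TINY, rng)
        patches = np.random.default_rng(5).normal(size=(7, TINY.patch_voxels))
        a = disc(patches).data
        assert a.shape == (7,)
        np.testing.assert_array_equal(a, disc(patches).data)

    def test_five_convolutional_layers(self, rng):
        assert PatchDiscriminator(TINY, rng).n_conv_layers == 5

    def test_wrong_patch_shape_rejected(self, rng):
        disc = PatchDiscriminator(TINY, rng)
        with pytest.raises(ValueError, match="patch vector length"):
            disc(np.zeros((2, 100)))


class TestTotalLoss:
    def test_additivity_and_ablation(self):
        assert float(total_loss(Tensor(0.0), Tensor(0.0))) == 0.0
        assert float(total_loss(Tensor(2.5), Tensor(0.5))) == 3.0
        assert float(total_loss(Tensor(2.5), Tensor(0.5), adv_weight=0.0)) == 2.5


class TestMaskedAutoencoderOverfit:
    def test_tiny_instance_loss_decreases(self, rng):
        """Overfitting a 2-patch toy instance: reconstruction loss at the end
        of a short optimization run is well below its start."""
        cfg = EmbeddingConfig.tiny(encoder_layers=1, decoder_layers=1)
        mae = MaskedAutoencoder(cfg, n_positions=2, rng=rng)
        opt = nn.AdamW(mae.parameters(), lr=1e-3)
        patches = np.random.default_rng(2).normal(size=(2, cfg.patch_voxels))
        vis, msk = np.array([0]), np.array([1])
        losses = []
        for _ in range(200):
            pred = mae(patches, vis, msk)
            loss = reconstruction_loss(pred, patches, msk)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss))
        assert losses[-1] < 0.05 * losses[0]
        # decreasing trend after warmup
        assert np.mean(losses[150:]) < np.mean(losses[:50])
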