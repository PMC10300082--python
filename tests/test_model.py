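"""UNet-RCAN architecture contracts: shapes, channels, attention, tiling."""

import numpy as np
import pytest

import sted_restore as sr
from sted_restore._engine import Tensor
from sted_restore.model import ChannelAttentionBlock


def conv_params(ci, co, k, d=2):
    return co * ci * k ** d + co


def resblock_params(ci, co, d=2):
    return (conv_params(ci, co, 3, d) + conv_params(co, co, 3, d)
            + conv_params(ci, co, 1, d))


def cab_params(c, r=4, d=2):
    return (conv_params(c, c, 3, d) + conv_params(c, c, 3, d)
            + conv_params(c, r, 1, d) + conv_params(r, c, 1, d))


def tconv_params(ci, co, d=2):
    return ci * co * 2 ** d + co


def unet_rcan_tally(base=64, depth=3, rcan_f=64, n_rg=3, n_cab=8, d=2):
    """Independent layer-by-layer parameter tally of the default net."""
    enc = [base * 2 ** i for i in range(depth)]
    total = resblock_params(1, enc[0], d)
    for a, b in zip(enc, enc[1:]):
        total += resblock_params(a, b, d)
    total += sum(cab_params(c, 4, d) for c in enc)        # skip CABs
    total += resblock_params(enc[-1], 2 * enc[-1], d)     # bottleneck
    ch = 2 * enc[-1]
    for c in reversed(enc):
        total += tconv_params(ch, c, d) + resblock_params(2 * c, c, d)
        ch = c
    total += conv_params(enc[0], 1, 1, d)                 # U-Net head
    rg = n_cab * cab_params(rcan_f, 4, d) + conv_params(rcan_f, rcan_f, 3, d)
    total += (conv_params(2, rcan_f, 3, d) + n_rg * rg
              + conv_params(rcan_f, rcan_f, 3, d)
              + conv_params(rcan_f, 1, 1, d))
    return total


class TestArchitecture:
    def test_2d_shape_preserved(self, tiny_config):
        model = sr.build_unet_rcan(tiny_config)
        x = np.random.default_rng(0).random((1, 1, 64, 64)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 1, 64, 64)

    def test_3d_shape_preserved(self):
        cfg = sr.NetworkConfig(dims=3, unet_base_filters=4, unet_depth=2,
                               rcan_filters=4, n_residual_groups=1,
                               n_cab_per_group=1, seed=0)
        model = sr.build_unet_rcan(cfg)
        x = np.random.default_rng(1).random((1, 1, 8, 16, 16)).astype(np.float32)
        assert model(Tensor(x)).data.shape == (1, 1, 8, 16, 16)

    def test_encoder_filter_progression_doubles(self):
        unet = sr.build_unet(sr.NetworkConfig())
        filters = [enc.conv1.weight.data.shape[0] for enc in unet.encoders]
        assert filters == [64, 128, 256]

    def test_rcan_input_is_two_channels(self):
        rcan = sr.build_rcan(sr.NetworkConfig())
        assert rcan.head.weight.data.shape[1] == 2

    def test_default_parameter_count_matches_hand_tally(self):
        model = sr.build_unet_rcan(sr.NetworkConfig())
        assert model.num_parameters() == unet_rcan_tally()

    def test_tiny_parameter_count_matches_hand_tally(self, tiny_config):
        model = sr.build_unet_rcan(tiny_config)
        assert model.num_parameters() == unet_rcan_tally(
            base=8, depth=2, rcan_f=8, n_rg=1, n_cab=2)

    def test_parameter_count_is_function_of_config(self, tiny_config):
        a = sr.build_unet_rcan(tiny_config).num_parameters()
        b = sr.build_unet_rcan(tiny_config).num_parameters()
        assert a == b

    def test_indivisible_input_rejected_with_padding_hint(self, tiny_config):
        model = sr.build_unet_rcan(tiny_config)
        x = np.zeros((1, 1, 63, 64), dtype=np.float32)
        with pytest.raises(ValueError, match="pad"):
            model(Tensor(x))

    def test_forward_deterministic_and_finite_on_zero(self, tiny_config):
        model = sr.build_unet_rcan(tiny_config)
        x = np.zeros((1, 1, 32, 32), dtype=np.float32)
        a = model(Tensor(x)).data
        b = model(Tensor(x)).data
        assert np.array_equal(a, b)
        assert np.all(np.isfinite(a))

    def test_seeded_rebuild_gives_identical_outputs(self, tiny_config):
        x = np.random.default_rng(2).random((1, 1, 32, 32)).astype(np.float32)
        a = sr.build_unet_rcan(tiny_config)(Tensor(x)).data
        b = sr.build_unet_rcan(tiny_config)(Tensor(x)).data
        assert np.array_equal(a, b)

    def test_invalid_dims_rejected(self):
        with pytest.raises(ValueError):
            sr.NetworkConfig(dims=4)


class TestChannelAttention:
    def test_gate_bounded_by_sigmoid(self, tiny_config, rng):
        cab = ChannelAttentionBlock(8, tiny_config,
                                    np.random.default_rng(0))
        feat = Tensor(rng.standard_normal((1, 8, 16, 16)))
        gate = cab.attention(feat).data
        assert gate.shape == (1, 8, 1, 1)
        assert np.all((gate > 0) & (gate < 1))

    def test_zero_gate_passes_skip_path_only(self, tiny_config, rng):
        cab = ChannelAttentionBlock(8, tiny_config,
                                    np.random.default_rng(0))
        x = rng.standard_normal((1, 8, 16, 16))
        cab.frozen_gate = np.zeros((1, 8, 1, 1))
        assert np.array_equal(cab(Tensor(x)).data, x)
        cab.frozen_gate = None


class TestPredict:
    def test_full_image_tile_equals_direct(self, tiny_config, rng):
        model = sr.build_unet_rcan(tiny_config)
        img = rng.random((64, 64))
        direct = sr.predict(model, img)
        tiled = sr.predict(model, img, tile_shape=(64, 64), overlap=0)
        assert np.allclose(direct, tiled)

    def test_tiled_matches_direct_when_overlap_covers_context(self, tiny_config,
                                                              rng):
        model = sr.build_unet_rcan(tiny_config)
        img = rng.random((128, 128))
        direct = sr.predict(model, img)
        tiled = sr.predict(model, img, tile_shape=96, overlap=64)
        dev = np.abs(tiled - direct).max() / np.abs(direct).max()
        assert dev <= 1e-4

    def test_constant_input_periodic_interior(self, tiny_config):
        # stride-2 pooling/upsampling makes the net shift-invariant only to
        # multiples of 2^depth: constant input gives a 2^depth-periodic
        # interior, invariant under shifts by the pooling period
        model = sr.build_unet_rcan(tiny_config)
        out = sr.predict(model, np.ones((128, 128)))
        period = 2 ** tiny_config.unet_depth
        interior = out[40:-40, 40:-40]
        shifted = out[40 + period:-40 + period, 40 + period:-40 + period]
        assert np.allclose(interior, shifted, rtol=1e-6, atol=1e-6)

    def test_undersized_tile_rejected(self, tiny_config, rng):
        model = sr.build_unet_rcan(tiny_config)
        with pytest.raises(ValueError, match="divisible"):
            sr.predict(model, rng.random((64, 64)), tile_shape=30, overlap=8)

    def test_misaligned_step_rejected(self, tiny_config, rng):
        model = sr.build_unet_rcan(tiny_config)
        with pytest.raises(ValueError, match="multiple"):
            sr.predict(model, rng.random((128, 128)), tile_shape=64,
                       overlap=30)


class TestPersistence:
    def test_checkpoint_roundtrip(self, tiny_config, tmp_path, rng):
        model = sr.build_unet_rcan(tiny_config)
        model.save(tmp_path / "ckpt")
        clone = sr.UNetRCAN.load(tmp_path / "ckpt")
        x = rng.random((1, 1, 32, 32)).astype(np.float32)
        assert np.array_equal(model(Tensor(x)).data, clone(Tensor(x)).data)
        assert clone.config == tiny_config

    def test_state_dict_mismatch_rejected(self, tiny_config):
        model = sr.build_unet_rcan(tiny_config)
        state = model.state_dict()
        state.pop(next(iter(state)))
        with pytest.raises(KeyError):
            model.load_state_dict(state)
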