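"""Architecture modules: shapes, gates, channel growth, parameter counts."""

import numpy as np
import pytest

from ptxseg import NetworkConfig, build_network, count_parameters
from ptxseg.arch import (
    ChannelSE,
    DenseBlock,
    MultiScaleStem,
    ScSE,
    SpatialSE,
    TransitionDown,
    TransitionUp,
    cse_forward,
    dense_block_forward,
    multiscale_forward,
    scse_forward,
    sse_forward,
    transition_down_forward,
    transition_up_forward,
)
from ptxseg.config import BASELINE_CONFIG, FULL_CONFIG
from ptxseg.nn import Conv2d

RNG = np.random.default_rng(0)


def rng():
    return np.random.default_rng(42)


class TestMultiScaleStem:
    def test_output_channels_are_concatenated_branches(self):
        stem = MultiScaleStem(1, (3, 5, 7), 16, rng())
        out = multiscale_forward(RNG.random((64, 64, 1)), stem)
        assert out.shape == (64, 64, 48)

    def test_zero_weights_give_zero_output(self):
        stem = MultiScaleStem(1, (3, 5, 7), 4, rng())
        for branch in stem.branches:
            branch.w.v[...] = 0.0
            branch.b.v[...] = 0.0
        out = multiscale_forward(RNG.random((8, 8, 1)), stem)
        assert out.shape == (8, 8, 12)
        assert np.allclose(out, 0.0)

    def test_identity_center_kernel_reproduces_input(self):
        stem = MultiScaleStem(1, (3,), 1, rng())
        stem.branches[0].w.v[...] = 0.0
        stem.branches[0].w.v[0, 0, 1, 1] = 1.0
        stem.branches[0].b.v[...] = 0.0
        delta = np.zeros((5, 5, 1), dtype=np.float32)
        delta[2, 2, 0] = 1.0
        out = multiscale_forward(delta, stem)
        assert np.allclose(out, delta, atol=1e-6)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            MultiScaleStem(1, (3, 4), 8, rng())

    def test_empty_image_rejected(self):
        stem = MultiScaleStem(1, (3,), 2, rng())
        with pytest.raises(ValueError):
            stem.forward(np.zeros((1, 1, 0, 4), dtype=np.float32))


class TestDenseBlock:
    @pytest.mark.parametrize("c0,n_layers,k,expected", [
        (4, 2, 3, 10),    # 4 + 2*3
        (48, 4, 12, 96),  # 48 + 4*12
        (5, 3, 2, 11),
    ])
    def test_channel_growth_is_linear(self, c0, n_layers, k, expected):
        block = DenseBlock(c0, n_layers, k, 0.0, rng())
        u = RNG.random((6, 6, c0))
        out = dense_block_forward(u, block, include_input_in_output=True)
        assert out.shape == (6, 6, expected)
        new = dense_block_forward(u, block, include_input_in_output=False)
        assert new.shape == (6, 6, n_layers * k)

    def test_zero_layers_returns_input(self):
        block = DenseBlock(4, 0, 3, 0.0, rng())
        u = RNG.random((5, 5, 4))
        out = dense_block_forward(u, block, include_input_in_output=True)
        assert np.allclose(out, u)

    def test_input_occupies_leading_channels(self):
        block = DenseBlock(3, 2, 2, 0.0, rng())
        u = RNG.random((4, 4, 3)).astype(np.float32)
        out = dense_block_forward(u, block, include_input_in_output=True)
        assert np.allclose(out[:, :, :3], u, atol=1e-6)


class TestSqueezeExcitation:
    def test_sse_zero_logits_halve_input(self):
        sse = SpatialSE(3, rng())
        sse.conv.w.v[...] = 0.0
        sse.conv.b.v[...] = 0.0
        u = RNG.random((4, 4, 3)) - 0.5
        assert np.allclose(sse_forward(u, sse), 0.5 * u, atol=1e-6)

    def test_sse_hand_example(self):
        # u = [1, -1] with unit weights: projection 0, gate 0.5
        sse = SpatialSE(2, rng())
        sse.conv.w.v[...] = 1.0
        sse.conv.b.v[...] = 0.0
        u = np.array([[[1.0, -1.0]]])
        out = sse_forward(u, sse)
        assert np.allclose(out, [[[0.5, -0.5]]], atol=1e-6)

    def test_sse_saturates_to_identity(self):
        sse = SpatialSE(2, rng())
        sse.conv.w.v[...] = 100.0
        sse.conv.b.v[...] = 0.0
        u = np.abs(RNG.random((3, 3, 2))) + 0.1
        assert np.allclose(sse_forward(u, sse), u, atol=1e-4)

    def test_cse_zero_weights_halve_input(self):
        cse = ChannelSE(4, 2, rng())
        for p in cse.params():
            p.v[...] = 0.0
        u = RNG.random((4, 4, 4))
        assert np.allclose(cse_forward(u, cse), 0.5 * u, atol=1e-6)

    def test_cse_hand_example(self):
        # constant channels [1, 3]; W2 = [1, 0], W1 = [1, -1]^T:
        # z = [1, 3], hidden = 1, z_hat = [1, -1], gates [sigma(1), sigma(-1)]
        cse = ChannelSE(2, 2, rng())
        cse.fc.layers[0].w.v[...] = np.array([[1.0], [0.0]], dtype=np.float32)
        cse.fc.layers[0].b.v[...] = 0.0
        cse.fc.layers[2].w.v[...] = np.array([[1.0, -1.0]], dtype=np.float32)
        cse.fc.layers[2].b.v[...] = 0.0
        u = np.stack([np.ones((2, 2)), 3 * np.ones((2, 2))], axis=-1)
        out = cse_forward(u, cse)
        s1, sm1 = 1 / (1 + np.exp(-1.0)), 1 / (1 + np.exp(1.0))
        assert np.allclose(out[:, :, 0], s1, atol=1e-5)
        assert np.allclose(out[:, :, 1], 3 * sm1, atol=1e-5)

    def test_cse_channel_smaller_than_reduction_rejected(self):
        with pytest.raises(ValueError):
            ChannelSE(1, 2, rng())

    def test_scse_is_sum_of_branches(self):
        scse = ScSE(3, 2, rng())
        u = (RNG.random((1, 3, 5, 5)) - 0.5).astype(np.float32)
        total = scse.forward(u.copy())
        parts = scse.sse.forward(u.copy()) + scse.cse.forward(u.copy())
        assert np.allclose(total, parts, atol=1e-6)

    def test_scse_zero_logit_identity(self):
        scse = ScSE(3, 2, rng())
        for p in scse.params():
            p.v[...] = 0.0
        u = (RNG.random((4, 4, 3)) - 0.5)
        assert np.allclose(scse_forward(u, scse), u, atol=1e-6)

    def test_scse_output_bounded_by_twice_input(self):
        scse = ScSE(4, 2, rng())
        u = (RNG.random((6, 6, 4)) - 0.5)
        out = scse_forward(u, scse)
        assert (np.abs(out) <= 2 * np.abs(u) + 1e-6).all()


class TestTransitions:
    def test_down_halves_spatial_and_preserves_channels(self):
        td = TransitionDown(5, 0.0, rng())
        out = transition_down_forward(RNG.random((32, 32, 5)), td)
        assert out.shape == (16, 16, 5)

    def test_down_floor_semantics_on_odd_size(self):
        td = TransitionDown(2, 0.0, rng())
        out = transition_down_forward(RNG.random((7, 7, 2)), td)
        assert out.shape == (3, 3, 2)

    def test_down_rejects_degenerate_input(self):
        td = TransitionDown(2, 0.0, rng())
        with pytest.raises(ValueError):
            transition_down_forward(RNG.random((1, 4, 2)), td)

    def test_up_doubles_spatial(self):
        tu = TransitionUp(6, 6, rng())
        out = transition_up_forward(RNG.random((8, 8, 6)), tu)
        assert out.shape == (16, 16, 6)

    def test_up_zero_weights_zero_output(self):
        tu = TransitionUp(3, 3, rng())
        tu.tconv.w.v[...] = 0.0
        tu.tconv.b.v[...] = 0.0
        out = transition_up_forward(RNG.random((4, 4, 3)), tu)
        assert out.shape == (8, 8, 3)
        assert np.allclose(out, 0.0)

    def test_down_then_up_restores_even_spatial_size(self):
        td = TransitionDown(2, 0.0, rng())
        tu = TransitionUp(2, 2, rng())
        u = RNG.random((12, 12, 2))
        assert transition_up_forward(
            transition_down_forward(u, td), tu).shape == u.shape


@pytest.fixture(scope="module")
def small_net():
    cfg = NetworkConfig(growth_rate=3, layers_per_block=(2, 2), initial_channels=6,
                        in_channels=1, multiscale=True, ms_filters_per_branch=2,
                        scse=True, dropout=0.0)
    return build_network(cfg, seed=0)


class TestFullNetwork:
    def test_probabilities_sum_to_one(self, small_net):
        x = RNG.random((2, 1, 32, 32)).astype(np.float32)
        p = small_net.predict_proba(x)
        assert p.shape == (2, 2, 32, 32)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-6)

    def test_indivisible_spatial_size_rejected(self, small_net):
        with pytest.raises(ValueError):
            small_net.forward(np.zeros((1, 1, 31, 31), dtype=np.float32))

    def test_checkpoint_roundtrip(self, small_net, tmp_path):
        from ptxseg.arch import SegmentationNetwork
        x = RNG.random((1, 1, 32, 32)).astype(np.float32)
        before = small_net.predict_proba(x)
        small_net.save(tmp_path / "model.npz")
        loaded = SegmentationNetwork.load(tmp_path / "model.npz")
        assert count_parameters(loaded) == count_parameters(small_net)
        assert np.allclose(loaded.predict_proba(x), before, atol=1e-7)


class TestParameterCounts:
    def test_single_conv_by_hand(self):
        conv = Conv2d(1, 2, 3, rng())
        assert sum(p.size for p in conv.params()) == 3 * 3 * 1 * 2 + 2

    def test_toy_two_block_config_matches_manual_enumeration(self):
        # stem conv 3x3 1->4 (40); block1 layers: BN(2*4)+conv(3*3*4*2+2)=82,
        # BN(2*6)+conv(3*3*6*2+2)=122 -> out 8; TD: BN(16)+conv1x1(8*8+8)=88;
        # bottleneck: BN(16)+conv(3*3*8*2+2)=162, BN(20)+conv(3*3*10*2+2)=202
        # -> new 4; TU 3x3 4->4 (148); up block in 4+8=12:
        # BN(24)+conv(3*3*12*2+2)=242, BN(28)+conv(3*3*14*2+2)=282;
        # head 1x1 16->2 (34)
        cfg = NetworkConfig(growth_rate=2, layers_per_block=(2, 2), initial_channels=4,
                            in_channels=1, multiscale=False, scse=False, dropout=0.0)
        expected = 40 + 82 + 122 + 88 + 162 + 202 + 148 + 242 + 282 + 34
        assert count_parameters(build_network(cfg, seed=0)) == expected

    def test_baseline_backbone_parameter_count(self):
        assert count_parameters(build_network(BASELINE_CONFIG, seed=0)) == 5_415_278

    def test_full_network_has_about_ten_percent_more_parameters(self):
        base = count_parameters(build_network(BASELINE_CONFIG, seed=0))
        full = count_parameters(build_network(FULL_CONFIG, seed=0))
        assert full > base
        assert full / base - 1 == pytest.approx(0.105, abs=0.005)

    def test_empty_model_counts_zero(self):
        from ptxseg.nn import Sequential
        assert count_parameters(Sequential()) == 0
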