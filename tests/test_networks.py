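"""Attention operations vs dense-loop oracles; model shape/softmax contracts."""

import numpy as np
import pytest

from sarcoseg import autodiff as ad
from sarcoseg import networks as nw
from sarcoseg.errors import ValidationError


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def channel_attention_loops(f, w1, w2):
    """Explicit-loop channel gate: GAP -> W1 -> ReLU -> W2 -> sigmoid -> scale."""
    H, W, C = f.shape
    z = np.zeros(C)
    for k in range(C):
        for i in range(H):
            for j in range(W):
                z[k] += f[i, j, k]
        z[k] /= H * W
    hidden = np.zeros(w1.shape[0])
    for a in range(w1.shape[0]):
        for k in range(C):
            hidden[a] += w1[a, k] * z[k]
        hidden[a] = max(hidden[a], 0.0)
    zhat = np.zeros(C)
    for k in range(C):
        for a in range(w1.shape[0]):
            zhat[k] += w2[k, a] * hidden[a]
    out = np.zeros_like(f)
    for i in range(H):
        for j in range(W):
            for k in range(C):
                out[i, j, k] = sigmoid(zhat[k]) * f[i, j, k]
    return out


def spatial_attention_loops(f, ws):
    """Explicit-loop spatial gate: sigmoid(channel-max + 1x1 projection) -> scale."""
    H, W, C = f.shape
    out = np.zeros_like(f)
    for i in range(H):
        for j in range(W):
            q = 0.0
            p = f[i, j, 0]
            for k in range(C):
                q += ws[k] * f[i, j, k]
                p = max(p, f[i, j, k])
            g = sigmoid(p + q)
            for k in range(C):
                out[i, j, k] = g * f[i, j, k]
    return out


def random_gate_params(rng, c):
    return nw.FusionParams(
        channel=nw.ChannelGateParams(
            w1=rng.normal(size=(c // 2, c)), w2=rng.normal(size=(c, c // 2))
        ),
        spatial=nw.SpatialGateParams(ws=rng.normal(size=c)),
    )


class TestAttentionOracles:
    def test_channel_attention_matches_dense_loops(self):
        rng = np.random.default_rng(10)
        for _ in range(30):
            h, w, c = rng.integers(1, 5), rng.integers(1, 5), 2 * rng.integers(1, 5)
            f = rng.normal(size=(h, w, c))
            p = random_gate_params(rng, int(c))
            ours = nw.channel_attention(f, p.channel)
            oracle = channel_attention_loops(f, p.channel.w1, p.channel.w2)
            assert np.abs(ours - oracle).max() < 1e-6

    def test_spatial_attention_matches_dense_loops(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            h, w, c = rng.integers(1, 5), rng.integers(1, 5), rng.integers(1, 9)
            f = rng.normal(size=(h, w, c))
            ws = rng.normal(size=int(c))
            ours = nw.spatial_attention(f, nw.SpatialGateParams(ws=ws))
            oracle = spatial_attention_loops(f, ws)
            assert np.abs(ours - oracle).max() < 1e-6

    def test_fusion_composes_the_two_gates(self):
        rng = np.random.default_rng(12)
        for _ in range(10):
            maps = [rng.normal(size=(2, 2, 2)) for _ in range(3)]
            params = random_gate_params(rng, 6)
            fused = nw.attention_fusion(maps, params)
            f = np.concatenate(maps, axis=2)
            oracle = channel_attention_loops(
                f, params.channel.w1, params.channel.w2
            ) + spatial_attention_loops(f, params.spatial.ws)
            assert np.abs(fused - oracle).max() < 1e-6

    def test_zero_input_annihilates_all_ops(self):
        rng = np.random.default_rng(13)
        params = random_gate_params(rng, 4)
        z = np.zeros((3, 3, 4))
        assert not nw.channel_attention(z, params.channel).any()
        assert not nw.spatial_attention(z, params.spatial).any()
        assert not nw.attention_fusion([z[:, :, :2], z[:, :, 2:]], params).any()

    def test_zero_weights_give_half_gate(self):
        rng = np.random.default_rng(14)
        f = rng.normal(size=(4, 4, 6))
        params = nw.FusionParams(
            channel=nw.ChannelGateParams(w1=np.zeros((3, 6)), w2=np.zeros((6, 3))),
            spatial=nw.SpatialGateParams(ws=np.zeros(6)),
        )
        assert np.allclose(nw.channel_attention(f, params.channel), 0.5 * f)
        # spatial gate keeps the channel-max term: gate = sigmoid(p)
        p = f.max(axis=2, keepdims=True)
        assert np.allclose(nw.spatial_attention(f, params.spatial), sigmoid(p) * f)

    def test_single_channel_spatial_gate_closed_form(self):
        # C=1 with ws=[1]: p = q = F, so F_s = sigmoid(2F) * F.
        f = np.random.default_rng(15).normal(size=(3, 3, 1))
        fs = nw.spatial_attention(f, nw.SpatialGateParams(ws=np.ones(1)))
        assert np.allclose(fs, sigmoid(2 * f) * f)

    def test_neutral_gates_make_fusion_the_identity(self):
        # Zero gate weights give a 0.5 channel gate everywhere; choosing F so
        # that the channel-max is 0 at every position makes the spatial gate
        # 0.5 too, hence F_f = 0.5 F + 0.5 F = F.
        rng = np.random.default_rng(23)
        f = -np.abs(rng.normal(size=(4, 4, 2)))
        f[:, :, 0] = 0.0
        params = nw.FusionParams(
            channel=nw.ChannelGateParams(w1=np.zeros((1, 2)), w2=np.zeros((2, 1))),
            spatial=nw.SpatialGateParams(ws=np.zeros(2)),
        )
        assert np.allclose(nw.attention_fusion([f], params), f, atol=1e-12)

    def test_gates_bound_output_norms(self):
        rng = np.random.default_rng(16)
        f = rng.normal(size=(5, 5, 8))
        params = random_gate_params(rng, 8)
        fc = nw.channel_attention(f, params.channel)
        fs = nw.spatial_attention(f, params.spatial)
        ff = nw.attention_fusion([f[:, :, :4], f[:, :, 4:]], params)
        inf = np.abs(f).max()
        assert np.abs(fc).max() <= inf + 1e-12
        assert np.abs(fs).max() <= inf + 1e-12
        assert np.abs(ff).max() <= 2 * inf + 1e-12

    def test_fusion_is_spatially_permutation_covariant(self):
        rng = np.random.default_rng(17)
        maps = [rng.normal(size=(4, 3, 2)) for _ in range(2)]
        params = random_gate_params(rng, 4)
        perm_r = rng.permutation(4)
        perm_c = rng.permutation(3)
        fused = nw.attention_fusion(maps, params)
        fused_perm = nw.attention_fusion(
            [m[perm_r][:, perm_c] for m in maps], params
        )
        assert np.allclose(fused[perm_r][:, perm_c], fused_perm, atol=1e-12)

    def test_shape_mismatches_are_rejected(self):
        rng = np.random.default_rng(18)
        params = random_gate_params(rng, 4)
        with pytest.raises(ValidationError):
            nw.channel_attention(rng.normal(size=(2, 2, 6)), params.channel)
        with pytest.raises(ValidationError):
            nw.attention_fusion(
                [rng.normal(size=(2, 2, 2)), rng.normal(size=(3, 2, 2))], params
            )


class TestTrainableBlocksMatchFunctional:
    def test_fusion_block_forward_equals_functional_composition(self):
        rng = np.random.default_rng(19)
        model = nw.build_model(nw.ModelConfig(base_channels=4), seed=3)
        block = model.fusions[0]
        maps = [rng.normal(size=(1, 4, 5, 5)).astype(np.float32) for _ in range(3)]
        module_out = block([ad.constant(m) for m in maps]).data[0]
        functional_out = nw.attention_fusion(
            [m[0].transpose(1, 2, 0) for m in maps], block.functional_params()
        )
        assert np.abs(module_out.transpose(1, 2, 0) - functional_out).max() < 1e-5


class TestModelContracts:
    @pytest.mark.parametrize("variant", ["sunet", "munet", "ours"])
    def test_softmax_probabilities_sum_to_one(self, variant):
        model = nw.build_model(
            nw.ModelConfig(variant=variant, base_channels=4), seed=0
        )
        x = np.random.default_rng(20).normal(size=(3, 64, 64)).astype(np.float32)
        prob, pred = nw.forward_segment(model, x)
        assert prob.shape == (2, 64, 64)
        assert pred.shape == (64, 64)
        assert np.abs(prob.sum(axis=0) - 1.0).max() < 1e-5
        assert prob.min() >= 0.0 and prob.max() <= 1.0

    def test_encoder_feature_schedule(self):
        model = nw.build_model(nw.ModelConfig(base_channels=4), seed=0)
        x = np.zeros((1, 1, 64, 64), dtype=np.float32)
        skips, pooled = model.encoders[0](ad.constant(x))
        # channels double per level; resolution halves after each pool
        assert [s.shape for s in skips] == [
            (1, 4, 64, 64), (1, 8, 32, 32), (1, 16, 16, 16), (1, 32, 8, 8),
        ]
        assert pooled.shape == (1, 32, 4, 4)
        assert nw.ModelConfig().channel_schedule == [64, 128, 256, 512]
        assert nw.ModelConfig().bottleneck_channels == 1024

    def test_parameter_count_is_a_pure_function_of_config(self):
        cfg = nw.ModelConfig(variant="ours", base_channels=4)
        n1 = nw.count_parameters(nw.build_model(cfg, seed=0))
        n2 = nw.count_parameters(nw.build_model(cfg, seed=99))
        assert n1 == n2
        assert n1 != nw.count_parameters(
            nw.build_model(nw.ModelConfig(variant="munet", base_channels=4), seed=0)
        )

    def test_indivisible_spatial_size_rejected(self):
        model = nw.build_model(nw.ModelConfig(base_channels=4), seed=0)
        with pytest.raises(ValidationError, match="divisible"):
            model(np.zeros((1, 3, 60, 60), dtype=np.float32))

    def test_modality_count_mismatch_rejected(self):
        model = nw.build_model(nw.ModelConfig(base_channels=4), seed=0)
        with pytest.raises(ValidationError, match="modalities"):
            model(np.zeros((1, 2, 64, 64), dtype=np.float32))

    def test_inference_is_deterministic(self):
        model = nw.build_model(nw.ModelConfig(base_channels=4), seed=1)
        x = np.random.default_rng(21).normal(size=(3, 64, 64)).astype(np.float32)
        p1, _ = nw.forward_segment(model, x)
        p2, _ = nw.forward_segment(model, x)
        assert np.array_equal(p1, p2)

    def test_checkpoint_round_trip(self, tmp_path):
        model = nw.build_model(nw.ModelConfig(variant="ours", base_channels=4), seed=5)
        path = tmp_path / "ckpt.npz"
        nw.save_checkpoint(model, path, extra={"note": "unit"})
        loaded, extra = nw.load_checkpoint(path)
        assert extra == {"note": "unit"}
        x = np.random.default_rng(22).normal(size=(3, 64, 64)).astype(np.float32)
        p1, _ = nw.forward_segment(model, x)
        p2, _ = nw.forward_segment(loaded, x)
        assert np.array_equal(p1, p2)
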