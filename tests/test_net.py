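"""Architecture contracts: dimension chain (3,256) -> 2048 -> 2080 -> 128 ->
logit, ablation switch semantics, determinism, and checkpoint round trips."""

import numpy as np
import pytest

from dsfnet import net, nn
from dsfnet.net import (DSFNet, ModelConfig, NormStats, frames_to_model_inputs,
                        fuse_frame, upsample_pleth)


@pytest.fixture(scope="module")
def model():
    m = DSFNet(ModelConfig(seed=3))
    m.eval()
    return m


@pytest.fixture(scope="module")
def batch(rng_mod=np.random.default_rng(0)):
    wave = rng_mod.normal(size=(2, 15, 3, 256)).astype(np.float32)
    num = rng_mod.normal(size=(2, 15, 14)).astype(np.float32)
    return wave, num


class TestUpsamplePleth:
    def test_constant_stays_constant(self):
        out = upsample_pleth(np.full(60, 3.25))
        np.testing.assert_allclose(out, 3.25)
        assert out.shape == (256,)

    def test_endpoints_preserved_and_bounded(self, rng):
        x = rng.normal(size=60)
        out = upsample_pleth(x)
        assert out[0] == x[0] and out[-1] == x[-1]
        assert out.min() >= x.min() - 1e-12 and out.max() <= x.max() + 1e-12

    def test_linear_ramp_maps_to_collinear_ramp(self):
        x = np.linspace(0.0, 59.0, 60)
        out = upsample_pleth(x)
        expected = np.linspace(0.0, 59.0, 256)
        assert np.max(np.abs(out - expected)) < 1e-6

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError, match="60"):
            upsample_pleth(np.zeros(59))


class TestEncoders:
    def test_waveform_flatten_is_2048(self, model, rng):
        out = model.encode_waveform(rng.normal(size=(3, 3, 256)))
        assert out.shape == (3, 2048)

    def test_intermediate_conv_lengths_128_then_64(self, model):
        assert model.wave_enc.intermediate_lengths() == (128, 64)

    def test_numeric_embedding_is_32(self, model, rng):
        out = model.encode_numeric(rng.normal(size=(5, 14)))
        assert out.shape == (5, 32)

    def test_eval_mode_deterministic(self, model, rng):
        x = rng.normal(size=(2, 3, 256))
        a = model.encode_waveform(x).data
        b = model.encode_waveform(x).data
        np.testing.assert_array_equal(a, b)

    def test_distinct_inputs_distinct_embeddings(self, model, rng):
        x = rng.normal(size=(8, 14))
        y = rng.normal(size=(8, 14))
        out_x = model.encode_numeric(x).data
        out_y = model.encode_numeric(y).data
        assert np.abs(out_x - out_y).max() > 1e-6

    def test_shape_errors(self, model):
        with pytest.raises(ValueError):
            model.encode_waveform(np.zeros((2, 3, 255)))
        with pytest.raises(ValueError):
            model.encode_numeric(np.zeros((2, 13)))


class TestFusion:
    def test_fused_length_2080_and_slicing_inverse(self, rng):
        w = rng.normal(size=(4, 2048))
        v = rng.normal(size=(4, 32))
        fused = fuse_frame(w, v)
        assert fused.shape == (4, 2080)
        np.testing.assert_array_equal(fused[:, :2048], w)
        np.testing.assert_array_equal(fused[:, 2048:], v)

    def test_zero_fusion_is_zero(self):
        fused = fuse_frame(np.zeros((1, 2048)), np.zeros((1, 32)))
        np.testing.assert_array_equal(fused, 0.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            fuse_frame(np.zeros((1, 2047)), np.zeros((1, 32)))


class TestTemporalAndForward:
    def test_dimension_contract_chain(self, model, batch):
        wave, num = batch
        assert model.proj.weight.shape == (2080, 128)
        logits = model(wave, num)
        assert logits.shape == (2,)
        probs = 1 / (1 + np.exp(-logits.data))
        assert np.all((probs > 0) & (probs < 1))

    def test_wrong_window_length_rejected(self, model, rng):
        with pytest.raises(ValueError, match="T="):
            model(rng.normal(size=(1, 10, 3, 256)), rng.normal(size=(1, 10, 14)))

    def test_eval_determinism_full_forward(self, model, batch):
        wave, num = batch
        np.testing.assert_array_equal(model(wave, num).data, model(wave, num).data)

    def test_identical_tokens_rotation_invariant_without_positional_encoding(self, rng):
        m = DSFNet(ModelConfig(use_positional_encoding=False, seed=5))
        m.eval()
        frame_w = rng.normal(size=(1, 1, 3, 256)).astype(np.float32)
        frame_n = rng.normal(size=(1, 1, 14)).astype(np.float32)
        wave = np.repeat(frame_w, 15, axis=1)
        num = np.repeat(frame_n, 15, axis=1)
        base = m(wave, num).data
        rolled = m(np.roll(wave, 4, axis=1), np.roll(num, 4, axis=1)).data
        np.testing.assert_allclose(base, rolled, atol=1e-5)

    def test_ablation_no_temporal_fusion_ignores_early_frames(self, rng):
        m = DSFNet(ModelConfig(use_temporal_fusion=False, seed=5))
        m.eval()
        wave = rng.normal(size=(1, 15, 3, 256)).astype(np.float32)
        num = rng.normal(size=(1, 15, 14)).astype(np.float32)
        base = m(wave, num).data
        wave2, num2 = wave.copy(), num.copy()
        wave2[:, :14] = rng.normal(size=(1, 14, 3, 256))
        num2[:, :14] = rng.normal(size=(1, 14, 14))
        np.testing.assert_allclose(m(wave2, num2).data, base, atol=1e-6)

    def test_ablation_no_waveform_branch_ignores_waveforms(self, rng):
        m = DSFNet(ModelConfig(use_waveform_branch=False, seed=5))
        m.eval()
        wave = rng.normal(size=(1, 15, 3, 256)).astype(np.float32)
        num = rng.normal(size=(1, 15, 14)).astype(np.float32)
        base = m(wave, num).data
        wave2 = rng.normal(size=(1, 15, 3, 256)).astype(np.float32)
        np.testing.assert_allclose(m(wave2, num).data, base, atol=1e-6)
        assert m.cfg.fused_dim == 32

    def test_temporal_forward_accepts_prefused_frames(self, model, rng):
        fused = rng.normal(size=(3, 15, 2080)).astype(np.float32)
        out = model.temporal_forward(fused)
        assert out.shape == (3,)


class TestTrainingPlumbing:
    def test_every_parameter_receives_gradient(self, rng):
        """Dead-branch guard: one synthetic batch reaches all weights."""
        m = DSFNet(ModelConfig(seed=9))
        m.train()
        wave = rng.normal(size=(4, 15, 3, 256)).astype(np.float32)
        num = rng.normal(size=(4, 15, 14)).astype(np.float32)
        loss = (m(wave, num) ** 2).sum()
        loss.backward()
        for name, p in m.named_parameters():
            assert p.grad is not None and np.any(p.grad != 0), f"dead parameter {name}"

    def test_parameter_count_invariant_to_batch_and_content(self, rng):
        m = DSFNet(ModelConfig(seed=1))
        n0 = m.n_parameters()
        m.eval()
        m(rng.normal(size=(1, 15, 3, 256)), rng.normal(size=(1, 15, 14)))
        m(rng.normal(size=(6, 15, 3, 256)), rng.normal(size=(6, 15, 14)))
        assert m.n_parameters() == n0
        assert DSFNet(ModelConfig(seed=99)).n_parameters() == n0

    def test_invalid_conv_plan_rejected(self):
        with pytest.raises(ValueError, match="2048"):
            ModelConfig(conv_channels=(16, 16))
        with pytest.raises(ValueError, match="divisible"):
            ModelConfig(n_heads=7)

    def test_norm_stats_required_for_prediction(self, model, rng):
        frames = rng.normal(size=(1, 15, 587)).astype(np.float32)
        with pytest.raises(RuntimeError, match="normalization"):
            model.predict_proba(frames, NormStats())

    def test_checkpoint_round_trip(self, tmp_path, rng):
        m = DSFNet(ModelConfig(seed=4))
        m.eval()
        frames = rng.normal(size=(3, 15, 587)).astype(np.float32)
        norm = NormStats.fit(frames.reshape(-1, 587))
        p0 = m.predict_proba(frames, norm)
        net.save_checkpoint(tmp_path / "ck.npz", m, norm, extra={"k": 1})
        m2, norm2, extra = net.load_checkpoint(tmp_path / "ck.npz")
        assert extra == {"k": 1}
        np.testing.assert_allclose(m2.predict_proba(frames, norm2), p0, atol=1e-7)

    def test_frames_to_model_inputs_layout(self, rng):
        frames = rng.normal(size=(2, 15, 587)).astype(np.float32)
        wave, num = frames_to_model_inputs(frames)
        assert wave.shape == (2, 15, 3, 256) and num.shape == (2, 15, 14)
        np.testing.assert_array_equal(num, frames[..., 1:15])
        np.testing.assert_array_equal(wave[..., 0, :], frames[..., 15:271])
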