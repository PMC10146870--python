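"""Architecture contracts: serialization order, attention normalization and
equivariance, pooling/unpooling round trips, residual identities, shape
conservation and gradient flow."""

import numpy as np
import pytest

from octseg import nn
from octseg.losses import LossConfig, loss_from_logits
from octseg.model import (
    ConfigError,
    GeometryError,
    ModelConfig,
    MultiHeadConvAttention,
    PatchSerializer,
    SegmentationModel,
    TransformerBlock,
    build_model,
    scaled_dot_product_attention,
)
from octseg.nn import Tensor


def tiny_config(**kw):
    base = dict(in_channels=1, n_classes=4, encoder_channels=(4, 8),
                vit_dim=8, vit_heads=2, vit_blocks=1, vit_mlp_dim=8,
                patch_size=2, attention_kernel=3)
    base.update(kw)
    return ModelConfig(**base)


# ---- configuration -----------------------------------------------------------

def test_build_determinism():
    cfg = tiny_config()
    m1 = build_model(cfg, seed=5)
    m2 = build_model(cfg, seed=5)
    s1, s2 = m1.state_dict(), m2.state_dict()
    assert s1.keys() == s2.keys()
    for k in s1:
        np.testing.assert_array_equal(s1[k], s2[k])


def test_head_divisibility_error():
    with pytest.raises(ConfigError, match="divisible"):
        build_model(ModelConfig(vit_heads=7, vit_dim=128))


def test_geometry_errors():
    m = build_model(tiny_config(), seed=0)
    with pytest.raises(GeometryError, match="divisible"):
        m.forward(np.zeros((1, 1, 15, 16), dtype=np.float32))
    # bottleneck not divisible by patch size
    cfg = tiny_config(patch_size=4)
    m2 = build_model(cfg, seed=0)
    with pytest.raises(GeometryError):
        m2.forward(np.zeros((1, 1, 4, 4), dtype=np.float32))


def test_parameter_count_reported():
    m = build_model(tiny_config(), seed=0)
    assert m.n_parameters() == sum(p.size for p in m.parameters()) > 0


# ---- serialization -----------------------------------------------------------

def test_serialize_identity_embedding_raster_order():
    rng = np.random.default_rng(0)
    ser = PatchSerializer(channels=1, patch_size=1, dim=1, rng=rng)
    ser.embed.weight.data = np.eye(1, dtype=np.float32)
    ser.embed.bias.data = np.zeros(1, dtype=np.float32)
    f = np.arange(4, dtype=np.float32).reshape(1, 1, 2, 2)
    seq = ser.serialize(Tensor(f))
    # raster order: (0,0), (0,1), (1,0), (1,1)
    np.testing.assert_allclose(seq.tokens.data[0, :, 0], [0, 1, 2, 3])
    assert seq.grid == (2, 2)


def test_token_count_from_patch_size():
    rng = np.random.default_rng(1)
    ser = PatchSerializer(channels=3, patch_size=16, dim=8, rng=rng)
    f = Tensor(np.zeros((1, 3, 32, 32), dtype=np.float32))
    assert ser.serialize(f).tokens.shape[1] == 4  # (32/16)^2
    ser_cls = PatchSerializer(channels=3, patch_size=16, dim=8, rng=rng,
                              use_class_token=True)
    assert ser_cls.serialize(f).tokens.shape[1] == 5


def test_serialize_deserialize_round_trip():
    """With an invertible embedding, deserialize(serialize(F)) == F."""
    rng = np.random.default_rng(2)
    ser = PatchSerializer(channels=2, patch_size=2, dim=8, rng=rng)
    w = rng.normal(size=(8, 8))
    ser.embed.weight.data = w.astype(np.float64)
    ser.embed.bias.data = np.zeros(8)
    ser.unembed.weight.data = np.linalg.inv(w)
    ser.unembed.bias.data = np.zeros(8)
    f = rng.normal(size=(2, 2, 4, 6))
    out = ser.deserialize(ser.serialize(Tensor(f)))
    np.testing.assert_allclose(out.data, f, atol=1e-10)


# ---- attention ---------------------------------------------------------------

def test_attention_rows_sum_to_one():
    rng = np.random.default_rng(3)
    q = Tensor(rng.normal(size=(2, 9, 4)))
    k = Tensor(rng.normal(size=(2, 9, 4)))
    scores = nn.matmul(q, nn.transpose(k, (0, 2, 1))) * (1 / 2.0)
    a = nn.softmax(scores, axis=-1)
    np.testing.assert_allclose(a.data.sum(axis=-1), 1.0, atol=1e-6)


def test_single_token_attention_returns_v():
    rng = np.random.default_rng(4)
    q = Tensor(rng.normal(size=(1, 1, 4)))
    k = Tensor(rng.normal(size=(1, 1, 4)))
    v = Tensor(rng.normal(size=(1, 1, 4)))
    out = scaled_dot_product_attention(q, k, v)
    np.testing.assert_allclose(out.data, v.data, atol=1e-12)


def test_attention_hand_example():
    """n=2, d_h=1, Q=(1,0), K=(1,0), V=(2,4): direct softmax(QK^T/1)V."""
    q = Tensor(np.array([[[1.0], [0.0]]]))
    k = Tensor(np.array([[[1.0], [0.0]]]))
    v = Tensor(np.array([[[2.0], [4.0]]]))
    out = scaled_dot_product_attention(q, k, v)
    e = np.e
    row0 = (e * 2 + 1 * 4) / (e + 1)   # scores (1, 0)
    row1 = (1 * 2 + 1 * 4) / 2         # scores (0, 0)
    np.testing.assert_allclose(out.data[0, :, 0], [row0, row1], atol=1e-6)


def test_multi_head_matches_longhand_oracle():
    """h=2 with 1x1 kernels: split, per-head linear Q/K/V, softmax, concat,
    mix -- all evaluated longhand in numpy from the module's own weights."""
    rng = np.random.default_rng(5)
    mha = MultiHeadConvAttention(dim=4, heads=2, kernel=1, rng=rng)
    x = rng.normal(size=(1, 6, 4)).astype(np.float32)
    out = mha(Tensor(x), grid=(2, 3)).data

    expected_heads = []
    for i, head in enumerate(mha.heads):
        xi = x[0, :, 2 * i:2 * i + 2]                     # (n, d_h)
        def lin(conv, t):
            w = conv.weight.data[:, :, 0, 0]              # (out, in)
            return t @ w.T + conv.bias.data
        q, k, v = lin(head.q_conv, xi), lin(head.k_conv, xi), lin(head.v_conv, xi)
        scores = q @ k.T / np.sqrt(2)
        a = np.exp(scores - scores.max(axis=1, keepdims=True))
        a /= a.sum(axis=1, keepdims=True)
        expected_heads.append(a @ v)
    concat = np.concatenate(expected_heads, axis=1)
    expected = concat @ mha.mix.weight.data + mha.mix.bias.data
    np.testing.assert_allclose(out[0], expected, atol=1e-5)


def test_output_token_count_preserved():
    rng = np.random.default_rng(6)
    mha = MultiHeadConvAttention(dim=4, heads=2, kernel=3, rng=rng)
    x = Tensor(np.random.default_rng(0).normal(size=(2, 12, 4)).astype(np.float32))
    assert mha(x, grid=(3, 4)).shape == (2, 12, 4)


def test_permutation_equivariance_with_1x1_kernels():
    """Without positional encoding and with 1x1 projections the attention
    stack commutes with any token permutation."""
    rng = np.random.default_rng(7)
    block = TransformerBlock(dim=4, heads=2, mlp_dim=8, kernel=1, rng=rng)
    x = np.random.default_rng(1).normal(size=(1, 12, 4)).astype(np.float64)
    perm = np.random.default_rng(2).permutation(12)
    out = block(Tensor(x), grid=(3, 4)).data
    out_perm = block(Tensor(x[:, perm]), grid=(3, 4)).data
    np.testing.assert_allclose(out_perm, out[:, perm], atol=1e-10)


def test_transformer_zero_branch_identity():
    rng = np.random.default_rng(8)
    block = TransformerBlock(dim=4, heads=2, mlp_dim=8, kernel=3, rng=rng)
    block.attn.mix.weight.data[:] = 0
    block.attn.mix.bias.data[:] = 0
    block.mlp_out.weight.data[:] = 0
    block.mlp_out.bias.data[:] = 0
    x = np.random.default_rng(3).normal(size=(1, 6, 4))
    out = block(Tensor(x), grid=(2, 3))
    np.testing.assert_allclose(out.data, x, atol=1e-12)


def test_transformer_matches_composition_oracle():
    rng = np.random.default_rng(9)
    block = TransformerBlock(dim=4, heads=2, mlp_dim=8, kernel=3, rng=rng)
    x = Tensor(np.random.default_rng(4).normal(size=(1, 6, 4)).astype(np.float32))
    full = block(x, grid=(2, 3)).data
    # longhand: norm -> MHA -> add -> norm -> MLP -> add
    y = x + block.attn(block.norm1(x), (2, 3))
    z = y + block.mlp_out(nn.relu(block.mlp_in(block.norm2(y))))
    np.testing.assert_allclose(full, z.data, atol=1e-5)


def test_vit_blocks_applied_stack_depth_times(monkeypatch):
    cfg = tiny_config(vit_blocks=3)
    m = build_model(cfg, seed=0)
    calls = []
    for b in m.vit.blocks:
        orig = b.forward
        def wrapped(tokens, grid, has_class_token=False, _o=orig):
            calls.append(1)
            return _o(tokens, grid, has_class_token)
        b.forward = wrapped
    m.predict_proba(np.zeros((8, 8), dtype=np.float32))
    assert len(calls) == 3


# ---- pooling / unpooling -----------------------------------------------------

def test_pool_indices_match_window_scan():
    rng = np.random.default_rng(10)
    x = rng.permutation(64).astype(np.float64).reshape(1, 1, 8, 8)
    out, idx = nn.max_pool2d(Tensor(x))
    for r in range(4):
        for c in range(4):
            window = x[0, 0, 2 * r:2 * r + 2, 2 * c:2 * c + 2]
            flat = window.ravel()
            assert out.data[0, 0, r, c] == flat.max()
            assert idx[0, 0, r, c] == flat.argmax()


def test_unpool_restores_maxima_positions():
    x = np.arange(16, dtype=np.float64).reshape(1, 1, 4, 4)
    pooled, idx = nn.max_pool2d(Tensor(x))
    restored = nn.max_unpool2d(pooled, idx).data[0, 0]
    expected = np.zeros((4, 4))
    for r in range(2):
        for c in range(2):
            win = x[0, 0, 2 * r:2 * r + 2, 2 * c:2 * c + 2]
            rr, cc = np.unravel_index(win.argmax(), (2, 2))
            expected[2 * r + rr, 2 * c + cc] = win.max()
    np.testing.assert_array_equal(restored, expected)


def test_unpool_requires_matching_indices():
    with pytest.raises(ValueError, match="indices"):
        nn.max_unpool2d(Tensor(np.zeros((1, 1, 4, 4))),
                        np.zeros((1, 1, 2, 2), dtype=int))


# ---- full model --------------------------------------------------------------

def test_forward_shape_and_probability_normalization():
    cfg = tiny_config()
    m = build_model(cfg, seed=1)
    img = np.random.default_rng(5).random((16, 16)).astype(np.float32)
    probs = m.predict_proba(img)
    assert probs.shape == (4, 16, 16)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-6)
    assert (probs >= 0).all()


def test_encoder_bottleneck_extent():
    cfg = tiny_config(encoder_channels=(4, 8, 8))
    m = build_model(cfg, seed=0)
    state = m.encode(Tensor(np.zeros((1, 1, 32, 32), dtype=np.float32)))
    assert state.bottleneck.shape[2:] == (8, 8)  # two halvings
    assert len(state.pool_indices) == 1


def test_inference_deterministic():
    m = build_model(tiny_config(), seed=2)
    img = np.random.default_rng(6).random((16, 16)).astype(np.float32)
    np.testing.assert_array_equal(m.predict_proba(img), m.predict_proba(img))


def test_default_config_shape_contract():
    """Default architecture on a 256x256 scan emits (9, 256, 256) probs."""
    m = build_model(ModelConfig(), seed=0)
    img = np.random.default_rng(7).random((256, 256)).astype(np.float32)
    probs = m.predict_proba(img)
    assert probs.shape == (9, 256, 256)
    np.testing.assert_allclose(probs.sum(axis=0), 1.0, atol=1e-5)


def test_gradient_flows_to_every_parameter():
    """The compound loss has a non-zero gradient for every trainable group:
    no dead path through the transformer bottleneck."""
    cfg = tiny_config()
    m = build_model(cfg, seed=3)
    rng = np.random.default_rng(8)
    img = rng.random((1, 1, 16, 16)).astype(np.float32)
    labels = rng.integers(0, 4, size=(1, 16, 16))
    logits = m.forward(img)
    loss, _, _ = loss_from_logits(logits, labels, LossConfig())
    loss.backward()
    for name, p in m.named_parameters():
        assert p.grad is not None, f"no gradient reached {name}"
        assert np.any(p.grad != 0), f"zero gradient at {name}"


def test_class_token_path_shapes():
    cfg = tiny_config(use_class_token=True)
    m = build_model(cfg, seed=0)
    probs = m.predict_proba(np.zeros((16, 16), dtype=np.float32))
    assert probs.shape == (4, 16, 16)
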