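"""Bottleneck transformer: serialization bookkeeping, residual structure,
attention normalization and equivariance properties."""

import numpy as np
import pytest

from anisoseg.errors import ConfigError, ShapeError
from anisoseg.nd.tensor import Tensor
from anisoseg.transformer import (Deserializer, MultiHeadSelfAttention,
                                  PositionEmbedding, ResDualAttention,
                                  ResTransBlock, Serializer, TransformerConfig,
                                  TransformerLayer)

RNG = np.random.default_rng(55)


def _x(shape):
    return Tensor(RNG.normal(size=shape).astype(np.float32))


def small_cfg(M=1, H=2, h=16, C3=12, C2=6):
    return TransformerConfig(M=M, H=H, h=h, C3=C3, C2=C2)


class TestSerialization:
    def test_token_shape_arithmetic(self):
        ser = Serializer(6, 12, rng=np.random.default_rng(0))
        tokens, dims = ser(_x((2, 6, 2, 3, 4)))
        assert tokens.shape == (2, 24, 12) and dims == (2, 3, 4)

    def test_default_plan_token_count_is_1024(self):
        """256 x 4 x 16 x 16 bottleneck input -> 1024 tokens of width 512."""
        from conftest import tiny_network_config
        from anisoseg.models import NetworkConfig
        cfg = NetworkConfig()  # full-size default plan
        assert cfg.stage_dims(5) == (4, 16, 16)
        assert int(np.prod(cfg.stage_dims(5))) == 1024
        assert cfg.transformer.C3 == 512 and cfg.transformer.C2 == 256

    def test_degenerate_single_token(self):
        ser = Serializer(6, 12, rng=np.random.default_rng(0))
        tokens, dims = ser(_x((1, 6, 1, 1, 1)))
        assert tokens.shape == (1, 1, 12)

    def test_roundtrip_restores_position_tagged_map(self):
        """With identity 1x1 projections, deserialize(serialize(x)) - x = x,
        i.e. the token index <-> (d,h,w) raster bijection is exact."""
        c = 5
        ser = Serializer(c, c, rng=np.random.default_rng(1))
        des = Deserializer(c, c, rng=np.random.default_rng(2))
        eye = np.eye(c, dtype=np.float32).reshape(c, c, 1, 1, 1)
        ser.proj.weight.data = eye.copy()
        ser.proj.bias.data[...] = 0
        des.proj.weight.data = eye.copy()
        des.proj.bias.data[...] = 0
        # position-tagged input: value encodes (d, h, w)
        d, h, w = 2, 3, 4
        tag = (np.arange(d)[:, None, None] * 10000
               + np.arange(h)[None, :, None] * 100
               + np.arange(w)[None, None, :]).astype(np.float32)
        x = Tensor(np.broadcast_to(tag, (1, c, d, h, w)).copy())
        tokens, dims = ser(x)
        out = des(tokens, x)  # deserialize adds the residual input
        np.testing.assert_allclose(out.data, 2 * x.data, rtol=1e-6)

    def test_provenance_mismatch_is_shape_error(self):
        des = Deserializer(4, 4, rng=np.random.default_rng(0))
        with pytest.raises(ShapeError):
            des(_x((1, 10, 4)), _x((1, 4, 2, 2, 2)))


class TestPositionEmbedding:
    def test_zero_embedding_is_identity(self):
        pe = PositionEmbedding(6, 4, rng=np.random.default_rng(0))
        pe.pe.data[...] = 0.0
        z = _x((2, 6, 4))
        np.testing.assert_array_equal(pe(z).data, z.data)

    def test_shape_mismatch_rejected(self):
        pe = PositionEmbedding(6, 4, rng=np.random.default_rng(0))
        with pytest.raises(ConfigError):
            pe(_x((2, 8, 4)))

    def test_distinct_rows_break_permutation_equivariance(self):
        pe = PositionEmbedding(6, 4, rng=np.random.default_rng(3))
        z = _x((1, 6, 4))
        perm = np.random.default_rng(1).permutation(6)
        before = pe(Tensor(z.data[:, perm])).data
        after = pe(z).data[:, perm]
        assert not np.allclose(before, after)


class TestTransformerLayer:
    def test_zeroed_output_projections_give_exact_identity(self):
        """Residual form of the two sublayers: zero MSA and MLP outputs
        leave z_m = z_{m-1} exactly."""
        layer = TransformerLayer(small_cfg(), rng=np.random.default_rng(4))
        layer.msa.wo.weight.data[...] = 0
        layer.msa.wo.bias.data[...] = 0
        layer.fc2.weight.data[...] = 0
        layer.fc2.bias.data[...] = 0
        z = _x((2, 5, 12))
        np.testing.assert_array_equal(layer(z).data, z.data)

    def test_head_dimension_from_paper_defaults(self):
        msa = MultiHeadSelfAttention(512, 8, rng=np.random.default_rng(0))
        assert msa.head_dim == 64

    def test_attention_rows_sum_to_one(self):
        msa = MultiHeadSelfAttention(12, 2, rng=np.random.default_rng(5))
        _, attn = msa(_x((2, 7, 12)), return_attention=True)
        np.testing.assert_allclose(attn.data.sum(axis=-1), 1.0, atol=1e-5)

    def test_layer_commutes_with_token_permutation(self):
        """Without a position embedding, self-attention + per-token MLP is
        permutation-equivariant."""
        layer = TransformerLayer(small_cfg(), rng=np.random.default_rng(6))
        z = _x((1, 8, 12))
        perm = np.random.default_rng(2).permutation(8)
        out_then_perm = layer(z).data[:, perm]
        perm_then_out = layer(Tensor(z.data[:, perm])).data
        np.testing.assert_allclose(perm_then_out, out_then_perm, atol=1e-4)

    def test_single_head_no_ln_matches_closed_form_on_two_tokens(self):
        """With LN disabled the layer is the textbook residual attention;
        compare against a direct NumPy evaluation of the closed form."""
        cfg = small_cfg(H=1, h=8, C3=4)
        layer = TransformerLayer(cfg, rng=np.random.default_rng(7))
        layer.ln1.gamma.data[...] = 1.0
        layer.ln1.beta.data[...] = 0.0
        layer.ln2.gamma.data[...] = 1.0
        layer.ln2.beta.data[...] = 0.0

        class _Identity:
            def __call__(self, t):
                return t
        layer.ln1 = _Identity()
        layer.ln2 = _Identity()

        z = RNG.normal(size=(1, 2, 4)).astype(np.float32)

        def lin(p, v):
            return v @ p.weight.data.T + p.bias.data

        q, k, v = lin(layer.msa.wq, z), lin(layer.msa.wk, z), lin(layer.msa.wv, z)
        scores = (q @ k.transpose(0, 2, 1)) / np.sqrt(4)
        e = np.exp(scores - scores.max(axis=-1, keepdims=True))
        attn = e / e.sum(axis=-1, keepdims=True)
        z_star = lin(layer.msa.wo, attn @ v) + z
        hidden = lin(layer.fc1, z_star)
        hidden = np.where(hidden > 0, hidden, 0.01 * hidden)
        expected = lin(layer.fc2, hidden) + z_star
        np.testing.assert_allclose(layer(Tensor(z)).data, expected, atol=1e-5)


class TestResDualAttention:
    def test_composed_shape_arithmetic(self):
        """Stage-4 features 16 x 4 x 8 x 8 -> bottleneck 8 x 2 x 4 x 4."""
        cfg = small_cfg(M=2, C2=8)
        rda = ResDualAttention(16, cfg, stage5_dims=(2, 4, 4),
                               rng=np.random.default_rng(8))
        out = rda(_x((1, 16, 4, 8, 8)))
        assert out.shape == (1, 8, 2, 4, 4)

    def test_gradient_reaches_pe_and_all_layers(self):
        cfg = small_cfg(M=2, C2=8)
        rda = ResDualAttention(16, cfg, stage5_dims=(2, 4, 4),
                               rng=np.random.default_rng(9))
        rda(_x((1, 16, 4, 8, 8))).sum().backward()
        for name, p in rda.named_parameters():
            assert p.grad is not None, name
            assert np.abs(p.grad).sum() > 0, name

    def test_identity_transformer_preserves_shape(self):
        cfg = small_cfg(M=2)
        blk = ResTransBlock(cfg, n_tokens=8, rng=np.random.default_rng(10))
        for layer in blk.layers:
            layer.msa.wo.weight.data[...] = 0
            layer.msa.wo.bias.data[...] = 0
            layer.fc2.weight.data[...] = 0
            layer.fc2.bias.data[...] = 0
        x = _x((1, 6, 2, 2, 2))
        out = blk(x)
        assert out.shape == x.shape
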