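"""Architecture contracts: attention/C-FFN oracles on tiny inputs,
row-stochasticity, permutation sensitivity, and branch independence."""

import numpy as np
import pytest

from ghtnet.autodiff import Tensor
from ghtnet.model import (GHTNet, GHTNetConfig, MultiHeadSelfAttention, CFFN,
                          EncoderBlock, LayerNorm)


def brute_force_attention(x, wq, bq, wk, bk, wv, bv, wo, bo, h):
    """Scalar-level scaled dot-product attention for the oracle."""
    n, d = x.shape
    dh = d // h
    q, k, v = x @ wq + bq, x @ wk + bk, x @ wv + bv
    out = np.zeros((n, d))
    maps = []
    for head in range(h):
        sl = slice(head * dh, (head + 1) * dh)
        qs, ks, vs = q[:, sl], k[:, sl], v[:, sl]
        scores = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                scores[i, j] = qs[i] @ ks[j] / np.sqrt(dh)
        A = np.exp(scores - scores.max(axis=1, keepdims=True))
        A /= A.sum(axis=1, keepdims=True)
        maps.append(A)
        out[:, sl] = A @ vs
    return out @ wo + bo, np.stack(maps)


class TestAttention:
    def test_rows_stochastic_every_head(self, rng):
        att = MultiHeadSelfAttention(8, 4, rng)
        x = Tensor(rng.normal(size=(2, 7, 8)).astype(np.float32))
        _, maps = att(x)
        assert maps.shape == (2, 4, 7, 7)
        assert (maps >= 0).all()
        np.testing.assert_allclose(maps.sum(axis=-1), 1.0, atol=1e-5)

    def test_single_token_attends_to_itself(self, rng):
        att = MultiHeadSelfAttention(4, 2, rng)
        x = Tensor(rng.normal(size=(1, 1, 4)).astype(np.float32))
        out, maps = att(x)
        np.testing.assert_allclose(maps, 1.0, atol=1e-6)
        # output equals value projection of the single token
        v = x.data[0] @ att.wv.W.data + att.wv.b.data
        np.testing.assert_allclose(out.data[0],
                                   v @ att.wo.W.data + att.wo.b.data,
                                   atol=1e-5)

    def test_matches_brute_force_oracle_on_three_tokens(self, rng):
        att = MultiHeadSelfAttention(6, 2, rng)
        x = rng.normal(size=(1, 3, 6)).astype(np.float32)
        out, maps = att(Tensor(x))
        expected, exp_maps = brute_force_attention(
            x[0].astype(np.float64),
            att.wq.W.data, att.wq.b.data, att.wk.W.data, att.wk.b.data,
            att.wv.W.data, att.wv.b.data, att.wo.W.data, att.wo.b.data, h=2)
        np.testing.assert_allclose(out.data[0], expected, atol=1e-5)
        np.testing.assert_allclose(maps[0], exp_maps, atol=1e-5)

    def test_width_must_divide_heads(self):
        with pytest.raises(ValueError, match="divisible"):
            GHTNetConfig(d=10, n_heads=4)


class TestCFFN:
    def test_output_shape_equals_input_shape(self, rng):
        cffn = CFFN(5, 9, 3, rng)
        for n in (1, 4, 13):
            x = Tensor(rng.normal(size=(2, n, 5)).astype(np.float32))
            assert cffn(x).shape == (2, n, 5)

    def test_kernel_one_identity_conv_reduces_to_plain_ffn(self, rng):
        cffn = CFFN(4, 6, 1, rng)
        cffn.conv.W.data = np.eye(6, dtype=np.float32)[None]  # (1, 6, 6)
        cffn.conv.b.data = np.zeros(6, dtype=np.float32)
        x = rng.normal(size=(1, 5, 4)).astype(np.float32)
        out = cffn(Tensor(x))
        h = x @ cffn.lin1.W.data + cffn.lin1.b.data
        plain = np.maximum(h, 0) @ cffn.lin2.W.data + cffn.lin2.b.data
        np.testing.assert_allclose(out.data, plain, atol=1e-5)

    def test_matches_sliding_window_oracle(self, rng):
        cffn = CFFN(3, 4, 3, rng)
        x = rng.normal(size=(1, 4, 3)).astype(np.float32)
        out = cffn(Tensor(x))
        h = x[0] @ cffn.lin1.W.data + cffn.lin1.b.data        # (4, 4)
        hp = np.vstack([np.zeros(4), h, np.zeros(4)])
        conv = np.zeros_like(h)
        for i in range(4):
            for j in range(3):
                conv[i] += hp[i + j] @ cffn.conv.W.data[j]
        conv += cffn.conv.b.data
        expected = np.maximum(conv, 0) @ cffn.lin2.W.data + cffn.lin2.b.data
        np.testing.assert_allclose(out.data[0], expected, atol=1e-5)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            GHTNetConfig(cffn_kernel=4)


class TestEncoderStack:
    def test_collects_maps_from_every_layer_and_head(self, tiny_config, rng):
        cfg = GHTNetConfig(d=8, n_heads=4, n_layers=2, cffn_hidden=8,
                           n_detectors=4, detector_width=5)
        m = GHTNet(cfg, seed=0)
        x = rng.normal(size=(3, 12, 8)).astype(np.float32)
        _, attn, _ = m.forward(x)
        maps = attn["sequence"]
        assert len(maps) == 2                       # layers
        assert maps[0].shape == (3, 4, 12, 12)      # heads per layer

    def test_single_layer_equals_one_block(self, rng):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=8,
                           n_detectors=4, detector_width=5)
        m = GHTNet(cfg, seed=3)
        block = m.seq_branch.blocks[0]
        x = rng.normal(size=(2, 6, 8)).astype(np.float32)
        direct, _ = block(Tensor(x), 0.0, None)
        _, attn, _ = m.forward(x)
        assert len(attn["sequence"]) == 1
        # pooled output comes from exactly that block's output
        pooled, _, _ = m.seq_branch(Tensor(x), 0.0, None)
        pooled2, _ = m.seq_branch.pool(direct)
        np.testing.assert_allclose(pooled.data, pooled2.data, atol=1e-6)

    def test_zeroed_second_block_residual_is_identity(self, rng):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=2, cffn_hidden=8,
                           n_detectors=4, detector_width=5)
        m = GHTNet(cfg, seed=1)
        b2 = m.seq_branch.blocks[1]
        # zero the residual-branch outputs (value/out proj and second linear)
        for lin in (b2.attn.wo, b2.cffn.lin2):
            lin.W.data[:] = 0.0
            lin.b.data[:] = 0.0
        x = Tensor(rng.normal(size=(1, 5, 8)).astype(np.float32))
        h1, _ = m.seq_branch.blocks[0](x, 0.0, None)
        h2, _ = b2(h1, 0.0, None)
        # with zeroed sublayer outputs, block 2 is layer-norm only; applying
        # it twice must not change the sublayer content
        expected = b2.ln2(b2.ln1(h1))
        np.testing.assert_allclose(h2.data, expected.data, atol=1e-5)


class TestConvPool:
    def test_pooled_length_and_profiles(self, rng):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=8,
                           n_detectors=6, detector_width=5)
        m = GHTNet(cfg, seed=0)
        x = rng.normal(size=(2, 9, 8)).astype(np.float32)
        _, _, prof = m.forward(x)
        assert prof["sequence"].shape == (2, 9, 6)

    def test_zero_input_zero_bias_pools_zero(self, rng):
        from ghtnet.model import ConvPool
        cfg = GHTNetConfig(d=4, n_heads=2, n_detectors=3, detector_width=3)
        pool = ConvPool(cfg, rng)
        pool.conv.b.data[:] = 0.0
        pooled, act = pool(Tensor(np.zeros((2, 6, 4), dtype=np.float32)))
        assert pooled.shape == (2, 3)
        np.testing.assert_array_equal(pooled.data, 0.0)
        np.testing.assert_array_equal(act, 0.0)

    def test_matched_detector_localizes_at_plant(self, rng):
        # detector equal to the embedded consensus pattern fires maximally
        # at the planted offset
        from ghtnet.model import ConvPool
        cfg = GHTNetConfig(d=4, n_heads=2, n_detectors=1, detector_width=5)
        pool = ConvPool(cfg, rng)
        pattern = rng.normal(size=(5, 4)).astype(np.float32)
        pool.conv.W.data = pattern[:, :, None]
        pool.conv.b.data[:] = 0.0
        x = np.zeros((1, 30, 4), dtype=np.float32)
        offset = 11
        x[0, offset:offset + 5] = pattern          # plant the pattern
        _, act = pool(Tensor(x))
        assert act[0, :, 0].argmax() == offset + 2  # centre of the plant


class TestForward:
    def test_probability_in_unit_interval(self, tiny_config, rng):
        m = GHTNet(tiny_config, seed=0)
        X = rng.normal(size=(8, 20, 8)).astype(np.float32)
        p = m.predict_proba(X)
        assert ((p >= 0) & (p <= 1)).all()

    def test_eval_mode_deterministic(self, tiny_config, rng):
        m = GHTNet(tiny_config, seed=0)
        X = rng.normal(size=(4, 15, 8)).astype(np.float32)
        np.testing.assert_array_equal(m.predict_proba(X), m.predict_proba(X))

    def test_permutation_sensitivity(self, tiny_config, rng):
        m = GHTNet(tiny_config, seed=0)
        X = rng.normal(size=(1, 15, 8)).astype(np.float32)
        perm = rng.permutation(15)
        p1 = m.predict_proba(X)
        p2 = m.predict_proba(X[:, perm, :])
        assert abs(p1[0] - p2[0]) > 1e-6

    def test_branch_independence_untied(self, rng):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=8,
                           n_detectors=4, detector_width=5,
                           n_feature_channels=3)
        m = GHTNet(cfg, seed=0)
        X = rng.normal(size=(2, 10, 8)).astype(np.float32)
        F = rng.normal(size=(2, 10, 3)).astype(np.float32)
        pooled_before, _, _ = m.seq_branch(Tensor(X), 0.0, None)
        for p in m.feat_branch.params:
            p.data += 1.0           # perturb the feature branch only
        pooled_after, _, _ = m.seq_branch(Tensor(X), 0.0, None)
        np.testing.assert_array_equal(pooled_before.data, pooled_after.data)

    def test_tied_branches_share_encoder_parameters(self):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=8,
                           n_detectors=4, detector_width=5,
                           n_feature_channels=3, tie_branches=True)
        m = GHTNet(cfg, seed=0)
        assert m.feat_branch.blocks is m.seq_branch.blocks

    def test_missing_feature_matrix_raises(self, rng):
        cfg = GHTNetConfig(d=8, n_heads=2, n_layers=1, cffn_hidden=8,
                           n_detectors=4, detector_width=5,
                           n_feature_channels=2)
        m = GHTNet(cfg, seed=0)
        X = rng.normal(size=(2, 10, 8)).astype(np.float32)
        with pytest.raises(ValueError, match="feature"):
            m.forward(X, None)
        with pytest.raises(ValueError, match="channels"):
            m.forward(X, rng.normal(size=(2, 10, 5)).astype(np.float32))

    def test_config_json_roundtrip(self, tiny_config):
        back = GHTNetConfig.from_json(tiny_config.to_json())
        assert back == tiny_config

    def test_checkpoint_roundtrip(self, tiny_config, rng, tmp_path):
        m = GHTNet(tiny_config, seed=2)
        X = rng.normal(size=(3, 12, 8)).astype(np.float32)
        path = tmp_path / "model.npz"
        m.save(path)
        back = GHTNet.load(path)
        assert back.config == tiny_config
        np.testing.assert_allclose(back.predict_proba(X),
                                   m.predict_proba(X), atol=1e-7)

    def test_state_roundtrip_changes_nothing(self, tiny_config, rng):
        m = GHTNet(tiny_config, seed=0)
        X = rng.normal(size=(3, 12, 8)).astype(np.float32)
        p1 = m.predict_proba(X)
        state = m.get_state()
        for p in m.params:
            p.data += 0.1
        m.set_state(state)
        np.testing.assert_allclose(m.predict_proba(X), p1, atol=1e-7)
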