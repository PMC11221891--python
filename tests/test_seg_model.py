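"""Spot Embedding Generator: CNN encoding, dual-coefficient attention,
expression head and training behavior."""

import numpy as np
import pytest

from stgat.autograd import Tensor
from stgat.datatypes import AdjacencyMatrix, ExpressionMatrix, PatchStack
from stgat.seg import (
    SegConfig,
    SegModel,
    attention_coefficients,
    cnn_encode,
    expression_head,
    embed_spots,
    gat_forward,
    intermediate_fc,
    seg_forward,
    seg_loss,
    train_seg,
)
from tests.conftest import random_adjacency


def tiny_config(**overrides):
    cfg = dict(n_genes=3, conv_channels=(2, 2), patch_side=8, input_downsample=1,
               embed_cnn=4, embed_attn=4, n_heads=1, head_hidden=4, seed=3)
    cfg.update(overrides)
    return SegConfig(**cfg)


def random_e2(rng, g, e_c, dtype=np.float32):
    return Tensor(rng.standard_normal((g, e_c)).astype(dtype))


def gat_oracle(e2, adj, model):
    """Independent triple-loop implementation of the attention layer."""
    g = e2.shape[0]
    cfg = model.config
    heads_out = []
    for head in model.heads:
        a_s = head["a_s"].data[:, 0]
        a_n = head["a_n"].data[:, 0]
        w_s, w_n = head["W_s"].data.T, head["W_n"].data.T  # (e_a, e_c)
        wv_s, wv_n = head["Wv_s"].data.T, head["Wv_n"].data.T
        out = np.zeros((g, cfg.embed_attn))
        for j in range(g):
            neighbors = [k for k in range(g) if adj.entries[j, k]]
            scores = {}
            for k in neighbors:
                raw = a_s @ (w_s @ e2[j]) + a_n @ (w_n @ e2[k])
                scores[k] = max(raw, 0.0)
            if neighbors:
                mx = max(scores.values())
                exps = {k: np.exp(v - mx) for k, v in scores.items()}
                total = sum(exps.values())
                alpha_n = {k: v / total for k, v in exps.items()}
            else:
                alpha_n = {}
            alpha_s = 1.0 / (1.0 + sum(alpha_n.values()))
            mixed = alpha_s * (wv_s @ e2[j])
            for k, a in alpha_n.items():
                mixed = mixed + a * (wv_n @ e2[k])
            out[j] = np.maximum(mixed, 0.0)
        heads_out.append(out)
    return np.concatenate(heads_out, axis=1)


class TestCnnEncode:
    def test_zero_image_gives_zero_embedding(self):
        model = SegModel(tiny_config())
        patches = PatchStack(patches=np.zeros((3, 8, 8, 3), dtype=np.uint8), side=8)
        e1 = cnn_encode(patches, model)
        np.testing.assert_allclose(e1.data, 0.0)

    def test_per_spot_independence_under_permutation(self, rng):
        model = SegModel(tiny_config())
        patches = rng.integers(0, 256, size=(5, 8, 8, 3), dtype=np.uint8)
        e1 = cnn_encode(PatchStack(patches=patches, side=8), model).data
        perm = rng.permutation(5)
        e1p = cnn_encode(PatchStack(patches=patches[perm], side=8), model).data
        np.testing.assert_allclose(e1p, e1[perm], atol=1e-6)

    def test_single_block_matches_hand_rolled_convolution(self, rng):
        cfg = tiny_config(conv_channels=(2,), dtype="float64")
        model = SegModel(cfg)
        patches = rng.integers(0, 256, size=(1, 8, 8, 3), dtype=np.uint8)
        got = cnn_encode(PatchStack(patches=patches, side=8), model).data[0]

        x = patches[0].astype(np.float64) / 255.0  # (8, 8, 3)
        w = model.blocks[0].conv.weight.data  # (2, 3, 3, 3)
        b = model.blocks[0].conv.bias.data
        xp = np.pad(x, ((1, 1), (1, 1), (0, 0)))
        conv = np.zeros((8, 8, 2))
        for o in range(2):
            for i in range(8):
                for j in range(8):
                    window = xp[i:i + 3, j:j + 3, :]  # (3, 3, C)
                    conv[i, j, o] = (window.transpose(2, 0, 1) * w[o]).sum() + b[o]
        feat = np.maximum(conv, 0.0).transpose(2, 0, 1).ravel()  # channel-major
        expected = feat @ model.fc_proj.weight.data + model.fc_proj.bias.data
        np.testing.assert_allclose(got, expected, atol=1e-10)

    def test_wrong_patch_size_errors(self):
        model = SegModel(tiny_config())
        with pytest.raises(ValueError, match="patch side"):
            cnn_encode(PatchStack(patches=np.zeros((2, 16, 16, 3), dtype=np.uint8),
                                  side=16), model)


class TestIntermediateFc:
    def test_identity_weights_pass_nonnegative_input(self, rng):
        model = SegModel(tiny_config())
        model.fc_mid.weight.data = np.eye(4, dtype=np.float32)
        model.fc_mid.bias.data[:] = 0
        x = np.abs(rng.standard_normal((5, 4))).astype(np.float32)
        np.testing.assert_allclose(intermediate_fc(Tensor(x), model).data, x)

    def test_zero_weights_broadcast_relu_bias(self, rng):
        model = SegModel(tiny_config())
        model.fc_mid.weight.data[:] = 0
        model.fc_mid.bias.data = np.array([1.0, -1.0, 0.5, -0.5], dtype=np.float32)
        out = intermediate_fc(random_e2(rng, 3, 4), model).data
        np.testing.assert_allclose(out, np.tile([1.0, 0.0, 0.5, 0.0], (3, 1)))

    def test_matches_affine_oracle(self, rng):
        model = SegModel(tiny_config())
        x = rng.standard_normal((6, 4)).astype(np.float32)
        expected = np.maximum(x @ model.fc_mid.weight.data + model.fc_mid.bias.data, 0)
        np.testing.assert_allclose(intermediate_fc(Tensor(x), model).data, expected,
                                   atol=1e-6)


class TestAttentionCoefficients:
    def test_alpha_self_is_exactly_half_with_neighbors_and_one_isolated(self, rng):
        model = SegModel(tiny_config())
        entries = np.array([[0, 1, 0], [1, 0, 0], [0, 0, 0]], dtype=np.uint8)
        adj = AdjacencyMatrix(entries=entries, threshold=0.5)
        alpha_n, alpha_s = attention_coefficients(random_e2(rng, 3, 4), adj, model, 0)
        assert alpha_s.data[0] == 0.5  # exact, not approximate
        assert alpha_s.data[1] == 0.5
        assert alpha_s.data[2] == 1.0
        np.testing.assert_array_equal(alpha_n.data[2], 0.0)

    def test_rows_sum_to_one_over_neighbor_sets(self, rng):
        model = SegModel(tiny_config(n_heads=2, embed_attn=3))
        adj = random_adjacency(rng, 10)
        for head in range(2):
            alpha_n, _ = attention_coefficients(random_e2(rng, 10, 4), adj, model, head)
            sums = alpha_n.data.sum(axis=1)
            has_nb = adj.entries.sum(axis=1) > 0
            np.testing.assert_allclose(sums[has_nb], 1.0, atol=1e-6)
            np.testing.assert_allclose(sums[~has_nb], 0.0)
            assert (alpha_n.data[adj.entries == 0] == 0).all()

    def test_extreme_scores_stay_finite_and_normalized(self, rng):
        """Large raw scores at neighbor or non-neighbor positions must not
        overflow or underflow the masked softmax."""
        model = SegModel(tiny_config(dtype="float64"))
        for name in ("a_s", "a_n", "W_s", "W_n"):
            model.heads[0][name].data *= 1e4
        entries = (rng.random((6, 6)) < 0.4).astype(np.uint8)
        np.fill_diagonal(entries, 0)
        entries[0, 1] = 1  # ensure at least one neighbor row
        adj = AdjacencyMatrix(entries=entries, threshold=0.5)
        e2 = Tensor(rng.standard_normal((6, 4)) * 10)
        alpha_n, alpha_s = attention_coefficients(e2, adj, model, 0)
        assert np.isfinite(alpha_n.data).all()
        has_nb = entries.sum(axis=1) > 0
        np.testing.assert_allclose(alpha_n.data.sum(axis=1)[has_nb], 1.0, atol=1e-12)
        assert (alpha_s.data[has_nb] == 0.5).all()

    def test_four_spot_instance_matches_per_edge_loop_oracle(self, rng):
        model = SegModel(tiny_config(dtype="float64"))
        e2 = rng.standard_normal((4, 4))
        entries = np.array([[0, 1, 1, 0], [1, 0, 0, 0],
                            [1, 1, 0, 1], [0, 0, 0, 0]], dtype=np.uint8)
        adj = AdjacencyMatrix(entries=entries, threshold=0.5)
        alpha_n, alpha_s = attention_coefficients(Tensor(e2), adj, model, 0)
        head = model.heads[0]
        a_s, a_n = head["a_s"].data[:, 0], head["a_n"].data[:, 0]
        w_s, w_n = head["W_s"].data.T, head["W_n"].data.T
        for j in range(4):
            neighbors = np.flatnonzero(entries[j])
            raws = [max(a_s @ (w_s @ e2[j]) + a_n @ (w_n @ e2[k]), 0.0)
                    for k in neighbors]
            if len(raws):
                exps = np.exp(np.array(raws) - max(raws))
                expected = exps / exps.sum()
                np.testing.assert_allclose(alpha_n.data[j, neighbors], expected,
                                           atol=1e-10)
            assert alpha_s.data[j] == (0.5 if len(raws) else 1.0)


class TestGatForward:
    def test_empty_adjacency_reduces_to_scaled_self_features(self, rng):
        model = SegModel(tiny_config())
        model.heads[0]["Wv_s"].data = np.eye(4, dtype=np.float32)
        adj = AdjacencyMatrix(entries=np.zeros((5, 5), dtype=np.uint8), threshold=0.5)
        e2 = np.abs(rng.standard_normal((5, 4))).astype(np.float32)
        out = gat_forward(Tensor(e2), adj, model).data
        np.testing.assert_allclose(out, e2, atol=1e-6)  # alpha_s = 1, ReLU no-op

    def test_two_heads_concatenate_single_head_runs(self, rng):
        model = SegModel(tiny_config(n_heads=2, embed_attn=3))
        adj = random_adjacency(rng, 6)
        e2 = random_e2(rng, 6, 4)
        full = gat_forward(e2, adj, model).data
        for l in range(2):
            single = SegModel(tiny_config(n_heads=1, embed_attn=3))
            for name in ("a_s", "a_n", "W_s", "W_n", "Wv_s", "Wv_n"):
                single.heads[0][name].data = model.heads[l][name].data.copy()
            part = gat_forward(e2, adj, single).data
            np.testing.assert_allclose(full[:, l * 3:(l + 1) * 3], part, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_triple_loop_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = int(rng.integers(2, 20))
        e_c = int(rng.integers(2, 8))
        heads = int(rng.integers(1, 3))
        model = SegModel(tiny_config(embed_cnn=e_c, embed_attn=int(rng.integers(2, 6)),
                                     n_heads=heads, dtype="float64", seed=seed))
        adj = random_adjacency(rng, g)
        e2 = rng.standard_normal((g, e_c))
        got = gat_forward(Tensor(e2), adj, model).data
        np.testing.assert_allclose(got, gat_oracle(e2, adj, model), atol=1e-5)

    def test_permutation_equivariance(self, rng):
        model = SegModel(tiny_config(n_heads=2, embed_attn=3, dtype="float64"))
        g = 7
        adj = random_adjacency(rng, g)
        e2 = rng.standard_normal((g, 4))
        out = gat_forward(Tensor(e2), adj, model).data
        perm = rng.permutation(g)
        adj_p = AdjacencyMatrix(entries=adj.entries[np.ix_(perm, perm)], threshold=0.5)
        out_p = gat_forward(Tensor(e2[perm]), adj_p, model).data
        np.testing.assert_allclose(out_p, out[perm], atol=1e-10)


class TestExpressionHead:
    def test_zero_embedding_zero_bias_gives_zero_expression(self):
        model = SegModel(tiny_config())
        out = expression_head(np.zeros((4, 4), dtype=np.float32), model)
        np.testing.assert_allclose(out.data, 0.0)

    def test_single_gene_matches_dot_product_oracle(self, rng):
        model = SegModel(tiny_config(n_genes=1, dtype="float64"))
        e3 = rng.standard_normal((5, 4))
        hidden = np.maximum(e3 @ model.fc_head1.weight.data + model.fc_head1.bias.data, 0)
        expected = hidden @ model.fc_head2.weight.data + model.fc_head2.bias.data
        np.testing.assert_allclose(expression_head(e3, model).data, expected, atol=1e-12)

    def test_detached_path_returns_embedding_unchanged(self, rng):
        model = SegModel(tiny_config(dtype="float64"))
        patches = rng.integers(0, 256, size=(4, 8, 8, 3), dtype=np.uint8)
        stack = PatchStack(patches=patches, side=8)
        adj = random_adjacency(rng, 4)
        e3 = embed_spots(stack, adj, model)
        e1 = cnn_encode(stack, model)
        expected = gat_forward(intermediate_fc(e1, model), adj, model).data
        np.testing.assert_array_equal(e3, expected)


class TestSegLoss:
    def test_perfect_prediction_is_zero(self, rng):
        y = rng.standard_normal((3, 4))
        assert seg_loss(y, y) == 0.0

    def test_unit_offset_gives_one(self, rng):
        y = rng.standard_normal((3, 4))
        assert seg_loss(y + 1.0, y) == pytest.approx(1.0)

    def test_matches_elementwise_oracle(self, rng):
        pred = rng.standard_normal((3, 4))
        truth = rng.standard_normal((3, 4))
        expected = sum((pred[i, j] - truth[i, j]) ** 2
                       for i in range(3) for j in range(4)) / 12
        assert seg_loss(pred, truth) == pytest.approx(expected)


class TestTrainSeg:
    def test_mismatched_gene_sets_error(self, rng):
        patches = PatchStack(patches=np.zeros((2, 8, 8, 3), dtype=np.uint8), side=8)
        adj = random_adjacency(rng, 2)
        e1 = ExpressionMatrix(values=np.ones((2, 3)), gene_ids=["a", "b", "c"])
        e2 = ExpressionMatrix(values=np.ones((2, 3)), gene_ids=["a", "b", "d"])
        with pytest.raises(ValueError, match="gene set"):
            train_seg([(patches, adj, e1), (patches, adj, e2)], tiny_config())

    def test_learns_noiseless_intensity_function(self, rng):
        """Expression that is a deterministic function of patch gray level is
        learned: 200 epochs cut the loss by at least 10x."""
        g = 16
        intensities = np.linspace(40, 220, g)
        patches = np.zeros((g, 8, 8, 3), dtype=np.uint8)
        for i, val in enumerate(intensities):
            patches[i] = int(val)
        scaled = intensities / 255.0
        truth = np.stack([scaled, 2 * scaled, scaled**2], axis=1)
        expr = ExpressionMatrix(values=truth, gene_ids=["g1", "g2", "g3"])
        entries = np.zeros((g, g), dtype=np.uint8)
        for i in range(g - 1):  # chain graph
            entries[i, i + 1] = entries[i + 1, i] = 1
        adj = AdjacencyMatrix(entries=entries, threshold=0.5)
        stack = PatchStack(patches=patches, side=8)
        cfg = tiny_config(conv_channels=(4, 4), embed_cnn=8, embed_attn=8,
                          head_hidden=16, epochs=200, learning_rate=1e-2)
        model = train_seg([(stack, adj, expr)], cfg)
        initial = SegModel(cfg)
        loss_before = seg_loss(seg_forward(stack, adj, initial).data, truth)
        loss_after = seg_loss(seg_forward(stack, adj, model).data, truth)
        assert loss_after <= loss_before / 10.0

    def test_training_is_bit_reproducible(self, rng):
        patches = PatchStack(
            patches=rng.integers(0, 256, size=(4, 8, 8, 3), dtype=np.uint8), side=8)
        adj = random_adjacency(rng, 4)
        expr = ExpressionMatrix(values=np.abs(rng.standard_normal((4, 3))),
                                gene_ids=["a", "b", "c"])
        cfg = tiny_config(epochs=3)
        m1 = train_seg([(patches, adj, expr)], cfg)
        m2 = train_seg([(patches, adj, expr)], cfg)
        assert m1.params_hash() == m2.params_hash()
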