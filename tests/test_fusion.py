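"""Feature adaptation, attention fusion, forward contracts, training loop."""

import numpy as np
import pytest

from adrfusion.autodiff import Tensor
from adrfusion.fusion import (AdrFusionModel, PipelineConfig, TrainConfig,
                              adapt_features, build_features, fuse_attention,
                              forward, predict_proba, save_checkpoint,
                              load_checkpoint, train_model)
from adrfusion import nn


@pytest.fixture(scope="module")
def model(desk_config_module):
    return AdrFusionModel(desk_config_module, vocab_size=20, n_train=10,
                          n_labels=4, seed=0).eval()


@pytest.fixture(scope="module")
def desk_config_module():
    return PipelineConfig.desk_scale()


class TestAdaptFeatures:
    def test_zero_input_zero_biases_gives_zero(self, model):
        for lin in list(model.adapters.values()) + list(model.reducers.values()):
            lin.b.data[:] = 0
        s = [Tensor(np.zeros(model.seq_encoder.output_dim)),
             Tensor(np.zeros(model.graph_encoder.output_dim)),
             Tensor(np.zeros(model.dp_encoder.output_dim))]
        out = adapt_features(*s, model)
        for o in out:
            np.testing.assert_allclose(o.data, 0.0, atol=1e-12)

    def test_output_length_is_block_dim(self, model):
        rng = np.random.default_rng(0)
        s = [Tensor(rng.normal(size=model.seq_encoder.output_dim)),
             Tensor(rng.normal(size=model.graph_encoder.output_dim)),
             Tensor(rng.normal(size=model.dp_encoder.output_dim))]
        for o in adapt_features(*s, model):
            assert o.shape == (model.config.fusion.block_dim,)

    def test_identity_adapters_recover_embedding(self, desk_config_module):
        """Adapter and reducer set to (padded) identities pass a block_dim
        embedding through unchanged — verified against a plain matmul."""
        model = AdrFusionModel(desk_config_module, vocab_size=20, n_train=10,
                               n_labels=2, seed=1).eval()
        fc = desk_config_module.fusion
        rng = np.random.default_rng(3)
        emb = rng.normal(size=fc.block_dim)
        padded = np.zeros(model.graph_encoder.output_dim)
        padded[: fc.block_dim] = emb
        A = np.zeros((model.graph_encoder.output_dim, fc.align_dim))
        A[: fc.block_dim, : fc.block_dim] = np.eye(fc.block_dim)
        R = np.zeros((fc.align_dim, fc.block_dim))
        R[: fc.block_dim, :] = np.eye(fc.block_dim)
        model.adapters["graph"].W.data = A
        model.adapters["graph"].b.data[:] = 0
        model.reducers["graph"].W.data = R
        model.reducers["graph"].b.data[:] = 0
        out = model.adapt_branches(
            {"graph": Tensor(padded[None, :])})["graph"]
        np.testing.assert_allclose(out.data[0], (padded @ A) @ R, atol=1e-12)
        np.testing.assert_allclose(out.data[0], emb, atol=1e-12)

    def test_dimension_mismatch_rejected(self, model):
        with pytest.raises(Exception):
            adapt_features(Tensor(np.zeros(3)), Tensor(np.zeros(3)),
                           Tensor(np.zeros(3)), model)


class TestFuseAttention:
    def test_identical_blocks_give_uniform_weights(self, model):
        block = np.random.default_rng(1).normal(
            size=model.config.fusion.block_dim)
        fused = fuse_attention([block] * 4, model)
        np.testing.assert_allclose(fused.attention_weights, 0.25, atol=1e-12)
        np.testing.assert_allclose(fused.S, block, atol=1e-10)

    def test_weights_sum_to_one(self, model):
        rng = np.random.default_rng(2)
        blocks = [rng.normal(size=model.config.fusion.block_dim)
                  for _ in range(4)]
        fused = fuse_attention(blocks, model)
        assert abs(fused.attention_weights.sum() - 1.0) < 1e-6
        assert (fused.attention_weights >= 0).all()

    def test_weighted_sum_matches_scalar_oracle(self, desk_config_module):
        model = AdrFusionModel(desk_config_module, vocab_size=20, n_train=10,
                               n_labels=2, seed=5).eval()
        rng = np.random.default_rng(4)
        blocks = [rng.normal(size=model.config.fusion.block_dim)
                  for _ in range(4)]
        fused = fuse_attention(blocks, model)
        # independent oracle: score each block through the two linear layers
        scores = []
        for b in blocks:
            h = np.maximum(0, b @ model.attn1.W.data + model.attn1.b.data)
            scores.append((h @ model.attn2.W.data + model.attn2.b.data).item())
        e = np.exp(scores - np.max(scores))
        w = e / e.sum()
        S = sum(wi * bi for wi, bi in zip(w, blocks))
        np.testing.assert_allclose(fused.attention_weights, w, atol=1e-9)
        np.testing.assert_allclose(fused.S, S, atol=1e-9)

    def test_non_finite_block_rejected(self, model):
        bad = np.full(model.config.fusion.block_dim, np.nan)
        with pytest.raises(ValueError, match="non-finite"):
            fuse_attention([bad] * 4, model)


class TestForward:
    def test_probabilities_in_unit_interval(self, tiny_bundle, desk_config):
        model = AdrFusionModel(desk_config, vocab_size=len(tiny_bundle.vocab),
                               n_train=5, n_labels=3, seed=0).eval()
        from adrfusion.chem_io import TokenSequence

        i = 2
        seq = TokenSequence(ids=tiny_bundle.token_ids[i],
                            n_real=int(tiny_bundle.n_real[i]))
        p = forward(seq, tiny_bundle.mol_graphs[i], tiny_bundle.dp_graphs[i],
                    np.random.default_rng(0).normal(size=5), model)
        assert p.shape == (3,)
        assert ((p > 0) & (p < 1)).all()

    def test_zero_weights_give_half_probability(self, desk_config):
        model = AdrFusionModel(desk_config, vocab_size=20, n_train=4,
                               n_labels=1, seed=0).eval()
        for p in model.parameters():
            p.data[:] = 0
        from adrfusion.chem_io import Fingerprint, TokenSequence, smiles_to_graph
        from adrfusion.encoders.dp_gcn import build_dp_graph

        seq = TokenSequence(ids=np.array([2, 3, 0, 0]), n_real=2)
        g = smiles_to_graph("CCO")
        dp = build_dp_graph(Fingerprint(np.ones(8, np.uint8), 2, 8), [],
                            node_width=desk_config.dp_gcn.in_dim)
        p = forward(seq, g, dp, np.zeros(4), model)
        np.testing.assert_allclose(p, 0.5, atol=1e-12)

    def test_eval_mode_forward_is_deterministic(self, tiny_bundle, desk_config):
        model = AdrFusionModel(desk_config, vocab_size=len(tiny_bundle.vocab),
                               n_train=6, n_labels=3, seed=0).eval()
        idx = np.arange(4)
        rows = np.random.default_rng(1).normal(size=(4, 6))
        a = model.forward_batch(tiny_bundle, idx, rows)
        b = model.forward_batch(tiny_bundle, idx, rows)
        assert (a.data == b.data).all()

    def test_missing_similarity_rows_error(self, tiny_bundle, desk_config):
        model = AdrFusionModel(desk_config, vocab_size=len(tiny_bundle.vocab),
                               n_train=6, n_labels=3, seed=0).eval()
        with pytest.raises(ValueError, match="similarity"):
            model.forward_batch(tiny_bundle, np.arange(3), None)

    def test_dropped_branch_reduces_parameter_count(self, desk_config):
        full = AdrFusionModel(desk_config, 20, 10, 4, seed=0)
        for branch in ("sequence", "graph", "dp_graph", "similarity"):
            ablated = AdrFusionModel(desk_config, 20, 10, 4, seed=0,
                                     dropped_branch=branch)
            assert ablated.n_parameters() < full.n_parameters()


class TestTraining:
    def test_same_seed_identical_loss_trace(self, tiny_bundle, tiny_dataset,
                                            desk_config):
        tc = TrainConfig(lr=1e-3, epochs=3, batch_size=16, seed=11)
        idx = np.arange(20)
        r1 = train_model(tiny_bundle, tiny_dataset.adr_table.Y, idx,
                         desk_config, tc)
        r2 = train_model(tiny_bundle, tiny_dataset.adr_table.Y, idx,
                         desk_config, tc)
        assert r1.loss_trace == r2.loss_trace

    def test_loss_decreases_on_fixed_batch(self, tiny_bundle, tiny_dataset,
                                           desk_config):
        tc = TrainConfig(lr=3e-3, epochs=20, batch_size=64, seed=0)
        res = train_model(tiny_bundle, tiny_dataset.adr_table.Y,
                          np.arange(24), desk_config, tc)
        assert res.loss_trace[-1] < res.loss_trace[0]

    def test_gradient_reaches_every_branch(self, tiny_bundle, tiny_dataset,
                                           desk_config):
        """One optimizer step on a nonzero-loss batch must move parameters
        in all four branches and the fusion head (no dead branch)."""
        model = AdrFusionModel(desk_config, vocab_size=len(tiny_bundle.vocab),
                               n_train=8, n_labels=tiny_dataset.adr_table.Y.shape[1],
                               seed=3)
        model.train()
        probes = {
            "sequence": model.seq_encoder.embed.table,
            "graph": model.graph_encoder.gat_layers[0].W,
            "dp_graph": model.dp_encoder.layers[0].lin.W,
            "similarity": model.sim_adapter.W,
            "head": model.head.W,
        }
        before = {k: v.data.copy() for k, v in probes.items()}
        opt = nn.Adam(model.parameters(), lr=1e-2)
        idx = np.arange(8)
        rows = np.random.default_rng(0).normal(size=(8, 8))
        logits = model.forward_batch(tiny_bundle, idx, rows)
        loss = nn.binary_cross_entropy_with_logits(
            logits, tiny_dataset.adr_table.Y[idx])
        loss.backward()
        opt.step()
        for name, p in probes.items():
            assert not np.allclose(p.data, before[name]), f"dead branch {name}"

    def test_empty_training_fold_rejected(self, tiny_bundle, tiny_dataset,
                                          desk_config):
        with pytest.raises(ValueError, match="empty"):
            train_model(tiny_bundle, tiny_dataset.adr_table.Y,
                        np.array([], dtype=int), desk_config, TrainConfig())


class TestCheckpoint:
    def test_round_trip_predictions(self, tmp_path, tiny_bundle, tiny_dataset,
                                    desk_config):
        tc = TrainConfig(lr=1e-3, epochs=2, batch_size=16, seed=4)
        res = train_model(tiny_bundle, tiny_dataset.adr_table.Y,
                          np.arange(25), desk_config, tc)
        res.label_names = tiny_dataset.adr_table.label_names
        save_checkpoint(res, tmp_path / "run")
        loaded = load_checkpoint(tmp_path / "run")
        from adrfusion.fusion import predict_new

        P1 = predict_new(res, tiny_bundle)
        P2 = predict_new(loaded, tiny_bundle)
        np.testing.assert_allclose(P1, P2, atol=1e-12)
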