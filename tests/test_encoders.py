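"""Layer-by-layer equivalence with dense brute-force oracles, plus the
structural invariants: masking, permutation symmetry, determinism, dims."""

import numpy as np
import pytest

from adrfusion.autodiff import Tensor
from adrfusion.chem_io import MolecularGraph, Fingerprint, Vocabulary, tokenize_smiles
from adrfusion.encoders.dp_gcn import (DpGcnConfig, DpGcnEncoder,
                                       build_dp_graph, encode_dp_graph)
from adrfusion.encoders.gat_gcn import (GatGcnConfig, GatGcnEncoder, GATLayer,
                                        GCNLayer, batch_graphs,
                                        encode_molecule_graph, gat_layer,
                                        gcn_layer)
from adrfusion.encoders.transformer import (FeedForward, MultiHeadAttention,
                                            SequenceEncoder, TransformerConfig,
                                            feed_forward, multi_head_attention)


def small_tconfig(**kw):
    base = dict(vocab_size=12, d_model=8, n_heads=2, d_ff=16, dropout=0.0,
                n_layers=1, max_len=10)
    base.update(kw)
    return TransformerConfig(**base)


# ---------------------------------------------------------------- transformer

def mha_oracle(H, mha, mask):
    """Dense single-sequence multi-head attention computed explicitly."""
    d = H.shape[1]
    h, d_k = mha.h, mha.d_k
    Q = H @ mha.Wq.W.data + mha.Wq.b.data
    K = H @ mha.Wk.W.data + mha.Wk.b.data
    V = H @ mha.Wv.W.data + mha.Wv.b.data
    heads = []
    for i in range(h):
        sl = slice(i * d_k, (i + 1) * d_k)
        s = Q[:, sl] @ K[:, sl].T / np.sqrt(d_k)
        s = np.where(mask[None, :], s, -np.inf)
        e = np.exp(s - s.max(axis=1, keepdims=True))
        a = e / e.sum(axis=1, keepdims=True)
        assert np.allclose(a.sum(axis=1), 1.0, atol=1e-6)  # score rows sum to 1
        heads.append(a @ V[:, sl])
    return np.concatenate(heads, axis=1) @ mha.Wo.W.data + mha.Wo.b.data


def test_multi_head_attention_matches_dense_oracle(rng):
    cfg = small_tconfig()
    mha = MultiHeadAttention(cfg, rng)
    H = rng.normal(size=(3, cfg.d_model))
    mask = np.array([True, True, True])
    out = multi_head_attention(Tensor(H), mha, mask)
    np.testing.assert_allclose(out.data, mha_oracle(H, mha, mask), atol=1e-6)


def test_attention_masked_keys_ignored(rng):
    cfg = small_tconfig()
    mha = MultiHeadAttention(cfg, rng)
    H = rng.normal(size=(4, cfg.d_model))
    mask = np.array([True, True, False, False])
    out = multi_head_attention(Tensor(H), mha, mask)
    H2 = H.copy()
    H2[2:] = 999.0  # garbage in masked key positions
    out2 = multi_head_attention(Tensor(H2), mha, mask)
    np.testing.assert_allclose(out.data[:2], out2.data[:2], atol=1e-8)


def test_attention_identical_rows_give_identical_output(rng):
    cfg = small_tconfig()
    mha = MultiHeadAttention(cfg, rng)
    H = np.tile(rng.normal(size=(1, cfg.d_model)), (5, 1))
    out = multi_head_attention(Tensor(H), mha, np.ones(5, dtype=bool))
    np.testing.assert_allclose(out.data, np.tile(out.data[0], (5, 1)),
                               atol=1e-10)


def test_attention_all_masked_errors(rng):
    cfg = small_tconfig()
    mha = MultiHeadAttention(cfg, rng)
    with pytest.raises(ValueError, match="masked"):
        multi_head_attention(Tensor(np.zeros((2, 8))), mha,
                             np.array([False, False]))


def test_feed_forward_matches_matrix_oracle(rng):
    cfg = small_tconfig()
    ffn = FeedForward(cfg, rng)
    x = rng.normal(size=(2, cfg.d_model))
    expected = (np.maximum(0, x @ ffn.lin1.W.data + ffn.lin1.b.data)
                @ ffn.lin2.W.data + ffn.lin2.b.data)
    np.testing.assert_allclose(feed_forward(Tensor(x), ffn).data,
                               expected, atol=1e-6)


def test_feed_forward_zero_input_zero_biases(rng):
    cfg = small_tconfig()
    ffn = FeedForward(cfg, rng)
    ffn.lin1.b.data[:] = 0
    ffn.lin2.b.data[:] = 0
    out = feed_forward(Tensor(np.zeros((3, cfg.d_model))), ffn)
    np.testing.assert_allclose(out.data, 0.0, atol=1e-12)


def test_feed_forward_saturation_returns_output_bias(rng):
    cfg = small_tconfig()
    ffn = FeedForward(cfg, rng)
    ffn.lin1.b.data[:] = -1e6  # ReLU zeroes the hidden layer
    out = feed_forward(Tensor(rng.normal(size=(2, cfg.d_model))), ffn)
    np.testing.assert_allclose(out.data, np.tile(ffn.lin2.b.data, (2, 1)),
                               atol=1e-9)


def test_sequence_encoder_padding_invariance(rng):
    cfg = small_tconfig(max_len=128, vocab_size=30)
    enc = SequenceEncoder(cfg, rng).eval()
    vocab = Vocabulary.from_corpus(["CCOc1ccccc1"])
    short = tokenize_smiles("CCOc1ccccc1", vocab, max_len=64)
    long = tokenize_smiles("CCOc1ccccc1", vocab, max_len=128)
    e_short = enc(short.ids[None, :], np.array([short.n_real]))
    e_long = enc(long.ids[None, :], np.array([long.n_real]))
    np.testing.assert_allclose(e_short.data, e_long.data, atol=1e-5)


def test_sequence_encoder_output_is_512_under_reference_config(rng):
    cfg = TransformerConfig(vocab_size=20)  # reference widths: 512/8/2048
    enc = SequenceEncoder(cfg, rng).eval()
    vocab = Vocabulary.from_corpus(["CCO"])
    seq = tokenize_smiles("CCO", vocab, max_len=cfg.max_len)
    out = enc(seq.ids[None, :], np.array([seq.n_real]))
    assert out.shape == (1, 512)


def test_sequence_encoder_deterministic_in_eval_mode(rng):
    cfg = small_tconfig(dropout=0.3)
    enc = SequenceEncoder(cfg, rng).eval()
    ids = np.array([[2, 3, 4, 0, 0, 0, 0, 0, 0, 0]])
    n = np.array([3])
    a, b = enc(ids, n), enc(ids, n)
    assert (a.data == b.data).all()


# ------------------------------------------------------------------- GAT/GCN

def path_graph(rng, n=3, f=4):
    feats = rng.normal(size=(n, f))
    src = list(range(n - 1)) + list(range(1, n))
    dst = list(range(1, n)) + list(range(n - 1))
    return MolecularGraph(feats, np.array([src, dst]), n)


def gat_oracle(layer, h, edge_index, n_nodes):
    """Enumerate pairwise attention explicitly per head."""
    K, F2 = layer.n_heads, layer.out_dim
    Wh = (h @ layer.W.data).reshape(n_nodes, K, F2)
    nbrs = {i: {i} for i in range(n_nodes)}  # self-loop included
    for s, d in edge_index.T:
        nbrs[d].add(s)
    out = np.zeros((n_nodes, K, F2))
    for i in range(n_nodes):
        for k in range(K):
            e = {}
            for j in nbrs[i]:
                raw = (layer.a_self.data[k] @ Wh[i, k]
                       + layer.a_neigh.data[k] @ Wh[j, k])
                e[j] = raw if raw > 0 else layer.slope * raw
            mx = max(e.values())
            z = {j: np.exp(v - mx) for j, v in e.items()}
            total = sum(z.values())
            alpha = {j: v / total for j, v in z.items()}
            assert abs(sum(alpha.values()) - 1.0) < 1e-6
            out[i, k] = sum(alpha[j] * Wh[j, k] for j in nbrs[i])
    # ELU then concat heads
    out = np.where(out > 0, out, np.exp(np.minimum(out, 0)) - 1)
    return out.reshape(n_nodes, K * F2)


def test_gat_layer_matches_pairwise_oracle(rng):
    g = path_graph(rng)
    layer = GATLayer(4, 3, n_heads=2, rng=rng)
    out = gat_layer(g, g.node_features, layer)
    expected = gat_oracle(layer, g.node_features, g.edge_index, g.n_nodes)
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_gat_attention_rows_sum_to_one(rng):
    g = path_graph(rng, n=5)
    layer = GATLayer(4, 3, n_heads=2, rng=rng)
    edges, alpha = layer.attention_coefficients(
        Tensor(g.node_features), g.edge_index, g.n_nodes)
    sums = np.zeros((g.n_nodes, layer.n_heads))
    np.add.at(sums, edges[1], alpha)
    np.testing.assert_allclose(sums, 1.0, atol=1e-6)


def test_gat_single_node_degenerate_neighborhood(rng):
    g = MolecularGraph(rng.normal(size=(1, 4)), np.zeros((2, 0), int), 1)
    layer = GATLayer(4, 3, n_heads=2, rng=rng)
    out = gat_layer(g, g.node_features, layer)
    Wh = (g.node_features @ layer.W.data).reshape(1, 2, 3)
    expected = np.where(Wh > 0, Wh, np.exp(np.minimum(Wh, 0)) - 1)
    np.testing.assert_allclose(out.data, expected.reshape(1, 6), atol=1e-9)


def gcn_oracle(layer, H, edge_index, n_nodes):
    A = np.zeros((n_nodes, n_nodes))
    A[edge_index[0], edge_index[1]] = 1.0
    A_t = A + np.eye(n_nodes)
    Dm = np.diag(1.0 / np.sqrt(A_t.sum(axis=1)))
    return np.maximum(0.0, Dm @ A_t @ Dm @ (H @ layer.lin.W.data
                                            + layer.lin.b.data))


def test_gcn_layer_matches_dense_oracle(rng):
    g = path_graph(rng, n=2)
    layer = GCNLayer(4, 3, rng)
    out = gcn_layer(g, g.node_features, layer)
    np.testing.assert_allclose(
        out.data, gcn_oracle(layer, g.node_features, g.edge_index, 2),
        atol=1e-6)


def test_gcn_single_node_identity_weight(rng):
    layer = GCNLayer(4, 4, rng)
    layer.lin.W.data = np.eye(4)
    layer.lin.b.data[:] = 0
    g = MolecularGraph(rng.normal(size=(1, 4)), np.zeros((2, 0), int), 1)
    out = gcn_layer(g, g.node_features, layer)
    np.testing.assert_allclose(out.data, np.maximum(0, g.node_features),
                               atol=1e-12)


def test_gcn_permutation_equivariance(rng):
    g = path_graph(rng, n=4)
    layer = GCNLayer(4, 3, rng)
    perm = np.array([2, 0, 3, 1])
    inv = np.argsort(perm)
    g_p = MolecularGraph(g.node_features[perm], inv[g.edge_index], 4)
    out = gcn_layer(g, g.node_features, layer)
    out_p = gcn_layer(g_p, g_p.node_features, layer)
    np.testing.assert_allclose(out_p.data, out.data[perm], atol=1e-9)


def test_molecule_encoder_matches_chained_layer_oracles(rng):
    cfg = GatGcnConfig(in_dim=4, hidden_dim=3, n_heads=2, dropout=0.0)
    enc = GatGcnEncoder(cfg, rng).eval()
    g = path_graph(rng)
    h = g.node_features
    for layer in enc.gat_layers:
        h = gat_oracle(layer, h, g.edge_index, g.n_nodes)
    for layer in enc.gcn_layers:
        h = gcn_oracle(layer, h, g.edge_index, g.n_nodes)
    expected = np.concatenate([h.max(axis=0), h.mean(axis=0)])
    out = encode_molecule_graph(g, enc)
    np.testing.assert_allclose(out.data, expected, atol=1e-6)


def test_molecule_encoder_permutation_invariance(rng):
    cfg = GatGcnConfig(in_dim=4, hidden_dim=3, n_heads=2, dropout=0.0)
    enc = GatGcnEncoder(cfg, rng).eval()
    g = path_graph(rng, n=5)
    perm = np.array([4, 2, 0, 1, 3])
    inv = np.argsort(perm)
    g_p = MolecularGraph(g.node_features[perm], inv[g.edge_index], 5)
    np.testing.assert_allclose(encode_molecule_graph(g, enc).data,
                               encode_molecule_graph(g_p, enc).data,
                               atol=1e-5)


def test_molecule_encoder_single_node_max_equals_mean(rng):
    cfg = GatGcnConfig(in_dim=4, hidden_dim=3, n_heads=2, dropout=0.0)
    enc = GatGcnEncoder(cfg, rng).eval()
    g = MolecularGraph(rng.normal(size=(1, 4)), np.zeros((2, 0), int), 1)
    out = encode_molecule_graph(g, enc).data
    assert out.shape == (6,)  # 2 * hidden_dim
    np.testing.assert_allclose(out[:3], out[3:], atol=1e-12)


def test_batched_graphs_equal_individual_encoding(rng, tiny_bundle, desk_config):
    enc = GatGcnEncoder(desk_config.gat_gcn, rng).eval()
    graphs = tiny_bundle.mol_graphs[:5]
    batched = enc(batch_graphs(graphs)).data
    singles = np.stack([encode_molecule_graph(g, enc).data for g in graphs])
    np.testing.assert_allclose(batched, singles, atol=1e-8)


def test_output_dims_match_configs(rng):
    gcfg = GatGcnConfig(in_dim=4, hidden_dim=7, n_heads=3, dropout=0.0)
    genc = GatGcnEncoder(gcfg, rng).eval()
    assert genc.output_dim == 14
    g = path_graph(rng, f=4)
    assert encode_molecule_graph(g, genc).shape == (14,)
    dcfg = DpGcnConfig(in_dim=32, hidden_dim=5)
    denc = DpGcnEncoder(dcfg, rng).eval()
    fp = Fingerprint(np.ones(16, dtype=np.uint8), 2, 16)
    star = build_dp_graph(fp, [np.ones(20) / 20], node_width=32)
    assert encode_dp_graph(star, denc).shape == (5,)


# ----------------------------------------------------------------- dp branch

def test_dp_star_topology():
    fp = Fingerprint(np.ones(16, dtype=np.uint8), 2, 16)
    two = build_dp_graph(fp, [np.ones(20) / 20, np.ones(20) / 20])
    assert two.n_nodes == 3 and two.edge_index.shape[1] == 4
    none = build_dp_graph(fp, [])
    assert none.n_nodes == 1 and none.edge_index.shape[1] == 0
    assert two.node_features.shape[1] == max(16, 20)  # common width


def test_dp_encoder_matches_dense_oracle(rng):
    cfg = DpGcnConfig(in_dim=24, hidden_dim=4)
    enc = DpGcnEncoder(cfg, rng).eval()
    fp = Fingerprint((rng.random(24) < 0.4).astype(np.uint8), 2, 24)
    star = build_dp_graph(fp, [rng.dirichlet(np.ones(20)) for _ in range(2)],
                          node_width=24)
    h = star.node_features
    for layer in enc.layers:
        h = gcn_oracle(layer, h, star.edge_index, star.n_nodes)
    np.testing.assert_allclose(encode_dp_graph(star, enc).data,
                               h.max(axis=0), atol=1e-6)


def test_dp_encoder_partner_permutation_invariance(rng):
    cfg = DpGcnConfig(in_dim=24, hidden_dim=4)
    enc = DpGcnEncoder(cfg, rng).eval()
    fp = Fingerprint((rng.random(24) < 0.4).astype(np.uint8), 2, 24)
    partners = [rng.dirichlet(np.ones(20)) for _ in range(3)]
    a = encode_dp_graph(build_dp_graph(fp, partners, 24), enc)
    b = encode_dp_graph(build_dp_graph(fp, partners[::-1], 24), enc)
    np.testing.assert_allclose(a.data, b.data, atol=1e-9)


def test_dp_encoder_isolated_node_is_relu_chain(rng):
    cfg = DpGcnConfig(in_dim=4, hidden_dim=4)
    enc = DpGcnEncoder(cfg, rng).eval()
    for layer in enc.layers:
        layer.lin.W.data = np.eye(4)
        layer.lin.b.data[:] = 0
    fp = Fingerprint(np.array([1, 0, 1, 0], dtype=np.uint8), 1, 4)
    star = build_dp_graph(fp, [], node_width=4)
    out = encode_dp_graph(star, enc)
    np.testing.assert_allclose(out.data, np.maximum(0, star.node_features[0]),
                               atol=1e-12)
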