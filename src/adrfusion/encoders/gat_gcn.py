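"""GAT-GCN branch over 2D molecular graphs.

Three graph-attention layers (multi-head, LeakyReLU scoring, neighborhood
softmax including a self-loop) followed by two graph-convolution layers with
symmetric degree normalization, then a concatenation of global max pooling
and global mean pooling yields one fixed-length vector per molecule.

Graphs are processed as disjoint-union batches (block-diagonal adjacency):
node features of all molecules are stacked, edge indices offset, and pooling
reduces over per-graph row ranges, so a whole dataset runs through each
layer in a single call.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..autodiff import Tensor, concat, segment_max, segment_mean, segment_sum
from ..chem_io import MolecularGraph
from .. import nn


@dataclass
class GatGcnConfig:
    in_dim: int = 27
    n_gat_layers: int = 3
    n_heads: int = 10
    n_gcn_layers: int = 2
    hidden_dim: int = 128  # per-head GAT width and GCN width
    dropout: float = 0.2
    leaky_relu_slope: float = 0.2

    def __post_init__(self):
        if self.n_gat_layers < 1 or self.n_gcn_layers < 1:
            raise ValueError("layer counts must be >= 1")
        if self.leaky_relu_slope <= 0:
            raise ValueError("LeakyReLU slope must be > 0")


@dataclass
class GraphBatch:
    """Disjoint union of molecular graphs with contiguous per-graph rows."""

    node_features: np.ndarray  # (N_total, F)
    edge_index: np.ndarray  # (2, E_total), offset into the union
    ptr: np.ndarray  # (n_graphs + 1,) row boundaries

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_graphs(self) -> int:
        return len(self.ptr) - 1


def batch_graphs(graphs: list[MolecularGraph]) -> GraphBatch:
    if not graphs:
        raise ValueError("empty graph list")
    feats = np.concatenate([g.node_features for g in graphs], axis=0)
    offsets = np.cumsum([0] + [g.n_nodes for g in graphs])
    edges = [g.edge_index + off for g, off in zip(graphs, offsets[:-1])]
    edge_index = np.concatenate(edges, axis=1) if edges else np.zeros((2, 0), int)
    return GraphBatch(feats, edge_index.astype(np.intp), offsets.astype(np.intp))


def _with_self_loops(edge_index: np.ndarray, n_nodes: int) -> np.ndarray:
    loops = np.arange(n_nodes, dtype=np.intp)
    return np.concatenate([edge_index, np.stack([loops, loops])], axis=1)


class GATLayer(nn.Module):
    """Multi-head graph attention (per-head width ``out_dim``, concatenated).

    Edge score e_ij = LeakyReLU(a^T [W h_i || W h_j]) with the attention
    vector split as a = [a_self || a_neigh]; coefficients are softmax-
    normalized over each node's neighborhood, which includes the node itself.
    """

    def __init__(self, in_dim: int, out_dim: int, n_heads: int,
                 rng: np.random.Generator, slope: float = 0.2,
                 activation: str = "elu"):
        super().__init__()
        self.n_heads, self.out_dim, self.slope = n_heads, out_dim, slope
        self.activation = activation
        self.W = nn.Parameter(nn.glorot_uniform(rng, in_dim, n_heads * out_dim))
        self.a_self = nn.Parameter(
            nn.glorot_uniform(rng, 2 * out_dim, 1, shape=(n_heads, out_dim)))
        self.a_neigh = nn.Parameter(
            nn.glorot_uniform(rng, 2 * out_dim, 1, shape=(n_heads, out_dim)))

    def forward(self, h: Tensor, edge_index: np.ndarray, n_nodes: int) -> Tensor:
        if n_nodes < 1:
            raise ValueError("empty graph")
        edges = _with_self_loops(edge_index, n_nodes)
        src, dst = edges[0], edges[1]
        Wh = (h @ self.W).reshape(n_nodes, self.n_heads, self.out_dim)
        score_self = (Wh * self.a_self).sum(axis=-1)   # (n, K)
        score_neigh = (Wh * self.a_neigh).sum(axis=-1)  # (n, K)
        e = (score_self[dst] + score_neigh[src]).leaky_relu(self.slope)
        alpha = edge_softmax(e, dst, n_nodes)
        msg = alpha.reshape(len(src), self.n_heads, 1) * Wh[src]
        out = segment_sum(msg, dst, n_nodes)  # (n, K, out_dim)
        if self.activation == "elu":
            out = out.elu()
        elif self.activation == "relu":
            out = out.relu()
        return out.reshape(n_nodes, self.n_heads * self.out_dim)

    def attention_coefficients(self, h: Tensor, edge_index: np.ndarray,
                               n_nodes: int) -> tuple[np.ndarray, np.ndarray]:
        """(edges-with-self-loops, alpha) for inspection/testing."""
        edges = _with_self_loops(edge_index, n_nodes)
        src, dst = edges[0], edges[1]
        Wh = (h @ self.W).reshape(n_nodes, self.n_heads, self.out_dim)
        score_self = (Wh * self.a_self).sum(axis=-1)
        score_neigh = (Wh * self.a_neigh).sum(axis=-1)
        e = (score_self[dst] + score_neigh[src]).leaky_relu(self.slope)
        return edges, edge_softmax(e, dst, n_nodes).data


def edge_softmax(e: Tensor, dst: np.ndarray, n_nodes: int) -> Tensor:
    """Softmax of edge scores over each destination's incoming edges."""
    # per-destination max is locally constant -> safe to treat as data
    m = np.full((n_nodes,) + e.shape[1:], -np.inf)
    np.maximum.at(m, dst, e.data)
    z = (e - Tensor(m[dst])).exp()
    denom = segment_sum(z, dst, n_nodes)
    return z / denom[dst]


class GCNLayer(nn.Module):
    """Graph convolution with self-loops and symmetric degree normalization:
    H' = sigma(D^{-1/2} (A + I) D^{-1/2} H W)."""

    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator,
                 activation: str = "relu"):
        super().__init__()
        self.lin = nn.Linear(in_dim, out_dim, rng)
        self.activation = activation

    def forward(self, h: Tensor, edge_index: np.ndarray, n_nodes: int) -> Tensor:
        edges = _with_self_loops(edge_index, n_nodes)
        src, dst = edges[0], edges[1]
        deg = np.bincount(dst, minlength=n_nodes).astype(float)
        norm = 1.0 / np.sqrt(deg[src] * deg[dst])
        hw = self.lin(h)
        msg = Tensor(norm[:, None]) * hw[src]
        out = segment_sum(msg, dst, n_nodes)
        if self.activation == "relu":
            out = out.relu()
        return out


class GatGcnEncoder(nn.Module):
    """Full 2D-structure branch: molecular graph batch -> (B, 2*hidden_dim)."""

    def __init__(self, config: GatGcnConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        width = config.in_dim
        self.gat_layers = []
        for _ in range(config.n_gat_layers):
            self.gat_layers.append(
                GATLayer(width, config.hidden_dim, config.n_heads, rng,
                         slope=config.leaky_relu_slope))
            width = config.n_heads * config.hidden_dim
        self.gcn_layers = []
        for _ in range(config.n_gcn_layers):
            self.gcn_layers.append(GCNLayer(width, config.hidden_dim, rng))
            width = config.hidden_dim
        self.drop = nn.Dropout(config.dropout, rng)

    @property
    def output_dim(self) -> int:
        return 2 * self.config.hidden_dim

    def forward(self, batch: GraphBatch) -> Tensor:
        h = Tensor(batch.node_features)
        for layer in self.gat_layers:
            h = self.drop(layer(h, batch.edge_index, batch.n_nodes))
        for layer in self.gcn_layers:
            h = self.drop(layer(h, batch.edge_index, batch.n_nodes))
        pooled = concat(
            [segment_max(h, batch.ptr), segment_mean(h, batch.ptr)], axis=-1)
        return pooled


def gat_layer(graph: MolecularGraph, h: Tensor | np.ndarray,
              params: GATLayer) -> Tensor:
    """Functional wrapper: one GAT layer over a single molecular graph."""
    h = h if isinstance(h, Tensor) else Tensor(h)
    return params(h, graph.edge_index, graph.n_nodes)


def gcn_layer(graph: MolecularGraph, H: Tensor | np.ndarray,
              params: GCNLayer) -> Tensor:
    """Functional wrapper: one GCN layer over a single molecular graph."""
    H = H if isinstance(H, Tensor) else Tensor(H)
    return params(H, graph.edge_index, graph.n_nodes)


def encode_molecule_graph(graph: MolecularGraph, encoder: GatGcnEncoder) -> Tensor:
    """Encode a single molecule to its branch embedding (2*hidden_dim)."""
    return encoder(batch_graphs([graph])).reshape(-1)
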