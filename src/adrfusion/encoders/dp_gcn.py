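"""Drug-protein interaction branch.

Each drug owns a star graph: one central drug node (features = its Morgan
fingerprint, zero-padded to the common node width) linked undirectedly to
one node per interacting protein (features = amino-acid composition vector,
zero-padded likewise).  A drug with no recorded partners is an isolated
node, so every drug still receives a drug-protein embedding.  The graph runs
through three GCN layers (ReLU each) and a global max pooling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ..autodiff import Tensor, segment_max
from ..chem_io import Fingerprint, MolecularGraph
from .. import nn
from .gat_gcn import GCNLayer, GraphBatch, batch_graphs


@dataclass
class DpGcnConfig:
    in_dim: int = 2048  # common node width (>= fingerprint bits and 20)
    n_gcn_layers: int = 3
    hidden_dim: int = 128


def build_dp_graph(drug_fp: Fingerprint,
                   partner_features: list[np.ndarray],
                   node_width: int | None = None) -> MolecularGraph:
    """Star graph over a drug and its interacting proteins.

    All nodes share one feature width: the maximum of the fingerprint length
    and the protein feature length (or an explicit ``node_width``), with
    zero padding on the right.  Protein vectors (compositions of magnitude
    ~1/20) are rescaled to the L2 norm of the fingerprint vector so both
    node types live on a comparable numeric scale; otherwise the partner
    identity is numerically invisible next to the 0/1 bits.
    """
    widths = [drug_fp.n_bits] + [len(p) for p in partner_features]
    width = node_width if node_width is not None else max(widths)
    if width < max(widths):
        raise ValueError("node_width smaller than a feature vector")
    n_nodes = 1 + len(partner_features)
    feats = np.zeros((n_nodes, width))
    feats[0, : drug_fp.n_bits] = drug_fp.bits
    drug_norm = np.linalg.norm(drug_fp.bits.astype(float))
    for k, pvec in enumerate(partner_features):
        norm = np.linalg.norm(pvec)
        scale = (drug_norm / norm) if norm > 0 and drug_norm > 0 else 1.0
        feats[1 + k, : len(pvec)] = np.asarray(pvec) * scale
    if partner_features:
        prot = np.arange(1, n_nodes, dtype=np.intp)
        drug = np.zeros(len(prot), dtype=np.intp)
        edge_index = np.stack(
            [np.concatenate([drug, prot]), np.concatenate([prot, drug])])
    else:
        edge_index = np.zeros((2, 0), dtype=np.intp)
    return MolecularGraph(feats, edge_index, n_nodes)


class DpGcnEncoder(nn.Module):
    """Drug-protein star graphs -> (B, hidden_dim) via 3 GCN layers + GMP."""

    def __init__(self, config: DpGcnConfig, rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.layers = []
        width = config.in_dim
        for _ in range(config.n_gcn_layers):
            self.layers.append(GCNLayer(width, config.hidden_dim, rng))
            width = config.hidden_dim

    @property
    def output_dim(self) -> int:
        return self.config.hidden_dim

    def forward(self, batch: GraphBatch) -> Tensor:
        h = Tensor(batch.node_features)
        for layer in self.layers:
            h = layer(h, batch.edge_index, batch.n_nodes)
        return segment_max(h, batch.ptr)


def encode_dp_graph(graph: MolecularGraph, encoder: DpGcnEncoder) -> Tensor:
    """Encode one drug's star graph to its branch embedding (hidden_dim)."""
    return encoder(batch_graphs([graph])).reshape(-1)
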