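"""Turn one drug into its four model inputs.

Aspirin's SMILES becomes (1) a fixed-length token sequence, (2) a
molecular graph, (3) a drug-protein star graph, and (4) an ECFP
fingerprint — the four characterizations the fusion model consumes.
"""

import numpy as np

from adrfusion.chem_io import (ProteinRecord, Vocabulary, compute_ecfp,
                               protein_features, smiles_to_graph,
                               tokenize_smiles)
from adrfusion.encoders.dp_gcn import build_dp_graph

ASPIRIN = "CC(=O)Oc1ccccc1C(=O)O"

vocab = Vocabulary.from_corpus([ASPIRIN, "CCO", "c1ccncc1"])
tokens = tokenize_smiles(ASPIRIN, vocab, max_len=32)
print(f"token ids ({tokens.n_real} real of {len(tokens.ids)}):",
      tokens.ids[:12], "...")

graph = smiles_to_graph(ASPIRIN)
print(f"molecular graph: {graph.n_nodes} atoms, "
      f"{graph.edge_index.shape[1] // 2} bonds, "
      f"{graph.node_features.shape[1]} features per atom")

fp = compute_ecfp(ASPIRIN, radius=2, n_bits=1024)
print(f"ECFP: {int(fp.bits.sum())} of {fp.n_bits} bits set")

# a toy target protein; in practice these come from a FASTA file
cox1 = ProteinRecord("COX1_FRAGMENT", "MSRSLLLRFLLFLLLLPPLPVLLADPGAPTPV")
star = build_dp_graph(fp, [protein_features(cox1)], node_width=1024)
print(f"drug-protein star graph: {star.n_nodes} nodes "
      f"(1 drug + {star.n_nodes - 1} protein), "
      f"{star.edge_index.shape[1]} directed edges")

# The token sequence feeds the transformer branch, the molecular graph the
# GAT-GCN branch, the star graph the drug-protein GCN branch, and the
# fingerprint drives Tanimoto similarity between drugs.
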