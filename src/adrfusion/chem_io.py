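"""Input parsing and the four drug characterizations.

A drug enters the model through four views of the same molecule:

1. a fixed-length integer token sequence of its SMILES string,
2. a 2D molecular graph (atoms as nodes, bonds as undirected edges),
3. a drug-protein star graph over its interacting proteins, and
4. an ECFP (Morgan) bit fingerprint, which also drives Tanimoto similarity.

RDKit does all chemistry (parsing, aromaticity, fingerprints); this module
owns the tabular dialects, screening rules and feature layouts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger
from rdkit.Chem import rdFingerprintGenerator

RDLogger.DisableLog("rdApp.*")  # RDKit parse chatter; rejects are logged below

logger = logging.getLogger("adrfusion")

PAD_ID = 0
UNK_ID = 1

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Pauling electronegativities for the supported element set (scaled /4 in
# features to keep magnitudes O(1)).
_ELECTRONEGATIVITY = {
    "C": 2.55, "N": 3.04, "O": 3.44, "S": 2.58, "F": 3.98, "Cl": 3.16,
    "Br": 2.96, "I": 2.66, "P": 2.19, "B": 2.04, "Si": 1.90, "Se": 2.55,
    "Na": 0.93, "K": 0.82, "Ca": 1.00, "Fe": 1.83,
}
_ELEMENTS = list(_ELECTRONEGATIVITY)  # top-16 elements; the rest map to "other"


class InvalidSmilesError(ValueError):
    """SMILES that RDKit cannot parse into a molecule with >= 1 atom."""


@dataclass(frozen=True)
class SmilesRecord:
    drug_id: str
    smiles: str


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str


@dataclass(frozen=True)
class TokenSequence:
    """Fixed-length integer encoding of a SMILES string."""

    ids: np.ndarray  # (max_len,) int
    n_real: int
    pad_id: int = PAD_ID

    def __post_init__(self):
        if self.n_real < 1:
            raise ValueError("token sequence must contain >= 1 real token")


@dataclass
class Vocabulary:
    """Character-token -> integer-id map; 0 is padding, 1 is unknown.

    Two-character halogens (Cl, Br) are the only multi-character tokens.
    Ids are assigned by sorted token order, so the vocabulary is a pure
    function of the token set of the training corpus.
    """

    token_to_id: dict[str, int]

    @classmethod
    def from_corpus(cls, smiles_iter) -> "Vocabulary":
        tokens = set()
        for smi in smiles_iter:
            tokens.update(split_smiles(smi))
        mapping = {tok: i + 2 for i, tok in enumerate(sorted(tokens))}
        return cls(mapping)

    def __len__(self) -> int:
        return len(self.token_to_id) + 2

    def __getitem__(self, token: str) -> int:
        return self.token_to_id.get(token, UNK_ID)


def split_smiles(smiles: str) -> list[str]:
    """Character-level split, keeping Cl/Br as single tokens."""
    out, i = [], 0
    while i < len(smiles):
        if smiles[i : i + 2] in ("Cl", "Br"):
            out.append(smiles[i : i + 2])
            i += 2
        else:
            out.append(smiles[i])
            i += 1
    return out


def tokenize_smiles(smiles: str, vocab: Vocabulary, max_len: int = 128) -> TokenSequence:
    """Truncate or right-pad the token stream to exactly ``max_len`` ids."""
    if not smiles:
        raise InvalidSmilesError("empty SMILES string")
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    toks = split_smiles(smiles)[:max_len]
    ids = np.full(max_len, PAD_ID, dtype=np.intp)
    ids[: len(toks)] = [vocab[t] for t in toks]
    return TokenSequence(ids=ids, n_real=len(toks))


@dataclass
class MolecularGraph:
    """Node-feature matrix plus a directed edge list storing each undirected
    edge in both orientations (also reused for drug-protein star graphs)."""

    node_features: np.ndarray  # (n_nodes, F) float
    edge_index: np.ndarray  # (2, n_edges) int; both directions present
    n_nodes: int

    def __post_init__(self):
        if self.n_nodes < 1:
            raise ValueError("graph needs >= 1 node")
        if self.edge_index.size and (
            self.edge_index.min() < 0 or self.edge_index.max() >= self.n_nodes
        ):
            raise ValueError("edge index out of range")


@dataclass(frozen=True)
class AtomFeatureSpec:
    """Layout of the per-atom descriptor vector."""

    elements: tuple[str, ...] = tuple(_ELEMENTS)
    max_degree: int = 5

    @property
    def width(self) -> int:
        # one-hot element (+other) | one-hot degree | charge | aromatic |
        # n_hydrogens | electronegativity
        return len(self.elements) + 1 + self.max_degree + 1 + 4


def _atom_features(atom: Chem.Atom, spec: AtomFeatureSpec) -> np.ndarray:
    v = np.zeros(spec.width)
    sym = atom.GetSymbol()
    idx = spec.elements.index(sym) if sym in spec.elements else len(spec.elements)
    v[idx] = 1.0
    off = len(spec.elements) + 1
    v[off + min(atom.GetDegree(), spec.max_degree)] = 1.0
    off += spec.max_degree + 1
    v[off] = atom.GetFormalCharge()
    v[off + 1] = 1.0 if atom.GetIsAromatic() else 0.0
    v[off + 2] = atom.GetTotalNumHs()
    v[off + 3] = _ELECTRONEGATIVITY.get(sym, 2.0) / 4.0
    return v


def parse_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    if mol is None or mol.GetNumAtoms() < 1:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def smiles_to_graph(smiles: str,
                    feature_spec: AtomFeatureSpec | None = None) -> MolecularGraph:
    """Molecular graph with per-atom descriptors and bidirectional bond edges."""
    spec = feature_spec or AtomFeatureSpec()
    mol = parse_smiles(smiles)
    feats = np.array([_atom_features(a, spec) for a in mol.GetAtoms()])
    src, dst = [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [i, j]
        dst += [j, i]
    edge_index = np.array([src, dst], dtype=np.intp).reshape(2, -1)
    return MolecularGraph(feats, edge_index, mol.GetNumAtoms())


@dataclass(frozen=True)
class Fingerprint:
    bits: np.ndarray  # (n_bits,) uint8 in {0,1}
    radius: int
    n_bits: int

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def compute_ecfp(smiles: str, radius: int = 2, n_bits: int = 2048) -> Fingerprint:
    """Extended-connectivity (Morgan) fingerprint as a binary bit vector."""
    if radius < 0:
        raise ValueError("radius must be >= 0")
    if n_bits < 8:
        raise ValueError("n_bits must be >= 8")
    mol = parse_smiles(smiles)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=n_bits)
    arr = np.array(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    return Fingerprint(bits=arr, radius=radius, n_bits=n_bits)


@dataclass
class DrugAdrTable:
    """Binary drugs x ADR-labels matrix."""

    drug_ids: list[str]
    label_names: list[str]
    Y: np.ndarray  # (n_drugs, n_labels) in {0,1}

    def __post_init__(self):
        if len(set(self.drug_ids)) != len(self.drug_ids):
            raise ValueError("duplicate drug_ids")
        if len(set(self.label_names)) != len(self.label_names):
            raise ValueError("duplicate label names")
        if self.Y.shape != (len(self.drug_ids), len(self.label_names)):
            raise ValueError("Y shape does not match id lists")

    def to_pairs(self) -> list[tuple[str, str]]:
        """Long-format (drug_id, adr_name) pairs (the de-duplicated set)."""
        rows, cols = np.nonzero(self.Y)
        return [(self.drug_ids[r], self.label_names[c]) for r, c in zip(rows, cols)]


@dataclass
class DrugProteinPairs:
    pairs: list[tuple[str, str]]

    def partners_of(self, drug_id: str) -> list[str]:
        return [p for d, p in self.pairs if d == drug_id]


def read_smiles_table(drugs_path) -> list[SmilesRecord]:
    """Read drugs.tsv (drug_id, smiles); screen out unparseable SMILES."""
    df = pd.read_csv(drugs_path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "smiles"], drugs_path)
    kept, rejected = [], 0
    for row in df.itertuples(index=False):
        try:
            parse_smiles("" if pd.isna(row.smiles) else row.smiles)
        except InvalidSmilesError:
            rejected += 1
            logger.warning("dropping drug %s: invalid SMILES %r", row.drug_id, row.smiles)
            continue
        kept.append(SmilesRecord(drug_id=str(row.drug_id), smiles=row.smiles))
    logger.info("read %d drugs from %s (%d rejected)", len(kept), drugs_path, rejected)
    return kept


def read_adr_table(pairs_path, drugs_path) -> DrugAdrTable:
    """Pivot long-format (drug_id, adr_name) pairs into a binary matrix.

    Drugs whose SMILES fails to parse are dropped (screened, with a logged
    count); pairs referencing unknown drugs are dropped with a warning;
    duplicate pairs collapse to a single 1.
    """
    drugs = read_smiles_table(drugs_path)
    drug_ids = [d.drug_id for d in drugs]
    if not drug_ids:
        raise ValueError(f"no drugs with valid SMILES in {drugs_path}")
    df = pd.read_csv(pairs_path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "adr_name"], pairs_path)
    if df.isna().any(axis=None):
        bad = int(df.isna().any(axis=1).idxmax()) + 2  # +header +0-base
        raise ValueError(f"malformed row at line {bad} of {pairs_path}")
    known = set(drug_ids)
    dropped = int((~df["drug_id"].isin(known)).sum())
    if dropped:
        logger.warning("dropped %d ADR pairs for drugs absent from %s",
                       dropped, drugs_path)
    df = df[df["drug_id"].isin(known)]
    label_names = sorted(df["adr_name"].unique())
    row = {d: i for i, d in enumerate(drug_ids)}
    col = {a: j for j, a in enumerate(label_names)}
    Y = np.zeros((len(drug_ids), len(label_names)), dtype=np.int8)
    for r in df.itertuples(index=False):
        Y[row[r.drug_id], col[r.adr_name]] = 1
    return DrugAdrTable(drug_ids=drug_ids, label_names=label_names, Y=Y)


def filter_rare_adrs(table: DrugAdrTable, min_count: int = 350) -> DrugAdrTable:
    """Censor rare labels (column sum < min_count), then drop drugs left
    with no labels at all."""
    if min_count < 0:
        raise ValueError("min_count must be >= 0")
    keep_labels = np.flatnonzero(table.Y.sum(axis=0) >= min_count)
    if keep_labels.size == 0:
        raise ValueError(
            f"min_count={min_count} removes every label; lower the threshold"
        )
    Y = table.Y[:, keep_labels]
    keep_drugs = np.flatnonzero(Y.sum(axis=1) >= 1)
    n_dropped = len(table.drug_ids) - keep_drugs.size
    if n_dropped:
        logger.info("filter_rare_adrs: %d drugs left label-free and removed",
                    n_dropped)
    return DrugAdrTable(
        drug_ids=[table.drug_ids[i] for i in keep_drugs],
        label_names=[table.label_names[j] for j in keep_labels],
        Y=Y[keep_drugs],
    )


def protein_features(record: ProteinRecord) -> np.ndarray:
    """20-dim amino-acid composition (frequencies over the standard alphabet).

    Unknown residues (X etc.) are excluded from the counts; the vector sums
    to 1 over recognised residues.
    """
    if not record.sequence:
        raise ValueError(f"empty sequence for protein {record.protein_id}")
    counts = np.zeros(20)
    for ch in record.sequence.upper():
        idx = AMINO_ACIDS.find(ch)
        if idx >= 0:
            counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError(
            f"protein {record.protein_id} has no recognised residues"
        )
    return counts / total


def read_protein_fasta(fasta_path) -> dict[str, ProteinRecord]:
    from Bio import SeqIO

    records = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        records[rec.id] = ProteinRecord(protein_id=rec.id, sequence=str(rec.seq))
    logger.info("read %d protein records from %s", len(records), fasta_path)
    return records


def read_dp_pairs(dp_path, drug_ids, proteins: dict[str, ProteinRecord]) -> DrugProteinPairs:
    """Read drug-protein pairs; unknown drugs/proteins dropped with a warning,
    duplicates collapsed."""
    df = pd.read_csv(dp_path, sep="\t", dtype=str)
    _require_columns(df, ["drug_id", "protein_id"], dp_path)
    known_drugs = set(drug_ids)
    pairs, seen, dropped = [], set(), 0
    for r in df.itertuples(index=False):
        key = (r.drug_id, r.protein_id)
        if r.drug_id not in known_drugs or r.protein_id not in proteins:
            dropped += 1
            continue
        if key in seen:
            continue
        seen.add(key)
        pairs.append(key)
    if dropped:
        logger.warning("dropped %d drug-protein pairs with unknown ids", dropped)
    logger.info("read %d drug-protein pairs from %s", len(pairs), dp_path)
    return DrugProteinPairs(pairs=pairs)


def _require_columns(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path} is missing required columns {missing}")
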