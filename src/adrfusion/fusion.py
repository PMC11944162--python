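"""Attention fusion of the four drug characterizations and the training loop.

The three neural branch embeddings (sequence, molecular graph, drug-protein
graph) are each aligned by their own affine adapter to ``align_dim`` (512 by
default) and reduced by a linear layer to ``block_dim`` (128); the
standardized similarity row passes through its own affine adapter straight
to ``block_dim`` so the four blocks are commensurate.  A two-linear-layer
scorer (weights shared across blocks) produces one scalar per block;
softmax over the active blocks gives the attention weights, and the fused
vector S is their weighted sum.  S feeds a small fully connected trunk with
one sigmoid output head per ADR label.

Training minimizes mean binary cross-entropy over all (drug, label) cells
with the adaptive-moment optimizer; everything is reproducible from the
seed in :class:`TrainConfig`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import nn
from .autodiff import Tensor, concat, stack
from .chem_io import (AtomFeatureSpec, DrugProteinPairs, Fingerprint,
                      MolecularGraph, ProteinRecord, SmilesRecord,
                      TokenSequence, Vocabulary, compute_ecfp,
                      protein_features, smiles_to_graph, tokenize_smiles)
from .encoders.dp_gcn import DpGcnConfig, DpGcnEncoder, build_dp_graph
from .encoders.gat_gcn import GatGcnConfig, GatGcnEncoder, batch_graphs
from .encoders.transformer import TransformerConfig, SequenceEncoder
from .similarity import similarity_matrix, similarity_row

logger = logging.getLogger("adrfusion")

BRANCHES = ("sequence", "graph", "dp_graph", "similarity")


@dataclass
class FusionConfig:
    align_dim: int = 512
    block_dim: int = 128
    attn_hidden: int = 64
    hidden_dims: tuple[int, ...] = (256, 128)
    dropout: float = 0.1
    # the similarity row is one feature per training drug and memorizes
    # easily; heavier input dropout forces distributed neighbor voting
    sim_dropout: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0,1)")


@dataclass
class TrainConfig:
    lr: float = 1e-4
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "adam"
    weight_decay: float = 0.0
    patience: int | None = None  # early stopping on an internal val split
    val_fraction: float = 0.15

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")


@dataclass
class PipelineConfig:
    """All knobs of the four-branch pipeline in one place."""

    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    gat_gcn: GatGcnConfig = field(default_factory=GatGcnConfig)
    dp_gcn: DpGcnConfig = field(default_factory=DpGcnConfig)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    fp_radius: int = 2
    fp_bits: int = 2048

    @classmethod
    def desk_scale(cls) -> "PipelineConfig":
        """Small widths for laptop-scale experiments and the test suite."""
        return cls(
            transformer=TransformerConfig(d_model=32, n_heads=4, d_ff=64,
                                          n_layers=1, max_len=48),
            gat_gcn=GatGcnConfig(hidden_dim=8, n_heads=2),
            dp_gcn=DpGcnConfig(in_dim=128, hidden_dim=16),
            fusion=FusionConfig(align_dim=32, block_dim=16, attn_hidden=16,
                                hidden_dims=(32,)),
            fp_bits=128,
        )

    @classmethod
    def study_scale(cls) -> "PipelineConfig":
        """Widths used for the package's synthetic cross-validation and
        ablation studies: a deliberately small sequence branch (it
        memorizes easily at a few hundred drugs) and wider graph/fusion
        blocks that can carry the planted multi-label signal."""
        return cls(
            transformer=TransformerConfig(d_model=16, n_heads=2, d_ff=32,
                                          n_layers=1, max_len=48, dropout=0.2),
            gat_gcn=GatGcnConfig(hidden_dim=12, n_heads=2),
            dp_gcn=DpGcnConfig(in_dim=128, hidden_dim=32),
            fusion=FusionConfig(align_dim=64, block_dim=32, attn_hidden=32,
                                hidden_dims=(64,), dropout=0.2),
            fp_bits=128,
        )


@dataclass
class FeatureBundle:
    """Precomputed model inputs for a fixed drug list."""

    drug_ids: list[str]
    smiles: list[str]
    vocab: Vocabulary
    token_ids: np.ndarray  # (n, max_len)
    n_real: np.ndarray  # (n,)
    mol_graphs: list[MolecularGraph]
    dp_graphs: list[MolecularGraph]
    fingerprints: list[Fingerprint]
    atom_spec: AtomFeatureSpec

    def __len__(self) -> int:
        return len(self.drug_ids)


def build_features(drugs: list[SmilesRecord],
                   dp_pairs: DrugProteinPairs,
                   proteins: dict[str, ProteinRecord],
                   config: PipelineConfig,
                   vocab: Vocabulary | None = None) -> FeatureBundle:
    """Convert parsed inputs into the four per-drug representations."""
    atom_spec = AtomFeatureSpec()
    vocab = vocab or Vocabulary.from_corpus(d.smiles for d in drugs)
    max_len = config.transformer.max_len
    tokens = [tokenize_smiles(d.smiles, vocab, max_len) for d in drugs]
    partner_map: dict[str, list[np.ndarray]] = {d.drug_id: [] for d in drugs}
    for drug_id, protein_id in dp_pairs.pairs:
        if drug_id in partner_map:
            partner_map[drug_id].append(protein_features(proteins[protein_id]))
    fps = [compute_ecfp(d.smiles, config.fp_radius, config.fp_bits)
           for d in drugs]
    node_width = max(config.fp_bits, 20)
    if config.dp_gcn.in_dim < node_width:
        raise ValueError(
            f"dp_gcn.in_dim={config.dp_gcn.in_dim} < node width {node_width}")
    dp_graphs = [
        build_dp_graph(fp, partner_map[d.drug_id], node_width=config.dp_gcn.in_dim)
        for fp, d in zip(fps, drugs)
    ]
    return FeatureBundle(
        drug_ids=[d.drug_id for d in drugs],
        smiles=[d.smiles for d in drugs],
        vocab=vocab,
        token_ids=np.stack([t.ids for t in tokens]),
        n_real=np.array([t.n_real for t in tokens]),
        mol_graphs=[smiles_to_graph(d.smiles, atom_spec) for d in drugs],
        dp_graphs=dp_graphs,
        fingerprints=fps,
        atom_spec=atom_spec,
    )


@dataclass
class FusedVector:
    S: np.ndarray  # (block_dim,)
    attention_weights: np.ndarray  # one non-negative weight per active block


class AdrFusionModel(nn.Module):
    """Four-branch encoder + attention fusion + multi-label sigmoid heads.

    ``dropped_branch`` removes one characterization entirely (its encoder is
    not even constructed); the attention softmax then runs over the
    remaining blocks.
    """

    def __init__(self, config: PipelineConfig, vocab_size: int, n_train: int,
                 n_labels: int, seed: int = 0,
                 dropped_branch: str | None = None):
        super().__init__()
        if dropped_branch is not None and dropped_branch not in BRANCHES:
            raise ValueError(f"unknown branch {dropped_branch!r}")
        if n_labels < 1:
            raise ValueError("n_labels must be >= 1")
        self.config = config
        self.n_labels = n_labels
        self.n_train = n_train
        self.active = tuple(b for b in BRANCHES if b != dropped_branch)
        rng = np.random.default_rng(seed)
        self.rng = rng
        fc = config.fusion

        tcfg = dataclasses.replace(config.transformer, vocab_size=vocab_size)
        self.seq_encoder = (SequenceEncoder(tcfg, rng)
                            if "sequence" in self.active else None)
        self.graph_encoder = (GatGcnEncoder(config.gat_gcn, rng)
                              if "graph" in self.active else None)
        self.dp_encoder = (DpGcnEncoder(config.dp_gcn, rng)
                           if "dp_graph" in self.active else None)

        self.adapters: dict[str, nn.Linear] = {}
        self.reducers: dict[str, nn.Linear] = {}
        for branch, enc in (("sequence", self.seq_encoder),
                            ("graph", self.graph_encoder),
                            ("dp_graph", self.dp_encoder)):
            if enc is not None:
                self.adapters[branch] = nn.Linear(enc.output_dim, fc.align_dim, rng)
                self.reducers[branch] = nn.Linear(fc.align_dim, fc.block_dim, rng)
        self.sim_adapter = (nn.Linear(n_train, fc.block_dim, rng)
                            if "similarity" in self.active else None)

        self.attn1 = nn.Linear(fc.block_dim, fc.attn_hidden, rng)
        self.attn2 = nn.Linear(fc.attn_hidden, 1, rng)

        self.trunk: list[nn.Linear] = []
        width = fc.block_dim
        for h in fc.hidden_dims:
            self.trunk.append(nn.Linear(width, h, rng))
            width = h
        self.head = nn.Linear(width, n_labels, rng)
        self.drop = nn.Dropout(fc.dropout, rng)
        self.sim_drop = nn.Dropout(fc.sim_dropout, rng)

    # -- fusion pieces -------------------------------------------------------
    def adapt_branches(self, embeddings: dict[str, Tensor]) -> dict[str, Tensor]:
        """Affine-align s1..s3 to align_dim then reduce to block_dim; the
        similarity row goes through its own adapter straight to block_dim."""
        blocks: dict[str, Tensor] = {}
        for branch in self.active:
            if branch not in embeddings:
                continue
            emb = embeddings[branch]
            if not np.isfinite(emb.data).all():
                raise ValueError(f"non-finite embedding in branch {branch!r}")
            if branch == "similarity":
                blocks[branch] = self.sim_adapter(self.sim_drop(emb))
            else:
                blocks[branch] = self.reducers[branch](self.adapters[branch](emb))
        return blocks

    def fuse(self, blocks: dict[str, Tensor]) -> tuple[Tensor, Tensor]:
        """Attention-weighted sum of the aligned blocks.

        Returns (S, weights): S (B, block_dim), weights (B, n_active).
        """
        ordered = [blocks[b] for b in self.active if b in blocks]
        scores = concat(
            [self.attn2(self.attn1(b).relu()) for b in ordered], axis=-1)
        weights = scores.softmax(axis=-1)
        stacked = stack(ordered, axis=1)  # (B, n_blocks, block_dim)
        S = (weights.reshape(*weights.shape, 1) * stacked).sum(axis=1)
        return S, weights

    def forward_batch(self, bundle: FeatureBundle, indices: np.ndarray,
                      sim_rows: np.ndarray | None) -> Tensor:
        """Logits (B, n_labels) for the drugs at ``indices``."""
        indices = np.asarray(indices)
        embeddings: dict[str, Tensor] = {}
        if self.seq_encoder is not None:
            embeddings["sequence"] = self.seq_encoder(
                bundle.token_ids[indices], bundle.n_real[indices])
        if self.graph_encoder is not None:
            embeddings["graph"] = self.graph_encoder(
                batch_graphs([bundle.mol_graphs[i] for i in indices]))
        if self.dp_encoder is not None:
            embeddings["dp_graph"] = self.dp_encoder(
                batch_graphs([bundle.dp_graphs[i] for i in indices]))
        if self.sim_adapter is not None:
            if sim_rows is None:
                raise ValueError("similarity branch active but sim_rows missing")
            embeddings["similarity"] = Tensor(sim_rows)
        missing = [b for b in self.active if b not in embeddings]
        if missing:
            raise ValueError(f"missing representations for branches {missing}")
        blocks = self.adapt_branches(embeddings)
        S, _ = self.fuse(blocks)
        x = S
        for lin in self.trunk:
            x = self.drop(lin(x).relu())
        return self.head(x)


# -- functional surface (single-drug contracts) ------------------------------

def adapt_features(s1: Tensor, s2: Tensor, s3: Tensor,
                   model: AdrFusionModel) -> tuple[Tensor, Tensor, Tensor]:
    """Align the three neural branch embeddings to block_dim vectors."""
    out = model.adapt_branches({
        "sequence": s1.reshape(1, -1),
        "graph": s2.reshape(1, -1),
        "dp_graph": s3.reshape(1, -1),
        "similarity": Tensor(np.zeros((1, model.n_train))),
    })
    return (out["sequence"].reshape(-1), out["graph"].reshape(-1),
            out["dp_graph"].reshape(-1))


def fuse_attention(blocks: list[Tensor | np.ndarray],
                   model: AdrFusionModel) -> FusedVector:
    """Attention-fuse already-aligned blocks into one vector."""
    named = {}
    for branch, b in zip(model.active, blocks):
        t = b if isinstance(b, Tensor) else Tensor(b)
        if not np.isfinite(t.data).all():
            raise ValueError(f"non-finite block for branch {branch!r}")
        named[branch] = t.reshape(1, -1)
    S, w = model.fuse(named)
    return FusedVector(S=S.data.reshape(-1), attention_weights=w.data.reshape(-1))


def forward(tokens: TokenSequence, mol_graph: MolecularGraph,
            dp_graph: MolecularGraph, sim_row: np.ndarray,
            model: AdrFusionModel, bundle_template: FeatureBundle | None = None
            ) -> np.ndarray:
    """Probability vector for one drug given its four representations."""
    bundle = FeatureBundle(
        drug_ids=["query"], smiles=[""], vocab=Vocabulary({}),
        token_ids=tokens.ids[None, :], n_real=np.array([tokens.n_real]),
        mol_graphs=[mol_graph], dp_graphs=[dp_graph], fingerprints=[],
        atom_spec=AtomFeatureSpec(),
    )
    was_training = model.training
    model.eval()
    logits = model.forward_batch(bundle, np.array([0]),
                                 np.asarray(sim_row)[None, :]
                                 if sim_row is not None else None)
    if was_training:
        model.train()
    return 1.0 / (1.0 + np.exp(-logits.data[0]))


# -- training ----------------------------------------------------------------

@dataclass
class TrainResult:
    model: AdrFusionModel
    train_idx: np.ndarray
    train_fps: list[Fingerprint]
    sim_rows_train: np.ndarray  # (n_train, n_train) standardized rows
    loss_trace: list[float]
    pipeline_config: PipelineConfig
    train_config: TrainConfig
    vocab: Vocabulary
    train_smiles: list[str]
    label_names: list[str] | None = None


def _train_similarity(bundle: FeatureBundle, train_idx: np.ndarray):
    """Leave-self-out similarity rows for the training drugs.

    The self-similarity entry (Tanimoto 1.0 with itself) is a one-hot drug
    identity that a linear adapter can memorize but that unseen drugs never
    carry; it is replaced by the row's off-diagonal mean before row
    standardization so training and inference rows are distributionally
    alike.
    """
    from .similarity import standardize_rows

    fps = [bundle.fingerprints[i] for i in train_idx]
    ids = [bundle.drug_ids[i] for i in train_idx]
    sim = similarity_matrix(fps, ids)
    S = sim.S_raw.copy()
    n = S.shape[0]
    off_mean = (S.sum(axis=1) - np.diag(S)) / max(n - 1, 1)
    S[np.diag_indices(n)] = off_mean
    return fps, standardize_rows(S)


def train_model(bundle: FeatureBundle, Y: np.ndarray, train_idx: np.ndarray,
                pipeline_config: PipelineConfig, train_config: TrainConfig,
                dropped_branch: str | None = None) -> TrainResult:
    """Fit the fusion model on the training drugs; reproducible from seed.

    With ``patience`` set, a fraction of the training drugs is held out as
    an internal validation split; training stops once the validation score
    (micro average precision, which tracks the ranking quality the
    evaluation cares about rather than calibration) has not improved for
    ``patience`` epochs, and the best-validation weights are restored.
    Validation drugs are treated as unseen for the similarity branch (row
    against the fit drugs only).
    """
    Y = np.asarray(Y)
    train_idx = np.asarray(train_idx)
    if train_idx.size == 0:
        raise ValueError("empty training fold")
    empty = np.flatnonzero(Y[train_idx].sum(axis=0) == 0)
    if empty.size:
        logger.warning("%d labels have no positive training example", empty.size)

    rng = np.random.default_rng(train_config.seed)
    if train_config.patience is not None and len(train_idx) >= 10:
        n_val = max(1, int(round(train_config.val_fraction * len(train_idx))))
        perm = rng.permutation(len(train_idx))
        val_idx = train_idx[perm[:n_val]]
        fit_idx = train_idx[perm[n_val:]]
    else:
        val_idx, fit_idx = np.array([], dtype=int), train_idx

    model = AdrFusionModel(
        pipeline_config, vocab_size=len(bundle.vocab),
        n_train=len(fit_idx), n_labels=Y.shape[1],
        seed=train_config.seed, dropped_branch=dropped_branch)
    if "similarity" in model.active:
        train_fps, sim_rows = _train_similarity(bundle, fit_idx)
        val_rows = (np.stack([similarity_row(bundle.fingerprints[i], train_fps)
                              for i in val_idx])
                    if val_idx.size else None)
    else:
        train_fps, sim_rows = [], np.zeros((len(fit_idx), len(fit_idx)))
        val_rows = None

    opt = nn.Adam(model.parameters(), lr=train_config.lr,
                  weight_decay=train_config.weight_decay)
    pos_of = {int(g): p for p, g in enumerate(fit_idx)}  # global -> sim row
    loss_trace: list[float] = []
    best_val, best_params, since_best = -np.inf, None, 0
    model.train()
    for epoch in range(train_config.epochs):
        order = rng.permutation(len(fit_idx))
        epoch_losses = []
        for start in range(0, len(order), train_config.batch_size):
            batch_local = order[start : start + train_config.batch_size]
            batch = fit_idx[batch_local]
            rows = sim_rows[[pos_of[int(g)] for g in batch]]
            logits = model.forward_batch(bundle, batch, rows)
            loss = nn.binary_cross_entropy_with_logits(logits, Y[batch])
            if not np.isfinite(loss.data):
                raise RuntimeError(f"training diverged at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_losses.append(loss.item())
        loss_trace.append(float(np.mean(epoch_losses)))
        if val_idx.size:
            from sklearn.metrics import average_precision_score

            model.eval()
            val_logits = model.forward_batch(bundle, val_idx, val_rows)
            model.train()
            y_val = Y[val_idx].ravel()
            if y_val.min() == y_val.max():  # degenerate split: fall back
                val_score = -nn.binary_cross_entropy_with_logits(
                    val_logits, Y[val_idx]).item()
            else:
                val_score = float(average_precision_score(
                    y_val, val_logits.data.ravel()))
            if val_score > best_val + 1e-6:
                best_val = val_score
                best_params = [p.data.copy() for p in model.parameters()]
                since_best = 0
            else:
                since_best += 1
                if since_best >= train_config.patience:
                    break
    if best_params is not None:
        for p, saved in zip(model.parameters(), best_params):
            p.data = saved
    model.eval()
    return TrainResult(model=model, train_idx=fit_idx, train_fps=train_fps,
                       sim_rows_train=sim_rows, loss_trace=loss_trace,
                       pipeline_config=pipeline_config,
                       train_config=train_config,
                       vocab=bundle.vocab,
                       train_smiles=[bundle.smiles[i] for i in fit_idx])


def predict_proba(result: TrainResult, bundle: FeatureBundle,
                  indices: np.ndarray) -> np.ndarray:
    """Per-label probabilities for drugs in ``bundle`` (train or unseen).

    Unseen drugs get a similarity row against the training set only,
    standardized with that row's own mean/sd.
    """
    model = result.model
    model.eval()
    indices = np.asarray(indices)
    if "similarity" in model.active:
        pos_of = {int(g): p for p, g in enumerate(result.train_idx)}
        rows = np.stack([
            result.sim_rows_train[pos_of[int(i)]] if int(i) in pos_of
            else similarity_row(bundle.fingerprints[i], result.train_fps)
            for i in indices
        ])
    else:
        rows = None
    logits = model.forward_batch(bundle, indices, rows)
    return 1.0 / (1.0 + np.exp(-logits.data))


def predict_new(result: TrainResult, bundle: FeatureBundle) -> np.ndarray:
    """Probabilities for a bundle of drugs outside the training set: every
    similarity row is computed against the stored training fingerprints."""
    model = result.model
    model.eval()
    if "similarity" in model.active:
        rows = np.stack([similarity_row(fp, result.train_fps)
                         for fp in bundle.fingerprints])
    else:
        rows = None
    logits = model.forward_batch(bundle, np.arange(len(bundle)), rows)
    return 1.0 / (1.0 + np.exp(-logits.data))


# -- checkpointing -----------------------------------------------------------

def save_checkpoint(result: TrainResult, run_dir) -> None:
    """Weights to ``weights.npz`` plus a JSON sidecar with every config
    field, the vocabulary and the training-set SMILES (needed to rebuild
    similarity rows for unseen drugs)."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    params = list(result.model.parameters())
    np.savez(run_dir / "weights.npz",
             **{f"p{i}": p.data for i, p in enumerate(params)})
    sidecar = {
        "pipeline_config": _config_to_dict(result.pipeline_config),
        "train_config": dataclasses.asdict(result.train_config),
        "n_labels": result.model.n_labels,
        "n_train": result.model.n_train,
        "dropped_branch": next(
            (b for b in BRANCHES if b not in result.model.active), None),
        "vocab": result.vocab.token_to_id,
        "train_smiles": result.train_smiles,
        "label_names": result.label_names,
        "loss_trace": result.loss_trace,
    }
    (run_dir / "checkpoint.json").write_text(json.dumps(sidecar, indent=2))


def load_checkpoint(run_dir) -> TrainResult:
    """Rebuild a trained model (and its similarity context) from disk."""
    run_dir = Path(run_dir)
    sidecar = json.loads((run_dir / "checkpoint.json").read_text())
    pc = PipelineConfig(
        transformer=TransformerConfig(**sidecar["pipeline_config"]["transformer"]),
        gat_gcn=GatGcnConfig(**sidecar["pipeline_config"]["gat_gcn"]),
        dp_gcn=DpGcnConfig(**sidecar["pipeline_config"]["dp_gcn"]),
        fusion=FusionConfig(**{
            k: tuple(v) if k == "hidden_dims" else v
            for k, v in sidecar["pipeline_config"]["fusion"].items()}),
        fp_radius=sidecar["pipeline_config"]["fp_radius"],
        fp_bits=sidecar["pipeline_config"]["fp_bits"],
    )
    tc = TrainConfig(**sidecar["train_config"])
    vocab = Vocabulary(dict(sidecar["vocab"]))
    model = AdrFusionModel(pc, vocab_size=len(vocab),
                           n_train=sidecar["n_train"],
                           n_labels=sidecar["n_labels"], seed=tc.seed,
                           dropped_branch=sidecar["dropped_branch"])
    weights = np.load(run_dir / "weights.npz")
    for i, p in enumerate(model.parameters()):
        p.data = weights[f"p{i}"]
    model.eval()
    train_smiles = sidecar["train_smiles"]
    if "similarity" in model.active:
        train_fps = [compute_ecfp(s, pc.fp_radius, pc.fp_bits)
                     for s in train_smiles]
        sim_rows = similarity_matrix(
            train_fps, [f"t{i}" for i in range(len(train_fps))]).S_std
    else:
        train_fps, sim_rows = [], np.zeros((len(train_smiles),) * 2)
    return TrainResult(
        model=model, train_idx=np.arange(len(train_smiles)),
        train_fps=train_fps, sim_rows_train=sim_rows,
        loss_trace=list(sidecar.get("loss_trace") or []),
        pipeline_config=pc, train_config=tc, vocab=vocab,
        train_smiles=train_smiles, label_names=sidecar.get("label_names"))


def _config_to_dict(pc: PipelineConfig) -> dict:
    return {
        "transformer": dataclasses.asdict(pc.transformer),
        "gat_gcn": dataclasses.asdict(pc.gat_gcn),
        "dp_gcn": dataclasses.asdict(pc.dp_gcn),
        "fusion": dataclasses.asdict(pc.fusion),
        "fp_radius": pc.fp_radius,
        "fp_bits": pc.fp_bits,
    }
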