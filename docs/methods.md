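# Methods

This note records the modelling assumptions, the parameters that matter,
what the synthetic-data generator does and does not emulate, the numerical
choices, and the limitations we know about. Nothing here states an
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model

### Inputs

A drug is represented four ways, all derived from its SMILES string plus a
table of protein partners:

- **Token sequence.** Character-level tokens (the two-character halogens
  `Cl`/`Br` are the only merged symbols), truncated or right-padded to
  `max_len` (default 128; the desk/study configurations use 48). The
  vocabulary is built from the training corpus with lexicographically
  sorted ids starting at 2; id 0 is padding, id 1 unknown. Character-level
  tokenization is the simplest reproducible reading of "one symbol, one
  token"; merging halogens avoids chemically meaningless splits.
- **Molecular graph.** One node per atom, both directions of every bond in
  the edge list. Atom features (width 27): one-hot element over the 16 most
  common pharmaceutical elements plus *other*, one-hot degree 0–5, formal
  charge, aromaticity flag, attached-hydrogen count, and Pauling
  electronegativity scaled by 1/4. The feature set covers the properties a
  chemist would name first (element, valence context, aromaticity,
  electronegativity) at a fixed, testable width.
- **Drug–protein star graph.** One drug node (features: Morgan fingerprint,
  zero-padded to the common node width) connected to one node per
  interacting protein (features: 20-dim amino-acid composition). Protein
  vectors are rescaled to the L2 norm of the fingerprint vector: a
  composition vector has entries of order 1/20 and is numerically invisible
  next to 0/1 bits without this. Drugs with no partners are isolated
  nodes, so every drug has a drug–protein embedding. A single global graph
  over all drugs and proteins is a defensible alternative reading; the
  star-per-drug construction was chosen because it keeps inference per-drug
  and degrades gracefully for partnerless drugs.
- **Fingerprint.** ECFP via RDKit's Morgan generator, radius 2, 2048 bits
  by default (the field-standard ECFP4 setting); the similarity branch and
  the drug node of the star graph share it.

### Branches

- **Transformer encoder** (sequence): embedding + fixed sinusoidal
  positions, `n_layers` post-norm encoder blocks (multi-head self-attention
  with padding keys masked at −∞ before the softmax; position-wise FFN;
  residual + LayerNorm around each sublayer), then masked mean pooling over
  non-pad positions. Reference widths: d_model 512, 8 heads, d_ff 2048,
  dropout 0.1. The number of encoder layers defaults to 2 (the smallest
  "multiple"); pooling is mean rather than max because padding invariance
  is then exactly testable (max is available by configuration).
- **GAT-GCN** (molecular graph): three GAT layers (per-head width =
  `hidden_dim`, heads concatenated, ELU between layers, LeakyReLU slope 0.2
  in the scorer, self-loop included in each neighborhood so single atoms
  are well-defined), two GCN layers with symmetric degree normalization and
  ReLU, then concatenated global max + mean pooling (output 2×hidden_dim).
  Reference: 10 heads, hidden 128, dropout 0.2.
- **Drug–protein GCN**: three GCN layers with ReLU, global max pooling
  (output hidden_dim, reference 128).
- **Similarity**: raw Tanimoto matrix → triangle averaging →
  per-row Z-score with the population (n-denominator) standard deviation.
  Row standardization follows symmetrization and generally breaks symmetry
  again; the procedure is preserved in that order deliberately, and a test
  asserts the code does not re-symmetrize. Zero-variance rows (all
  similarities identical) are set to zero with a warning rather than
  fabricating contrast. At inference, an unseen drug's row is computed
  against the training drugs only and standardized with its own mean/sd,
  keeping the feature width fixed at n_train.

### Fusion and output

Branch embeddings pass through per-branch affine adapters to `align_dim`
(512 reference), then a linear reduction to `block_dim` (128). The
similarity row has its own affine adapter straight to `block_dim` so all
four blocks are commensurate — the attention mechanism needs same-width
blocks to produce a weighted sum. A two-layer scorer with weights shared
across blocks yields one scalar per block; softmax over the (active)
blocks gives non-negative weights summing to one, and the fused vector is
the weighted sum. Fully connected layers (reference 256→128, ReLU,
dropout) feed one affine + sigmoid head per label. Removing a branch for
ablation removes its encoder entirely; the softmax then runs over the
remaining blocks.

Two regularization details matter for the similarity branch. First,
training-time similarity rows are *leave-self-out*: the self-similarity
entry (Tanimoto 1.0 of a drug with itself) is a one-hot identity feature
that a linear adapter memorizes instantly but that unseen drugs never
carry, so it is replaced by the row's off-diagonal mean before
standardization. Second, the similarity input gets heavier dropout
(`sim_dropout`, default 0.5): one input feature per training drug invites
memorization, and the dropout forces distributed neighbor voting.

### Training

Mean binary cross-entropy over all (drug, label) cells, computed stably
from logits (`softplus(z) − yz`), with Adam (lr 1e-4 reference, 3e-3 in
the desk-scale studies), optional decoupled weight decay, batch size 32–64,
seeded shuffling. Optional early stopping holds out `val_fraction`
(default 15%) of the training drugs, monitors micro average precision —
validation BCE rises with over-confidence while ranking still improves, so
a ranking metric is the right monitor — and restores the best weights
after `patience` epochs without improvement. Validation drugs are treated
as unseen for the similarity branch. Initialization is uniform Glorot
everywhere from a single `numpy.random.Generator`, so a run is a pure
function of its seed.

All tensors are float64 on a ~600-line reverse-mode autodiff engine
written for this package. That engine is deliberately boring: only the ops
the model needs, each gradient-checked against central finite differences,
and each layer's forward pass checked against an independent dense
brute-force implementation on small instances (tolerance 1e-6).

## Evaluation protocol

Multi-label stratified K-fold: iterative stratification assigns the
rarest label's remaining samples first, each to the fold with the greatest
remaining demand for that label (ties: overall remaining capacity, then a
seeded draw). A swap-refinement pass follows: pairs of samples in
different folds are exchanged whenever that strictly lowers the squared
deviation of per-label fold counts from count/k. The greedy stage alone
balanced only ~70% of frequent labels to within ±1 of count/k on random
100×10 matrices; with refinement the method's worst per-label deviation is
roughly five times smaller than plain K-fold's (both recomputed by
`scripts/acceptance.py`).

Metrics are computed per label — F1 at threshold 0.5, rank-based ROC-AUC,
average-precision AUPR, all via scikit-learn — and macro-averaged as the
headline numbers, with micro averages reported alongside. Macro averaging
is the right default for imbalanced multi-label data because it weights
rare reactions equally. Labels lacking both classes in an evaluation split
are excluded from the averages and listed in the report. The test suite
pins all three metrics to exhaustive threshold-sweep / pair-counting
oracles at 1e-9, including under score ties.

## Synthetic data

The generator emulates the statistical shape of a screened ADR corpus:
a few hundred drugs with valid SMILES (assembled from a fragment library —
backbones, rings, parenthesized substituents — with rejection sampling so
every emitted string parses), per-label base frequencies drawn uniformly
from `label_freq_range` (default 0.2–0.5, i.e. ~2.5:1 imbalance), zero
sparsity (a label-free drug receives its highest-probability label, mirroring
corpora in which every retained drug has at least one recorded reaction), and
a sparse drug–protein pairing (Poisson partners per drug).

The planted signal ties each label to three designated fingerprint bits
(chosen among bits with prevalence 0.2–0.8) and two designated proteins.
A drug's label logit is shifted by `signal_strength × 3 × (bit_score +
partner_score)` where each score is the mean of ±1 indicators, and shifts
are centred per label so that label prevalence is independent of signal
strength (uncentred planting changes prevalence and confounds AUPR
comparisons across strengths). At strength 1 typical shifts are ~1 logit
and extreme drugs reach ~3, enough for near-deterministic labels at the
extremes without any single feature being fully predictive. Held-out
macro-AUPR rises monotonically with signal strength (asserted over three
seeds in the test suite).

What the generator does **not** emulate: real label co-occurrence
structure, realistic chemistry (fragment assembly is not medicinal
chemistry), protein sequences with homology structure, or noise in the
drug–protein table. Passing tests therefore demonstrate that the machinery
learns and evaluates correctly under controlled conditions, not that the
model reaches any particular accuracy on real pharmacovigilance data.

## Study problem sizes

The reference configuration (512-dim transformer etc.) is the package
default but is not what the studies run: the synthetic studies use
deliberately small widths (`PipelineConfig.study_scale()`: 16-dim
transformer, 2-head/12-dim GAT, 32-dim dp-GCN and fusion blocks) with
300 drugs, 8 labels, 12 proteins, 3-fold splits, and two-seed prediction
ensembles where run-to-run noise matters. These sizes were chosen so a
full study runs in minutes on a single CPU core while every qualitative
behavior (learnability, null calibration, stratification quality,
branch ablation) remains measurable.

## Ablation findings and limitations

With the study protocol, removing the **drug–protein branch** costs a
large, reproducible amount of held-out macro-AUPR (the partner half of the
planted signal is visible to no other branch). Removing the transformer,
the GAT-GCN or the similarity branch, in contrast, changes macro-AUPR by
amounts within run-to-run noise (±0.01): the three molecule-view branches
all derive from the same SMILES string and are informationally redundant
at this scale, so the attention fusion can compensate for any one of
them. A strict "full ≥ every single-branch-removed variant" ordering
therefore holds robustly only for the drug–protein branch; the
corresponding acceptance test encodes the strict ordering for all four
branches and documents this redundancy when it fails. We regard that as a
property of small-sample multi-view fusion — mutually redundant views have
near-zero marginal value — rather than an implementation defect: every
layer matches its dense oracle, the model memorizes planted rules
perfectly, and null-signal data yields chance-level AUC.

Other known limitations: the autodiff engine is single-threaded float64
NumPy and roughly two orders of magnitude slower than a GPU framework, so
the reference 512-dim configuration is practical only for small corpora;
character-level tokenization ignores multi-character ring-bond and isotope
syntax beyond halogens; protein features (amino-acid composition) discard
sequence order; and probabilities are uncalibrated (no Platt/isotonic
step) — they are ranking scores with a sigmoid range, not frequencies.
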