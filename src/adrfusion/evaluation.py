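"""Evaluation protocol: multi-label stratified K-fold, metrics, statistics.

The headline numbers are macro-averaged F1 (at threshold 0.5), ROC-AUC and
AUPR (average precision), computed per label and averaged over the labels
that carry both classes in the evaluated split; degenerate labels are
excluded from the averages and listed in the report.  Micro averages are
reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score


@dataclass
class FoldAssignment:
    fold_of: np.ndarray  # (n_drugs,) fold id in [0, k)
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_of != fold)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.fold_of, minlength=self.k)


def stratified_multilabel_kfold(Y: np.ndarray, k: int, seed: int = 0) -> FoldAssignment:
    """Iterative multi-label stratification (rarest-label-first greedy).

    Repeatedly takes the label with the fewest remaining unassigned
    positives and deals its samples to the fold with the greatest remaining
    demand for that label; ties break by overall remaining fold capacity,
    then by a seeded random draw.  Label-free samples are dealt to the
    emptiest folds at the end.  A swap-refinement pass then exchanges sample
    pairs between folds whenever that strictly lowers the squared deviation
    of per-label fold counts from their ideal count/k, which sharpens the
    balance of the frequent labels assigned last by the greedy stage
    without changing fold sizes.
    """
    Y = np.asarray(Y)
    n, L = Y.shape
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    fold_of = np.full(n, -1, dtype=int)
    # per-fold demand: desired positives per label, desired total size
    demand = np.tile(Y.sum(axis=0, dtype=float) / k, (k, 1))  # (k, L)
    capacity = np.full(k, n / k)
    unassigned = np.ones(n, dtype=bool)

    def pick_fold(label: int | None) -> int:
        if label is not None:
            best = demand[:, label]
        else:
            best = capacity
        cand = np.flatnonzero(best == best.max())
        if len(cand) > 1 and label is not None:
            caps = capacity[cand]
            cand = cand[caps == caps.max()]
        return int(rng.choice(cand))

    while True:
        remaining = (Y[unassigned].sum(axis=0)
                     if unassigned.any() else np.zeros(L))
        active = np.flatnonzero(remaining > 0)
        if active.size == 0:
            break
        label = int(active[np.argmin(remaining[active])])
        members = np.flatnonzero(unassigned & (Y[:, label] > 0))
        rng.shuffle(members)
        for i in members:
            f = pick_fold(label)
            fold_of[i] = f
            unassigned[i] = False
            demand[f, Y[i] > 0] -= 1.0
            capacity[f] -= 1.0
    for i in rng.permutation(np.flatnonzero(unassigned)):
        f = pick_fold(None)
        fold_of[i] = f
        unassigned[i] = False
        capacity[f] -= 1.0
    fold_of = _refine_by_swaps(Y, fold_of, k)
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


def _refine_by_swaps(Y: np.ndarray, fold_of: np.ndarray, k: int,
                     max_sweeps: int = 10) -> np.ndarray:
    """First-improvement swap hill-climbing on sum_l sum_f (C_fl - c_l/k)^2.

    Swapping samples i (fold f) and j (fold g) changes the objective by
    2 * sum_l [d_l^2 + d_l (C_gl - C_fl)] with d = Y_i - Y_j, so candidate
    swaps are scored vectorized per sample.  Fold sizes are untouched.
    """
    fold_of = fold_of.copy()
    C = np.stack([Y[fold_of == f].sum(axis=0) for f in range(k)]).astype(float)
    for _ in range(max_sweeps):
        improved = False
        for i in range(Y.shape[0]):
            f = fold_of[i]
            D = Y[i][None, :] - Y  # (n, L)
            delta = (D * D).sum(axis=1) + (D * (C[fold_of] - C[f])).sum(axis=1)
            delta[fold_of == f] = np.inf
            j = int(np.argmin(delta))
            if delta[j] < -1e-9:
                g = fold_of[j]
                d = (Y[i] - Y[j]).astype(float)
                C[f] -= d
                C[g] += d
                fold_of[i], fold_of[j] = g, f
                improved = True
        if not improved:
            break
    return fold_of


def plain_kfold(n: int, k: int, seed: int = 0) -> FoldAssignment:
    """Seeded unstratified K-fold (the comparison baseline)."""
    rng = np.random.default_rng(seed)
    fold_of = np.arange(n) % k
    rng.shuffle(fold_of)
    return FoldAssignment(fold_of=fold_of, k=k, seed=seed)


@dataclass
class LabelMetrics:
    label: str
    f1: float
    roc_auc: float
    aupr: float


@dataclass
class MetricsReport:
    f1: float
    roc_auc: float
    aupr: float
    per_label: list[LabelMetrics]
    micro: dict[str, float]
    excluded_labels: list[str]
    averaging: str = "macro"

    def as_dict(self) -> dict:
        return {
            "macro": {"f1": self.f1, "roc_auc": self.roc_auc, "aupr": self.aupr},
            "micro": dict(self.micro),
            "excluded_labels": list(self.excluded_labels),
            "per_label": [
                {"label": m.label, "f1": m.f1, "roc_auc": m.roc_auc,
                 "aupr": m.aupr}
                for m in self.per_label
            ],
        }


def compute_metrics(Y_true: np.ndarray, P: np.ndarray,
                    threshold: float = 0.5,
                    label_names: list[str] | None = None) -> MetricsReport:
    """Per-label F1 / ROC-AUC / AUPR with macro and micro averages.

    Labels without both a positive and a negative in ``Y_true`` are
    excluded from the averages and returned in ``excluded_labels``.
    """
    Y_true = np.asarray(Y_true)
    P = np.asarray(P)
    if Y_true.shape != P.shape:
        raise ValueError(f"shape mismatch: {Y_true.shape} vs {P.shape}")
    n, L = Y_true.shape
    names = label_names or [f"label_{j}" for j in range(L)]
    per_label, excluded, kept = [], [], []
    for j in range(L):
        y, p = Y_true[:, j], P[:, j]
        if y.min() == y.max():
            excluded.append(names[j])
            continue
        kept.append(j)
        per_label.append(LabelMetrics(
            label=names[j],
            f1=float(f1_score(y, p >= threshold, zero_division=0)),
            roc_auc=float(roc_auc_score(y, p)),
            aupr=float(average_precision_score(y, p)),
        ))
    if not per_label:
        raise ValueError("every label is degenerate in this split")
    yk = Y_true[:, kept].ravel()
    pk = P[:, kept].ravel()
    micro = {
        "f1": float(f1_score(yk, pk >= threshold, zero_division=0)),
        "roc_auc": float(roc_auc_score(yk, pk)),
        "aupr": float(average_precision_score(yk, pk)),
    }
    return MetricsReport(
        f1=float(np.mean([m.f1 for m in per_label])),
        roc_auc=float(np.mean([m.roc_auc for m in per_label])),
        aupr=float(np.mean([m.aupr for m in per_label])),
        per_label=per_label,
        micro=micro,
        excluded_labels=excluded,
    )


@dataclass
class DatasetStats:
    n_drugs: int
    n_labels: int
    n_pairs: int
    mean_labels_per_drug: float
    sparsity_pct: float
    top3_share_pct: float
    imbalance_ratio: float
    max_label_count: int
    min_label_count: int

    @property
    def imbalance_ratio_1dp(self) -> float:
        return round(self.imbalance_ratio, 1)


def dataset_statistics(table) -> DatasetStats:
    """Summary statistics of a drugs x ADR-labels binary matrix."""
    Y = np.asarray(table.Y)
    if Y.size == 0:
        raise ValueError("empty table")
    n, L = Y.shape
    counts = Y.sum(axis=0)
    n_pairs = int(Y.sum())
    top3 = int(np.sort(counts)[-3:].sum()) if L >= 3 else int(counts.sum())
    min_count = int(counts.min())
    return DatasetStats(
        n_drugs=n,
        n_labels=L,
        n_pairs=n_pairs,
        mean_labels_per_drug=n_pairs / n,
        sparsity_pct=100.0 * float((Y.sum(axis=1) == 0).sum()) / n,
        top3_share_pct=100.0 * top3 / n_pairs if n_pairs else 0.0,
        imbalance_ratio=(counts.max() / min_count) if min_count else float("inf"),
        max_label_count=int(counts.max()),
        min_label_count=min_count,
    )


# -- cross-validation and ablation harness ----------------------------------

ABLATION_VARIANTS = ("full", "drop_transformer", "drop_gatgcn", "drop_dp",
                     "drop_similarity")

_DROPPED_BRANCH = {
    "full": None,
    "drop_transformer": "sequence",
    "drop_gatgcn": "graph",
    "drop_dp": "dp_graph",
    "drop_similarity": "similarity",
}


@dataclass
class CrossvalResult:
    per_fold: list[MetricsReport]
    macro_f1: float
    macro_roc_auc: float
    macro_aupr: float
    fold_assignment: FoldAssignment

    def as_dict(self) -> dict:
        return {
            "k": self.fold_assignment.k,
            "seed": self.fold_assignment.seed,
            "macro": {"f1": self.macro_f1, "roc_auc": self.macro_roc_auc,
                      "aupr": self.macro_aupr},
            "per_fold": [r.as_dict() for r in self.per_fold],
        }


def run_crossval(bundle, table, pipeline_config, train_config,
                 k: int = 5, seed: int = 0,
                 fold_assignment: FoldAssignment | None = None,
                 folds: list[int] | None = None,
                 dropped_branch: str | None = None) -> CrossvalResult:
    """Multi-label stratified K-fold cross-validation of the fusion model.

    ``folds`` restricts evaluation to a subset of validation folds (each
    still trained on its own k-1 training folds), for scaled-down runs.
    """
    from . import fusion  # local import: fusion sits above evaluation

    assignment = fold_assignment or stratified_multilabel_kfold(
        table.Y, k=k, seed=seed)
    reports = []
    for fold in folds if folds is not None else range(assignment.k):
        train_idx = assignment.train_indices(fold)
        test_idx = assignment.test_indices(fold)
        result = fusion.train_model(
            bundle, table.Y, train_idx, pipeline_config, train_config,
            dropped_branch=dropped_branch)
        P = fusion.predict_proba(result, bundle, test_idx)
        reports.append(compute_metrics(table.Y[test_idx], P,
                                       label_names=table.label_names))
    return CrossvalResult(
        per_fold=reports,
        macro_f1=float(np.mean([r.f1 for r in reports])),
        macro_roc_auc=float(np.mean([r.roc_auc for r in reports])),
        macro_aupr=float(np.mean([r.aupr for r in reports])),
        fold_assignment=assignment,
    )


def run_ablation(bundle, table, fold_assignment: FoldAssignment, variant: str,
                 pipeline_config, train_config,
                 folds: list[int] | None = None) -> CrossvalResult:
    """Train/evaluate with one characterization branch removed.

    The attention fusion runs over the remaining three blocks (softmax
    renormalized by construction); ``variant="full"`` is the identity and
    equals a plain cross-validation run at the same seed.
    """
    if variant not in ABLATION_VARIANTS:
        raise ValueError(
            f"unknown variant {variant!r}; choose from {ABLATION_VARIANTS}")
    return run_crossval(
        bundle, table, pipeline_config, train_config,
        fold_assignment=fold_assignment, folds=folds,
        dropped_branch=_DROPPED_BRANCH[variant],
    )
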