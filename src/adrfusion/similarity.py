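"""Tanimoto drug-drug similarity with triangle averaging and per-row Z-score.

The raw matrix holds pairwise Tanimoto coefficients of binary fingerprints,
TC(A, B) = |A n B| / |A u B|.  It is symmetrized by averaging the upper and
lower triangles, then each row is standardized to zero mean and unit
variance (population standard deviation, n in the denominator).  Row
standardization happens *after* symmetrization and generally breaks the
symmetry again; that ordering is part of the procedure and is preserved
deliberately.  A row whose similarities are all identical has no contrast
to standardize; it is set to zeros with a logged warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .chem_io import Fingerprint

logger = logging.getLogger("adrfusion")


@dataclass
class SimilarityMatrix:
    S_raw: np.ndarray  # (n, n) symmetric Tanimoto coefficients
    S_std: np.ndarray  # (n, n) row-standardized
    drug_ids: list[str]

    def row_for(self, drug_id: str) -> np.ndarray:
        return self.S_std[self.drug_ids.index(drug_id)]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        ids = self.drug_ids
        return (pd.DataFrame(self.S_raw, index=ids, columns=ids),
                pd.DataFrame(self.S_std, index=ids, columns=ids))


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """|A n B| / |A u B| over the set bits of two equal-width fingerprints."""
    if a.n_bits != b.n_bits:
        raise ValueError("fingerprints differ in n_bits")
    inter = int(np.sum((a.bits & b.bits) > 0))
    union = int(np.sum((a.bits | b.bits) > 0))
    if union == 0:
        raise ValueError("Tanimoto undefined: both fingerprints are all-zero")
    return inter / union


def standardize_rows(S: np.ndarray) -> np.ndarray:
    """Per-row Z-score with population sd; zero-variance rows become zeros."""
    mean = S.mean(axis=1, keepdims=True)
    sd = S.std(axis=1, keepdims=True)  # population convention (ddof=0)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning("%d zero-variance similarity rows set to zeros",
                       int(flat.sum()))
    out = np.where(sd > 0, (S - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return out


def similarity_matrix(fps: list[Fingerprint],
                      drug_ids: list[str]) -> SimilarityMatrix:
    """Full pipeline: pairwise Tanimoto -> triangle average -> row Z-score."""
    if len(fps) < 2:
        raise ValueError("need >= 2 drugs for a similarity matrix")
    if len(fps) != len(drug_ids):
        raise ValueError("fps and drug_ids length mismatch")
    for fp, did in zip(fps, drug_ids):
        if fp.bits.sum() == 0:
            raise ValueError(f"drug {did} has an all-zero fingerprint")
    bits = np.stack([fp.bits.astype(np.float64) for fp in fps])
    inter = bits @ bits.T
    popcount = bits.sum(axis=1)
    union = popcount[:, None] + popcount[None, :] - inter
    S = inter / union
    S = (S + S.T) / 2.0  # triangle averaging guards against float asymmetry
    return SimilarityMatrix(S_raw=S, S_std=standardize_rows(S),
                            drug_ids=list(drug_ids))


def similarity_row(fp: Fingerprint, train_fps: list[Fingerprint]) -> np.ndarray:
    """Standardized similarity row of an unseen drug against the training
    set, using that row's own mean/sd (keeps the feature width at n_train)."""
    raw = np.array([tanimoto(fp, t) for t in train_fps])
    sd = raw.std()
    if sd == 0:
        logger.warning("zero-variance similarity row for unseen drug")
        return np.zeros_like(raw)
    return (raw - raw.mean()) / sd
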