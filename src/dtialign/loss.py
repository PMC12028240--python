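"""Contrastive objective on a batch of positive (protein, drug) pairs.

A batch of N observed DTI pairs yields an N x N cosine-similarity matrix in
the shared space whose diagonal holds the positives.  Supervision is weak:
only diagonal cells carry a label, off-diagonal cells are unconstrained and
contribute solely as in-batch negatives through the softmax denominators.
The loss is the bidirectional cross-entropy

    L = 1/2 (L_PM + L_MP),
    L_PM = -(1/N) sum_i log softmax_row(S / tau)[i, i],
    L_MP = -(1/N) sum_i log softmax_col(S / tau)[i, i],

i.e. each protein must retrieve its drug among the batch's drugs and vice
versa.  Optionally, off-diagonal cells that are *known* true interactions
(the same drug serving several proteins in one batch) can be masked out of
both denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embeddings import l2_normalize_rows

__all__ = [
    "cosine_similarity_matrix",
    "WeakLabelMask",
    "weak_label_matrix",
    "bidirectional_contrastive_loss",
    "bidirectional_contrastive_loss_grad",
]


def cosine_similarity_matrix(P: np.ndarray, M: np.ndarray) -> np.ndarray:
    """Pairwise cosine similarities: entry (i, j) = cos(P_i, M_j) in [-1, 1]."""
    P = np.asarray(P, dtype=np.float64)
    M = np.asarray(M, dtype=np.float64)
    if P.shape[1] != M.shape[1]:
        raise ValueError(
            f"column counts differ: proteins {P.shape[1]} vs drugs {M.shape[1]}"
        )
    for name, X in (("protein", P), ("drug", M)):
        zero = np.flatnonzero(np.linalg.norm(X, axis=1) == 0)
        if zero.size:
            raise FloatingPointError(f"zero {name} row(s) at index {zero.tolist()}")
    sims = l2_normalize_rows(P) @ l2_normalize_rows(M).T
    return np.clip(sims, -1.0, 1.0)


@dataclass
class WeakLabelMask:
    """Label structure of one batch: diagonal positives plus an exclusion mask.

    ``excluded[i, j]`` flags an off-diagonal cell that is a known true
    interaction and must be dropped from both softmax denominators; diagonal
    cells are never excluded.
    """

    n: int
    excluded: np.ndarray  # bool (n, n)

    def validate(self) -> None:
        if self.excluded.shape != (self.n, self.n):
            raise ValueError("exclusion mask shape mismatch")
        if np.any(np.diag(self.excluded)):
            raise ValueError("diagonal (positive) cells cannot be excluded")

    @property
    def positives(self) -> np.ndarray:
        return np.eye(self.n, dtype=bool)


def weak_label_matrix(
    protein_ids: list[str],
    drug_ids: list[str],
    known_positives: set[tuple[str, str]] | None = None,
) -> WeakLabelMask:
    """Build the weak-label structure for a batch of aligned id lists.

    Diagonal cells (i, i) are positives by construction.  When
    ``known_positives`` is given, off-diagonal cells (i, j) with
    (protein_ids[i], drug_ids[j]) an observed interaction are flagged for
    exclusion; otherwise no cell is excluded and off-diagonal known positives
    simply act as in-batch negatives.
    """
    if len(protein_ids) != len(drug_ids):
        raise ValueError(
            f"batch id lists differ in length: {len(protein_ids)} vs {len(drug_ids)}"
        )
    n = len(protein_ids)
    excluded = np.zeros((n, n), dtype=bool)
    if known_positives:
        for i, p in enumerate(protein_ids):
            for j, d in enumerate(drug_ids):
                if i != j and (p, d) in known_positives:
                    excluded[i, j] = True
    mask = WeakLabelMask(n=n, excluded=excluded)
    mask.validate()
    return mask


def _masked_log_softmax(logits: np.ndarray, excluded: np.ndarray, axis: int) -> np.ndarray:
    z = np.where(excluded, -np.inf, logits)
    z = z - z.max(axis=axis, keepdims=True)
    ez = np.exp(z)
    return z - np.log(ez.sum(axis=axis, keepdims=True))


def _check_sims(sims: np.ndarray, temperature: float) -> np.ndarray:
    sims = np.asarray(sims, dtype=np.float64)
    if sims.ndim != 2 or sims.shape[0] != sims.shape[1]:
        raise ValueError(f"similarity matrix must be square, got shape {sims.shape}")
    if not np.all(np.isfinite(sims)):
        raise FloatingPointError("similarity matrix contains non-finite entries")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return sims


def bidirectional_contrastive_loss(
    sims: np.ndarray,
    temperature: float = 1.0,
    mask: WeakLabelMask | None = None,
) -> float:
    """Mean of the row-wise and column-wise diagonal cross-entropies."""
    sims = _check_sims(sims, temperature)
    n = sims.shape[0]
    excluded = mask.excluded if mask is not None else np.zeros((n, n), dtype=bool)
    logits = sims / temperature
    log_p = _masked_log_softmax(logits, excluded, axis=1)
    log_q = _masked_log_softmax(logits, excluded, axis=0)
    diag = np.arange(n)
    loss = -0.5 * (log_p[diag, diag].mean() + log_q[diag, diag].mean())
    return float(loss)


def bidirectional_contrastive_loss_grad(
    sims: np.ndarray,
    temperature: float = 1.0,
    mask: WeakLabelMask | None = None,
) -> tuple[float, np.ndarray]:
    """Loss plus its analytic gradient with respect to ``sims``.

    With A the row softmax and B the column softmax of ``sims/tau`` (masked
    cells carrying zero probability), dL/dS = (A + B - 2 I) / (2 N tau).
    """
    sims = _check_sims(sims, temperature)
    n = sims.shape[0]
    excluded = mask.excluded if mask is not None else np.zeros((n, n), dtype=bool)
    logits = sims / temperature
    log_p = _masked_log_softmax(logits, excluded, axis=1)
    log_q = _masked_log_softmax(logits, excluded, axis=0)
    diag = np.arange(n)
    loss = -0.5 * (log_p[diag, diag].mean() + log_q[diag, diag].mean())
    A = np.exp(log_p)
    B = np.exp(log_q)
    eye = np.eye(n)
    grad = (A + B - 2.0 * eye) / (2.0 * n * temperature)
    grad[excluded] = 0.0
    return float(loss), grad
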