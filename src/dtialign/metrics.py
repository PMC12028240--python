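"""Ranking and classification metrics for DTI prediction.

Per-protein ranking metrics treat drug retrieval as multi-label
classification: precision@k and recall@k against the protein's true drug
set, averaged into MAP (mean precision@1 over proteins) and MAR (mean
average recall over the top-5 ranks).  The N-candidate protocol measures
Top-k hit rate of the single positive among sampled distractors.  AUROC and
AUPR pool all protein-drug pair scores (micro averaging) and are delegated
to scikit-learn; a macro (per-protein) variant is available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .inference import RankingCase

logger = logging.getLogger(__name__)

__all__ = [
    "LabelSet",
    "MetricReport",
    "precision_at_k",
    "recall_at_k",
    "mean_average_precision",
    "mean_average_recall",
    "topk_candidate_accuracy",
    "auroc_aupr",
    "build_label_sets",
]


@dataclass
class LabelSet:
    """Ground truth and prediction for one query protein."""

    protein_id: str
    true_drugs: set[str]
    predicted_ranking: list[str]

    def __post_init__(self) -> None:
        if len(self.predicted_ranking) != len(set(self.predicted_ranking)):
            raise ValueError(f"ranking for {self.protein_id!r} contains duplicates")


@dataclass
class MetricReport:
    map_at_1: float
    mar_at_5: float
    topk_accuracy: dict[int, float] = field(default_factory=dict)
    auroc: float | None = None
    aupr: float | None = None

    def as_dict(self) -> dict:
        out = {"MAP@1": self.map_at_1, "MAR@5": self.mar_at_5}
        for k in sorted(self.topk_accuracy):
            out[f"top{k}_accuracy"] = self.topk_accuracy[k]
        if self.auroc is not None:
            out["AUROC"] = self.auroc
        if self.aupr is not None:
            out["AUPR"] = self.aupr
        return out


def build_label_sets(
    score_matrix: np.ndarray,
    protein_ids: list[str],
    drug_ids: list[str],
    truth_edges,
    exclude_edges=None,
) -> list[LabelSet]:
    """Turn a score matrix into per-protein label sets for MAP/MAR.

    Each protein's predicted ranking orders all drugs by descending score
    (ascending drug id on ties); drugs whose pair with the protein appears in
    ``exclude_edges`` (typically the training interactions) are removed from
    both the ranking and the candidate universe.  ``truth_edges`` supplies
    the true drug set per protein; proteins without any truth edge are
    skipped.
    """
    scores = np.asarray(score_matrix, dtype=np.float64)
    truth_by_protein: dict[str, set[str]] = {}
    for p, d in truth_edges:
        truth_by_protein.setdefault(p, set()).add(d)
    excluded_by_protein: dict[str, set[str]] = {}
    for p, d in exclude_edges or ():
        excluded_by_protein.setdefault(p, set()).add(d)
    label_sets = []
    for i, p in enumerate(protein_ids):
        truths = truth_by_protein.get(p)
        if not truths:
            continue
        banned = excluded_by_protein.get(p, set())
        order = sorted(
            (j for j, d in enumerate(drug_ids) if d not in banned),
            key=lambda j: (-scores[i, j], drug_ids[j]),
        )
        label_sets.append(
            LabelSet(
                protein_id=p,
                true_drugs=truths - banned,
                predicted_ranking=[drug_ids[j] for j in order],
            )
        )
    return label_sets


def precision_at_k(truth: LabelSet, k: int) -> float:
    """|top-k ∩ true drugs| / k."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(truth.predicted_ranking):
        raise ValueError(
            f"k={k} exceeds ranking length {len(truth.predicted_ranking)}"
        )
    hits = len(set(truth.predicted_ranking[:k]) & truth.true_drugs)
    return hits / k


def recall_at_k(truth: LabelSet, k: int) -> float:
    """|top-k ∩ true drugs| / |true drugs|."""
    if not truth.true_drugs:
        raise ValueError(f"protein {truth.protein_id!r} has no true drugs (recall undefined)")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if k > len(truth.predicted_ranking):
        raise ValueError(
            f"k={k} exceeds ranking length {len(truth.predicted_ranking)}"
        )
    hits = len(set(truth.predicted_ranking[:k]) & truth.true_drugs)
    return hits / len(truth.true_drugs)


def mean_average_precision(truths: list[LabelSet]) -> float:
    """Mean over proteins of precision@1 (top-1 hit rate of the ranking)."""
    if not truths:
        raise ValueError("no label sets supplied")
    return float(np.mean([precision_at_k(t, 1) for t in truths]))


def mean_average_recall(truths: list[LabelSet], k: int = 5, normalized: bool = True) -> float:
    """Mean over proteins of the average recall over the top-k ranks.

    Per protein the summand is sum_{j=1..k} recall@j; ``normalized`` (the
    default) divides by k so the metric stays in [0, 1].  Proteins with an
    empty true-drug set are excluded (undefined denominator) and counted in
    a log message.
    """
    usable = [t for t in truths if t.true_drugs]
    skipped = len(truths) - len(usable)
    if skipped:
        logger.info("mean_average_recall: excluded %d protein(s) with no true drugs", skipped)
    if not usable:
        raise ValueError("no label sets with non-empty true-drug sets")
    per_protein = []
    for t in usable:
        total = sum(recall_at_k(t, j) for j in range(1, k + 1))
        per_protein.append(total / k if normalized else total)
    return float(np.mean(per_protein))


def topk_candidate_accuracy(cases: list[RankingCase], k: int) -> float:
    """Fraction of N-candidate cases whose positive lands in the top k."""
    if not cases:
        raise ValueError("no ranking cases supplied")
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    hits = sum(case.positive_drug in case.ranking()[:k] for case in cases)
    return hits / len(cases)


def auroc_aupr(
    score_matrix: np.ndarray,
    positive_edges,
    protein_ids: list[str],
    drug_ids: list[str],
    macro: bool = False,
) -> tuple[float, float]:
    """AUROC and AUPR over all protein-drug pairs of the score matrix.

    Rows follow ``protein_ids``, columns ``drug_ids``; pairs in
    ``positive_edges`` are the positive class, every other cell a negative.
    Micro pooling (default) ranks all pairs together; ``macro`` averages
    per-protein values over proteins with both classes present.
    """
    scores = np.asarray(score_matrix, dtype=np.float64)
    if scores.shape != (len(protein_ids), len(drug_ids)):
        raise ValueError(
            f"score matrix shape {scores.shape} does not match id lists "
            f"({len(protein_ids)}, {len(drug_ids)})"
        )
    positives = set(positive_edges)
    labels = np.zeros(scores.shape, dtype=int)
    for i, p in enumerate(protein_ids):
        for j, d in enumerate(drug_ids):
            if (p, d) in positives:
                labels[i, j] = 1
    if macro:
        aurocs, auprs = [], []
        for i in range(len(protein_ids)):
            if 0 < labels[i].sum() < labels.shape[1]:
                aurocs.append(roc_auc_score(labels[i], scores[i]))
                auprs.append(average_precision_score(labels[i], scores[i]))
        if not aurocs:
            raise ValueError("no protein has both a positive and a negative pair")
        return float(np.mean(aurocs)), float(np.mean(auprs))
    flat_labels, flat_scores = labels.ravel(), scores.ravel()
    if flat_labels.min() == flat_labels.max():
        raise ValueError("need at least one positive and one negative pair")
    return (
        float(roc_auc_score(flat_labels, flat_scores)),
        float(average_precision_score(flat_labels, flat_scores)),
    )
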