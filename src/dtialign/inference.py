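"""Zero-shot DTI scoring: rank candidate drugs for a query protein.

A query protein and each candidate drug are projected through the trained
heads; candidates are ranked by cosine similarity in the shared space, and a
softmax over the candidate cosines yields interpretable likelihood scores.
Scoring requires only that an entity has an embedding — drugs absent from
the training graph (novel drugs) and proteins held out of training
(cold-start targets) are scored identically, which is the zero-shot
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import softmax

from .embeddings import EmbeddingTable, align_tables
from .loss import cosine_similarity_matrix
from .projection import ProjectionHead

__all__ = [
    "CandidateScore",
    "RankingCase",
    "score_candidates",
    "rank_topk",
    "score_all_pairs",
    "build_ranking_cases",
    "score_ranking_cases",
]


class MissingEmbeddingError(ValueError):
    """An entity required for scoring has no embedding."""

    def __init__(self, ids: list[str]):
        self.ids = list(ids)
        super().__init__(f"missing embeddings for: {', '.join(self.ids)}")


@dataclass(frozen=True)
class CandidateScore:
    drug_id: str
    cosine: float
    likelihood: float


@dataclass
class RankingCase:
    """One N-candidate evaluation instance: a protein, its known interacting
    drug, and N sampled non-interacting distractors."""

    protein_id: str
    positive_drug: str
    negative_drugs: list[str]
    scores: list[CandidateScore] = field(default_factory=list)

    @property
    def candidate_ids(self) -> list[str]:
        return [self.positive_drug] + self.negative_drugs

    def ranking(self) -> list[str]:
        if not self.scores:
            raise RuntimeError(f"case for protein {self.protein_id!r} has not been scored")
        return [s.drug_id for s in self.scores]


def _project_ids(ids, head: ProjectionHead, table: EmbeddingTable) -> np.ndarray:
    matrix, missing = align_tables(table, list(ids))
    if missing:
        raise MissingEmbeddingError(missing)
    return head.forward(matrix)


def score_candidates(
    protein_id: str,
    candidate_ids: list[str],
    heads: tuple[ProjectionHead, ProjectionHead],
    tables: tuple[EmbeddingTable, EmbeddingTable],
    temperature: float = 1.0,
) -> list[CandidateScore]:
    """Score candidate drugs against one protein in the shared space.

    ``heads``/``tables`` are the (protein, drug) pairs.  Output is ordered by
    descending cosine, ties broken by ascending drug id; likelihoods are the
    softmax of cosines/temperature over this candidate list and sum to 1.
    """
    if not candidate_ids:
        raise ValueError("candidate list is empty")
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    protein_head, drug_head = heads
    protein_table, drug_table = tables
    P = _project_ids([protein_id], protein_head, protein_table)
    M = _project_ids(candidate_ids, drug_head, drug_table)
    cosines = cosine_similarity_matrix(P, M)[0]
    likelihoods = softmax(cosines / temperature)
    order = sorted(range(len(candidate_ids)), key=lambda i: (-cosines[i], candidate_ids[i]))
    return [
        CandidateScore(candidate_ids[i], float(cosines[i]), float(likelihoods[i])) for i in order
    ]


def rank_topk(scores: list[CandidateScore], k: int) -> list[str]:
    """Top-k drug ids by descending cosine (ascending id on ties)."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    ordered = sorted(scores, key=lambda s: (-s.cosine, s.drug_id))
    return [s.drug_id for s in ordered[:k]]


def score_all_pairs(
    protein_ids: list[str],
    drug_ids: list[str],
    heads: tuple[ProjectionHead, ProjectionHead],
    tables: tuple[EmbeddingTable, EmbeddingTable],
) -> np.ndarray:
    """Shared-space cosine matrix, rows following ``protein_ids`` and columns
    ``drug_ids``; identical values to per-pair :func:`score_candidates`."""
    protein_head, drug_head = heads
    protein_table, drug_table = tables
    P = _project_ids(protein_ids, protein_head, protein_table)
    M = _project_ids(drug_ids, drug_head, drug_table)
    return cosine_similarity_matrix(P, M)


def build_ranking_cases(
    eval_edges,
    known_edges,
    drug_pool,
    n_negatives: int,
    seed: int,
) -> list[RankingCase]:
    """One case per evaluation edge: the edge's drug as positive plus
    ``n_negatives`` drugs sampled uniformly from ``drug_pool`` among those
    with no known interaction with the protein."""
    known_by_protein: dict[str, set[str]] = {}
    for p, d in known_edges:
        known_by_protein.setdefault(p, set()).add(d)
    pool = sorted(set(drug_pool))
    rng = np.random.default_rng(seed)
    cases = []
    for p, d in sorted(eval_edges):
        interacting = known_by_protein.get(p, set())
        eligible = [x for x in pool if x not in interacting and x != d]
        if len(eligible) < n_negatives:
            raise ValueError(
                f"protein {p!r}: only {len(eligible)} eligible negatives, need {n_negatives}"
            )
        negatives = [eligible[i] for i in rng.choice(len(eligible), n_negatives, replace=False)]
        cases.append(RankingCase(protein_id=p, positive_drug=d, negative_drugs=negatives))
    return cases


def score_ranking_cases(
    cases: list[RankingCase],
    heads: tuple[ProjectionHead, ProjectionHead],
    tables: tuple[EmbeddingTable, EmbeddingTable],
    temperature: float = 1.0,
) -> list[RankingCase]:
    """Fill ``case.scores`` in place for every case; returns the list."""
    for case in cases:
        case.scores = score_candidates(
            case.protein_id, case.candidate_ids, heads, tables, temperature
        )
    return cases


def write_scores_tsv(path, protein_id: str, scores: list[CandidateScore]) -> None:
    """Append-style scoring output: protein, drug, cosine, likelihood, rank."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\tdrug_id\tcosine\tlikelihood\trank\n")
        for rank, s in enumerate(scores, start=1):
            fh.write(f"{protein_id}\t{s.drug_id}\t{s.cosine:.10g}\t{s.likelihood:.10g}\t{rank}\n")
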