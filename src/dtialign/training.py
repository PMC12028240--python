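"""Training wrapper: embedding tables + dataset split -> fitted head pair.

Thin layer over :class:`dtialign.estimator.ContrastiveAligner`: assembles
the row-aligned positive-pair matrices from the split's training edges,
runs the contrastive fit, and reports a per-epoch validation metric (Top-1
accuracy on validation edges against sampled non-interacting distractors).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .embeddings import EmbeddingTable, align_tables
from .estimator import ContrastiveAligner
from .graph import DatasetSplit
from .inference import (
    MissingEmbeddingError,
    build_ranking_cases,
    score_ranking_cases,
)
from .projection import ProjectionConfig, ProjectionHead

__all__ = ["TrainConfig", "TrainResult", "train"]


@dataclass(frozen=True)
class TrainConfig:
    """Optimization hyperparameters (all package defaults, none canonical)."""

    batch_size: int = 64
    epochs: int = 50
    learning_rate: float = 1e-2
    temperature: float = 1.0
    mask_known_positives: bool = False
    optimizer: str = "adam"
    normalize_inputs: bool = False
    valid_negatives: int = 4  # distractors per validation ranking case
    seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if self.learning_rate <= 0 or self.temperature <= 0:
            raise ValueError("learning_rate and temperature must be positive")


@dataclass
class TrainResult:
    protein_head: ProjectionHead
    drug_head: ProjectionHead
    loss_history: list[float] = field(default_factory=list)
    valid_history: list[float] = field(default_factory=list)


def _pair_matrices(
    protein_table: EmbeddingTable, drug_table: EmbeddingTable, edges
) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    ordered = sorted(edges)
    protein_ids = [p for p, _ in ordered]
    drug_ids = [d for _, d in ordered]
    X, missing_p = align_tables(protein_table, protein_ids)
    Y, missing_m = align_tables(drug_table, drug_ids)
    missing = sorted(set(missing_p) | set(missing_m))
    if missing:
        raise MissingEmbeddingError(missing)
    return protein_ids, drug_ids, X, Y


def train(
    protein_table: EmbeddingTable,
    drug_table: EmbeddingTable,
    split: DatasetSplit,
    p_config: ProjectionConfig,
    m_config: ProjectionConfig,
    t_config: TrainConfig,
) -> TrainResult:
    """Contrastively fit projection heads on the split's training edges.

    Every entity in the train and valid edges must have an embedding; the
    validation metric is Top-1 accuracy over valid edges with
    ``t_config.valid_negatives`` sampled distractors, recorded per epoch
    (reporting only — no early stopping).
    """
    if p_config.output_dim != m_config.output_dim:
        raise ValueError(
            f"output_dim mismatch: protein {p_config.output_dim} vs drug {m_config.output_dim}"
        )
    protein_ids, drug_ids, X, Y = _pair_matrices(protein_table, drug_table, split.train_dti)
    # validate valid-edge embeddings up front (fatal at train time)
    if split.valid_dti:
        _pair_matrices(protein_table, drug_table, split.valid_dti)

    known_edges = split.train_dti | split.valid_dti | split.test_dti
    drug_pool = sorted(drug_table.vectors)

    est = ContrastiveAligner(
        n_components=p_config.output_dim,
        temperature=t_config.temperature,
        learning_rate=t_config.learning_rate,
        batch_size=t_config.batch_size,
        epochs=t_config.epochs,
        optimizer=t_config.optimizer,
        mask_known_positives=t_config.mask_known_positives,
        normalize_inputs=t_config.normalize_inputs,
        random_state=t_config.seed,
        protein_config=p_config,
        drug_config=m_config,
    )

    callback = None
    if split.valid_dti:
        cases = build_ranking_cases(
            split.valid_dti,
            known_edges,
            drug_pool,
            n_negatives=t_config.valid_negatives,
            seed=t_config.seed,
        )

        def callback(model: ContrastiveAligner, epoch: int) -> float:
            heads = (model.protein_head_, model.drug_head_)
            score_ranking_cases(cases, heads, (protein_table, drug_table), t_config.temperature)
            hits = sum(case.ranking()[0] == case.positive_drug for case in cases)
            return hits / len(cases)

    est.fit(
        X,
        Y,
        protein_ids=protein_ids,
        drug_ids=drug_ids,
        known_positives=known_edges if t_config.mask_known_positives else None,
        epoch_callback=callback,
    )
    return TrainResult(
        protein_head=est.protein_head_,
        drug_head=est.drug_head_,
        loss_history=list(est.loss_history_),
        valid_history=list(est.valid_history_),
    )
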