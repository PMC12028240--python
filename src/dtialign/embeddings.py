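"""Embedding-table IO: entity-ID-keyed fixed-dimension vectors from upstream models.

Tables arrive as TSV (``id<TAB>v1<TAB>...<TAB>vd``) produced by whatever
representation model supplied them — a network-embedding method, a protein
language model, a molecular VAE, a text LLM.  This package never computes
such embeddings; it only reads, validates, aligns and projects them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class EmbeddingFormatError(ValueError):
    """Malformed embedding TSV (ragged row, non-numeric cell, duplicate id)."""


@dataclass
class EmbeddingTable:
    """Mapping entity_id -> real vector of fixed length ``dim``.

    ``source`` is a free-text tag naming the upstream representation model;
    it is informational only and never interpreted.
    """

    source: str
    dim: int
    vectors: dict[str, np.ndarray] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.vectors)

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.vectors

    def validate(self) -> None:
        if self.dim <= 0:
            raise EmbeddingFormatError(f"dim must be positive, got {self.dim}")
        for eid, vec in self.vectors.items():
            if vec.shape != (self.dim,):
                raise EmbeddingFormatError(
                    f"vector for {eid!r} has shape {vec.shape}, expected ({self.dim},)"
                )
            if not np.all(np.isfinite(vec)):
                raise EmbeddingFormatError(f"vector for {eid!r} has non-finite components")


def read_embedding_table(path, expected_dim: int | None = None, source: str = "") -> EmbeddingTable:
    """Read a TSV embedding table; dimension is inferred from the first row
    unless ``expected_dim`` pins it."""
    vectors: dict[str, np.ndarray] = {}
    dim = expected_dim
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise EmbeddingFormatError(f"{path}:{lineno}: expected id plus >=1 value")
            eid, cells = parts[0], parts[1:]
            if dim is None:
                dim = len(cells)
            elif len(cells) != dim:
                raise EmbeddingFormatError(
                    f"{path}:{lineno}: row has {len(cells)} values, expected {dim}"
                )
            try:
                vec = np.array([float(c) for c in cells], dtype=np.float64)
            except ValueError as exc:
                raise EmbeddingFormatError(f"{path}:{lineno}: non-numeric cell ({exc})") from None
            if eid in vectors:
                raise EmbeddingFormatError(f"{path}:{lineno}: duplicate entity id {eid!r}")
            vectors[eid] = vec
    if dim is None:
        raise EmbeddingFormatError(f"{path}: empty embedding table")
    table = EmbeddingTable(source=source or str(path), dim=dim, vectors=vectors)
    table.validate()
    return table


def write_embedding_table(table: EmbeddingTable, path) -> None:
    """Write the table as TSV with full float precision (``repr`` round-trips)."""
    with open(path, "w", encoding="utf-8") as fh:
        for eid in sorted(table.vectors):
            cells = "\t".join(repr(float(v)) for v in table.vectors[eid])
            fh.write(f"{eid}\t{cells}\n")


def align_tables(table: EmbeddingTable, ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Stack vectors for ``ids`` in order; ids absent from the table are
    returned in ``missing`` and skipped (the caller decides whether that is
    fatal — at training time it is)."""
    rows, missing = [], []
    for eid in ids:
        vec = table.vectors.get(eid)
        if vec is None:
            missing.append(eid)
        else:
            rows.append(vec)
    matrix = np.vstack(rows) if rows else np.empty((0, table.dim))
    return matrix, missing


def l2_normalize_rows(matrix: np.ndarray) -> np.ndarray:
    """Scale each row to unit Euclidean norm (required before cosine via dot)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    norms = np.linalg.norm(matrix, axis=1)
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        raise FloatingPointError(f"cannot normalize all-zero row(s) at index {zero.tolist()}")
    return matrix / norms[:, None]
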