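"""Heterogeneous interaction graph: entities, edge layers, and dataset splits.

The graph follows the shape of heterogeneous biomedical networks used for
drug-target interaction (DTI) prediction: drug, protein and disease nodes,
with a DTI layer (protein-drug), a drug-disease layer and an undirected
drug-drug layer.  Only the DTI layer drives contrastive training; the other
layers are stored for data-model fidelity.

Splits operate on DTI *edges*: a validation fraction is sampled uniformly,
cold-start proteins move all of their edges to the test partition, and novel
drugs (drugs with embeddings but no training edges) are tracked explicitly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

ENTITY_KINDS = ("drug", "protein", "disease")
RELATIONS = ("dti", "drug_disease", "drug_drug")

Edge = tuple[str, str]


class GraphFormatError(ValueError):
    """A malformed row in an edge-list or manifest file."""


class GraphValidationError(ValueError):
    """Graph content violates an invariant (unknown entity, bad kind, ...)."""


@dataclass(frozen=True)
class Entity:
    """A typed node: a drug, a protein target, or a disease."""

    id: str
    kind: str

    def __post_init__(self) -> None:
        if not self.id:
            raise GraphValidationError("entity id must be non-empty")
        if self.kind not in ENTITY_KINDS:
            raise GraphValidationError(
                f"unknown entity kind {self.kind!r}; expected one of {ENTITY_KINDS}"
            )


@dataclass
class InteractionGraph:
    """Typed entities plus per-relation edge layers.

    ``dti_edges`` are (protein_id, drug_id) pairs; ``drug_drug_edges`` are
    stored with lexicographically ordered endpoints so the undirected layer
    deduplicates canonically.
    """

    drugs: set[str] = field(default_factory=set)
    proteins: set[str] = field(default_factory=set)
    diseases: set[str] = field(default_factory=set)
    dti_edges: set[Edge] = field(default_factory=set)
    drug_disease_edges: set[Edge] = field(default_factory=set)
    drug_drug_edges: set[Edge] = field(default_factory=set)

    def validate(self) -> None:
        for p, d in self.dti_edges:
            if p not in self.proteins:
                raise GraphValidationError(f"DTI edge references unknown protein {p!r}")
            if d not in self.drugs:
                raise GraphValidationError(f"DTI edge references unknown drug {d!r}")
        for d, z in self.drug_disease_edges:
            if d not in self.drugs:
                raise GraphValidationError(f"drug_disease edge references unknown drug {d!r}")
            if z not in self.diseases:
                raise GraphValidationError(f"drug_disease edge references unknown disease {z!r}")
        for a, b in self.drug_drug_edges:
            if a > b:
                raise GraphValidationError(
                    f"drug_drug edge ({a!r}, {b!r}) not in canonical (sorted) order"
                )
            if a not in self.drugs or b not in self.drugs:
                raise GraphValidationError(f"drug_drug edge ({a!r}, {b!r}) references unknown drug")

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def n_proteins(self) -> int:
        return len(self.proteins)


@dataclass
class DatasetSplit:
    """Disjoint train/valid/test partition of the DTI edges of one graph.

    ``novel_drugs`` are drugs with no train or valid edge (the zero-shot
    candidates); ``cold_proteins`` are proteins with no train edge.
    """

    train_dti: set[Edge] = field(default_factory=set)
    valid_dti: set[Edge] = field(default_factory=set)
    test_dti: set[Edge] = field(default_factory=set)
    novel_drugs: set[str] = field(default_factory=set)
    cold_proteins: set[str] = field(default_factory=set)
    seed: int = 0

    def validate(self) -> None:
        if self.train_dti & self.valid_dti or self.train_dti & self.test_dti or self.valid_dti & self.test_dti:
            raise GraphValidationError("train/valid/test DTI sets are not pairwise disjoint")
        for part in (self.train_dti, self.valid_dti):
            for _, d in part:
                if d in self.novel_drugs:
                    raise GraphValidationError(f"novel drug {d!r} has a train/valid edge")
        for p, _ in self.train_dti:
            if p in self.cold_proteins:
                raise GraphValidationError(f"cold protein {p!r} has a training edge")


def load_interaction_graph(path, entity_manifest=None) -> InteractionGraph:
    """Read a three-column edge list ``source<TAB>relation<TAB>target``.

    Relations: ``dti`` rows are (protein, drug); ``drug_disease`` rows are
    (drug, disease); ``drug_drug`` rows are unordered drug pairs.  ``#`` lines
    are comments.  Duplicate rows collapse, with the count logged.  When an
    entity manifest (``id<TAB>kind`` TSV) is supplied, edges may only
    reference declared entities.
    """
    declared: dict[str, str] | None = None
    if entity_manifest is not None:
        declared = {}
        with open(entity_manifest, encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise GraphFormatError(
                        f"{entity_manifest}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                eid, kind = parts
                Entity(eid, kind)  # validates
                if eid in declared:
                    raise GraphValidationError(
                        f"{entity_manifest}:{lineno}: duplicate entity id {eid!r}"
                    )
                declared[eid] = kind

    graph = InteractionGraph()
    if declared is not None:
        for eid, kind in declared.items():
            getattr(graph, kind + "s").add(eid)

    def check(eid: str, kind: str, lineno: int) -> None:
        if declared is None:
            getattr(graph, kind + "s").add(eid)
        elif declared.get(eid) != kind:
            raise GraphValidationError(
                f"{path}:{lineno}: edge references {eid!r} which is not a declared {kind}"
            )

    n_duplicates = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 columns, got {len(parts)}")
            src, rel, dst = parts
            if not src or not dst:
                raise GraphFormatError(f"{path}:{lineno}: empty entity id")
            if rel == "dti":
                check(src, "protein", lineno)
                check(dst, "drug", lineno)
                edge, layer = (src, dst), graph.dti_edges
            elif rel == "drug_disease":
                check(src, "drug", lineno)
                check(dst, "disease", lineno)
                edge, layer = (src, dst), graph.drug_disease_edges
            elif rel == "drug_drug":
                check(src, "drug", lineno)
                check(dst, "drug", lineno)
                edge, layer = (min(src, dst), max(src, dst)), graph.drug_drug_edges
            else:
                raise GraphFormatError(
                    f"{path}:{lineno}: unknown relation {rel!r}; expected one of {RELATIONS}"
                )
            if edge in layer:
                n_duplicates += 1
            else:
                layer.add(edge)
    if n_duplicates:
        logger.info("collapsed %d duplicate edge rows while reading %s", n_duplicates, path)
    graph.validate()
    return graph


def write_interaction_graph(graph: InteractionGraph, path) -> None:
    """Write the graph as the canonical three-column edge list (sorted rows)."""
    with open(path, "w", encoding="utf-8") as fh:
        for p, d in sorted(graph.dti_edges):
            fh.write(f"{p}\tdti\t{d}\n")
        for d, z in sorted(graph.drug_disease_edges):
            fh.write(f"{d}\tdrug_disease\t{z}\n")
        for a, b in sorted(graph.drug_drug_edges):
            fh.write(f"{a}\tdrug_drug\t{b}\n")


def _sample_edges(edges: set[Edge], n: int, rng: np.random.Generator) -> set[Edge]:
    ordered = sorted(edges)  # platform-independent determinism
    idx = rng.choice(len(ordered), size=n, replace=False)
    return {ordered[i] for i in idx}


def split_dti_edges(graph: InteractionGraph, valid_fraction: float, seed: int) -> DatasetSplit:
    """Partition DTI edges into train/valid, ``floor(valid_fraction * |edges|)``
    validation edges sampled uniformly without replacement under ``seed``."""
    if not 0.0 < valid_fraction < 1.0:
        raise ValueError(f"valid_fraction must be in (0, 1), got {valid_fraction}")
    if len(graph.dti_edges) < 2:
        raise ValueError("graph must have at least 2 DTI edges to split")
    n_valid = int(np.floor(valid_fraction * len(graph.dti_edges)))
    rng = np.random.default_rng(seed)
    valid = _sample_edges(graph.dti_edges, n_valid, rng)
    split = DatasetSplit(train_dti=graph.dti_edges - valid, valid_dti=valid, seed=seed)
    split.validate()
    return split


def hold_out_cold_proteins(
    graph: InteractionGraph,
    fraction: float,
    seed: int,
    valid_fraction: float = 0.1,
) -> DatasetSplit:
    """Hold out ``round(fraction * |proteins|)`` proteins entirely from training.

    Every DTI edge touching a held-out (cold-start) protein moves to the test
    partition; the remaining edges split into train/valid as in
    :func:`split_dti_edges`.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    proteins = sorted(graph.proteins)
    n_cold = int(round(fraction * len(proteins)))
    if n_cold < 1:
        raise ValueError(f"fraction {fraction} selects zero cold proteins")
    if n_cold >= len(proteins):
        raise ValueError(f"fraction {fraction} leaves zero training proteins")
    rng = np.random.default_rng(seed)
    cold = {proteins[i] for i in rng.choice(len(proteins), size=n_cold, replace=False)}
    test = {e for e in graph.dti_edges if e[0] in cold}
    remaining = graph.dti_edges - test
    if not remaining:
        raise ValueError("cold-protein hold-out leaves an empty training edge set")
    n_valid = int(np.floor(valid_fraction * len(remaining)))
    valid = _sample_edges(remaining, n_valid, rng) if n_valid else set()
    split = DatasetSplit(
        train_dti=remaining - valid,
        valid_dti=valid,
        test_dti=test,
        cold_proteins=cold,
        seed=seed,
    )
    split.validate()
    return split


def label_density(graph: InteractionGraph) -> float:
    """Fraction of observed DTI pairs among all possible drug-protein pairs."""
    if not graph.drugs or not graph.proteins:
        raise ValueError("label density needs at least one drug and one protein")
    return len(graph.dti_edges) / (graph.n_drugs * graph.n_proteins)


def write_split_manifest(split: DatasetSplit, path) -> None:
    """Write ``protein_id<TAB>drug_id<TAB>partition`` rows (sorted)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("#protein_id\tdrug_id\tpartition\n")
        for part_name, edges in (
            ("train", split.train_dti),
            ("valid", split.valid_dti),
            ("test", split.test_dti),
        ):
            for p, d in sorted(edges):
                fh.write(f"{p}\t{d}\t{part_name}\n")


def read_split_manifest(path) -> DatasetSplit:
    """Inverse of :func:`write_split_manifest` (novel/cold sets not persisted)."""
    split = DatasetSplit()
    parts = {"train": split.train_dti, "valid": split.valid_dti, "test": split.test_dti}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 3:
                raise GraphFormatError(f"{path}:{lineno}: expected 3 columns, got {len(cols)}")
            p, d, part = cols
            if part not in parts:
                raise GraphFormatError(f"{path}:{lineno}: unknown partition {part!r}")
            parts[part].add((p, d))
    split.validate()
    return split
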