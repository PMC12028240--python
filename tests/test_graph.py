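import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtialign.graph import (
    DatasetSplit,
    Entity,
    GraphFormatError,
    GraphValidationError,
    InteractionGraph,
    hold_out_cold_proteins,
    label_density,
    load_interaction_graph,
    read_split_manifest,
    split_dti_edges,
    write_interaction_graph,
    write_split_manifest,
)
from dtialign.synthetic import default_paper_scale_world


def test_entity_rejects_empty_id_and_bad_kind():
    with pytest.raises(GraphValidationError):
        Entity("", "drug")
    with pytest.raises(GraphValidationError):
        Entity("X", "gene")


class TestLoadInteractionGraph:
    def test_duplicate_rows_collapse(self, tmp_path, caplog):
        path = tmp_path / "edges.tsv"
        path.write_text("P1\tdti\tD1\nP1\tdti\tD1\n")
        graph = load_interaction_graph(path)
        assert graph.dti_edges == {("P1", "D1")}

    def test_layers_parsed_separately(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("P1\tdti\tD1\nP2\tdti\tD1\nD1\tdrug_drug\tD2\n")
        graph = load_interaction_graph(path)
        assert len(graph.dti_edges) == 2
        assert graph.drug_drug_edges == {("D1", "D2")}

    def test_drug_drug_edges_canonicalized(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("D2\tdrug_drug\tD1\nD1\tdrug_drug\tD2\n")
        graph = load_interaction_graph(path)
        assert graph.drug_drug_edges == {("D1", "D2")}

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("P1\tdti\tD1\nP2\tdti\n")
        with pytest.raises(GraphFormatError, match=":2"):
            load_interaction_graph(path)

    def test_unknown_relation_rejected(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("P1\tbinds\tD1\n")
        with pytest.raises(GraphFormatError, match="binds"):
            load_interaction_graph(path)

    def test_manifest_enforces_declared_entities(self, tmp_path):
        edges = tmp_path / "edges.tsv"
        edges.write_text("P1\tdti\tD9\n")
        manifest = tmp_path / "entities.tsv"
        manifest.write_text("P1\tprotein\nD1\tdrug\n")
        with pytest.raises(GraphValidationError, match="D9"):
            load_interaction_graph(edges, entity_manifest=manifest)

    def test_comments_and_blank_lines_ignored(self, tmp_path):
        path = tmp_path / "edges.tsv"
        path.write_text("# a comment\n\nP1\tdti\tD1\n")
        assert load_interaction_graph(path).dti_edges == {("P1", "D1")}


def test_paper_scale_world_round_trips_through_edge_list(tmp_path):
    """A generated world at curated-dataset scale (670 drugs / 1894 proteins)
    survives write-then-read unchanged."""
    world = default_paper_scale_world(seed=0)
    assert world.graph.n_drugs == 670
    assert world.graph.n_proteins == 1894
    path = tmp_path / "edges.tsv"
    write_interaction_graph(world.graph, path)
    reread = load_interaction_graph(path)
    assert reread.dti_edges == world.graph.dti_edges
    assert reread.drugs == world.graph.drugs
    assert reread.proteins == world.graph.proteins


class TestSplitDtiEdges:
    def test_ten_edges_fraction_tenth(self, rng):
        graph = InteractionGraph(
            drugs={f"D{i}" for i in range(10)},
            proteins={"P0"},
            dti_edges={("P0", f"D{i}") for i in range(10)},
        )
        split = split_dti_edges(graph, 0.1, seed=3)
        assert len(split.train_dti) == 9 and len(split.valid_dti) == 1

    def test_floor_arithmetic_at_scale(self):
        graph = InteractionGraph(
            drugs={f"D{i}" for i in range(4839)},
            proteins={"P0"},
            dti_edges={("P0", f"D{i}") for i in range(4839)},
        )
        split = split_dti_edges(graph, 0.1, seed=0)
        assert len(split.valid_dti) == 483
        assert len(split.train_dti) == 4356

    def test_same_seed_identical(self, toy_graph):
        a = split_dti_edges(toy_graph, 0.25, seed=11)
        b = split_dti_edges(toy_graph, 0.25, seed=11)
        assert a.train_dti == b.train_dti and a.valid_dti == b.valid_dti

    def test_fraction_out_of_range(self, toy_graph):
        with pytest.raises(ValueError):
            split_dti_edges(toy_graph, 1.0, seed=0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(5, 60))
    def test_partition_property(self, seed, n_edges):
        graph = InteractionGraph(
            drugs={f"D{i}" for i in range(n_edges)},
            proteins={"P0", "P1"},
            dti_edges={(f"P{i % 2}", f"D{i}") for i in range(n_edges)},
        )
        split = split_dti_edges(graph, 0.2, seed=seed)
        assert split.train_dti | split.valid_dti == graph.dti_edges
        assert not split.train_dti & split.valid_dti


class TestColdProteinHoldOut:
    def test_cold_edges_all_in_test(self, toy_graph):
        split = hold_out_cold_proteins(toy_graph, 0.34, seed=1)
        for p, d in split.test_dti:
            assert p in split.cold_proteins
        for p, _ in split.train_dti:
            assert p not in split.cold_proteins

    def test_cold_count_rounds(self):
        graph = InteractionGraph(
            drugs={"D0"},
            proteins={f"P{i}" for i in range(1894)},
            dti_edges={(f"P{i}", "D0") for i in range(1894)},
        )
        split = hold_out_cold_proteins(graph, 0.1, seed=0)
        assert len(split.cold_proteins) == 189

    def test_single_hub_protein_raises(self):
        graph = InteractionGraph(
            drugs={"D0", "D1"},
            proteins={"P0", "P1"},
            dti_edges={("P0", "D0"), ("P0", "D1")},
        )
        # whichever seed samples the hub protein leaves nothing to train on
        with pytest.raises(ValueError):
            for seed in range(20):
                hold_out_cold_proteins(graph, 0.5, seed=seed)

    def test_no_leakage_on_random_graphs(self, rng):
        for trial in range(5):
            n_p, n_d = 30, 20
            edges = {
                (f"P{rng.integers(n_p)}", f"D{rng.integers(n_d)}") for _ in range(80)
            }
            graph = InteractionGraph(
                drugs={f"D{i}" for i in range(n_d)},
                proteins={f"P{i}" for i in range(n_p)},
                dti_edges=edges,
            )
            split = hold_out_cold_proteins(graph, 0.2, seed=trial)
            train_proteins = {p for p, _ in split.train_dti}
            assert not split.cold_proteins & train_proteins
            assert split.train_dti | split.valid_dti | split.test_dti == edges


class TestLabelDensity:
    def test_paper_counts_reproduce_printed_proportion(self):
        graph = InteractionGraph(
            drugs={f"D{i}" for i in range(670)},
            proteins={f"P{i}" for i in range(1894)},
        )
        # density over the full 670 x 1894 grid with 4839 observed interactions
        graph.dti_edges = {(f"P{i % 1894}", f"D{i % 670}") for i in range(4839)}
        assert len(graph.dti_edges) == 4839
        assert round(label_density(graph), 3) == 0.004

    def test_complete_bipartite_is_one(self):
        graph = InteractionGraph(
            drugs={"D0", "D1"},
            proteins={"P0", "P1"},
            dti_edges={(p, d) for p in ("P0", "P1") for d in ("D0", "D1")},
        )
        assert label_density(graph) == 1.0

    def test_empty_edges_zero_and_empty_entities_error(self):
        graph = InteractionGraph(drugs={"D0"}, proteins={"P0"})
        assert label_density(graph) == 0.0
        with pytest.raises(ValueError):
            label_density(InteractionGraph(drugs=set(), proteins={"P0"}))


def test_split_manifest_round_trip(tmp_path, toy_graph):
    split = split_dti_edges(toy_graph, 0.25, seed=2)
    split.test_dti = set()
    path = tmp_path / "split.tsv"
    write_split_manifest(split, path)
    reread = read_split_manifest(path)
    assert reread.train_dti == split.train_dti
    assert reread.valid_dti == split.valid_dti


def test_split_validate_catches_leakage():
    split = DatasetSplit(
        train_dti={("P1", "D1")},
        novel_drugs={"D1"},
    )
    with pytest.raises(GraphValidationError):
        split.validate()
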