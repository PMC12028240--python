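import numpy as np
import pytest

from dtialign.inference import CandidateScore, RankingCase
from dtialign.metrics import (
    LabelSet,
    auroc_aupr,
    build_label_sets,
    mean_average_precision,
    mean_average_recall,
    precision_at_k,
    recall_at_k,
    topk_candidate_accuracy,
)


def _random_label_set(rng, n_drugs=12, protein="P"):
    drugs = [f"D{i:02d}" for i in range(n_drugs)]
    ranking = list(rng.permutation(drugs))
    n_true = int(rng.integers(1, n_drugs))
    true = set(rng.choice(drugs, size=n_true, replace=False))
    return LabelSet(protein_id=protein, true_drugs=true, predicted_ranking=ranking)


class TestPrecisionRecallAtK:
    def test_hand_examples(self):
        truth = LabelSet("P", {"A"}, ["A", "B", "C"])
        assert precision_at_k(truth, 1) == 1.0
        truth = LabelSet("P", {"A", "B"}, ["A", "C", "D"])
        assert precision_at_k(truth, 3) == pytest.approx(1 / 3)
        assert recall_at_k(truth, 3) == 0.5
        truth = LabelSet("P", {"A", "B"}, ["A", "C", "B"])
        assert recall_at_k(truth, 3) == 1.0

    def test_k_beyond_ranking_rejected(self):
        truth = LabelSet("P", {"A"}, ["A", "B"])
        with pytest.raises(ValueError):
            precision_at_k(truth, 3)

    def test_empty_truth_recall_rejected(self):
        truth = LabelSet("P", set(), ["A"])
        with pytest.raises(ValueError):
            recall_at_k(truth, 1)

    def test_against_brute_force_on_random_instances(self, rng):
        """500 random instances agree exactly with set-intersection
        enumeration."""
        for _ in range(500):
            t = _random_label_set(rng)
            k = int(rng.integers(1, len(t.predicted_ranking) + 1))
            hits = sum(1 for d in t.predicted_ranking[:k] if d in t.true_drugs)
            assert precision_at_k(t, k) == hits / k
            assert recall_at_k(t, k) == hits / len(t.true_drugs)

    def test_intersection_identity(self, rng):
        # precision@k * k == recall@k * |truth| == |top-k intersection|
        for _ in range(100):
            t = _random_label_set(rng)
            k = int(rng.integers(1, len(t.predicted_ranking) + 1))
            lhs = precision_at_k(t, k) * k
            rhs = recall_at_k(t, k) * len(t.true_drugs)
            assert lhs == pytest.approx(rhs, abs=1e-12)


class TestMapMar:
    def test_all_top1_correct(self):
        truths = [LabelSet(f"P{i}", {"A"}, ["A", "B"]) for i in range(4)]
        assert mean_average_precision(truths) == 1.0

    def test_half_correct(self):
        truths = [
            LabelSet("P0", {"A"}, ["A", "B"]),
            LabelSet("P1", {"A"}, ["B", "A"]),
        ]
        assert mean_average_precision(truths) == 0.5

    def test_map_is_mean_of_precision_at_1(self, rng):
        truths = [_random_label_set(rng, protein=f"P{i}") for i in range(50)]
        direct = np.mean([precision_at_k(t, 1) for t in truths])
        assert mean_average_precision(truths) == pytest.approx(direct, abs=1e-12)

    def test_mar_top_hit_everywhere(self):
        t = LabelSet("P", {"A"}, ["A", "B", "C", "D", "E"])
        assert mean_average_recall([t], k=5) == pytest.approx(1.0)

    def test_mar_hit_at_rank5_only(self):
        t = LabelSet("P", {"A"}, ["B", "C", "D", "E", "A"])
        assert mean_average_recall([t], k=5) == pytest.approx(0.2)

    def test_mar_unnormalized_reproduces_plain_sum(self, rng):
        truths = [_random_label_set(rng, protein=f"P{i}") for i in range(30)]
        raw = mean_average_recall(truths, k=5, normalized=False)
        direct = np.mean(
            [sum(recall_at_k(t, j) for j in range(1, 6)) for t in truths]
        )
        assert raw == pytest.approx(direct, abs=1e-12)
        assert raw == pytest.approx(5 * mean_average_recall(truths, k=5), abs=1e-12)

    def test_mar_normalized_in_unit_interval_and_monotone_in_k(self, rng):
        truths = [_random_label_set(rng, protein=f"P{i}") for i in range(30)]
        values = [mean_average_recall(truths, k=k) for k in range(1, 8)]
        assert all(0.0 <= v <= 1.0 for v in values)
        assert all(b >= a - 1e-12 for a, b in zip(values, values[1:]))

    def test_empty_truth_proteins_excluded(self):
        truths = [
            LabelSet("P0", {"A"}, ["A", "B", "C", "D", "E"]),
            LabelSet("P1", set(), ["A", "B", "C", "D", "E"]),
        ]
        assert mean_average_recall(truths, k=5) == pytest.approx(1.0)


def _case_with_ranking(protein, ranked_ids, positive):
    scores = [
        CandidateScore(d, 1.0 - 0.01 * i, 0.0) for i, d in enumerate(ranked_ids)
    ]
    negatives = [d for d in ranked_ids if d != positive]
    return RankingCase(protein, positive, negatives, scores=scores)


class TestTopKCandidateAccuracy:
    def test_oracle_scorer_is_perfect(self):
        cases = [
            _case_with_ranking(f"P{i}", [f"D{i}", "X1", "X2", "X3", "X4"], f"D{i}")
            for i in range(20)
        ]
        for k in (1, 3, 5):
            assert topk_candidate_accuracy(cases, k) == 1.0

    def test_random_scorer_matches_symmetry_argument(self, rng):
        """With 5 symmetric slots, a uniform-random ranking puts the positive
        in the top-1 with probability 0.2 and top-3 with probability 0.6."""
        n_cases = 4000
        cases = []
        for i in range(n_cases):
            ids = ["POS", "N1", "N2", "N3", "N4"]
            order = list(rng.permutation(ids))
            cases.append(_case_with_ranking(f"P{i}", order, "POS"))
        top1 = topk_candidate_accuracy(cases, 1)
        top3 = topk_candidate_accuracy(cases, 3)
        # 4 binomial sd's: sd = sqrt(p q / n)
        assert abs(top1 - 0.2) < 4 * np.sqrt(0.2 * 0.8 / n_cases)
        assert abs(top3 - 0.6) < 4 * np.sqrt(0.6 * 0.4 / n_cases)

    def test_non_decreasing_in_k(self, rng):
        cases = []
        for i in range(50):
            ids = ["POS", "N1", "N2", "N3"]
            cases.append(_case_with_ranking(f"P{i}", list(rng.permutation(ids)), "POS"))
        accs = [topk_candidate_accuracy(cases, k) for k in (1, 2, 3, 4)]
        assert accs == sorted(accs)
        assert accs[-1] == 1.0


class TestAurocAupr:
    def _toy(self, rng, n_p=4, n_d=5):
        proteins = [f"P{i}" for i in range(n_p)]
        drugs = [f"D{i}" for i in range(n_d)]
        scores = rng.standard_normal((n_p, n_d))
        edges = {
            (p, d)
            for p in proteins
            for d in drugs
            if rng.random() < 0.3
        }
        return scores, edges, proteins, drugs

    def test_perfect_separation(self):
        proteins, drugs = ["P0"], ["D0", "D1", "D2"]
        scores = np.array([[0.9, 0.1, 0.2]])
        auroc, aupr = auroc_aupr(scores, {("P0", "D0")}, proteins, drugs)
        assert auroc == 1.0 and aupr == 1.0

    def test_random_scores_near_half(self, rng):
        proteins = [f"P{i}" for i in range(40)]
        drugs = [f"D{i}" for i in range(40)]
        scores = rng.standard_normal((40, 40))
        edges = {(p, d) for p in proteins for d in drugs if rng.random() < 0.5}
        auroc, _ = auroc_aupr(scores, edges, proteins, drugs)
        assert abs(auroc - 0.5) < 0.05

    def test_auroc_matches_pairwise_oracle(self, rng):
        """Exhaustive positive-negative pair comparison (half credit for
        ties) equals the computed AUROC to 1e-12."""
        for trial in range(20):
            scores, edges, proteins, drugs = self._toy(rng)
            flat = []
            for i, p in enumerate(proteins):
                for j, d in enumerate(drugs):
                    flat.append((scores[i, j], (p, d) in edges))
            pos = [s for s, is_pos in flat if is_pos]
            neg = [s for s, is_pos in flat if not is_pos]
            if not pos or not neg:
                continue
            wins = sum(
                1.0 if sp > sn else 0.5 if sp == sn else 0.0
                for sp in pos
                for sn in neg
            )
            oracle = wins / (len(pos) * len(neg))
            auroc, _ = auroc_aupr(scores, edges, proteins, drugs)
            assert auroc == pytest.approx(oracle, abs=1e-12)

    def test_invariant_under_monotone_transform(self, rng):
        scores, edges, proteins, drugs = self._toy(rng, 6, 6)
        if not edges or len(edges) == 36:
            pytest.skip("degenerate draw")
        a1, _ = auroc_aupr(scores, edges, proteins, drugs)
        a2, _ = auroc_aupr(np.tanh(2 * scores), edges, proteins, drugs)
        assert a1 == pytest.approx(a2, abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            auroc_aupr(np.array([[0.5]]), set(), ["P0"], ["D0"])

    def test_macro_averages_per_protein(self, rng):
        scores, edges, proteins, drugs = self._toy(rng, 6, 8)
        usable = [
            i
            for i, p in enumerate(proteins)
            if 0 < sum((p, d) in edges for d in drugs) < len(drugs)
        ]
        if not usable:
            pytest.skip("degenerate draw")
        macro_auroc, _ = auroc_aupr(scores, edges, proteins, drugs, macro=True)
        assert 0.0 <= macro_auroc <= 1.0


class TestBuildLabelSets:
    def test_ranking_excludes_training_drugs(self):
        scores = np.array([[0.9, 0.8, 0.7]])
        sets = build_label_sets(
            scores,
            ["P0"],
            ["D0", "D1", "D2"],
            truth_edges={("P0", "D1")},
            exclude_edges={("P0", "D0")},
        )
        assert sets[0].predicted_ranking == ["D1", "D2"]
        assert sets[0].true_drugs == {"D1"}

    def test_ties_break_by_drug_id(self):
        scores = np.array([[0.5, 0.5, 0.5]])
        sets = build_label_sets(
            scores, ["P0"], ["D2", "D0", "D1"], truth_edges={("P0", "D1")}
        )
        assert sets[0].predicted_ranking == ["D0", "D1", "D2"]

    def test_proteins_without_truth_skipped(self):
        scores = np.zeros((2, 2))
        sets = build_label_sets(
            scores, ["P0", "P1"], ["D0", "D1"], truth_edges={("P1", "D0")}
        )
        assert [s.protein_id for s in sets] == ["P1"]
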