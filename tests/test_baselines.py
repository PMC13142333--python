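"""Baseline predictor contracts: frequency, alignment transfer, k-NN, evidence."""

import numpy as np
import pandas as pd
import pytest

import funcbench as fb
from funcbench.synthetic import simulate_predictor


class TestNaive:
    def test_toy_frequencies(self, toy_corpus, toy_graph):
        scores = fb.naive_term_scores(toy_corpus, toy_graph, toy_graph)
        assert scores == {"r": 1.0, "a": 0.5, "b": 0.25, "c": 0.25}

    def test_single_protein_corpus_scores_one(self, toy_graph):
        corpus = fb.AnnotationSet.from_records(
            [fb.AnnotationRecord("P1", "c", "IDA")], toy_graph
        )
        scores = fb.naive_term_scores(corpus, toy_graph, toy_graph)
        assert set(scores.values()) == {1.0}

    def test_terms_absent_from_target_ontology_dropped(self, toy_corpus, toy_graph):
        from conftest import TOY_OBO

        target = fb.parse_obo(TOY_OBO.replace(
            "\n[Term]\nid: c\nname: c\nnamespace: molecular_function\nis_a: a\n", "\n"))
        scores = fb.naive_term_scores(toy_corpus, toy_graph, target)
        assert "c" not in scores
        assert scores["a"] == 0.5  # c's protein still counts for ancestor a

    def test_duplication_invariance(self, toy_graph, toy_corpus):
        doubled = fb.AnnotationSet.from_records(
            [
                fb.AnnotationRecord(f"{p}:{i}", t, "IDA")
                for i in range(2)
                for p, _, ts in toy_corpus.items()
                for t in ts
            ],
            toy_graph,
        )
        assert fb.naive_term_scores(doubled, toy_graph, toy_graph) == \
            fb.naive_term_scores(toy_corpus, toy_graph, toy_graph)

    def test_identical_scores_for_every_target(self, toy_corpus, toy_graph):
        preds = fb.naive_baseline(toy_corpus, toy_graph, toy_graph, ["X", "Y"])
        assert preds.scores("X") == preds.scores("Y")

    def test_empty_corpus_is_error(self, toy_graph):
        with pytest.raises(ValueError, match="empty"):
            fb.naive_term_scores(
                fb.AnnotationSet({}, toy_graph.version_tag), toy_graph, toy_graph
            )


class TestBlastTransfer:
    def reference(self, toy_graph):
        return fb.AnnotationSet.from_records(
            [fb.AnnotationRecord("P2", "c", "IDA"), fb.AnnotationRecord("P3", "b", "IDA")],
            toy_graph,
        )  # P2:{r,a,c}, P3:{r,b}

    def hits(self, rows):
        return fb.AlignmentHitTable(pd.DataFrame(rows, columns=["query", "subject", "pident"]))

    def test_per_term_max_identity(self, toy_graph):
        preds = fb.blast_transfer(
            self.hits([("X", "P2", 80.0), ("X", "P3", 90.0)]), self.reference(toy_graph)
        )
        assert preds.scores("X") == {"a": 0.8, "c": 0.8, "b": 0.9, "r": 0.9}

    def test_full_identity_copies_subject(self, toy_graph):
        preds = fb.blast_transfer(self.hits([("X", "P3", 100.0)]), self.reference(toy_graph))
        assert preds.scores("X") == {"b": 1.0, "r": 1.0}

    def test_query_without_hits_emits_nothing(self, toy_graph):
        preds = fb.blast_transfer(self.hits([("X", "P2", 75.0)]), self.reference(toy_graph))
        assert "Y" not in preds.proteins

    def test_unknown_subject_ignored_with_warning(self, toy_graph):
        with pytest.warns(UserWarning, match="missing from the reference"):
            preds = fb.blast_transfer(
                self.hits([("X", "P99", 95.0), ("X", "P3", 50.0)]),
                self.reference(toy_graph),
            )
        assert preds.scores("X") == {"b": 0.5, "r": 0.5}

    def test_identity_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="identities"):
            self.hits([("X", "P2", 101.0)])


class TestEmbeddingTransfer:
    def make_world(self, toy_graph):
        reference = fb.AnnotationSet.from_records(
            [
                fb.AnnotationRecord("R1", "a", "IDA"),
                fb.AnnotationRecord("R2", "b", "IDA"),
                fb.AnnotationRecord("R3", "b", "IDA"),
                fb.AnnotationRecord("R3", "c", "IDA"),
            ],
            toy_graph,
        )
        # target at origin; references at euclidean distances 1, 2, 4
        table = fb.EmbeddingTable(
            ["T", "R1", "R2", "R3"],
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [4.0, 0.0]]),
        )
        return table, reference

    def test_hand_geometry_k2(self, toy_graph):
        table, reference = self.make_world(toy_graph)
        preds = fb.embedding_knn_transfer(table, reference, k=2, metric="euclidean")
        scores = preds.scores("T")
        # dmax = 4 over all target-reference pairs; neighbours at d=1 ({r,a}), d=2 ({r,b})
        assert scores["a"] == pytest.approx(0.75)  # (4-1)/4
        assert scores["b"] == pytest.approx(0.5)  # (4-2)/4
        assert "c" not in scores  # R3 is not among the 2 nearest

    def test_normalization_endpoints(self, toy_graph):
        table, reference = self.make_world(toy_graph)
        preds = fb.embedding_knn_transfer(table, reference, k=3, metric="euclidean")
        scores = preds.scores("T")
        assert scores["c"] == 0.0  # R3 sits exactly at dmax
        coincident = fb.EmbeddingTable(
            ["T", "R1", "R2"], np.array([[0.0, 0.0], [0.0, 0.0], [3.0, 4.0]])
        )
        ref2 = fb.AnnotationSet.from_records(
            [fb.AnnotationRecord("R1", "a", "IDA"), fb.AnnotationRecord("R2", "b", "IDA")],
            toy_graph,
        )
        preds2 = fb.embedding_knn_transfer(coincident, ref2, k=1, metric="euclidean")
        assert preds2.scores("T")["a"] == 1.0  # d=0 -> similarity 100

    def test_k_clamped_with_warning(self, toy_graph):
        table, reference = self.make_world(toy_graph)
        with pytest.warns(UserWarning, match="clamped"):
            fb.embedding_knn_transfer(table, reference, k=10, metric="euclidean")

    def test_cosine_zero_vector_rejected(self, toy_graph):
        _, reference = self.make_world(toy_graph)
        table = fb.EmbeddingTable(
            ["T", "R1", "R2", "R3"],
            np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0], [4.0, 0.0]]),
        )
        with pytest.raises(ValueError, match="zero embedding vector for 'T'"):
            fb.embedding_knn_transfer(table, reference, k=2, metric="cosine")

    def test_cosine_scores_within_unit_interval(self, small_world):
        world = small_world
        preds = fb.embedding_knn_transfer(
            world.embeddings, world.corpus_t0, k=3, metric="cosine",
            targets=world.targets[:20],
        )
        for _, scores in preds.items():
            assert all(0.0 <= s <= 1.0 for s in scores.values())


class TestNonExperimental:
    def test_all_annotated_terms_scored_one(self, toy_graph):
        t0_all = fb.AnnotationSet.from_records(
            [fb.AnnotationRecord("P1", "c", "IEA")], toy_graph
        )
        preds = fb.nonexperimental_transfer(t0_all)
        assert preds.scores("P1") == {"c": 1.0, "a": 1.0, "r": 1.0}
        assert "P2" not in preds.proteins

    def test_prescient_electronic_annotations_reach_perfect_fmax(self, toy_graph):
        """If t0 electronic annotations equal the later experimental truth,
        the evidence-transfer baseline is a perfect predictor end to end."""
        from funcbench.evaluation import EvaluationPartition, PartitionEntry

        t0_all = fb.AnnotationSet.from_records(
            [fb.AnnotationRecord("P1", "b", "IEA")], toy_graph
        )
        part = EvaluationPartition(
            [PartitionEntry("P1", "MFO", "NK", frozenset(), frozenset({"b"}))]
        )
        preds = fb.prepare_predictions(
            fb.nonexperimental_transfer(t0_all), toy_graph, part
        )
        curve = fb.metric_curves(preds, part, "NK", "MFO", toy_graph)
        assert fb.fmax(curve).value == 1.0


def test_transfer_outputs_are_ancestor_consistent(small_world):
    """Parent score >= child score whenever the reference is propagated."""
    world = small_world
    for preds in (
        fb.blast_transfer(world.hits, world.corpus_t0),
        fb.embedding_knn_transfer(
            world.embeddings, world.corpus_t0, k=3, targets=world.targets[:25]
        ),
    ):
        for _, scores in preds.items():
            for term, score in scores.items():
                for parent in world.graph.parents(term):
                    assert scores[parent] >= score - 1e-12


def test_baseline_scores_feed_evaluation_unchanged(small_world):
    world = small_world
    preds = fb.blast_transfer(world.hits, world.corpus_t0)
    prepared = fb.prepare_predictions(preds, world.graph, world.partition)
    curve = fb.metric_curves(prepared, world.partition, "PK", "BPO", world.graph)
    assert np.nanmax(curve.pr) <= 1.0
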