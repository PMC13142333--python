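"""Partitioning, prediction preparation, metric curves, Fmax/Smin, bootstrap."""

import io

import numpy as np
import pytest

import funcbench as fb
from funcbench.evaluation import (
    DEFAULT_GRID,
    EvaluationPartition,
    PartitionEntry,
)
from funcbench.synthetic import WorldParams, generate_world, simulate_predictor


def build_set(toy_graph, assignments, tag):
    records = [
        fb.AnnotationRecord(p, t, "IDA") for p, terms in assignments.items() for t in terms
    ]
    return fb.AnnotationSet.from_records(records, toy_graph, snapshot_tag=tag)


# --------------------------------------------------------------- partition


class TestPartitionSettings:
    def partition(self, toy_graph, t0_map, te_map):
        t0 = build_set(toy_graph, t0_map, "t0")
        te = build_set(toy_graph, te_map, "te")
        growth = fb.snapshot_growth(t0, te, toy_graph)
        return fb.partition_settings(t0, growth, toy_graph)

    def test_root_only_prior_is_no_knowledge(self, toy_graph):
        part = self.partition(toy_graph, {"P4": ["r"]}, {"P4": ["b"]})
        entry = part.entry("P4", "MFO")
        assert entry.setting == "NK"
        assert entry.truth == {"b"}

    def test_annotated_prior_same_aspect_is_partial_knowledge(self, toy_graph):
        part = self.partition(toy_graph, {"P2": ["c"]}, {"P2": ["c", "b"]})
        entry = part.entry("P2", "MFO")
        assert entry.setting == "PK"
        assert entry.prior == {"r", "a", "c"}
        assert entry.truth == {"b"}

    def test_other_aspect_prior_is_limited_knowledge(self, small_world):
        """LK pairs exist and their proteins are annotated elsewhere at t0."""
        lk = small_world.partition.entries("LK")
        assert lk
        for entry in lk:
            annotated = small_world.corpus_t0.annotated_aspects(entry.protein, small_world.graph)
            assert annotated and entry.aspect not in annotated

    def test_same_protein_can_be_lk_and_pk_in_different_aspects(self, toy_graph):
        # single-aspect toy graph cannot host this; use a synthetic world
        world = generate_world(seed=3)
        by_protein = {}
        for entry in world.partition:
            by_protein.setdefault(entry.protein, set()).add(entry.setting)
        assert any({"LK", "PK"} <= s for s in by_protein.values())

    def test_every_entry_has_truth(self, small_world):
        for entry in small_world.partition:
            assert entry.truth


# ------------------------------------------------------------- preparation


class TestPreparePredictions:
    def test_pk_prior_subtracted(self, toy_graph):
        part = EvaluationPartition(
            [PartitionEntry("P2", "MFO", "PK", frozenset({"r", "a", "c"}), frozenset({"b"}))]
        )
        preds = fb.PredictionSet({"P2": {"a": 1.0, "c": 0.9, "b": 0.6}})
        prepared = fb.prepare_predictions(preds, toy_graph, part)
        assert prepared.scores("P2") == {"b": 0.6}

    def test_propagation_takes_max_over_descendants(self, toy_graph):
        prepared = fb.prepare_predictions(
            fb.PredictionSet({"P": {"c": 0.7}}), toy_graph, None, propagate=True
        )
        assert prepared.scores("P") == {"c": 0.7, "a": 0.7, "r": 0.7}
        prepared = fb.prepare_predictions(
            fb.PredictionSet({"P": {"c": 0.7, "a": 0.9}}), toy_graph, None, propagate=True
        )
        assert prepared.scores("P")["a"] == 0.9

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError, match="P1.*outside"):
            fb.PredictionSet({"P1": {"a": 1.5}})

    def test_unknown_terms_dropped_with_count(self, toy_graph):
        with pytest.warns(UserWarning, match="unknown terms"):
            prepared = fb.prepare_predictions(
                fb.PredictionSet({"P": {"a": 0.5, "zz": 0.4}}), toy_graph, None,
                propagate=False,
            )
        assert prepared.scores("P") == {"a": 0.5}


def test_prediction_file_round_trip_with_cafa_header(tmp_path):
    text = "AUTHOR team\nMODEL 1\nKEYWORDS machine learning\nP1 a 0.70\nP1 b 0.30\nEND\n"
    preds = fb.PredictionSet.from_file(io.StringIO(text))
    assert preds.header["AUTHOR"] == "team"
    assert preds.scores("P1") == {"a": 0.70, "b": 0.30}
    path = str(tmp_path / "preds.tsv")
    preds.to_file(path)
    assert fb.PredictionSet.from_file(path) == preds


# ------------------------------------------------------------------ curves


@pytest.fixture
def p4_partition(toy_graph):
    return EvaluationPartition(
        [PartitionEntry("P4", "MFO", "NK", frozenset(), frozenset({"b"}))]
    )


@pytest.fixture
def p4_preds():
    return fb.PredictionSet({"P4": {"a": 0.9, "b": 0.8, "c": 0.3}})


class TestMetricCurves:
    def test_hand_example_micro(self, toy_graph, p4_partition, p4_preds):
        curve = fb.metric_curves(p4_preds, p4_partition, "NK", "MFO", toy_graph)
        at = {t: i for i, t in enumerate(curve.thresholds)}
        assert curve.pr[at[0.8]] == 0.5 and curve.rc[at[0.8]] == 1.0
        assert curve.pr[at[0.2]] == pytest.approx(1 / 3) and curve.rc[at[0.2]] == 1.0
        assert np.isnan(curve.pr[at[0.95]])  # no predictions past 0.9
        assert curve.cov[at[0.8]] == 1.0 and curve.cov[at[0.95]] == 0.0

    def test_hand_example_ru_mi(self, toy_graph, toy_ia, p4_partition, p4_preds):
        curve = fb.metric_curves(
            p4_preds, p4_partition, "NK", "MFO", toy_graph, ia=toy_ia
        )
        at = {t: i for i, t in enumerate(curve.thresholds)}
        assert (curve.ru[at[0.8]], curve.mi[at[0.8]]) == (0.0, 1.0)
        assert (curve.ru[at[0.9]], curve.mi[at[0.9]]) == (2.0, 1.0)

    def test_coverage_non_increasing(self, small_world, toy_ia):
        world = small_world
        preds = simulate_predictor(world, 0.5, seed=5)
        prepared = fb.prepare_predictions(preds, world.graph, world.partition)
        curve = fb.metric_curves(prepared, world.partition, "PK", "BPO", world.graph)
        assert (np.diff(curve.cov) <= 0).all()
        assert ((curve.cov >= 0) & (curve.cov <= 1)).all()

    def test_micro_recall_non_increasing(self, small_world):
        world = small_world
        preds = simulate_predictor(world, 0.4, seed=6)
        prepared = fb.prepare_predictions(preds, world.graph, world.partition)
        for aspect in ("MFO", "BPO", "CCO"):
            curve = fb.metric_curves(prepared, world.partition, "PK", aspect, world.graph)
            assert (np.diff(curve.rc) <= 1e-15).all()

    def test_adding_true_prediction_never_lowers_recall(self, toy_graph, p4_partition):
        base = fb.metric_curves(
            fb.PredictionSet({"P4": {"a": 0.9}}), p4_partition, "NK", "MFO", toy_graph
        )
        more = fb.metric_curves(
            fb.PredictionSet({"P4": {"a": 0.9, "b": 0.6}}),
            p4_partition, "NK", "MFO", toy_graph,
        )
        assert (more.rc >= base.rc - 1e-15).all()

    def test_ia_table_required_for_weighted(self, toy_graph, p4_partition, p4_preds):
        with pytest.raises(ValueError, match="IA table"):
            fb.metric_curves(
                p4_preds, p4_partition, "NK", "MFO", toy_graph, weighting="ia"
            )


# ------------------------------------------------------------- fmax / smin


class TestSummaries:
    def test_fmax_hand_example(self, toy_graph, p4_partition, p4_preds):
        curve = fb.metric_curves(p4_preds, p4_partition, "NK", "MFO", toy_graph)
        summary = fb.fmax(curve)
        assert summary.value == pytest.approx(2 / 3)
        assert summary.tau == pytest.approx(0.80)

    def test_smin_hand_example(self, toy_graph, toy_ia, p4_partition, p4_preds):
        curve = fb.metric_curves(
            p4_preds, p4_partition, "NK", "MFO", toy_graph, ia=toy_ia
        )
        summary = fb.smin(curve)
        assert summary.value == 1.0
        assert summary.tau == pytest.approx(0.80)

    def test_disjoint_predictor_scores_zero(self, toy_graph, p4_partition):
        preds = fb.PredictionSet({"P4": {"a": 0.9, "c": 0.4}})  # truth is {b}
        curve = fb.metric_curves(preds, p4_partition, "NK", "MFO", toy_graph)
        assert fb.fmax(curve).value == 0.0

    def test_empty_predictor_smin_is_truth_information(self, toy_graph, toy_ia, p4_partition):
        curve = fb.metric_curves(
            fb.PredictionSet(), p4_partition, "NK", "MFO", toy_graph, ia=toy_ia
        )
        assert (curve.mi == 0).all()
        assert fb.smin(curve).value == 2.0  # ia(b)

    def test_pk_predictor_of_only_prior_terms_has_no_evaluable_predictions(self, toy_graph):
        part = EvaluationPartition(
            [PartitionEntry("P2", "MFO", "PK", frozenset({"r", "a", "c"}), frozenset({"b"}))]
        )
        preds = fb.PredictionSet({"P2": {"r": 1.0, "a": 1.0, "c": 1.0}})
        prepared = fb.prepare_predictions(preds, toy_graph, part)
        curve = fb.metric_curves(prepared, part, "PK", "MFO", toy_graph)
        assert np.isnan(curve.pr).all()  # precision undefined everywhere
        assert (curve.rc == 0).all()
        assert fb.fmax(curve).value == 0.0


def exhaustive_fmax(entries_scores, truths):
    """Independent oracle: sweep every distinct score as a threshold (micro)."""
    distinct = sorted({s for scores in entries_scores for s in scores.values()})
    best = 0.0
    for tau in distinct:
        tp = fp = fn = 0
        covered = 0
        for scores, truth in zip(entries_scores, truths):
            predicted = {t for t, s in scores.items() if s >= tau}
            if predicted:
                covered += 1
            tp += len(predicted & truth)
            fp += len(predicted - truth)
            fn += len(truth - predicted)
        if covered == 0:
            continue
        pr = tp / (tp + fp) if tp + fp else 0.0
        rc = tp / (tp + fn)
        f1 = 2 * pr * rc / (pr + rc) if pr + rc else 0.0
        best = max(best, f1)
    return best


def exhaustive_smin(entries_scores, truths, weights):
    distinct = sorted({s for scores in entries_scores for s in scores.values()}) + [2.0]
    n = len(truths)
    best = float("inf")
    for tau in distinct:
        ru = mi = 0.0
        for scores, truth in zip(entries_scores, truths):
            predicted = {t for t, s in scores.items() if s >= tau}
            ru += sum(weights.get(t, 0.0) for t in truth - predicted)
            mi += sum(weights.get(t, 0.0) for t in predicted - truth)
        best = min(best, np.hypot(ru / n, mi / n))
    return best


def test_grid_summaries_match_exhaustive_oracle(toy_graph, toy_ia):
    """On instances with grid-quantized scores, the 0.01 grid sweep equals
    exhaustive evaluation over all distinct score thresholds, exactly."""
    rng = np.random.default_rng(2024)
    terms = ["a", "b", "c"]
    n_checked = 0
    for _ in range(250):
        n_prot = int(rng.integers(1, 4))
        entries, scores_list, truths = [], [], []
        for i in range(n_prot):
            truth = frozenset(rng.choice(terms, size=rng.integers(1, 3), replace=False))
            scored = [t for t in terms if rng.random() < 0.8]
            scores = {
                t: float(rng.choice(np.round(np.arange(1, 101) / 100, 2))) for t in scored
            }
            entries.append(PartitionEntry(f"P{i}", "MFO", "NK", frozenset(), truth))
            scores_list.append(scores)
            truths.append(set(truth))
        if not any(scores_list):
            continue
        part = EvaluationPartition(entries)
        preds = fb.PredictionSet(
            {f"P{i}": s for i, s in enumerate(scores_list) if s}
        )
        curve = fb.metric_curves(preds, part, "NK", "MFO", toy_graph)
        assert fb.fmax(curve).value == exhaustive_fmax(scores_list, truths)
        curve_w = fb.metric_curves(preds, part, "NK", "MFO", toy_graph, ia=toy_ia)
        assert fb.smin(curve_w).value == pytest.approx(
            exhaustive_smin(scores_list, truths, dict(toy_ia.values)), abs=1e-12
        )
        n_checked += 1
    assert n_checked >= 200


# --------------------------------------------------------------- aggregate


def test_aggregate_score_is_mean_of_three():
    assert fb.aggregate_score({"MFO": 1.0, "BPO": 1.0, "CCO": 1.0}) == 1.0
    assert fb.aggregate_score({"MFO": 0.6, "BPO": 0.3, "CCO": 0.9}) == pytest.approx(0.6)
    with pytest.raises(ValueError, match="missing aspect"):
        fb.aggregate_score({"MFO": 0.5, "BPO": 0.5})


def test_challenge_score_matches_per_aspect_fmax(tiny_world):
    world = tiny_world
    ia = fb.compute_ia(world.corpus_t0, world.graph)
    preds = simulate_predictor(world, 0.7, seed=4)
    prepared = fb.prepare_predictions(preds, world.graph, world.partition)
    per_aspect = {}
    for aspect in ("MFO", "BPO", "CCO"):
        curve = fb.metric_curves(
            prepared, world.partition, ("NK", "LK"), aspect, world.graph,
            ia=ia, weighting="ia",
        )
        per_aspect[aspect] = fb.fmax(curve).value
    score = fb.challenge_score(prepared, world.partition, world.graph, ia)
    assert score == pytest.approx(np.mean(list(per_aspect.values())))


# --------------------------------------------------------------- bootstrap


class TestBootstrap:
    def metric(self, toy_graph):
        def fn(entries):
            preds = fb.PredictionSet({"P4": {"b": 0.8, "a": 0.9}})
            part = EvaluationPartition(list({(e.protein, e.aspect): e for e in entries}.values()))
            curve = fb.metric_curves(
                preds, part, "NK", "MFO", toy_graph, entries=entries
            )
            return fb.fmax(curve).value

        return fn

    def test_single_protein_ci_width_zero(self, toy_graph, p4_partition):
        result = fb.bootstrap_metric(
            self.metric(toy_graph), p4_partition.entries(), B=50, seed=1
        )
        assert result.low == result.high == result.point
        assert result.mean == pytest.approx(result.point)

    def test_b_equals_one(self, toy_graph, p4_partition):
        result = fb.bootstrap_metric(
            self.metric(toy_graph), p4_partition.entries(), B=1, seed=2
        )
        assert result.low == result.high == result.mean

    def test_seeded_runs_bit_reproducible(self, tiny_world):
        world = tiny_world
        prepared = fb.prepare_predictions(
            simulate_predictor(world, 0.6, seed=9), world.graph, world.partition
        )
        entries = world.partition.entries("PK", "BPO")

        def fn(es):
            curve = fb.metric_curves(
                prepared, world.partition, "PK", "BPO", world.graph, entries=es
            )
            return fb.fmax(curve).value

        a = fb.bootstrap_metric(fn, entries, B=200, seed=17)
        b = fb.bootstrap_metric(fn, entries, B=200, seed=17)
        assert (a.low, a.high, a.mean) == (b.low, b.high, b.mean)

    def test_ci_orders_and_contains_mean(self, tiny_world):
        world = tiny_world
        prepared = fb.prepare_predictions(
            simulate_predictor(world, 0.6, seed=9), world.graph, world.partition
        )
        entries = world.partition.entries("PK", "BPO")

        def fn(es):
            curve = fb.metric_curves(
                prepared, world.partition, "PK", "BPO", world.graph, entries=es
            )
            return fb.fmax(curve).value

        result = fb.bootstrap_metric(fn, entries, B=300, seed=5)
        assert result.low <= result.mean <= result.high


# ---------------------------------------------------------------- summary


def test_summarize_dataset_matches_generator_ledger(small_world):
    world = small_world
    table = fb.summarize_dataset(world.partition)
    ledger_counts = {}
    for (protein, aspect), (setting, new) in world.ledger.items():
        key = (setting, aspect)
        n_prot, n_terms = ledger_counts.get(key, (0, 0))
        ledger_counts[key] = (n_prot + 1, n_terms + len(new))
    for (setting, aspect), (n_prot, n_terms) in ledger_counts.items():
        row = table[(table.setting == setting) & (table.aspect == aspect)].iloc[0]
        assert (row.proteins, row.terms) == (n_prot, n_terms)
    grand = table[(table.setting == "total") & (table.aspect == "total")].iloc[0]
    assert grand.terms == sum(len(new) for _, new in world.ledger.values())
    assert grand.proteins == len({p for p, _ in world.ledger})


def test_summarize_empty_partition_is_all_zero():
    table = fb.summarize_dataset(EvaluationPartition([]))
    assert (table.proteins == 0).all() and (table.terms == 0).all()
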