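"""Baseline predictors: term frequency, evidence transfer, sequence- and
embedding-similarity annotation transfer.

All four baselines are built exclusively from information frozen at the
submission deadline t0 and emit scores in [0, 1], so their outputs are valid
inputs to the evaluation module unchanged.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass
from typing import TextIO

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .annotations import AnnotationSet
from .evaluation import PredictionSet
from .ontology import OntologyGraph, UnknownTermError


@dataclass
class AlignmentHitTable:
    """Pairwise local-alignment hits: query, subject, percent identity.

    Consumed from 12-column tabular alignment output (BLAST ``-outfmt 6``);
    only the first three columns are used, the rest are ignored.
    """

    hits: pd.DataFrame  # columns: query, subject, pident

    def __post_init__(self) -> None:
        required = {"query", "subject", "pident"}
        if not required.issubset(self.hits.columns):
            raise ValueError(f"hit table needs columns {sorted(required)}")
        pid = self.hits["pident"]
        if ((pid < 0) | (pid > 100)).any():
            raise ValueError("percent identities must lie in [0, 100]")
        if (self.hits["query"].astype(str) == "").any() or (
            self.hits["subject"].astype(str) == ""
        ).any():
            raise ValueError("query/subject identifiers must be non-empty")

    @classmethod
    def from_file(cls, source: str | TextIO) -> "AlignmentHitTable":
        df = pd.read_csv(source, sep="\t", header=None, comment="#")
        df = df.iloc[:, :3]
        df.columns = ["query", "subject", "pident"]
        return cls(df)

    def to_file(self, target: str | TextIO) -> None:
        # pad to the standard 12 columns so the file re-reads as outfmt 6
        df = self.hits.copy()
        for i, col in enumerate(
            ["length", "mismatch", "gapopen", "qstart", "qend", "sstart", "send",
             "evalue", "bitscore"]
        ):
            if col not in df.columns:
                df[col] = 0
        df.to_csv(target, sep="\t", header=False, index=False)

    def __len__(self) -> int:
        return len(self.hits)


@dataclass
class EmbeddingTable:
    """Fixed-length numeric vector per protein (e.g. language-model embeddings)."""

    ids: list[str]
    matrix: np.ndarray
    source_tag: str = ""

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != len(self.ids):
            raise ValueError("matrix must be (n_proteins, dim)")
        if not np.isfinite(self.matrix).all():
            raise ValueError("embeddings contain non-finite entries")
        self._index = {p: i for i, p in enumerate(self.ids)}

    @property
    def dimension(self) -> int:
        return self.matrix.shape[1]

    def __contains__(self, protein: str) -> bool:
        return protein in self._index

    def vectors(self, proteins: Sequence[str]) -> np.ndarray:
        try:
            rows = [self._index[p] for p in proteins]
        except KeyError as exc:
            raise KeyError(f"protein {exc.args[0]!r} has no embedding") from None
        return self.matrix[rows]

    @classmethod
    def from_file(cls, source: str | TextIO, source_tag: str = "") -> "EmbeddingTable":
        df = pd.read_csv(source, sep="\t", header=None, comment="#")
        return cls(df.iloc[:, 0].astype(str).tolist(), df.iloc[:, 1:].to_numpy(float), source_tag)

    def to_file(self, target: str | TextIO) -> None:
        handle = open(target, "w") if isinstance(target, str) else target
        try:
            for pid, row in zip(self.ids, self.matrix):
                handle.write(pid + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
        finally:
            if isinstance(target, str):
                handle.close()


# ----------------------------------------------------------------- baselines


def naive_term_scores(
    corpus_t0: AnnotationSet,
    graph_t0: OntologyGraph,
    graph_target: OntologyGraph,
) -> dict[str, float]:
    """Per-term corpus frequencies on the target ontology.

    The corpus (already propagated on the t0 ontology) is restricted to terms
    present in the target ontology, re-propagated there to restore
    connectivity, and each term scored as the fraction of corpus proteins
    annotated with it.
    """
    if len(corpus_t0) == 0:
        raise ValueError("corpus is empty")
    counts: dict[str, int] = {}
    for protein in corpus_t0.proteins:
        terms: set[str] = set()
        for aspect in corpus_t0.aspects_of(protein):
            kept = []
            for t in corpus_t0.terms(protein, aspect):
                try:
                    kept.append(graph_target.resolve(t))
                except UnknownTermError:
                    continue
            if kept:
                terms |= graph_target.propagate(kept)
        for t in terms:
            counts[t] = counts.get(t, 0) + 1
    n = len(corpus_t0)
    return {t: c / n for t, c in sorted(counts.items())}


def naive_baseline(
    corpus_t0: AnnotationSet,
    graph_t0: OntologyGraph,
    graph_target: OntologyGraph,
    targets: Iterable[str],
) -> PredictionSet:
    """Identical frequency-score predictions for every target protein."""
    scores = naive_term_scores(corpus_t0, graph_t0, graph_target)
    out = PredictionSet(model_tag="naive")
    for protein in targets:
        for term, s in scores.items():
            out.set_score(protein, term, s)
    return out


def blast_transfer(hits: AlignmentHitTable, reference: AnnotationSet) -> PredictionSet:
    """Transfer reference annotations at the maximum local sequence identity.

    For each query and each GO term annotated to at least one of its hit
    subjects, the score is the highest percent identity among subjects
    bearing that term, divided by 100.  Queries without hits emit nothing;
    hits whose subject is absent from the reference are ignored (counted).
    """
    out = PredictionSet(model_tag="blast")
    n_missing = 0
    best: dict[str, dict[str, float]] = {}
    for query, subject, pident in hits.hits[["query", "subject", "pident"]].itertuples(index=False):
        if subject not in reference.proteins:
            n_missing += 1
            continue
        bucket = best.setdefault(str(query), {})
        score = float(pident) / 100.0
        for aspect in reference.aspects_of(subject):
            for term in reference.terms(subject, aspect):
                if bucket.get(term, -1.0) < score:
                    bucket[term] = score
    for query, terms in best.items():
        for term, score in terms.items():
            out.set_score(query, term, score)
    if n_missing:
        warnings.warn(f"ignored {n_missing} hit(s) with subjects missing from the reference",
                      stacklevel=2)
    return out


def embedding_knn_transfer(
    embeddings: EmbeddingTable,
    reference: AnnotationSet,
    k: int = 3,
    metric: str = "euclidean",
    targets: Sequence[str] | None = None,
) -> PredictionSet:
    """Transfer annotations from the k nearest reference proteins in embedding space.

    Euclidean distances d are converted to similarities (dmax - d)/dmax x 100
    with dmax the maximum distance over all target-reference pairs considered;
    cosine similarities are min-max scaled to [0, 100].  The per-term score is
    the maximum normalized similarity over the k neighbours bearing the term,
    divided by 100.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if metric not in ("euclidean", "cosine"):
        raise ValueError(f"unknown metric {metric!r}")
    ref_ids = sorted(p for p in reference.proteins if p in embeddings)
    missing_ref = reference.proteins - set(ref_ids)
    if missing_ref:
        raise ValueError(f"reference protein(s) without embeddings: {sorted(missing_ref)[:3]}")
    if targets is None:
        targets = sorted(set(embeddings.ids) - set(ref_ids))
    if k > len(ref_ids):
        warnings.warn(f"k={k} exceeds reference size {len(ref_ids)}; clamped", stacklevel=2)
        k = len(ref_ids)

    T = embeddings.vectors(list(targets))
    R = embeddings.vectors(ref_ids)
    if metric == "cosine":
        for name, M in (("target", T), ("reference", R)):
            norms = np.linalg.norm(M, axis=1)
            if (norms == 0).any():
                which = (list(targets) if name == "target" else ref_ids)[int(np.argmax(norms == 0))]
                raise ValueError(f"zero embedding vector for {which!r} under cosine metric")
        dist = cdist(T, R, metric="cosine")
        raw_sim = 1.0 - dist
        lo, hi = raw_sim.min(), raw_sim.max()
        sim = np.full_like(raw_sim, 100.0) if hi == lo else (raw_sim - lo) / (hi - lo) * 100.0
    else:
        dist = cdist(T, R, metric="euclidean")
        dmax = dist.max()
        sim = np.full_like(dist, 100.0) if dmax == 0 else (dmax - dist) / dmax * 100.0

    out = PredictionSet(model_tag=f"embed-{metric}-k{k}")
    out.header["DMAX" if metric == "euclidean" else "SIM_RANGE"] = (
        f"{dist.max():.8g}" if metric == "euclidean" else f"{raw_sim.min():.8g},{raw_sim.max():.8g}"
    )
    for i, target in enumerate(targets):
        order = np.argsort(dist[i], kind="stable")[:k]
        best: dict[str, float] = {}
        for j in order:
            subject = ref_ids[j]
            score = float(sim[i, j]) / 100.0
            for aspect in reference.aspects_of(subject):
                for term in reference.terms(subject, aspect):
                    if best.get(term, -1.0) < score:
                        best[term] = score
        for term, score in best.items():
            out.set_score(target, term, score)
    return out


def nonexperimental_transfer(all_annotations_t0: AnnotationSet) -> PredictionSet:
    """Score 1.0 for every term annotated at t0 regardless of evidence code.

    Measures how well electronic/computational annotations anticipate later
    experimental validation.
    """
    out = PredictionSet(model_tag="nonexp")
    for protein, _, terms in all_annotations_t0.items():
        for term in terms:
            out.set_score(protein, term, 1.0)
    return out
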