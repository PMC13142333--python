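"""Seeded synthetic worlds for hermetic, desk-scale testing.

A world bundles everything the evaluation pipeline consumes: a random
multi-aspect ontology, a two-snapshot annotation corpus whose growth
produces all three knowledge settings in declared proportions, publication
dates (a tunable fraction of new annotations citing post-deadline
references), protein embeddings whose proximity correlates with annotation
similarity, an alignment hit table, and predictors of tunable quality.

Defaults emulate the structure of a real prospective-evaluation corpus:
partial-knowledge pairs dominate the evaluable annotations, term frequencies
are power-law skewed so information accretion spans a wide range, and about
a tenth of new annotations stem from publications dated after the deadline.
Everything is deterministic under the seed.
"""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import os
from collections.abc import Sequence
from dataclasses import asdict, dataclass, field

import numpy as np

from .annotations import (
    AnnotationRecord,
    AnnotationSet,
    GrowthSet,
    snapshot_growth,
    write_annotations_tsv,
)
from .baselines import AlignmentHitTable, EmbeddingTable
from .evaluation import EvaluationPartition, PredictionSet, partition_settings
from .ontology import ASPECT_TO_NAMESPACE, ASPECTS, OntologyGraph, parse_obo

import networkx as nx

_EXP_CODES = ("IDA", "IMP", "IGI", "IEP", "IPI")
_NONEXP_CODES = ("IEA", "ISS", "IBA")


@dataclass(frozen=True)
class WorldParams:
    """Generation parameters; defaults are the package's study conditions."""

    aspects: tuple[str, ...] = ASPECTS
    terms_per_aspect: int = 40
    max_depth: int = 5
    branching: int = 3
    n_proteins: int = 200
    term_popularity_skew: float = 1.2
    #: fraction of proteins whose growth realises each setting; the rest gain nothing
    growth_fraction_per_setting: dict = field(
        default_factory=lambda: {"NK": 0.10, "LK": 0.12, "PK": 0.45}
    )
    #: fraction of new annotations citing a publication dated after t0
    unpublished_fraction: float = 0.10
    embedding_dim: int = 16
    embedding_informativeness: float = 0.85
    t0_date: str = "2023-08-21"
    te_date: str = "2025-06-01"

    def __post_init__(self) -> None:
        if min(self.terms_per_aspect, self.max_depth, self.branching, self.n_proteins) <= 0:
            raise ValueError("size parameters must be positive")
        total = sum(self.growth_fraction_per_setting.values())
        if total > 1.0 + 1e-9:
            raise ValueError("growth fractions must sum to at most 1")


@dataclass
class SyntheticWorld:
    """A generated benchmark world plus its bookkeeping ledger."""

    params: WorldParams
    seed: int
    graph: OntologyGraph
    records_t0: tuple[AnnotationRecord, ...]  # all evidence codes
    records_te: tuple[AnnotationRecord, ...]
    corpus_t0: AnnotationSet  # experimental, propagated
    corpus_te: AnnotationSet
    corpus_t0_all: AnnotationSet  # any evidence, propagated
    growth: GrowthSet
    partition: EvaluationPartition
    #: per (protein, aspect): (intended setting, new non-root terms)
    ledger: dict[tuple[str, str], tuple[str, frozenset[str]]]
    embeddings: EmbeddingTable
    hits: AlignmentHitTable
    targets: list[str]

    def popularity(self) -> dict[str, float]:
        """Corpus frequency of each non-root term at t0 (for decoy sampling)."""
        counts: dict[str, int] = {}
        for _, _, ts in self.corpus_t0.items():
            for t in self.graph.nonroot(ts):
                counts[t] = counts.get(t, 0) + 1
        return counts


# ------------------------------------------------------------------ ontology


def _random_aspect_dag(
    rng: np.random.Generator,
    aspect_idx: int,
    aspect: str,
    n_terms: int,
    max_depth: int,
    branching: int,
) -> tuple[nx.MultiDiGraph, str]:
    """Random rooted DAG: each non-root term links to 1-2 shallower parents."""
    g = nx.MultiDiGraph()
    root = f"GO:{aspect_idx + 1}000000"
    g.add_node(root, aspect=aspect, name=f"{aspect}_root")
    if n_terms == 1:
        return g, root
    # level sizes grow geometrically with `branching`, capped by n_terms - 1
    sizes: list[int] = []
    remaining = n_terms - 1
    width = 1
    for _ in range(max_depth):
        width = min(max(1, width * branching), remaining)
        sizes.append(width)
        remaining -= width
        if remaining == 0:
            break
    if remaining:
        sizes[-1] += remaining
    levels: list[list[str]] = [[root]]
    counter = 1
    for depth, size in enumerate(sizes, start=1):
        level = []
        for _ in range(size):
            term = f"GO:{aspect_idx + 1}{counter:06d}"
            counter += 1
            g.add_node(term, aspect=aspect, name=f"{aspect}_{term[-6:]}")
            shallower = [t for lv in levels for t in lv]
            k = 1 if len(shallower) == 1 or rng.random() < 0.6 else 2
            parents = rng.choice(len(shallower), size=k, replace=False)
            for p in parents:
                rel = "is_a" if rng.random() < 0.8 else "part_of"
                g.add_edge(term, shallower[int(p)], key=rel)
            level.append(term)
        levels.append(level)
    return g, root


def _build_graph(params: WorldParams, rng: np.random.Generator) -> OntologyGraph:
    g = nx.MultiDiGraph()
    for i, aspect in enumerate(params.aspects):
        sub, _ = _random_aspect_dag(
            rng, i, aspect, params.terms_per_aspect, params.max_depth, params.branching
        )
        g = nx.union(g, sub)
    return OntologyGraph(g, version_tag=f"synthetic-{params.terms_per_aspect}")


# ----------------------------------------------------------------- sampling


def _popularity_weights(
    graph: OntologyGraph, aspect: str, skew: float, rng: np.random.Generator
) -> tuple[list[str], np.ndarray]:
    terms = sorted(graph.nonroot(graph.aspect_terms(aspect)))
    ranks = rng.permutation(len(terms))
    w = (ranks + 1.0) ** (-skew)
    return terms, w / w.sum()


def _rand_date(rng: np.random.Generator, lo: dt.date, hi: dt.date) -> dt.date:
    span = (hi - lo).days
    return lo + dt.timedelta(days=int(rng.integers(0, max(span, 1))))


# ----------------------------------------------------------------- generator


def generate_world(params: WorldParams | None = None, seed: int = 0) -> SyntheticWorld:
    """Generate a complete seeded world; identical seeds give identical worlds.

    Proteins are assigned roles per ``growth_fraction_per_setting``.  NK
    proteins have no experimental annotation in any aspect at t0 (possibly
    electronic ones); LK proteins are annotated in one aspect and gain terms
    in another; PK proteins gain deeper terms in an already-annotated aspect.
    The generator's ledger of intended settings is cross-checked against the
    partitioner before the world is returned.
    """
    params = params or WorldParams()
    rng = np.random.default_rng(seed)
    graph = _build_graph(params, rng)
    t0_date = dt.date.fromisoformat(params.t0_date)
    te_date = dt.date.fromisoformat(params.te_date)
    early = dt.date(2019, 1, 1)

    pop = {a: _popularity_weights(graph, a, params.term_popularity_skew, rng)
           for a in params.aspects}

    def sample_terms(aspect: str, k: int) -> list[str]:
        terms, w = pop[aspect]
        idx = rng.choice(len(terms), size=min(k, len(terms)), replace=False, p=w)
        return [terms[i] for i in sorted(idx)]

    proteins = [f"P{i:05d}" for i in range(1, params.n_proteins + 1)]
    order = rng.permutation(params.n_proteins)
    fr = params.growth_fraction_per_setting
    n_nk = int(round(fr.get("NK", 0.0) * params.n_proteins))
    n_lk = int(round(fr.get("LK", 0.0) * params.n_proteins))
    n_pk = int(round(fr.get("PK", 0.0) * params.n_proteins))
    if n_nk + n_lk + n_pk > params.n_proteins:
        raise ValueError("growth fractions infeasible for n_proteins")
    roles: dict[str, str] = {}
    pos = 0
    for role, count in (("NK", n_nk), ("LK", n_lk), ("PK", n_pk)):
        for i in range(pos, pos + count):
            roles[proteins[order[i]]] = role
        pos += count
    for i in range(pos, params.n_proteins):
        roles[proteins[order[i]]] = "none"

    records_t0: list[AnnotationRecord] = []
    new_records: list[AnnotationRecord] = []
    pmid = 10_000

    def add_record(bucket, protein, term, code, ref_date, assigned):
        nonlocal pmid
        pmid += 1
        ref = f"PMID:{pmid}" if ref_date is not None else ""
        bucket.append(
            AnnotationRecord(protein, term, code, ref, ref_date, assigned)
        )

    def exp_code() -> str:
        return _EXP_CODES[int(rng.integers(0, len(_EXP_CODES)))]

    ledger: dict[tuple[str, str], tuple[str, frozenset[str]]] = {}
    aspect_list = list(params.aspects)

    def prior_closure(protein: str, aspect: str) -> frozenset[str]:
        terms = {r.term for r in records_t0
                 if r.protein == protein and r.evidence in _EXP_CODES
                 and graph.aspect(r.term) == aspect}
        return graph.propagate(terms) if terms else frozenset()

    def add_growth(protein: str, aspect: str, prior: frozenset[str], setting: str) -> bool:
        """Sample new te terms whose closure extends `prior`; record ledger."""
        for _ in range(12):
            candidates = sample_terms(aspect, int(rng.integers(1, 4)))
            new_terms = [t for t in candidates if t not in prior]
            closure = graph.propagate(new_terms) if new_terms else frozenset()
            gained = graph.nonroot(closure - prior)
            if gained:
                break
        else:
            return False
        for t in new_terms:
            if rng.random() < params.unpublished_fraction:
                ref_date = _rand_date(rng, t0_date + dt.timedelta(days=1), te_date)
            elif rng.random() < 0.8:
                ref_date = _rand_date(rng, early, t0_date)
            else:
                ref_date = None
            add_record(new_records, protein, t, exp_code(), ref_date,
                       _rand_date(rng, t0_date + dt.timedelta(days=1), te_date))
        ledger[(protein, aspect)] = (setting, gained)
        return True

    for protein in proteins:
        role = roles[protein]
        if role == "NK":
            if rng.random() < 0.5:  # some electronic-only records at t0
                for aspect in rng.choice(aspect_list, size=1, replace=False):
                    for t in sample_terms(str(aspect), int(rng.integers(1, 3))):
                        add_record(records_t0, protein, t,
                                   _NONEXP_CODES[int(rng.integers(0, len(_NONEXP_CODES)))],
                                   None, _rand_date(rng, early, t0_date))
            n_aspects = int(rng.integers(1, min(2, len(aspect_list)) + 1))
            grown = rng.choice(aspect_list, size=n_aspects, replace=False)
            for aspect in grown:
                add_growth(protein, str(aspect), frozenset(), "NK")
        elif role in ("LK", "PK", "none"):
            prior_aspect = str(rng.choice(aspect_list))
            for t in sample_terms(prior_aspect, int(rng.integers(1, 4))):
                add_record(records_t0, protein, t, exp_code(),
                           _rand_date(rng, early, t0_date),
                           _rand_date(rng, early, t0_date))
            if role == "LK":
                others = [a for a in aspect_list if a != prior_aspect]
                aspect = str(rng.choice(others))
                add_growth(protein, aspect, frozenset(), "LK")
            elif role == "PK":
                prior = prior_closure(protein, prior_aspect)
                add_growth(protein, prior_aspect, prior, "PK")
                # some PK proteins also gain first terms in another aspect,
                # landing in LK there (settings are per protein-aspect pair)
                others = [a for a in aspect_list if a != prior_aspect]
                if others and rng.random() < 0.3:
                    add_growth(protein, str(rng.choice(others)), frozenset(), "LK")

    records_te = tuple(records_t0) + tuple(new_records)
    corpus_t0 = AnnotationSet.from_records(
        [r for r in records_t0 if r.evidence in _EXP_CODES], graph, snapshot_tag="t0"
    )
    corpus_te = AnnotationSet.from_records(
        [r for r in records_te if r.evidence in _EXP_CODES], graph, snapshot_tag="te"
    )
    corpus_t0_all = AnnotationSet.from_records(records_t0, graph, snapshot_tag="t0-all")
    growth = snapshot_growth(corpus_t0, corpus_te, graph)
    partition = partition_settings(corpus_t0, growth, graph)

    # cross-check the ledger against the partitioner (generator correctness)
    got = {(e.protein, e.aspect): (e.setting, e.truth) for e in partition}
    if got != ledger:
        extra = set(got) ^ set(ledger)
        raise RuntimeError(f"generator ledger disagrees with partitioner (e.g. {sorted(extra)[:3]})")

    targets = sorted({p for (p, _) in ledger})
    embeddings = _build_embeddings(params, rng, graph, corpus_te, proteins)
    hits = _build_hits(rng, graph, corpus_t0, corpus_te, targets)

    return SyntheticWorld(
        params=params,
        seed=seed,
        graph=graph,
        records_t0=tuple(records_t0),
        records_te=records_te,
        corpus_t0=corpus_t0,
        corpus_te=corpus_te,
        corpus_t0_all=corpus_t0_all,
        growth=growth,
        partition=partition,
        ledger=ledger,
        embeddings=embeddings,
        hits=hits,
        targets=targets,
    )


def _build_embeddings(
    params: WorldParams,
    rng: np.random.Generator,
    graph: OntologyGraph,
    corpus_te: AnnotationSet,
    proteins: Sequence[str],
) -> EmbeddingTable:
    """Protein vectors = mean of fixed random term vectors, blended with noise.

    At informativeness 1 proteins sharing annotations coincide in embedding
    space; at 0 the embedding carries no signal.
    """
    term_vecs = {
        t: rng.normal(size=params.embedding_dim)
        for t in sorted(graph.terms - graph.root_terms)
    }
    rows = []
    alpha = params.embedding_informativeness
    for p in proteins:
        terms = sorted(
            t
            for a in corpus_te.aspects_of(p)
            for t in graph.nonroot(corpus_te.terms(p, a))
        )
        signal = (
            np.mean([term_vecs[t] for t in terms], axis=0)
            if terms
            else np.zeros(params.embedding_dim)
        )
        noise = rng.normal(size=params.embedding_dim)
        rows.append(alpha * signal + (1.0 - alpha) * noise)
    return EmbeddingTable(list(proteins), np.array(rows), source_tag="synthetic")


def _build_hits(
    rng: np.random.Generator,
    graph: OntologyGraph,
    corpus_t0: AnnotationSet,
    corpus_te: AnnotationSet,
    targets: Sequence[str],
) -> AlignmentHitTable:
    """Alignment identities correlated with annotation overlap (Jaccard)."""
    import pandas as pd

    reference = sorted(corpus_t0.proteins)
    rows = []
    for target in targets:
        t_terms = {
            t for a in corpus_te.aspects_of(target)
            for t in graph.nonroot(corpus_te.terms(target, a))
        }
        n_hits = int(rng.integers(1, min(6, len(reference)) + 1))
        subjects = rng.choice(len(reference), size=n_hits, replace=False)
        for j in subjects:
            subject = reference[int(j)]
            if subject == target:
                continue
            s_terms = {
                t for a in corpus_t0.aspects_of(subject)
                for t in graph.nonroot(corpus_t0.terms(subject, a))
            }
            union = t_terms | s_terms
            jac = len(t_terms & s_terms) / len(union) if union else 0.0
            ident = float(np.clip(30.0 + 65.0 * jac + rng.normal(0, 5.0), 20.0, 100.0))
            rows.append((target, subject, round(ident, 1)))
    df = pd.DataFrame(rows, columns=["query", "subject", "pident"])
    return AlignmentHitTable(df)


# ---------------------------------------------------------------- predictors


def simulate_predictor(
    world: SyntheticWorld,
    quality: float,
    noise_model: str = "blend",
    seed: int = 0,
    quantize: float | None = 0.01,
) -> PredictionSet:
    """A predictor whose scores interpolate between truth and noise.

    Per evaluable protein-aspect pair, candidate terms are the true terms
    (prior plus new) and popularity-sampled decoys; each candidate scores
    ``quality * 1[true] + (1 - quality) * U(0, 1)``.  Quality 1 reproduces
    the ground truth exactly at score 1.0; quality 0 scores independently of
    the truth.  ``noise_model`` selects decoy sampling: "blend" draws decoys
    by corpus popularity, "uniform" uniformly.  Scores are rounded to the
    ``quantize`` grid (None disables) and zero scores are omitted.
    """
    if not 0.0 <= quality <= 1.0:
        raise ValueError("quality must be in [0, 1]")
    if noise_model not in ("blend", "uniform"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = np.random.default_rng(seed)
    counts = world.popularity()
    out = PredictionSet(model_tag=f"sim-q{quality:g}")
    for entry in world.partition:
        truth = set(entry.truth) | set(world.graph.nonroot(entry.prior))
        aspect_terms = sorted(world.graph.nonroot(world.graph.aspect_terms(entry.aspect)))
        others = [t for t in aspect_terms if t not in truth]
        n_decoys = min(len(others), 2 * len(truth) + 3)
        if n_decoys and others:
            if noise_model == "blend":
                w = np.array([counts.get(t, 0) + 1.0 for t in others])
                w = w / w.sum()
                idx = rng.choice(len(others), size=n_decoys, replace=False, p=w)
            else:
                idx = rng.choice(len(others), size=n_decoys, replace=False)
            decoys = [others[i] for i in sorted(idx)]
        else:
            decoys = []
        for term in sorted(truth) + decoys:
            is_true = term in truth
            score = quality * is_true + (1.0 - quality) * rng.uniform()
            if quantize:
                score = round(round(score / quantize) * quantize, 10)
            score = min(max(score, 0.0), 1.0)
            if score > 0:
                out.set_score(entry.protein, term, score)
    return out


# ------------------------------------------------------------------ fixtures


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_gaf(world: SyntheticWorld, records, path: str) -> None:
    aspect_letter = {"MFO": "F", "BPO": "P", "CCO": "C"}
    qualifier = {"MFO": "enables", "BPO": "involved_in", "CCO": "located_in"}
    with open(path, "w") as fh:
        fh.write("!gaf-version: 2.2\n")
        for r in records:
            aspect = world.graph.aspect(r.term)
            date = (r.assigned_date or dt.date(2023, 1, 1)).strftime("%Y%m%d")
            fields = [
                "UniProtKB", r.protein, r.protein, qualifier[aspect], r.term,
                r.reference or "GO_REF:0000000", r.evidence, "", aspect_letter[aspect],
                r.protein, "", "protein", "taxon:9606", date, "SynthDB", "", "",
            ]
            fh.write("\t".join(fields) + "\n")


def write_fixture_files(world: SyntheticWorld, directory: str) -> dict:
    """Emit the world as plain-text files and return a checksummed manifest.

    Files: OBO ontology, 6-column annotation TSVs per snapshot (plus a GAF
    2.2 rendering of t0), target list, embedding matrix, alignment table.
    Re-reading the files reproduces the in-memory world exactly.
    """
    os.makedirs(directory, exist_ok=True)
    paths = {
        "ontology": os.path.join(directory, "ontology.obo"),
        "annotations_t0": os.path.join(directory, "annotations_t0.tsv"),
        "annotations_te": os.path.join(directory, "annotations_te.tsv"),
        "annotations_t0_gaf": os.path.join(directory, "annotations_t0.gaf"),
        "targets": os.path.join(directory, "targets.txt"),
        "embeddings": os.path.join(directory, "embeddings.tsv"),
        "hits": os.path.join(directory, "hits.tsv"),
    }
    world.graph.write_obo(paths["ontology"])
    write_annotations_tsv(world.records_t0, paths["annotations_t0"])
    write_annotations_tsv(world.records_te, paths["annotations_te"])
    _write_gaf(world, world.records_t0, paths["annotations_t0_gaf"])
    with open(paths["targets"], "w") as fh:
        fh.writelines(t + "\n" for t in world.targets)
    world.embeddings.to_file(paths["embeddings"])
    world.hits.to_file(paths["hits"])

    manifest = {
        "seed": world.seed,
        "params": asdict(world.params),
        "files": {
            name: {"path": os.path.basename(p), "sha256": _sha256(p)}
            for name, p in sorted(paths.items())
        },
    }
    with open(os.path.join(directory, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def read_world_files(directory: str) -> dict:
    """Re-parse the files written by :func:`write_fixture_files`.

    Returns the parsed graph, experimental t0/te snapshots, the any-evidence
    t0 snapshot, embeddings, hits and the target list.
    """
    from .annotations import EXPERIMENTAL_CODES, KNOWN_CODES, read_annotations

    graph = parse_obo(os.path.join(directory, "ontology.obo"))
    out = {
        "graph": graph,
        "corpus_t0": read_annotations(
            os.path.join(directory, "annotations_t0.tsv"), graph, snapshot_tag="t0"
        ),
        "corpus_te": read_annotations(
            os.path.join(directory, "annotations_te.tsv"), graph, snapshot_tag="te"
        ),
        "corpus_t0_all": read_annotations(
            os.path.join(directory, "annotations_t0.tsv"), graph,
            evidence_filter=KNOWN_CODES, snapshot_tag="t0-all",
        ),
        "embeddings": EmbeddingTable.from_file(os.path.join(directory, "embeddings.tsv")),
        "hits": AlignmentHitTable.from_file(os.path.join(directory, "hits.tsv")),
    }
    with open(os.path.join(directory, "targets.txt")) as fh:
        out["targets"] = [line.strip() for line in fh if line.strip()]
    return out
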