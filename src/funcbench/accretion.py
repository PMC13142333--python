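"""Information accretion: per-term conditional information content.

The information accretion of a term t is ia(t) = log 1/Pr(t | Pa(t)), the
surprise of observing t on a protein that already carries every parent of t,
with the probability estimated from a propagated annotation corpus frozen at
the submission deadline.  Because annotation sets are ancestor-closed, the
information content of a closed set is the plain sum of ia over its terms,
and the conditional content of newly added terms given the prior set is the
sum over the difference — the additive decomposition that makes the
partial-knowledge evaluation tractable.

Weights are frozen once at t0 and reused for every later evaluation so that
all snapshots are scored on the same scale.
"""

from __future__ import annotations

import math
import types
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass
from typing import TextIO

import numpy as np

from .annotations import AnnotationSet
from .ontology import OntologyGraph

SMOOTHING_MODES = ("drop", "add_one")


@dataclass(frozen=True)
class IATable:
    """Frozen per-term information-accretion values.

    ``values`` maps term -> ia in log units of ``log_base`` (bits for base 2).
    Roots have ia 0; terms absent from the table weigh 0 downstream (with a
    counted warning under the default "drop" smoothing).
    """

    values: Mapping[str, float]
    corpus_size: int
    log_base: float = 2.0
    snapshot_tag: str = ""
    smoothing: str = "drop"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", types.MappingProxyType(dict(self.values)))
        for term, v in self.values.items():
            if not (v >= 0.0 and math.isfinite(v)):
                raise ValueError(f"ia({term}) = {v} is not finite and non-negative")

    def ia(self, term: str) -> float:
        return self.values.get(term, 0.0)

    def weight(self, terms: Iterable[str]) -> float:
        """Total information content of a term set (missing terms weigh 0)."""
        return float(sum(self.values.get(t, 0.0) for t in terms))

    def __contains__(self, term: str) -> bool:
        return term in self.values

    def __len__(self) -> int:
        return len(self.values)

    # ---------------------------------------------------------------- io
    def to_tsv(self, target: str | TextIO) -> None:
        handle = open(target, "w") if isinstance(target, str) else target
        try:
            handle.write(f"# corpus_size: {self.corpus_size}\n")
            handle.write(f"# log_base: {self.log_base}\n")
            handle.write(f"# snapshot_tag: {self.snapshot_tag}\n")
            handle.write(f"# smoothing: {self.smoothing}\n")
            handle.write("term\tia\n")
            for term in sorted(self.values):
                handle.write(f"{term}\t{self.values[term]:.10g}\n")
        finally:
            if isinstance(target, str):
                handle.close()

    @classmethod
    def from_tsv(cls, source: str | TextIO) -> "IATable":
        handle = open(source) if isinstance(source, str) else source
        meta = {"corpus_size": "0", "log_base": "2.0", "snapshot_tag": "", "smoothing": "drop"}
        values: dict[str, float] = {}
        try:
            for line in handle:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    key, _, val = line[1:].partition(":")
                    meta[key.strip()] = val.strip()
                    continue
                if not line or line.startswith("term\t"):
                    continue
                term, _, v = line.partition("\t")
                values[term] = float(v)
        finally:
            if isinstance(source, str):
                handle.close()
        return cls(
            values,
            corpus_size=int(meta["corpus_size"]),
            log_base=float(meta["log_base"]),
            snapshot_tag=meta["snapshot_tag"],
            smoothing=meta["smoothing"],
        )


def compute_ia(
    corpus: AnnotationSet,
    graph: OntologyGraph,
    log_base: float = 2.0,
    smoothing: str = "drop",
) -> IATable:
    """Estimate ia(t) = -log Pr(t | Pa(t)) from a propagated corpus.

    ``Pr(t | Pa(t))`` is the number of corpus proteins annotated with t over
    the number annotated with *every* parent of t, counted on the propagated
    corpus.  Roots get ia 0 exactly.  Under ``smoothing="drop"`` terms never
    observed are absent from the table (weight 0 downstream); ``"add_one"``
    applies Laplace smoothing (count+1)/(denominator+2) so every term with
    observed parents receives a finite value.
    """
    if smoothing not in SMOOTHING_MODES:
        raise ValueError(f"smoothing must be one of {SMOOTHING_MODES}")
    if len(corpus) == 0:
        raise ValueError("corpus is empty")
    if corpus.graph_version != graph.version_tag:
        raise ValueError("corpus was not built on this graph version")

    proteins = sorted(corpus.proteins)
    terms = sorted(graph.terms)
    t_index = {t: i for i, t in enumerate(terms)}
    incidence = np.zeros((len(proteins), len(terms)), dtype=bool)
    for i, protein in enumerate(proteins):
        for aspect in corpus.aspects_of(protein):
            for t in corpus.terms(protein, aspect):
                incidence[i, t_index[t]] = True

    counts = incidence.sum(axis=0)
    log_b = math.log(log_base)
    values: dict[str, float] = {}
    n_unobserved = 0
    for t in terms:
        if graph.is_root(t):
            values[t] = 0.0
            continue
        parents = graph.parents(t)
        if not parents:  # disconnected from root: no conditioning set
            continue
        idx = [t_index[p] for p in parents]
        denom = int(incidence[:, idx].all(axis=1).sum())
        num = int(counts[t_index[t]])
        if smoothing == "add_one":
            pr = (num + 1) / (denom + 2)
        else:
            if num == 0:
                n_unobserved += 1
                continue
            pr = num / denom  # propagated corpus => num <= denom, denom > 0
        values[t] = -math.log(pr) / log_b
    if n_unobserved:
        warnings.warn(
            f"{n_unobserved} term(s) never observed in the corpus; absent from the "
            "table and weighted 0 downstream",
            stacklevel=2,
        )
    return IATable(
        values,
        corpus_size=len(proteins),
        log_base=log_base,
        snapshot_tag=corpus.snapshot_tag,
        smoothing=smoothing,
    )


def information_content(
    table: IATable,
    new_terms: Iterable[str],
    prior_terms: Iterable[str] = (),
) -> float:
    """Information accretion of ``new_terms`` given ``prior_terms``.

    Both sets must be disjoint and jointly ancestor-closed; the conditional
    content is then exactly the sum of ia over the new terms.  With an empty
    prior this is the unconditional information content of the set.  Terms
    missing from the table contribute 0 with a counted warning.
    """
    new_terms = frozenset(new_terms)
    prior_terms = frozenset(prior_terms)
    if new_terms & prior_terms:
        raise ValueError("new_terms and prior_terms must be disjoint")
    missing = [t for t in new_terms if t not in table]
    if missing:
        warnings.warn(
            f"{len(missing)} term(s) missing from the IA table contribute 0",
            stacklevel=2,
        )
    return table.weight(new_terms)
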