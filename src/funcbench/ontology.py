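"""Gene Ontology DAG handling: parsing, validation, ancestor closure.

The ontology is a directed acyclic graph in three aspects (MFO, BPO, CCO).
Annotations propagate upward: a protein annotated with a term is implicitly
annotated with every ancestor of that term reachable over the retained
relations.  Each aspect is kept as a self-contained DAG — edges crossing
aspects are dropped at parse time so propagation never leaks annotations
between aspects.
"""

from __future__ import annotations

import io
import warnings
from collections.abc import Iterable, Sequence
from typing import TextIO

import networkx as nx
import obonet

ASPECTS = ("MFO", "BPO", "CCO")

#: OBO namespace labels -> short aspect codes.
NAMESPACE_TO_ASPECT = {
    "molecular_function": "MFO",
    "biological_process": "BPO",
    "cellular_component": "CCO",
}
ASPECT_TO_NAMESPACE = {v: k for k, v in NAMESPACE_TO_ASPECT.items()}

#: GAF single-letter aspect column -> short aspect codes.
GAF_ASPECT = {"F": "MFO", "P": "BPO", "C": "CCO"}

#: Relations over which annotations propagate.
RELATIONS = frozenset(
    {"is_a", "part_of", "regulates", "negatively_regulates", "positively_regulates"}
)


class OntologyError(ValueError):
    """Structural problem in an ontology (cycle, bad namespace, empty graph)."""


class UnknownTermError(KeyError):
    """A term identifier could not be resolved in the frozen ontology."""

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message readable
        return self.args[0] if self.args else ""


class OntologyGraph:
    """Aspect-labelled GO DAG with typed child->parent edges.

    Parameters
    ----------
    graph:
        ``networkx.MultiDiGraph`` with edges directed child -> parent and the
        edge key naming the relation.  Every node must carry an ``aspect``
        attribute in :data:`ASPECTS`.
    alt_ids:
        Mapping of alternate/secondary identifiers to canonical identifiers.
    version_tag:
        Free-text version label (e.g. a release date); snapshots built on
        different versions refuse to be compared downstream.
    """

    def __init__(
        self,
        graph: nx.MultiDiGraph,
        alt_ids: dict[str, str] | None = None,
        version_tag: str = "",
    ) -> None:
        if graph.number_of_nodes() == 0:
            raise OntologyError("ontology has no terms")
        if not nx.is_directed_acyclic_graph(graph):
            cycle = nx.find_cycle(graph)
            raise OntologyError(f"ontology contains a cycle through {cycle[0][0]!r}")
        for term, data in graph.nodes(data=True):
            if data.get("aspect") not in ASPECTS:
                raise OntologyError(f"term {term!r} has unknown aspect {data.get('aspect')!r}")
        self._g = graph
        self.alt_ids: dict[str, str] = dict(alt_ids or {})
        self.version_tag = version_tag
        self._roots: dict[str, str] = {}
        self._disconnected: set[str] = set()
        self._find_roots()
        self._ancestor_cache: dict[str, frozenset[str]] = {}

    # ------------------------------------------------------------------ roots
    def _find_roots(self) -> None:
        for aspect in ASPECTS:
            sinks = [
                t
                for t, d in self._g.nodes(data=True)
                if d["aspect"] == aspect and self._g.out_degree(t) == 0
            ]
            if not sinks:
                continue
            if len(sinks) == 1:
                self._roots[aspect] = sinks[0]
                continue
            # Multiple sink nodes: the root is the sink reachable from the most
            # terms; the others are disconnected from their root.
            reach = {s: len(nx.ancestors(self._g, s)) for s in sinks}
            root = max(sorted(sinks), key=reach.__getitem__)
            self._roots[aspect] = root
            extras = [s for s in sinks if s != root]
            self._disconnected.update(extras)
            warnings.warn(
                f"aspect {aspect}: {len(extras)} non-root term(s) have no parent "
                f"(e.g. {extras[0]!r}); they are disconnected from root {root!r}",
                stacklevel=3,
            )

    # ------------------------------------------------------------- accessors
    @property
    def terms(self) -> frozenset[str]:
        return frozenset(self._g.nodes)

    @property
    def roots(self) -> dict[str, str]:
        """One root term per aspect present in the graph."""
        return dict(self._roots)

    @property
    def root_terms(self) -> frozenset[str]:
        return frozenset(self._roots.values())

    @property
    def nx_graph(self) -> nx.MultiDiGraph:
        return self._g

    def __contains__(self, term: str) -> bool:
        return term in self._g or term in self.alt_ids

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def resolve(self, term: str) -> str:
        """Map a (possibly alternate) identifier to its canonical term."""
        if term in self._g:
            return term
        if term in self.alt_ids:
            return self.alt_ids[term]
        raise UnknownTermError(f"unknown term {term!r}")

    def aspect(self, term: str) -> str:
        return self._g.nodes[self.resolve(term)]["aspect"]

    def is_root(self, term: str) -> bool:
        return self.resolve(term) in self.root_terms

    def parents(self, term: str) -> frozenset[str]:
        return frozenset(self._g.successors(self.resolve(term)))

    def children(self, term: str) -> frozenset[str]:
        return frozenset(self._g.predecessors(self.resolve(term)))

    def ancestors(self, term: str) -> frozenset[str]:
        """All terms reachable from ``term`` over retained relations (excl. itself)."""
        term = self.resolve(term)
        cached = self._ancestor_cache.get(term)
        if cached is None:
            cached = frozenset(nx.descendants(self._g, term))
            self._ancestor_cache[term] = cached
        return cached

    def descendants(self, term: str) -> frozenset[str]:
        return frozenset(nx.ancestors(self._g, self.resolve(term)))

    def aspect_terms(self, aspect: str) -> frozenset[str]:
        return frozenset(t for t, d in self._g.nodes(data=True) if d["aspect"] == aspect)

    def topological_order(self) -> list[str]:
        """Terms ordered children-before-parents (edges run child -> parent)."""
        return list(nx.topological_sort(self._g))

    def edges(self) -> list[tuple[str, str, str]]:
        """Sorted (child, parent, relation) triples."""
        return sorted(self._g.edges(keys=True))

    # ----------------------------------------------------------- propagation
    def propagate(self, terms: Iterable[str]) -> frozenset[str]:
        """Ancestor closure of ``terms``: the input plus every ancestor.

        Idempotent and monotone.  Unknown identifiers raise
        :class:`UnknownTermError` after alternate-id resolution.
        """
        out: set[str] = set()
        for t in terms:
            t = self.resolve(t)
            out.add(t)
            out.update(self.ancestors(t))
        return frozenset(out)

    def nonroot(self, terms: Iterable[str]) -> frozenset[str]:
        """Drop the aspect roots from a term collection."""
        return frozenset(terms) - self.root_terms

    # -------------------------------------------------------------------- io
    def write_obo(self, target: str | TextIO) -> None:
        """Serialize to minimal OBO 1.2 (terms, namespaces, typed parent links)."""
        handle = open(target, "w") if isinstance(target, str) else target
        try:
            handle.write("format-version: 1.2\n")
            if self.version_tag:
                handle.write(f"data-version: {self.version_tag}\n")
            alt_by_canonical: dict[str, list[str]] = {}
            for alt, canon in self.alt_ids.items():
                alt_by_canonical.setdefault(canon, []).append(alt)
            for term in sorted(self._g.nodes):
                data = self._g.nodes[term]
                handle.write("\n[Term]\n")
                handle.write(f"id: {term}\n")
                handle.write(f"name: {data.get('name', term)}\n")
                handle.write(f"namespace: {ASPECT_TO_NAMESPACE[data['aspect']]}\n")
                for alt in sorted(alt_by_canonical.get(term, [])):
                    handle.write(f"alt_id: {alt}\n")
                for _, parent, rel in sorted(self._g.out_edges(term, keys=True)):
                    if rel == "is_a":
                        handle.write(f"is_a: {parent}\n")
                    else:
                        handle.write(f"relationship: {rel} {parent}\n")
        finally:
            if isinstance(target, str):
                handle.close()

    def write_edge_list(self, target: str | TextIO) -> None:
        """Plain-text (child, parent, relation) export for debugging."""
        handle = open(target, "w") if isinstance(target, str) else target
        try:
            handle.write("child\tparent\trelation\n")
            for child, parent, rel in self.edges():
                handle.write(f"{child}\t{parent}\t{rel}\n")
        finally:
            if isinstance(target, str):
                handle.close()


def parse_obo(
    source: str | TextIO,
    relations: Iterable[str] = RELATIONS,
    version_tag: str | None = None,
) -> OntologyGraph:
    """Parse an OBO 1.2/1.4 file into an :class:`OntologyGraph`.

    Only edges whose relation is in ``relations`` are retained; edges whose
    endpoints lie in different aspects are dropped (per-aspect evaluation must
    not propagate across aspects).  Obsolete terms are absent.  Alternate-id
    mappings are kept for input normalization.
    """
    relations = frozenset(relations)
    unknown_rel = relations - RELATIONS
    if unknown_rel:
        raise ValueError(f"unknown relations: {sorted(unknown_rel)}")
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    import logging

    logging.disable(logging.WARNING)  # obonet logs about absent optional headers
    try:
        raw = obonet.read_obo(source, ignore_obsolete=True)
    finally:
        logging.disable(logging.NOTSET)
    if version_tag is None:
        version_tag = raw.graph.get("data-version", "") or ""

    g = nx.MultiDiGraph()
    alt_ids: dict[str, str] = {}
    for term, data in raw.nodes(data=True):
        ns = data.get("namespace")
        if ns not in NAMESPACE_TO_ASPECT:
            raise OntologyError(f"term {term!r}: unknown or missing namespace {ns!r}")
        g.add_node(term, aspect=NAMESPACE_TO_ASPECT[ns], name=data.get("name", term))
        for alt in data.get("alt_id", []):
            alt_ids[alt] = term
    n_cross = 0
    for child, parent, rel in raw.edges(keys=True):
        if rel not in relations:
            continue
        if parent not in g or child not in g:
            continue
        if g.nodes[child]["aspect"] != g.nodes[parent]["aspect"]:
            n_cross += 1
            continue
        g.add_edge(child, parent, key=rel)
    if n_cross:
        warnings.warn(f"dropped {n_cross} cross-aspect edge(s)", stacklevel=2)
    return OntologyGraph(g, alt_ids=alt_ids, version_tag=version_tag)


def propagate_terms(graph: OntologyGraph, terms: Iterable[str]) -> frozenset[str]:
    """Ancestor closure over the graph's retained relations (module-level alias)."""
    return graph.propagate(terms)


def common_subgraph(graphs: Sequence[OntologyGraph]) -> OntologyGraph:
    """Induced graph on the intersection of term sets across ontology versions.

    Edges are taken from the newest graph (the last element).  Terms that lose
    their path to the aspect root in the induced graph are removed; their
    identifiers are recorded on the result as ``dropped_disconnected``.
    """
    if len(graphs) < 2:
        raise ValueError("need at least two graphs")
    shared = set.intersection(*(set(g.terms) for g in graphs))
    if not shared:
        raise OntologyError("no terms common to all graphs")
    newest = graphs[-1]
    sub = nx.MultiDiGraph()
    for term in shared:
        sub.add_node(term, **newest.nx_graph.nodes[term])
    for child, parent, rel in newest.nx_graph.edges(keys=True):
        if child in shared and parent in shared:
            sub.add_edge(child, parent, key=rel)

    # Iteratively drop terms that no longer reach their aspect root.
    dropped: set[str] = set()
    roots = {a: r for a, r in newest.roots.items() if r in shared}
    while True:
        bad = [
            t
            for t in sub.nodes
            if t not in roots.values()
            and roots.get(sub.nodes[t]["aspect"]) not in nx.descendants(sub, t)
        ]
        if not bad:
            break
        dropped.update(bad)
        sub.remove_nodes_from(bad)
    if sub.number_of_nodes() == 0:
        raise OntologyError("common subgraph is empty after removing disconnected terms")
    alt_ids = {a: c for a, c in newest.alt_ids.items() if c in sub}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = OntologyGraph(sub, alt_ids=alt_ids, version_tag=f"common({newest.version_tag})")
    result.dropped_disconnected = frozenset(dropped)  # type: ignore[attr-defined]
    return result
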