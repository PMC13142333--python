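"""Annotation snapshots: reading, evidence/date filtering, propagation, growth.

A snapshot is the set of protein -> GO-term assignments known at one point in
time.  Prospective evaluation compares two snapshots built on the same frozen
ontology: the terms added between the submission deadline (t0) and the
evaluation date (te) are the ground truth, and the terms already present at
t0 determine the evaluation setting of each protein-aspect pair.
"""

from __future__ import annotations

import datetime as dt
import logging
import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from typing import TextIO

from Bio.UniProt import GOA

from .ontology import GAF_ASPECT, OntologyGraph, UnknownTermError

logger = logging.getLogger(__name__)

#: Default evidence filter: GO experimental, high-throughput and
#: curator/author-statement codes (standard CAFA practice; configurable).
EXPERIMENTAL_CODES = frozenset(
    {"EXP", "IDA", "IPI", "IMP", "IGI", "IEP",
     "HTP", "HDA", "HMP", "HGI", "HEP", "TAS", "IC"}
)

#: Known GO evidence-code vocabulary (used only to flag unknown codes).
KNOWN_CODES = EXPERIMENTAL_CODES | frozenset(
    {"ISS", "ISO", "ISA", "ISM", "IGC", "IBA", "IBD", "IKR", "IRD", "RCA",
     "NAS", "ND", "IEA"}
)

TSV_COLUMNS = ("protein", "term", "evidence", "reference", "reference_date", "assigned_date")


def parse_date(text: str) -> dt.date | None:
    """Parse ISO-8601 ``YYYY[-MM[-DD]]``; empty -> unknown (None).

    Partial dates are completed with the first month/day so that a
    strictly-after comparison is conservative.
    """
    text = text.strip()
    if not text:
        return None
    parts = text.split("-")
    if len(parts) > 3:
        raise ValueError(f"bad date {text!r}")
    year = int(parts[0])
    month = int(parts[1]) if len(parts) > 1 else 1
    day = int(parts[2]) if len(parts) > 2 else 1
    return dt.date(year, month, day)


@dataclass(frozen=True)
class AnnotationRecord:
    """One protein-term assignment with its provenance."""

    protein: str
    term: str
    evidence: str
    reference: str = ""
    reference_date: dt.date | None = None
    assigned_date: dt.date | None = None

    def __post_init__(self) -> None:
        if not self.protein or not self.term:
            raise ValueError("protein and term must be non-empty")

    @property
    def evidence_known(self) -> bool:
        return self.evidence in KNOWN_CODES


class AnnotationSet:
    """Ancestor-closed per-protein, per-aspect term sets on a frozen ontology.

    Built from records via :func:`read_annotations` or
    :meth:`from_records`; every term set is closed under the graph's retained
    relations, and every term sits in the bucket of its own aspect.
    """

    def __init__(
        self,
        data: Mapping[str, Mapping[str, frozenset[str]]],
        graph_version: str,
        snapshot_tag: str = "",
        provenance: tuple[AnnotationRecord, ...] = (),
    ) -> None:
        self._data: dict[str, dict[str, frozenset[str]]] = {
            p: {a: frozenset(ts) for a, ts in aspects.items() if ts}
            for p, aspects in data.items()
        }
        self._data = {p: aspects for p, aspects in self._data.items() if aspects}
        self.graph_version = graph_version
        self.snapshot_tag = snapshot_tag
        self.provenance = provenance

    # ------------------------------------------------------------- accessors
    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self._data)

    def terms(self, protein: str, aspect: str) -> frozenset[str]:
        return self._data.get(protein, {}).get(aspect, frozenset())

    def aspects_of(self, protein: str) -> frozenset[str]:
        return frozenset(self._data.get(protein, {}))

    def items(self) -> Iterable[tuple[str, str, frozenset[str]]]:
        for protein in sorted(self._data):
            for aspect in sorted(self._data[protein]):
                yield protein, aspect, self._data[protein][aspect]

    def annotated_aspects(self, protein: str, graph: OntologyGraph) -> frozenset[str]:
        """Aspects in which the protein carries at least one non-root term."""
        return frozenset(
            a for a in self.aspects_of(protein) if graph.nonroot(self.terms(protein, a))
        )

    def n_annotations(self, nonroot_of: OntologyGraph | None = None) -> int:
        """Total propagated term count (optionally excluding aspect roots)."""
        total = 0
        for _, _, ts in self.items():
            total += len(nonroot_of.nonroot(ts)) if nonroot_of else len(ts)
        return total

    def __len__(self) -> int:
        return len(self._data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSet):
            return NotImplemented
        return self._data == other._data and self.graph_version == other.graph_version

    # ---------------------------------------------------------- construction
    @classmethod
    def from_records(
        cls,
        records: Iterable[AnnotationRecord],
        graph: OntologyGraph,
        snapshot_tag: str = "",
        propagate: bool = True,
    ) -> "AnnotationSet":
        """Resolve, restrict to the graph, and close each aspect upward.

        Terms absent from the frozen ontology are discarded with a counted
        warning (they cannot participate in a frozen-graph evaluation).
        """
        records = tuple(records)
        data: dict[str, dict[str, set[str]]] = {}
        n_unknown = 0
        for rec in records:
            try:
                term = graph.resolve(rec.term)
            except UnknownTermError:
                n_unknown += 1
                continue
            aspect = graph.aspect(term)
            data.setdefault(rec.protein, {}).setdefault(aspect, set()).add(term)
        if n_unknown:
            warnings.warn(
                f"discarded {n_unknown} annotation(s) on terms absent from the ontology",
                stacklevel=3,
            )
        closed: dict[str, dict[str, frozenset[str]]] = {}
        for protein, aspects in data.items():
            closed[protein] = {}
            for aspect, ts in aspects.items():
                closed[protein][aspect] = graph.propagate(ts) if propagate else frozenset(ts)
        return cls(closed, graph.version_tag, snapshot_tag=snapshot_tag, provenance=records)


@dataclass
class GrowthSet:
    """Per protein-aspect annotation growth between two snapshots.

    ``entries[(protein, aspect)] = (prior, new)`` where ``prior`` is the t0
    closure and ``new`` the non-root terms present at te but not t0.  Pairs
    whose difference is empty carry no entry.
    """

    entries: dict[tuple[str, str], tuple[frozenset[str], frozenset[str]]]
    graph_version: str
    t0_tag: str = ""
    te_tag: str = ""

    def new_terms(self, protein: str, aspect: str) -> frozenset[str]:
        return self.entries.get((protein, aspect), (frozenset(), frozenset()))[1]

    def counts_by_aspect(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for (_, aspect), (_, new) in self.entries.items():
            out[aspect] = out.get(aspect, 0) + len(new)
        return out

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------- io


def _iter_tsv_records(handle: TextIO) -> Iterable[tuple[int, AnnotationRecord | None]]:
    for lineno, line in enumerate(handle, 1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            yield lineno, None
            continue
        parts += [""] * (6 - len(parts))
        try:
            yield lineno, AnnotationRecord(
                protein=parts[0],
                term=parts[1],
                evidence=parts[2],
                reference=parts[3],
                reference_date=parse_date(parts[4]),
                assigned_date=parse_date(parts[5]),
            )
        except (ValueError, IndexError):
            yield lineno, None


def _iter_gaf_records(handle: TextIO) -> Iterable[tuple[int, AnnotationRecord | None]]:
    # GAF has no publication date; the reference identifier is kept and the
    # date column (col 14) is the curator assignment date.
    for lineno, row in enumerate(GOA.gafiterator(handle), 1):
        try:
            assigned = None
            if row.get("Date"):
                d = row["Date"]
                assigned = dt.date(int(d[:4]), int(d[4:6]), int(d[6:8]))
            yield lineno, AnnotationRecord(
                protein=row["DB_Object_ID"],
                term=row["GO_ID"],
                evidence=row["Evidence"],
                reference=";".join(row.get("DB:Reference", [])),
                reference_date=None,
                assigned_date=assigned,
            )
        except (ValueError, KeyError, IndexError):
            yield lineno, None


def _sniff_gaf(handle: TextIO) -> bool:
    pos = handle.tell()
    try:
        for line in handle:
            if line.startswith("!"):
                return True
            if not line.strip() or line.startswith("#"):
                continue
            return len(line.rstrip("\n").split("\t")) >= 15
        return False
    finally:
        handle.seek(pos)


def read_annotations(
    source: str | TextIO,
    graph: OntologyGraph,
    evidence_filter: Iterable[str] = EXPERIMENTAL_CODES,
    min_reference_date: dt.date | str | None = None,
    snapshot_tag: str = "",
) -> AnnotationSet:
    """Read a GAF 2.x file or the 6-column TSV dialect into an AnnotationSet.

    TSV dialect (tab-separated, ``#`` comments): protein, term, evidence,
    reference, reference_date, assigned_date; ISO-8601 dates; empty = unknown.

    Records failing the evidence filter are dropped.  When
    ``min_reference_date`` is given, only records with a reference whose
    publication date is strictly after the boundary survive (records with no
    reference or no date are dropped) — the stringent "unpublished at t0"
    restriction.  Surviving terms are alternate-id-resolved, restricted to the
    frozen graph, and propagated per aspect.
    """
    evidence_filter = frozenset(evidence_filter)
    if not evidence_filter:
        raise ValueError("evidence_filter must be non-empty")
    if isinstance(min_reference_date, str):
        min_reference_date = parse_date(min_reference_date)

    close_handle = isinstance(source, str)
    handle = open(source) if isinstance(source, str) else source
    try:
        iterator = _iter_gaf_records(handle) if _sniff_gaf(handle) else _iter_tsv_records(handle)
        records: list[AnnotationRecord] = []
        n_rows = n_bad = n_evidence = n_date = 0
        for lineno, rec in iterator:
            n_rows += 1
            if rec is None:
                n_bad += 1
                logger.warning("skipping malformed annotation row %d", lineno)
                continue
            if rec.evidence not in evidence_filter:
                n_evidence += 1
                continue
            if min_reference_date is not None:
                if not rec.reference or rec.reference_date is None:
                    n_date += 1
                    continue
                if rec.reference_date <= min_reference_date:
                    n_date += 1
                    continue
            records.append(rec)
    finally:
        if close_handle:
            handle.close()

    if n_rows and n_bad == n_rows:
        raise ValueError("all annotation rows were malformed")
    logger.info(
        "read %d rows: %d malformed, %d failed evidence filter, %d failed date filter, %d kept",
        n_rows, n_bad, n_evidence, n_date, len(records),
    )
    return AnnotationSet.from_records(records, graph, snapshot_tag=snapshot_tag)


def write_annotations_tsv(records: Iterable[AnnotationRecord], target: str | TextIO) -> None:
    """Write records in the 6-column TSV dialect (dates ISO-8601, empty = unknown)."""
    handle = open(target, "w") if isinstance(target, str) else target
    try:
        handle.write("#" + "\t".join(TSV_COLUMNS) + "\n")
        for r in records:
            handle.write(
                "\t".join(
                    [
                        r.protein,
                        r.term,
                        r.evidence,
                        r.reference,
                        r.reference_date.isoformat() if r.reference_date else "",
                        r.assigned_date.isoformat() if r.assigned_date else "",
                    ]
                )
                + "\n"
            )
    finally:
        if isinstance(target, str):
            handle.close()


# ------------------------------------------------------------------- growth


def propagate_annotations(annos: AnnotationSet, graph: OntologyGraph) -> AnnotationSet:
    """Replace every protein-aspect term set by its ancestor closure (idempotent).

    Terms unknown to the graph are dropped with a counted warning.  Each
    aspect closes independently; no cross-aspect terms are introduced.
    """
    data: dict[str, dict[str, frozenset[str]]] = {}
    n_unknown = 0
    for protein, _, ts in annos.items():
        known: dict[str, set[str]] = {}
        for t in ts:
            try:
                canon = graph.resolve(t)
            except UnknownTermError:
                n_unknown += 1
                continue
            known.setdefault(graph.aspect(canon), set()).add(canon)
        bucket = data.setdefault(protein, {})
        for aspect, terms in known.items():
            merged = set(bucket.get(aspect, frozenset())) | set(graph.propagate(terms))
            bucket[aspect] = frozenset(merged)
    if n_unknown:
        warnings.warn(f"dropped {n_unknown} term(s) unknown to the graph", stacklevel=2)
    return AnnotationSet(
        data, graph.version_tag, snapshot_tag=annos.snapshot_tag, provenance=annos.provenance
    )


def snapshot_growth(t0: AnnotationSet, te: AnnotationSet, graph: OntologyGraph) -> GrowthSet:
    """New annotations per protein-aspect: ``te \\ t0``, aspect roots excluded.

    Both snapshots must be propagated on the same frozen graph version.
    Protein-aspect pairs that gained nothing carry no entry.
    """
    if t0.graph_version != te.graph_version:
        raise ValueError(
            f"snapshots built on different graphs: {t0.graph_version!r} vs {te.graph_version!r}"
        )
    entries: dict[tuple[str, str], tuple[frozenset[str], frozenset[str]]] = {}
    for protein, aspect, te_terms in te.items():
        prior = t0.terms(protein, aspect)
        new = graph.nonroot(te_terms - prior)
        if new:
            entries[(protein, aspect)] = (prior, new)
    return GrowthSet(entries, t0.graph_version, t0_tag=t0.snapshot_tag, te_tag=te.snapshot_tag)


# ------------------------------------------------------------ target filter


@dataclass
class ExclusionReport:
    """Per-reason exclusion bookkeeping from :func:`filter_targets`."""

    removed: list[str] = field(default_factory=list)
    merged: list[str] = field(default_factory=list)
    sequence_changed: list[str] = field(default_factory=list)
    missing_sequence: list[str] = field(default_factory=list)  # retained, flagged

    def counts(self) -> dict[str, int]:
        return {
            "removed": len(self.removed),
            "merged": len(self.merged),
            "sequence_changed": len(self.sequence_changed),
            "missing_sequence": len(self.missing_sequence),
        }


def filter_targets(
    targets: Iterable[str],
    t0_sequences: Mapping[str, str],
    te_sequences: Mapping[str, str],
    removed: Iterable[str] = (),
    merged: Iterable[str] = (),
) -> tuple[list[str], ExclusionReport]:
    """Exclude targets that were removed, merged, or whose sequence changed.

    Sequence comparison is exact string inequality between the two snapshots.
    A target missing from both sequence maps is retained but flagged.
    """
    removed = frozenset(removed)
    merged = frozenset(merged)
    report = ExclusionReport()
    kept: list[str] = []
    for t in targets:
        if t in removed:
            report.removed.append(t)
            continue
        if t in merged:
            report.merged.append(t)
            continue
        s0, s1 = t0_sequences.get(t), te_sequences.get(t)
        if s0 is not None and s1 is not None and s0 != s1:
            report.sequence_changed.append(t)
            continue
        if s0 is None and s1 is None:
            report.missing_sequence.append(t)
        kept.append(t)
    return kept, report
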