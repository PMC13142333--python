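"""Shared fixtures: the four-term toy ontology, its annotation corpus, and
small seeded synthetic worlds."""

from __future__ import annotations

import pytest

import funcbench as fb
from funcbench.synthetic import WorldParams, generate_world

TOY_OBO = """format-version: 1.2

[Term]
id: r
name: root
namespace: molecular_function

[Term]
id: a
name: a
namespace: molecular_function
is_a: r

[Term]
id: b
name: b
namespace: molecular_function
is_a: r

[Term]
id: c
name: c
namespace: molecular_function
is_a: a
"""


@pytest.fixture(scope="session")
def toy_graph() -> fb.OntologyGraph:
    """Root r with children a, b; c under a.  One aspect (MFO)."""
    return fb.parse_obo(TOY_OBO)


@pytest.fixture(scope="session")
def toy_corpus(toy_graph) -> fb.AnnotationSet:
    """P1:{r,a}, P2:{r,a,c}, P3:{r,b}, P4:{r} after propagation."""
    records = [
        fb.AnnotationRecord("P1", "a", "IDA"),
        fb.AnnotationRecord("P2", "c", "IDA"),
        fb.AnnotationRecord("P3", "b", "IMP"),
        fb.AnnotationRecord("P4", "r", "IDA"),
    ]
    return fb.AnnotationSet.from_records(records, toy_graph, snapshot_tag="toy-t0")


@pytest.fixture(scope="session")
def toy_ia(toy_graph, toy_corpus) -> fb.IATable:
    """ia(r)=0, ia(a)=1, ia(b)=2, ia(c)=1 bits on the toy corpus."""
    return fb.compute_ia(toy_corpus, toy_graph, log_base=2.0)


@pytest.fixture(scope="session")
def small_world() -> fb.SyntheticWorld:
    """Default-parameter synthetic world (200 proteins, 3 aspects)."""
    return generate_world(seed=7)


@pytest.fixture(scope="session")
def tiny_world() -> fb.SyntheticWorld:
    """Smaller world for repeated-evaluation tests."""
    params = WorldParams(terms_per_aspect=25, n_proteins=100)
    return generate_world(params, seed=11)
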