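"""Shared fixtures and independent oracles for the suite.

The oracles here deliberately re-derive results by brute force (explicit
graph reachability, exhaustive assignment enumeration, naive logical
saturation) so they share no code path with the implementation they check.
"""
from __future__ import annotations

import itertools
import random

import networkx as nx
import pytest

from termserve.fixtures import demo_fixture
from termserve.model import (
    CodeSystemRecord,
    ConceptEntry,
    Designation,
    TerminologyStore,
)


@pytest.fixture()
def demo_record() -> CodeSystemRecord:
    return demo_fixture()


@pytest.fixture()
def demo_store(demo_record) -> TerminologyStore:
    store = TerminologyStore()
    store.add(demo_record)
    return store


def random_dag_record(
    rng: random.Random,
    n: int,
    url: str = "http://example.org/dag",
    version: str = "1",
    max_parents: int = 3,
    n_refsets: int = 2,
    inactive_fraction: float = 0.0,
) -> CodeSystemRecord:
    """A random DAG code system built directly (no generator involvement).

    Node i draws parents among nodes < i, so acyclicity holds by
    construction.
    """
    record = CodeSystemRecord(url=url, version=version)
    codes = [str(100 + i) for i in range(n)]
    for i, code in enumerate(codes):
        parents = set()
        if i > 0:
            k = rng.randint(0, min(max_parents, i))
            parents = set(rng.sample(codes[:i], k))
        record.concepts[code] = ConceptEntry(
            code=code,
            active=(rng.random() >= inactive_fraction),
            designations=[Designation(value=f"concept {code}")],
            parents=parents,
        )
    for r in range(n_refsets):
        rid = f"rs{r}"
        record.refsets[rid] = {c for c in codes if rng.random() < 0.3}
    return record


def reachability_oracle(record: CodeSystemRecord, active_only: bool = True):
    """DFS-reachability pairs (ancestor, descendant) via networkx."""
    g = nx.DiGraph()
    codes = record.active_codes() if active_only else set(record.concepts)
    g.add_nodes_from(codes)
    for code in codes:
        for p in record.concepts[code].parents:
            if p in codes:
                g.add_edge(code, p)  # child -> parent
    return {
        (anc, desc)
        for desc in codes
        for anc in nx.descendants(g, desc)  # following child->parent edges
    }


def brute_force_mpm(prefixes, words):
    """Exhaustive injective-assignment enumeration of the ranking score.

    Returns the maximal sigma over complete injective assignments, or
    None when no assignment exists.
    """
    m, n = len(prefixes), len(words)
    if m == 0 or m > n:
        return None
    best = None
    for combo in itertools.permutations(range(n), m):
        if all(words[j].startswith(q) for q, j in zip(prefixes, combo)):
            s = sum(len(q) / len(words[j]) for q, j in zip(prefixes, combo)) / n
            if best is None or s > best:
                best = s
    return best
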