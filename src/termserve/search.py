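"""Autocomplete concept search: SBF baseline and multi-prefix matching.

Two autocompletion strategies over concept labels:

* **SBF** (standard breadth-first): the label must extend the typed string
  to the right — a whole-string prefix test.
* **MPM** (multi-prefix matching): every whitespace-delimited token of the
  query must be a prefix of some *distinct* word of the label. Matches are
  ranked by the score

      sigma = (1/n) * sum_i |q_i| / |F(q_i)|

  where ``q_1..q_m`` are the query prefixes, ``F`` assigns each prefix to
  the label word it matches, and ``n`` is the label's word count. The
  score rewards queries that cover more of more of the label's words, and
  is invariant under permutation of the query prefixes.

Requiring ``F`` to be injective (each prefix consumes a distinct word) is
what makes duplicated prefixes behave sensibly: "pne pne" matches
"pneumococcal pneumonia" but not "pneumonia". Among the injective complete
assignments the score-maximizing one is chosen, computed exactly as a
maximum-weight bipartite matching.
"""
from __future__ import annotations

import re
from bisect import bisect_left
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import linear_sum_assignment

from .model import CodeSystemRecord

_SPLIT_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase and split on runs of non-alphanumerics; drop empties."""
    return [w for w in _SPLIT_RE.split(text.lower()) if w]


@dataclass(frozen=True)
class SearchQuery:
    raw_text: str
    prefixes: tuple[str, ...]

    @classmethod
    def parse(cls, text: str) -> "SearchQuery":
        return cls(raw_text=text, prefixes=tuple(tokenize(text)))

    @property
    def m(self) -> int:
        return len(self.prefixes)


@dataclass(frozen=True)
class TokenizedLabel:
    label: str
    words: tuple[str, ...]

    @classmethod
    def parse(cls, label: str) -> "TokenizedLabel":
        return cls(label=label, words=tuple(tokenize(label)))

    @property
    def n(self) -> int:
        return len(self.words)


@dataclass(frozen=True)
class MatchAssignment:
    """An injective prefix-to-word assignment and its score."""

    mapping: tuple[int, ...]  # mapping[i] = index of the word assigned to q_i
    sigma: float


def _normalize(text: str) -> str:
    return " ".join(text.lower().split())


def sbf_match(query: str, label: str) -> bool:
    """Whole-string prefix match (case- and whitespace-normalized)."""
    return _normalize(label).startswith(_normalize(query))


def mpm_match(
    query: SearchQuery, label: TokenizedLabel
) -> Optional[MatchAssignment]:
    """Best injective assignment of query prefixes to label words, or None.

    Exact maximization of sigma via maximum-weight bipartite matching on
    the m x n matrix of prefix-coverage ratios (|q_i|/|w_j| where q_i is a
    prefix of w_j, -inf otherwise).
    """
    m, n = query.m, label.n
    if m == 0 or m > n:
        return None
    weights = np.full((m, n), -np.inf)
    for i, q in enumerate(query.prefixes):
        for j, w in enumerate(label.words):
            if w.startswith(q):
                weights[i, j] = len(q) / len(w)
    # any prefix with no matching word at all -> no complete assignment
    if not np.isfinite(weights).any(axis=1).all():
        return None
    # make infeasible cells finitely bad so the LP stays well-posed, then
    # reject solutions that used one
    feasible = np.isfinite(weights)
    filled = np.where(feasible, weights, -1e9)
    rows, cols = linear_sum_assignment(filled, maximize=True)
    if not feasible[rows, cols].all():
        return None
    sigma = float(weights[rows, cols].sum()) / n
    mapping = [0] * m
    for i, j in zip(rows, cols):
        mapping[i] = int(j)
    return MatchAssignment(mapping=tuple(mapping), sigma=sigma)


def rank(
    query: str, candidates: list[tuple[str, str]]
) -> list[tuple[str, str, float]]:
    """Rank (code, label) candidates by MPM score, descending.

    Ties break by fewer label words, then shorter label, then code
    ascending, so the output order is fully deterministic.
    """
    q = SearchQuery.parse(query)
    if q.m == 0:
        return []
    scored = []
    for code, label in candidates:
        tl = TokenizedLabel.parse(label)
        match = mpm_match(q, tl)
        if match is not None:
            scored.append((code, label, match.sigma, tl.n))
    scored.sort(key=lambda t: (-t[2], t[3], len(t[1]), t[0]))
    return [(code, label, sigma) for code, label, sigma, _ in scored]


class PrefixIndex:
    """Word-level prefix index over concept designations.

    A sorted table of (word, entry id) supports range scans per query
    prefix with :func:`bisect.bisect_left`; candidate entries are the
    intersection across prefixes, then scored exactly like a linear-scan
    ``rank``. One result per concept (its best-scoring designation).
    """

    def __init__(self, entries: list[tuple[str, str]]):
        # entries: (code, label) pairs, one per active designation
        self.entries = entries
        table = []
        for eid, (_, label) in enumerate(entries):
            for word in set(tokenize(label)):
                table.append((word, eid))
        table.sort()
        self._words = [w for w, _ in table]
        self._eids = [e for _, e in table]

    def _candidates(self, prefix: str) -> set[int]:
        lo = bisect_left(self._words, prefix)
        hi = bisect_left(self._words, prefix + "￿")
        return set(self._eids[lo:hi])

    def search(self, query: str, limit: Optional[int] = None):
        q = SearchQuery.parse(query)
        if q.m == 0:
            return []
        cand: Optional[set[int]] = None
        for prefix in set(q.prefixes):
            hits = self._candidates(prefix)
            cand = hits if cand is None else cand & hits
            if not cand:
                return []
        ranked = rank(query, [self.entries[eid] for eid in sorted(cand)])
        best: dict[str, tuple[str, str, float]] = {}
        order: list[str] = []
        for code, label, sigma in ranked:
            if code not in best:
                best[code] = (code, label, sigma)
                order.append(code)
        out = [best[c] for c in order]
        return out[:limit] if limit is not None else out


def build_prefix_index(
    cs: CodeSystemRecord, value_set_codes: Optional[set[str]] = None
) -> PrefixIndex:
    """Index the active designations of (optionally scoped) active concepts."""
    entries = []
    for code in sorted(cs.concepts):
        entry = cs.concepts[code]
        if not entry.active:
            continue
        if value_set_codes is not None and code not in value_set_codes:
            continue
        for d in entry.designations:
            if d.active:
                entries.append((code, d.value))
    return PrefixIndex(entries)
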