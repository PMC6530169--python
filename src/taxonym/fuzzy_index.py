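"""Character n-gram inverted index with ranked approximate lookup.

Retrieval is two-stage: a trigram-overlap pre-filter narrows the
dictionary to ``10 * k`` candidates, which are then rescored by
normalized Damerau-Levenshtein similarity; the top ``k`` are returned
with deterministic tie-breaking.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field

from ._distance import normalized_similarity
from .taxa_io import TaxonomyTable, TaxonRecord, TaxonomyError

PAD = "#"
INDEX_MAGIC = "taxonym-index"
INDEX_VERSION = 1

MIN_QUERY_LEN = 4  # anything shorter cannot be a binomial fragment


class IndexError_(ValueError):
    """Raised for invalid index construction or queries."""


@dataclass(frozen=True)
class CandidateMatch:
    record_id: str
    retrieval_score: float
    rank: int


@dataclass
class FuzzyIndex:
    """Immutable n-gram inverted index over a taxonomy's canonical names."""

    n: int
    postings: dict[str, dict[str, int]]  # gram -> {record_id: count}
    gram_counts: dict[str, int]  # record_id -> total grams
    table: TaxonomyTable = field(repr=False)


def ngrams(s: str, n: int) -> Counter[str]:
    """All length-``n`` substrings of *s* padded with one ``#`` per side."""
    if not s:
        raise IndexError_("empty string")
    if n < 2:
        raise IndexError_(f"n-gram size must be >= 2, got {n}")
    padded = PAD + s + PAD
    if n > len(padded):
        raise IndexError_(
            f"name too short for n-gram size: {s!r} (n={n})"
        )
    return Counter(padded[i : i + n] for i in range(len(padded) - n + 1))


def build_index(table: TaxonomyTable, n: int = 3) -> FuzzyIndex:
    """Index every record's canonical name; postings are never mutated after."""
    if len(table) == 0:
        raise IndexError_("cannot index an empty table")
    postings: dict[str, dict[str, int]] = {}
    gram_counts: dict[str, int] = {}
    for rec in table:
        grams = ngrams(rec.canonical_name, n)
        gram_counts[rec.record_id] = sum(grams.values())
        for g, c in grams.items():
            postings.setdefault(g, {})[rec.record_id] = c
    return FuzzyIndex(n=n, postings=postings, gram_counts=gram_counts, table=table)


def query_candidates(index: FuzzyIndex, q: str, k: int = 10) -> list[CandidateMatch]:
    """Top-``k`` records ranked by similarity to the normalized query *q*.

    Stage one keeps the ``10 * k`` records with the largest n-gram multiset
    overlap with *q*; stage two rescores those by
    ``1 - DL(q, name) / max(len)``.  Ties break on overlap, then canonical
    name, then record id, so identical inputs always give identical lists.
    """
    if not q or not q.strip():
        raise IndexError_("empty query")
    if len(q) < MIN_QUERY_LEN:
        raise IndexError_(f"query too short: {q!r} (minimum {MIN_QUERY_LEN} chars)")
    if k < 1:
        raise IndexError_(f"k must be >= 1, got {k}")
    qgrams = ngrams(q, index.n)
    overlap: dict[str, int] = {}
    for g, qc in qgrams.items():
        posting = index.postings.get(g)
        if not posting:
            continue
        for rid, rc in posting.items():
            overlap[rid] = overlap.get(rid, 0) + min(qc, rc)
    if not overlap:
        return []
    by_id = index.table.by_id
    prefilter = sorted(
        overlap.items(),
        key=lambda item: (-item[1], by_id[item[0]].canonical_name, item[0]),
    )[: 10 * k]
    scored = []
    for rid, ov in prefilter:
        name = by_id[rid].canonical_name
        sim = normalized_similarity(q, name)
        scored.append((-sim, -ov, name, rid, sim))
    scored.sort()
    return [
        CandidateMatch(record_id=rid, retrieval_score=sim, rank=i + 1)
        for i, (_, _, _, rid, sim) in enumerate(scored[:k])
    ]


def save_index(index: FuzzyIndex, path) -> None:
    """Persist the index as a versioned JSON artifact (reloadable byte-identically)."""
    payload = {
        "magic": INDEX_MAGIC,
        "version": INDEX_VERSION,
        "n": index.n,
        "records": [
            {
                "record_id": r.record_id,
                "name": r.raw_name,
                "canonical": r.canonical_name,
                "status": r.status,
                "accepted_id": r.accepted_id,
                "rank": r.rank,
                "kingdom": r.kingdom,
                "sources": sorted(r.sources),
            }
            for r in index.table
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, sort_keys=True, separators=(",", ":"))


def load_index(path) -> FuzzyIndex:
    """Reload an index artifact written by :func:`save_index`."""
    with open(path, "r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if payload.get("magic") != INDEX_MAGIC:
        raise IndexError_(f"{path}: not a taxonym index artifact")
    if payload.get("version") != INDEX_VERSION:
        raise IndexError_(
            f"{path}: unsupported index version {payload.get('version')!r}"
        )
    records = [
        TaxonRecord(
            record_id=r["record_id"],
            canonical_name=r["canonical"],
            raw_name=r["name"],
            status=r["status"],
            accepted_id=r["accepted_id"],
            rank=r["rank"],
            kingdom=r["kingdom"],
            sources=frozenset(r["sources"]),
        )
        for r in payload["records"]
    ]
    table = TaxonomyTable(records=records)
    return build_index(table, n=payload["n"])
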