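"""Sentence splitting, candidate span detection and mention annotation.

Candidate spans are found with a deterministic capitalization/shape
heuristic: a capitalized word (or single capital + period, the
abbreviated-genus form) followed by one or two lowercase words.  Spans
deliberately over-run the true name; the alignment stage's coverage
constraint trims and validates them.  Swap in a different chunker by
passing ``candidates_fn`` to :func:`annotate`.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Callable, Optional

from .alignment import AlignmentParams, DEFAULT_PARAMS, ResolutionResult, resolve_name
from .fuzzy_index import FuzzyIndex
from .taxa_io import TaxonomyError, TaxonomyTable, normalize_name

logger = logging.getLogger(__name__)

_SENT_END = re.compile(r"[.!?]+")
_WORD = re.compile(r"[A-Za-z]+")

_CAP = re.compile(r"^[A-Z][a-z]+$")
_LOWER = re.compile(r"^[a-z]+$")
_ABBREV = re.compile(r"^[A-Z]\.$")


@dataclass(frozen=True)
class Span:
    start: int  # 0-based, inclusive
    end: int  # exclusive
    text: str
    sentence_index: int


@dataclass(frozen=True)
class Mention:
    span: Span
    resolution: ResolutionResult


def split_sentences(text: str) -> list[Span]:
    """Non-overlapping sentence spans covering all non-whitespace content.

    Splits on sentence-final punctuation followed by whitespace and a
    capital letter, except when the punctuation terminates a single-letter
    abbreviation (protects abbreviated genus forms like ``Q. alba``).
    """
    if not text.strip():
        return []
    boundaries = []
    for m in _SENT_END.finditer(text):
        rest = text[m.end():]
        if not rest or not rest[0].isspace():
            continue
        stripped = rest.lstrip()
        if not stripped or not stripped[0].isupper():
            continue
        # the word immediately before the punctuation
        before = _WORD.findall(text[: m.start()][-40:])
        if before and len(before[-1]) == 1 and before[-1].isupper():
            continue  # single-letter abbreviation: not a sentence end
        boundaries.append(m.end())
    spans = []
    prev = 0
    for cut in boundaries + [len(text)]:
        chunk = text[prev:cut]
        lead = len(chunk) - len(chunk.lstrip())
        trail = len(chunk) - len(chunk.rstrip())
        start = prev + lead
        end = cut - trail
        if end > start:
            spans.append(Span(start, end, text[start:end], len(spans)))
        prev = cut
    return spans


def _tokens(text: str, offset: int = 0) -> list[tuple[int, int, str]]:
    """Letter-run tokens as (doc_start, doc_end, token); a single capital
    letter absorbs a directly following period (abbreviated genus)."""
    out = []
    for m in _WORD.finditer(text):
        s, e, tok = m.start(), m.end(), m.group()
        if len(tok) == 1 and tok.isupper() and e < len(text) and text[e] == ".":
            e += 1
            tok += "."
        out.append((s + offset, e + offset, tok))
    return out


def candidate_spans(sentence: Span, document: str) -> list[Span]:
    """Maximal non-overlapping spans shaped like species mentions.

    Head: capitalized alphabetic word or ``X.`` abbreviation; followers:
    one or two lowercase alphabetic words.  All-caps tokens never start
    or extend a span.
    """
    toks = _tokens(sentence.text, offset=sentence.start)
    spans = []
    i = 0
    while i < len(toks):
        s, e, tok = toks[i]
        if _CAP.match(tok) or _ABBREV.match(tok):
            j = i + 1
            while j < len(toks) and j - i <= 2 and _LOWER.match(toks[j][2]):
                j += 1
            if j > i + 1:
                end = toks[j - 1][1]
                spans.append(Span(s, end, document[s:end], sentence.sentence_index))
                i = j
                continue
        i += 1
    return spans


def _build_query(
    toks: list[tuple[int, int, str]],
    expansion: dict[str, str],
) -> Optional[tuple[str, list[tuple[int, int]]]]:
    """Lowercased query string plus per-character document offsets.

    Abbreviated heads are expanded via the genus map; every character of
    the expanded genus maps onto the abbreviation's document span.
    Returns None when an abbreviation has no known expansion.
    """
    parts: list[str] = []
    origins: list[tuple[int, int]] = []
    for idx, (s, e, tok) in enumerate(toks):
        if idx > 0:
            parts.append(" ")
            origins.append((toks[idx - 1][1], s))
        if _ABBREV.match(tok):
            genus = expansion.get(tok[0].lower())
            if genus is None:
                return None
            parts.append(genus)
            origins.extend([(s, e)] * len(genus))
        else:
            low = tok.lower()
            parts.append(low)
            origins.extend((s + p, s + p + 1) for p in range(len(low)))
    return "".join(parts), origins


def annotate(
    document: str,
    index: FuzzyIndex,
    table: TaxonomyTable,
    params: AlignmentParams = DEFAULT_PARAMS,
    expansion: Optional[dict[str, str]] = None,
    coverage_threshold: float = 0.8,
    k: int = 10,
    stop_list: Optional[set[str]] = None,
    candidates_fn: Callable[[Span, str], list[Span]] = candidate_spans,
) -> list[Mention]:
    """Find resolved species-level mentions in *document*.

    Each candidate span is resolved with :func:`resolve_name`; matches are
    trimmed to the locally aligned query region so offsets land on the
    name itself, not the over-run span.  A full-genus match fixes the
    expansion for later abbreviated mentions with the same initial.
    """
    genus_map: dict[str, str] = dict(expansion or {})
    stop = stop_list or set()
    mentions: list[Mention] = []
    for sentence in split_sentences(document):
        for span in candidates_fn(sentence, document):
            toks = _tokens(span.text, offset=span.start)
            built = _build_query(toks, genus_map)
            if built is None:
                logger.debug("no genus expansion for span %r", span.text)
                continue
            query, origins = built
            if query.split()[0] in stop:
                continue
            try:
                if normalize_name(query) != query:
                    logger.debug("span %r not alignable to offsets", span.text)
                    continue
                res = resolve_name(
                    index, table, query, params=params,
                    coverage_threshold=coverage_threshold, k=k,
                )
            except (TaxonomyError, ValueError):
                logger.debug("span %r not resolvable", span.text)
                continue
            if res.decision != "match":
                continue
            qs, qe = res.alignment.query_span
            start = origins[qs][0]
            end = origins[qe - 1][1]
            text = document[start:end]
            # trim incidental whitespace at the aligned edges
            lead = len(text) - len(text.lstrip())
            trail = len(text) - len(text.rstrip())
            start += lead
            end -= trail
            # snap to word boundaries: an edit at a token edge may push the
            # aligned region one character inside the word
            for ts, te, _tok in toks:
                if ts <= start < te:
                    start = ts
                if ts < end <= te:
                    end = te
            mention = Mention(
                Span(start, end, document[start:end], sentence.sentence_index),
                res,
            )
            mentions.append(mention)
            matched = table.by_id[res.matched_id]
            genus_map[matched.genus[0]] = matched.genus
    return _drop_overlaps(mentions)


def _drop_overlaps(mentions: list[Mention]) -> list[Mention]:
    """Keep the higher-alignment-score mention wherever spans overlap."""
    kept: list[Mention] = []
    for m in sorted(
        mentions,
        key=lambda m: (-m.resolution.alignment.score, m.span.start, m.span.end),
    ):
        if all(
            m.span.end <= o.span.start or m.span.start >= o.span.end for o in kept
        ):
            kept.append(m)
    kept.sort(key=lambda m: m.span.start)
    return kept
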