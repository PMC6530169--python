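"""Smith-Waterman rescoring, constraint filtering and the match decision.

Candidates from the fuzzy index are re-ranked by local alignment score
(linear gap penalties).  A candidate survives only if (1) the aligned
region covers strictly more than ``coverage_threshold`` of the record
name and (2) the first characters of the query's genus and epithet
tokens equal the record's; the surviving candidate with the maximum
alignment score becomes the match, otherwise the decision is no-match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .fuzzy_index import FuzzyIndex, query_candidates
from .taxa_io import TaxonomyTable, normalize_name, resolve_accepted


@dataclass(frozen=True)
class AlignmentParams:
    """Linear-gap scoring weights; comparison is on already-folded strings."""

    match_score: int = 2
    mismatch_penalty: int = -1
    gap_penalty: int = -1

    def __post_init__(self) -> None:
        if self.match_score <= 0:
            raise ValueError("match_score must be > 0")
        if self.mismatch_penalty > 0 or self.gap_penalty > 0:
            raise ValueError("penalties must be <= 0")


DEFAULT_PARAMS = AlignmentParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Best local alignment: score plus half-open spans on both strings."""

    score: int
    query_span: tuple[int, int]
    record_span: tuple[int, int]
    aligned_pairs: int


@dataclass(frozen=True)
class ConstraintFlags:
    coverage_ok: bool = False
    initials_ok: bool = False


@dataclass(frozen=True)
class ResolutionResult:
    query: str
    normalized_query: str
    matched_id: Optional[str]
    accepted_id: Optional[str]
    decision: str  # "match" | "no_match"
    alignment: Optional[AlignmentResult] = None
    coverage: Optional[float] = None
    constraints_passed: ConstraintFlags = field(default_factory=ConstraintFlags)


def smith_waterman(a: str, b: str, params: AlignmentParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Best-scoring local alignment of *a* (query) against *b* (record).

    When several cells tie for the maximum score the one with the smallest
    ``(end_row, end_col)`` is traced back; traceback prefers diagonal over
    vertical over horizontal moves, so results are deterministic.
    """
    if not a or not b:
        raise ValueError("smith_waterman requires non-empty strings")
    m, mm, g = params.match_score, params.mismatch_penalty, params.gap_penalty
    la, lb = len(a), len(b)
    H = [[0] * (lb + 1) for _ in range(la + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, la + 1):
        ai = a[i - 1]
        row = H[i]
        prev = H[i - 1]
        for j in range(1, lb + 1):
            diag = prev[j - 1] + (m if ai == b[j - 1] else mm)
            up = prev[j] + g
            left = row[j - 1] + g
            h = diag
            if up > h:
                h = up
            if left > h:
                h = left
            if h < 0:
                h = 0
            row[j] = h
            if h > best:  # strict: first maximum has smallest (i, j)
                best, bi, bj = h, i, j
    if best == 0:
        return AlignmentResult(0, (0, 0), (0, 0), 0)
    i, j = bi, bj
    pairs = 0
    while i > 0 and j > 0 and H[i][j] > 0:
        h = H[i][j]
        diag = H[i - 1][j - 1] + (m if a[i - 1] == b[j - 1] else mm)
        if h == diag:
            pairs += 1
            i -= 1
            j -= 1
        elif h == H[i - 1][j] + g:
            i -= 1
        else:
            j -= 1
    return AlignmentResult(best, (i, bi), (j, bj), pairs)


def record_coverage(aln: AlignmentResult, record_name: str) -> float:
    """Fraction of the record name spanned by the aligned region, in [0, 1]."""
    if aln.score == 0:
        return 0.0
    start, end = aln.record_span
    return (end - start) / len(record_name)


def initials_constraint(q: str, record_name: str) -> bool:
    """True iff the query's genus and epithet initials match the record's."""
    q_tokens = q.split()
    r_tokens = record_name.split()
    if len(q_tokens) < 2 or len(r_tokens) < 2:
        return False
    return q_tokens[0][0] == r_tokens[0][0] and q_tokens[1][0] == r_tokens[1][0]


def resolve_name(
    index: FuzzyIndex,
    table: TaxonomyTable,
    raw_query: str,
    params: AlignmentParams = DEFAULT_PARAMS,
    coverage_threshold: float = 0.8,
    k: int = 10,
    min_score: Optional[int] = None,
) -> ResolutionResult:
    """Run the full pipeline on a raw query string.

    Normalizes the query, retrieves the top-``k`` candidates, aligns the
    query against each candidate name, drops candidates failing the
    coverage (strictly greater than ``coverage_threshold``) or initials
    constraints, and returns the surviving candidate with the maximum
    alignment score (ties: higher retrieval score, then lexicographic
    name) as a match; otherwise no-match.
    """
    nq = normalize_name(raw_query)
    candidates = query_candidates(index, nq, k=k)
    survivors = []
    best_failed = None  # diagnostics for no-match results
    for cand in candidates:
        rec = table.by_id[cand.record_id]
        aln = smith_waterman(nq, rec.canonical_name, params)
        cov = record_coverage(aln, rec.canonical_name)
        flags = ConstraintFlags(
            coverage_ok=cov > coverage_threshold,
            initials_ok=initials_constraint(nq, rec.canonical_name),
        )
        if min_score is not None and aln.score < min_score:
            continue
        entry = (aln, cov, flags, cand, rec)
        if flags.coverage_ok and flags.initials_ok:
            survivors.append(entry)
        elif best_failed is None or aln.score > best_failed[0].score:
            best_failed = entry
    if survivors:
        aln, cov, flags, cand, rec = min(
            survivors,
            key=lambda e: (-e[0].score, -e[3].retrieval_score, e[4].canonical_name, e[4].record_id),
        )
        accepted = resolve_accepted(table, rec.record_id)
        return ResolutionResult(
            query=raw_query,
            normalized_query=nq,
            matched_id=rec.record_id,
            accepted_id=accepted.record_id,
            decision="match",
            alignment=aln,
            coverage=cov,
            constraints_passed=flags,
        )
    if best_failed is not None:
        aln, cov, flags, _, _ = best_failed
        return ResolutionResult(
            query=raw_query,
            normalized_query=nq,
            matched_id=None,
            accepted_id=None,
            decision="no_match",
            alignment=aln,
            coverage=cov,
            constraints_passed=flags,
        )
    return ResolutionResult(
        query=raw_query,
        normalized_query=nq,
        matched_id=None,
        accepted_id=None,
        decision="no_match",
    )
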