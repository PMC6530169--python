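"""Taxonomic dictionary I/O, name normalization and synonym resolution.

The dictionary is a TSV table with header columns
``record_id, name, status, accepted_id, rank, kingdom, sources``.
Rows are validated into :class:`TaxonRecord` objects; names are normalized
to lowercase two-token binomials with authorities and hybrid markers
stripped.  Only species-rank rows are kept.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "record_id",
    "name",
    "status",
    "accepted_id",
    "rank",
    "kingdom",
    "sources",
)

#: infraspecific rank / cultivar markers that begin an authority tail
_RANK_MARKERS = frozenset({"var", "subsp", "ssp", "f", "cv"})

_WS = re.compile(r"\s+")
_BINOMIAL = re.compile(r"^[a-z]+ [a-z]+$")


class TaxonomyError(ValueError):
    """Raised for malformed dictionaries or invalid name strings."""


@dataclass(frozen=True)
class TaxonRecord:
    """One dictionary entry.

    ``accepted_id`` equals ``record_id`` for accepted names and points at
    the accepted record for synonyms (single hop only).
    """

    record_id: str
    canonical_name: str
    raw_name: str
    status: str  # "accepted" | "synonym"
    accepted_id: str
    rank: str = "species"
    kingdom: str = "plantae"
    sources: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.status not in ("accepted", "synonym"):
            raise TaxonomyError(
                f"record {self.record_id!r}: invalid status {self.status!r}"
            )
        if self.status == "accepted" and self.accepted_id != self.record_id:
            raise TaxonomyError(
                f"accepted record {self.record_id!r} must have "
                f"accepted_id == record_id (got {self.accepted_id!r})"
            )
        if not _BINOMIAL.match(self.canonical_name):
            raise TaxonomyError(
                f"record {self.record_id!r}: canonical name "
                f"{self.canonical_name!r} is not a two-token binomial"
            )

    @property
    def genus(self) -> str:
        return self.canonical_name.split(" ", 1)[0]

    @property
    def epithet(self) -> str:
        return self.canonical_name.split(" ", 1)[1]


@dataclass
class TaxonomyTable:
    """Ordered collection of validated records with id lookup."""

    records: list[TaxonRecord]
    by_id: dict[str, TaxonRecord] = field(default_factory=dict)
    n_rejected: int = 0

    def __post_init__(self) -> None:
        if not self.by_id:
            self.by_id = {r.record_id: r for r in self.records}
        self._validate()

    def _validate(self) -> None:
        if len(self.by_id) != len(self.records):
            seen: set[str] = set()
            for r in self.records:
                if r.record_id in seen:
                    raise TaxonomyError(f"duplicate record_id {r.record_id!r}")
                seen.add(r.record_id)
        for r in self.records:
            if r.status == "synonym":
                target = self.by_id.get(r.accepted_id)
                if target is None:
                    raise TaxonomyError(
                        f"synonym {r.record_id!r} points at missing "
                        f"accepted_id {r.accepted_id!r}"
                    )
                if target.status != "accepted":
                    raise TaxonomyError(
                        f"synonym {r.record_id!r} points at non-accepted "
                        f"record {r.accepted_id!r} (chains must be flattened)"
                    )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[TaxonRecord]:
        return iter(self.records)


def normalize_name(raw: str) -> str:
    """Normalize a name string to lowercase space-separated tokens.

    Hybrid signs are removed; the tail of the token list is cut at the
    first authority-like token (contains ``.``, has an uppercase letter
    past its first character, or is an infraspecific rank marker with
    tokens following it).  Authorities are stripped, never matched.
    """
    if raw is None or not raw.strip():
        raise TaxonomyError("no name content")
    text = raw.replace("×", " ")  # hybrid sign ×
    tokens = [t for t in _WS.split(text.strip()) if t]
    out: list[str] = []
    for i, tok in enumerate(tokens):
        if tok in ("x", "X") and len(tokens) > 1:  # hybrid marker "x "
            continue
        if "." in tok:
            break
        if any(c.isupper() for c in tok[1:]):
            break
        if tok.lower() in _RANK_MARKERS and i < len(tokens) - 1:
            break
        out.append(tok.lower())
    if not out:
        raise TaxonomyError("no name content")
    return " ".join(out)


def is_binomial(name: str) -> bool:
    """True iff *name* is a normalized two-token alphabetic binomial."""
    return bool(_BINOMIAL.match(name))


def load_taxonomy(path, delimiter: str = "\t") -> TaxonomyTable:
    """Read a dictionary table, validate rows and build a :class:`TaxonomyTable`.

    Rows that are not species rank or whose normalized name is not a
    two-token binomial are excluded with a logged warning; the exclusion
    count is reported on ``TaxonomyTable.n_rejected``.  Duplicate ids and
    dangling or chained synonyms are hard errors.
    """
    records: list[TaxonRecord] = []
    seen_ids: set[str] = set()
    n_rejected = 0
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise TaxonomyError(f"{path}: empty file")
        missing = [c for c in REQUIRED_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise TaxonomyError(f"{path}: missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            rid = (row["record_id"] or "").strip()
            if not rid:
                raise TaxonomyError(f"{path}:{lineno}: empty record_id")
            if rid in seen_ids:
                raise TaxonomyError(f"duplicate record_id {rid!r}")
            seen_ids.add(rid)
            rank = (row["rank"] or "").strip().lower()
            if rank != "species":
                logger.warning("%s:%d: rank %r not supported; row excluded",
                               path, lineno, rank)
                n_rejected += 1
                continue
            raw_name = (row["name"] or "").strip()
            try:
                canonical = normalize_name(raw_name)
            except TaxonomyError:
                canonical = ""
            if not is_binomial(canonical):
                logger.warning("%s:%d: name %r does not normalize to a "
                               "binomial; row excluded", path, lineno, raw_name)
                n_rejected += 1
                continue
            status = (row["status"] or "").strip().lower()
            accepted_id = (row["accepted_id"] or "").strip()
            if status == "accepted" and not accepted_id:
                accepted_id = rid
            sources = frozenset(
                s.strip() for s in (row["sources"] or "").split(",") if s.strip()
            )
            records.append(
                TaxonRecord(
                    record_id=rid,
                    canonical_name=canonical,
                    raw_name=raw_name,
                    status=status,
                    accepted_id=accepted_id,
                    rank=rank,
                    kingdom=(row["kingdom"] or "").strip().lower(),
                    sources=sources,
                )
            )
    table = TaxonomyTable(records=records, n_rejected=n_rejected)
    return table


def write_taxonomy(table: TaxonomyTable, path, delimiter: str = "\t") -> None:
    """Write a table back to TSV (round-trips through :func:`load_taxonomy`)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter, lineterminator="\n")
        writer.writerow(REQUIRED_COLUMNS)
        for r in table:
            writer.writerow(
                [
                    r.record_id,
                    r.raw_name,
                    r.status,
                    r.accepted_id,
                    r.rank,
                    r.kingdom,
                    ",".join(sorted(r.sources)),
                ]
            )


def resolve_accepted(table: TaxonomyTable, record_id: str) -> TaxonRecord:
    """Follow ``accepted_id`` exactly once to reach the accepted record."""
    try:
        rec = table.by_id[record_id]
    except KeyError:
        raise TaxonomyError(f"unknown record_id {record_id!r}") from None
    if rec.status == "accepted":
        return rec
    return table.by_id[rec.accepted_id]
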