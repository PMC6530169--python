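"""Seeded generators: taxonomies, misspelled queries, planted-mention docs.

Everything is driven by a single ``random.Random(seed)`` per call, so the
same seed always yields byte-identical output regardless of platform.
Names are pronounceable latinate strings built from consonant/vowel
syllables (seed-stable, no Markov chains).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from ._distance import damerau_levenshtein
from .taxa_io import TaxonRecord, TaxonomyTable

_CONSONANTS = "bcdfglmnprstvz"
_VOWELS = "aeiou"
_ALPHABET = "abcdefghijklmnopqrstuvwxyz"

EDIT_KINDS = ("substitution", "deletion", "insertion", "transposition")


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class TypoModel:
    """How to corrupt a name: number of edits and edit-kind probabilities."""

    n_edits: int = 1
    edit_weights: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    alphabet: str = _ALPHABET
    protect_first_chars: bool = True

    def __post_init__(self) -> None:
        if self.n_edits < 0:
            raise SyntheticError("n_edits must be >= 0")
        if abs(sum(self.edit_weights) - 1.0) > 1e-9:
            raise SyntheticError("edit_weights must sum to 1")


@dataclass(frozen=True)
class BenchmarkItem:
    query: str
    gold_id: Optional[str]  # accepted record_id, or None for distractors


@dataclass
class BenchmarkSet:
    items: list[BenchmarkItem]
    seed: int
    provenance: dict = field(default_factory=dict)


def _syllable(rng: random.Random) -> str:
    return rng.choice(_CONSONANTS) + rng.choice(_VOWELS)


def _latinate(rng: random.Random, lo: int, hi: int) -> str:
    """Alternating consonant/vowel word with length in [lo, hi]."""
    target = rng.randint(lo, hi)
    word = ""
    while len(word) < target:
        word += _syllable(rng)
    if len(word) > target:
        word = word[:target]
    return word


def _fresh(rng: random.Random, lo: int, hi: int, used: set[str], what: str) -> str:
    for _ in range(1000):
        w = _latinate(rng, lo, hi)
        if w not in used:
            used.add(w)
            return w
    raise SyntheticError(f"requested count exceeds unique-name capacity ({what})")


def generate_taxonomy(
    n_genera: int,
    species_per_genus: int,
    synonym_fraction: float = 0.0,
    seed: int = 0,
) -> TaxonomyTable:
    """Synthetic dictionary: unique binomials plus optional synonym records.

    The synonym count is ``round(synonym_fraction * n_accepted)``; each
    synonym is a fresh binomial pointing at a uniformly chosen accepted
    record.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise SyntheticError("n_genera and species_per_genus must be >= 1")
    if not 0 <= synonym_fraction < 1:
        raise SyntheticError("synonym_fraction must be in [0, 1)")
    rng = random.Random(seed)
    genera: set[str] = set()
    binomials: set[str] = set()
    records: list[TaxonRecord] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"t{counter:06d}"

    for _ in range(n_genera):
        genus = _fresh(rng, 6, 10, genera, "genus")
        epithets: set[str] = set()
        for _ in range(species_per_genus):
            epithet = _fresh(rng, 4, 9, epithets, "epithet")
            name = f"{genus} {epithet}"
            if name in binomials:
                raise SyntheticError("requested count exceeds unique-name capacity")
            binomials.add(name)
            rid = next_id()
            records.append(
                TaxonRecord(
                    record_id=rid,
                    canonical_name=name,
                    raw_name=name,
                    status="accepted",
                    accepted_id=rid,
                    kingdom="plantae",
                    sources=frozenset({"synthetic"}),
                )
            )
    n_accepted = len(records)
    n_syn = round(synonym_fraction * n_accepted)
    accepted = list(records)
    for _ in range(n_syn):
        target = rng.choice(accepted)
        genus = _fresh(rng, 6, 10, genera, "genus")
        epithet = _latinate(rng, 4, 9)
        name = f"{genus} {epithet}"
        if name in binomials:
            epithet = _fresh(rng, 4, 9, {t.split()[1] for t in binomials}, "epithet")
            name = f"{genus} {epithet}"
        binomials.add(name)
        records.append(
            TaxonRecord(
                record_id=next_id(),
                canonical_name=name,
                raw_name=name,
                status="synonym",
                accepted_id=target.record_id,
                kingdom="plantae",
                sources=frozenset({"synthetic"}),
            )
        )
    return TaxonomyTable(records=records)


def _eligible_positions(name: str, protect: bool) -> list[int]:
    """Letter indices open to substitution/deletion."""
    positions = []
    for i, c in enumerate(name):
        if c == " ":
            continue  # never break the binomial separator
        if protect and (i == 0 or name[i - 1] == " "):
            continue
        positions.append(i)
    return positions


def _apply_edit(name: str, kind: str, rng: random.Random, model: TypoModel) -> Optional[str]:
    protect = model.protect_first_chars
    if kind == "substitution":
        pos = _eligible_positions(name, protect)
        if not pos:
            return None
        i = rng.choice(pos)
        c = rng.choice([x for x in model.alphabet if x != name[i]])
        return name[:i] + c + name[i + 1 :]
    if kind == "deletion":
        pos = _eligible_positions(name, protect)
        if not pos:
            return None
        i = rng.choice(pos)
        return name[:i] + name[i + 1 :]
    if kind == "insertion":
        # insertion before index i; i == len means append
        if protect:
            pos = [i for i in range(1, len(name) + 1) if name[i - 1] != " "]
        else:
            pos = list(range(len(name) + 1))
        if not pos:
            return None
        i = rng.choice(pos)
        return name[:i] + rng.choice(model.alphabet) + name[i:]
    if kind == "transposition":
        pos = [
            i
            for i in _eligible_positions(name, protect)
            if i + 1 < len(name)
            and name[i + 1] != " "
            and name[i] != name[i + 1]
        ]
        if not pos:
            return None
        i = rng.choice(pos)
        return name[:i] + name[i + 1] + name[i] + name[i + 2 :]
    raise SyntheticError(f"unknown edit kind {kind!r}")


def corrupt(name: str, model: TypoModel, seed: int = 0) -> str:
    """Apply exactly ``model.n_edits`` random edits to a binomial.

    With ``protect_first_chars`` token-initial characters are never
    touched (so the resolver's initials constraint stays satisfiable).
    Redraws until the result sits at edit distance exactly ``n_edits``
    from the input (edits can otherwise cancel or, with transpositions,
    compound); gives up after 100 attempts.
    """
    if len(name) < 4:
        raise SyntheticError(f"name too short to corrupt: {name!r}")
    if model.n_edits >= len(name) / 2:
        raise SyntheticError("n_edits must be < len(name)/2")
    if model.n_edits == 0:
        return name
    rng = random.Random(seed)
    for _ in range(100):
        out = name
        ok = True
        for _ in range(model.n_edits):
            kind = rng.choices(EDIT_KINDS, weights=model.edit_weights, k=1)[0]
            edited = _apply_edit(out, kind, rng, model)
            if edited is None:
                ok = False
                break
            out = edited
        if ok and out != name and damerau_levenshtein(out, name) == model.n_edits:
            return out
    raise SyntheticError(f"could not produce a distinct corruption of {name!r}")


def make_benchmark(
    table: TaxonomyTable,
    n_queries: int,
    model: TypoModel,
    distractor_fraction: float = 0.0,
    seed: int = 0,
) -> BenchmarkSet:
    """Corrupted queries paired with gold accepted ids; a fixed fraction of
    items are fresh names absent from the table (gold None)."""
    if len(table) == 0:
        raise SyntheticError("table is empty")
    rng = random.Random(seed)
    n_distract = round(distractor_fraction * n_queries)
    known = {r.canonical_name for r in table}
    items: list[BenchmarkItem] = []
    distractor_slots = set(rng.sample(range(n_queries), n_distract))
    genera_used: set[str] = set()
    for i in range(n_queries):
        if i in distractor_slots:
            for _ in range(1000):
                g = _latinate(rng, 6, 10)
                e = _latinate(rng, 4, 9)
                name = f"{g} {e}"
                if name not in known:
                    break
            else:
                raise SyntheticError("could not draw a distractor name")
            items.append(BenchmarkItem(query=name, gold_id=None))
        else:
            rec = table.records[rng.randrange(len(table.records))]
            q = corrupt(rec.canonical_name, model, seed=rng.randrange(2**31))
            accepted = rec.accepted_id
            items.append(BenchmarkItem(query=q, gold_id=accepted))
    return BenchmarkSet(
        items=items,
        seed=seed,
        provenance={
            "n_queries": n_queries,
            "n_edits": model.n_edits,
            "distractor_fraction": distractor_fraction,
        },
    )


_FILLER_SENT_WORDS = (4, 8)


def make_documents(
    table: TaxonomyTable,
    n_docs: int,
    mentions_per_doc: int = 2,
    model: Optional[TypoModel] = None,
    seed: int = 0,
) -> list[tuple[str, list[tuple[int, int, str]]]]:
    """Documents of filler prose with planted capitalized binomials.

    Returns ``(text, [(start, end, record_id), ...])`` per document;
    offsets are 0-based half-open on the text.  When *model* is given the
    planted surface form is a corruption of the dictionary name.
    """
    rng = random.Random(seed)
    docs = []
    for _ in range(n_docs):
        planted: list[tuple[int, int, str]] = []
        sentences: list[str] = []
        offset = 0
        n_sent = mentions_per_doc + rng.randint(1, 2)
        plant_in = set(rng.sample(range(n_sent), mentions_per_doc))
        for si in range(n_sent):
            n_words = rng.randint(*_FILLER_SENT_WORDS)
            words = [_latinate(rng, 3, 7) for _ in range(n_words)]
            words[0] = words[0].capitalize()
            if si in plant_in:
                rec = table.records[rng.randrange(len(table.records))]
                surface = rec.canonical_name
                if model is not None and model.n_edits > 0:
                    surface = corrupt(surface, model, seed=rng.randrange(2**31))
                surface = surface[0].upper() + surface[1:]
                # insert past the sentence head + its possible followers
                at = rng.randint(3, max(3, n_words - 1))
                prefix = " ".join(words[:at])
                start = offset + len(prefix) + 1
                planted.append((start, start + len(surface), rec.record_id))
                words = words[:at] + [surface] + words[at:]
            sent = " ".join(words) + "."
            sentences.append(sent)
            offset += len(sent) + 1
        docs.append((" ".join(sentences), planted))
    return docs
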