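# taxonym

Resolve (possibly misspelled) plant species name strings to accepted
taxonomic names, and annotate species-level mentions (*Genus species*) in
free text.

The resolver works in two stages over a taxonomic dictionary of accepted
names and synonyms:

1. **Fuzzy candidate retrieval** — a character-trigram inverted index
   pre-filters the dictionary by n-gram overlap, then rescores by
   normalized Damerau-Levenshtein similarity and keeps the top 10
   candidates.
2. **Smith-Waterman rescoring** — each candidate is locally aligned
   against the query (linear gaps; match +2, mismatch −1, gap −1 by
   default). A candidate survives only if the aligned region covers
   strictly more than 80% of the record name and the first characters of
   the query's genus and epithet match the record's. The surviving
   candidate with the maximum alignment score is the match; otherwise the
   decision is no-match. Synonym hits are resolved to their accepted name.

For text annotation, documents are sentence-tokenized (single-letter
abbreviations such as `Q. alba` are protected), candidate spans are
proposed by a capitalization-shape heuristic (capitalized word or
abbreviated genus followed by one or two lowercase words; all-caps tokens
excluded), and each span is run through the resolver — the alignment
trims over-run spans to the mention itself. Abbreviated genera are
expanded from the most recent matching full-genus mention.

A seeded synthetic module generates dictionaries, misspelled query
benchmarks and planted-mention documents, so the whole pipeline is
testable without any external downloads. The evaluation module scores
resolution output as TRUE / FALSE / NOT FOUND with precision
(TRUE/(TRUE+FALSE)), recall (TRUE/TOTAL) and F-score.

## CLI

```sh
# generate a synthetic dictionary, a 1-edit misspelling benchmark and docs
taxonym simulate --n-genera 100 --species-per-genus 10 --synonym-fraction 0.1 \
    --seed 1 --out-dictionary dict.tsv \
    --queries 500 --n-edits 1 --out-queries queries.tsv \
    --docs 20 --out-docs docs.jsonl

# build a reusable index artifact
taxonym build-index dict.tsv --out index.json

# resolve names (one per line; TSV to stdout or --out)
taxonym resolve queries.tsv --index index.json --out results.tsv

# score against gold (query TAB gold_id)
taxonym evaluate results.tsv queries.tsv --dictionary dict.tsv --json-out metrics.json

# annotate text documents (plain files and/or JSON-lines {id, text})
taxonym annotate abstract.txt --dictionary dict.tsv
taxonym annotate --jsonl docs.jsonl --index index.json --out mentions.jsonl
```

Dictionary format: UTF-8 TSV with header
`record_id  name  status  accepted_id  rank  kingdom  sources`, where
`status` is `accepted` or `synonym`, synonyms point at an accepted
`accepted_id` (one hop only), and only `rank=species` rows are kept.

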