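import pytest
from hypothesis import given, settings, strategies as st

from taxonym import (
    build_index,
    generate_taxonomy,
    load_index,
    ngrams,
    query_candidates,
    save_index,
)
from taxonym._distance import damerau_levenshtein, normalized_similarity
from taxonym.fuzzy_index import IndexError_

from _oracles import dl_oracle

words = st.text(alphabet="abcdefghijklmnopqrstuvwxyz ", min_size=0, max_size=20)


class TestDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("abc", "abc", 0),
            ("abc", "abd", 1),
            ("abc", "acb", 1),  # transposition
            ("abc", "ab", 1),
            ("", "abc", 3),
            ("kitten", "sitting", 3),
        ],
    )
    def test_known(self, a, b, expected):
        assert damerau_levenshtein(a, b) == expected

    @given(words, words)
    @settings(max_examples=300)
    def test_matches_independent_oracle(self, a, b):
        assert damerau_levenshtein(a, b) == dl_oracle(a, b)

    @given(words, words)
    def test_symmetry_and_identity(self, a, b):
        assert damerau_levenshtein(a, b) == damerau_levenshtein(b, a)
        assert (damerau_levenshtein(a, b) == 0) == (a == b)

    @given(words, words)
    def test_similarity_bounds(self, a, b):
        sim = normalized_similarity(a, b)
        assert 0.0 <= sim <= 1.0
        assert (sim == 1.0) == (a == b)


class TestNgrams:
    def test_alba(self):
        assert ngrams("alba", 3) == {"#al": 1, "alb": 1, "lba": 1, "ba#": 1}

    def test_short_string(self):
        assert ngrams("aa", 3) == {"#aa": 1, "aa#": 1}

    def test_binomial_count(self):
        # padded "#quercus alba#" has 14 chars -> 14 - 3 + 1 = 12 grams
        grams = ngrams("quercus alba", 3)
        assert sum(grams.values()) == 12

    @given(st.text(alphabet="abc ", min_size=1, max_size=15),
           st.integers(min_value=2, max_value=5))
    def test_count_formula(self, s, n):
        padded_len = len(s) + 2
        if n > padded_len:
            with pytest.raises(IndexError_, match="too short"):
                ngrams(s, n)
        else:
            assert sum(ngrams(s, n).values()) == padded_len - n + 1

    def test_too_short_error(self):
        with pytest.raises(IndexError_, match="too short"):
            ngrams("a", 4)


class TestBuildIndex:
    def test_single_record(self, make_record):
        from taxonym import TaxonomyTable

        table = TaxonomyTable(records=[make_record("a1", "poa annua")])
        idx = build_index(table, n=3)
        for gram, posting in idx.postings.items():
            assert set(posting) == {"a1"}
        assert set(idx.gram_counts) == {"a1"}

    def test_shared_genus_grams(self, oak_index):
        assert set(idx_ids := oak_index.postings["que"]) >= {"ub1", "ub2"}

    def test_empty_table_error(self):
        from taxonym import TaxonomyTable

        with pytest.raises(IndexError_, match="empty"):
            build_index(TaxonomyTable(records=[]), n=3)

    def test_posting_mass_conservation(self):
        table = generate_taxonomy(100, 10, 0.0, seed=11)
        idx = build_index(table, n=3)
        total_postings = sum(
            c for posting in idx.postings.values() for c in posting.values()
        )
        assert total_postings == sum(idx.gram_counts.values())
        # and every record appears in at least one posting list
        covered = set()
        for posting in idx.postings.values():
            covered.update(posting)
        assert covered == {r.record_id for r in table}


class TestQueryCandidates:
    def test_exact_hit_rank_one(self, oak_index):
        out = query_candidates(oak_index, "quercus alba", k=10)
        assert out[0].record_id == "ub1"
        assert out[0].retrieval_score == 1.0
        assert out[0].rank == 1

    def test_misspelled_nearest_first(self, oak_index, oak_table):
        # oracle: exhaustive DL over all records
        q = "quercus albaa"
        dists = {r.record_id: dl_oracle(q, r.canonical_name) for r in oak_table}
        best = min(dists, key=dists.get)
        assert best == "ub1"
        out = query_candidates(oak_index, q, k=10)
        assert out[0].record_id == "ub1"

    def test_k_bounded_by_index_size(self, oak_index):
        out = query_candidates(oak_index, "quercus alba", k=10)
        assert len(out) <= 4

    def test_ranks_contiguous_scores_nonincreasing(self, oak_index):
        out = query_candidates(oak_index, "quercus", k=10)
        assert [c.rank for c in out] == list(range(1, len(out) + 1))
        scores = [c.retrieval_score for c in out]
        assert scores == sorted(scores, reverse=True)
        assert all(0.0 <= s <= 1.0 for s in scores)

    def test_short_query_rejected(self, oak_index):
        with pytest.raises(IndexError_, match="too short"):
            query_candidates(oak_index, "poa", k=10)

    def test_empty_query_rejected(self, oak_index):
        with pytest.raises(IndexError_, match="empty"):
            query_candidates(oak_index, "  ", k=10)

    def test_determinism(self, oak_index):
        a = query_candidates(oak_index, "quercus rubro", k=10)
        b = query_candidates(oak_index, "quercus rubro", k=10)
        assert a == b

    def test_no_overlap_returns_empty(self, oak_index):
        assert query_candidates(oak_index, "zzzzyyyy", k=10) == []


class TestCompleteness:
    def test_nearest_always_retrieved_small(self):
        """Queries within DL<=2 of an indexed name retrieve their source."""
        from taxonym import TypoModel, corrupt

        table = generate_taxonomy(40, 5, 0.0, seed=3)
        idx = build_index(table, n=3)
        import random

        rng = random.Random(99)
        for trial in range(60):
            rec = table.records[rng.randrange(len(table.records))]
            model = TypoModel(n_edits=rng.choice([1, 2]))
            q = corrupt(rec.canonical_name, model, seed=rng.randrange(2**31))
            got = {c.record_id for c in query_candidates(idx, q, k=10)}
            assert rec.record_id in got, (q, rec.canonical_name)


class TestPersistence:
    def test_round_trip_and_determinism(self, oak_index, tmp_path):
        p1, p2 = tmp_path / "a.idx", tmp_path / "b.idx"
        save_index(oak_index, p1)
        reloaded = load_index(p1)
        assert reloaded.n == oak_index.n
        assert reloaded.postings == oak_index.postings
        assert reloaded.gram_counts == oak_index.gram_counts
        save_index(reloaded, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_magic_header_checked(self, tmp_path):
        bad = tmp_path / "bad.idx"
        bad.write_text('{"something": "else"}')
        with pytest.raises(IndexError_, match="not a taxonym index"):
            load_index(bad)
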