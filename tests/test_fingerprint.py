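"""Descriptive lexicon selection, signatures, Levenshtein, clustering."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ontoseek.corpus import Document, Token, is_low_complexity
from ontoseek.fingerprint import (DescriptiveLexicon, EmptyLexiconError,
                                  Signature, cluster_documents,
                                  compute_signature, normalized_levenshtein,
                                  select_descriptive_words)


def dp_levenshtein(a: str, b: str) -> int:
    """Independent oracle: the classic O(nm) dynamic-programming table."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1,
                           prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def doc_from_words(doc_id, words, source="s"):
    doc = Document(doc_id=doc_id, source=source)
    doc.zones["body"] = [Token(w, is_low_complexity(w)) for w in words]
    return doc


class TestSelectDescriptiveWords:
    def test_universal_word_selected_first(self):
        docs = [
            doc_from_words(f"d{i}", ["shared", "shared", f"rare{i}", f"fill{i}"])
            for i in range(6)
        ]
        lexicon = select_descriptive_words(docs, coverage_target=0.5)
        assert lexicon.words[0] == "shared"

    def test_stable_word_outranks_erratic_equal_coverage(self):
        # six docs, two sources; "stable" is frequent exactly in source A,
        # "erratic" is frequent in a mix of both sources (same coverage: 3);
        # pads are per-document so neither filler can dominate
        freqs = {
            # doc: (stable tf, erratic tf) over 10 body words
            "a1": (4, 4), "a2": (4, 1), "a3": (4, 4),
            "b1": (1, 4), "b2": (1, 1), "b3": (1, 1),
        }
        docs = []
        for doc_id, (s_tf, e_tf) in freqs.items():
            words = (["stable"] * s_tf + ["erratic"] * e_tf +
                     [f"pad{doc_id}"] * (10 - s_tf - e_tf))
            docs.append(doc_from_words(doc_id, words, source=doc_id[0]))
        lexicon = select_descriptive_words(docs, coverage_target=1.0)
        # exhaustive evaluation of the selection score on this fixture:
        # both words set their bit in 3 documents (tf 4 > median tf), but
        # "stable"'s bit is constant within each source (quality 1) while
        # "erratic"'s varies in both, so "stable" wins the first pick
        assert lexicon.words[0] == "stable"

    def test_stops_when_coverage_target_reached(self):
        docs = [doc_from_words(f"d{i}", [f"w{i}"] * 3) for i in range(4)]
        lexicon = select_descriptive_words(docs, coverage_target=0.75)
        assert len(lexicon) == 3

    def test_all_low_complexity_corpus_rejected(self):
        docs = [doc_from_words("d1", ["acgt", "1234"]),
                doc_from_words("d2", ["aaaa"])]
        with pytest.raises(EmptyLexiconError):
            select_descriptive_words(docs)

    def test_no_low_complexity_word_enters_lexicon(self, corpus):
        docs, _, _ = corpus
        lexicon = select_descriptive_words(docs)
        assert len(lexicon) >= 1
        assert not any(is_low_complexity(w) for w in lexicon.words)
        assert all(0 < b <= 1 for b in lexicon.thresholds)

    def test_dump_load_round_trip(self, corpus, tmp_path):
        docs, _, _ = corpus
        lexicon = select_descriptive_words(docs)
        path = tmp_path / "lexicon.tsv"
        lexicon.dump(path)
        loaded = DescriptiveLexicon.load(path)
        assert loaded.words == lexicon.words
        assert loaded.thresholds == lexicon.thresholds
        assert loaded.quality == lexicon.quality


class TestComputeSignature:
    lexicon = DescriptiveLexicon(
        words=[f"w{i}" for i in range(6)],
        thresholds=[0.1] * 6,
        quality=[1.0] * 6,
    )

    def doc_with_n_hot_words(self, n):
        # each hot word at relative frequency 1/4 > 0.1; rest filler
        words = []
        for i in range(n):
            words.append(f"w{i}")
        words += ["pad"] * max(0, 4 - n)
        return doc_from_words("d", words)

    def test_no_lexicon_words_excluded(self):
        assert compute_signature(self.lexicon, doc_from_words("d", ["pad"])) is None

    def test_exactly_three_set_bits_excluded(self):
        assert compute_signature(self.lexicon, self.doc_with_n_hot_words(3)) is None

    def test_exactly_four_set_bits_retained(self):
        sig = compute_signature(self.lexicon, self.doc_with_n_hot_words(4))
        assert isinstance(sig, Signature)
        assert sig.n_set == 4
        assert len(sig.bits) == len(self.lexicon)

    def test_bit_requires_strictly_above_threshold(self):
        lex = DescriptiveLexicon(["w"], [0.25], [1.0])
        at_threshold = doc_from_words("d", ["w", "a", "b", "c"])       # 1/4
        above = doc_from_words("d", ["w", "w", "a", "b"])              # 2/4
        rel_at = compute_signature(lex, at_threshold)
        assert rel_at is None  # bit not set at exactly b(i)
        # single set bit is still excluded (<4), check the raw bit instead
        assert compute_signature(lex, above) is None


class TestNormalizedLevenshtein:
    def test_identical_sequences(self):
        assert normalized_levenshtein("abc", "abc") == 0.0

    def test_kitten_sitting(self):
        assert normalized_levenshtein("kitten", "sitting") == pytest.approx(3 / 7)

    def test_bit_strings_with_ten_substitutions(self):
        a = [0, 1] * 50
        b = list(a)
        for i in range(0, 20, 2):
            b[i] = 1 - b[i]
        assert normalized_levenshtein(a, b) == pytest.approx(0.10)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            normalized_levenshtein("", "abc")

    @given(st.text(alphabet="01ab", min_size=1, max_size=30),
           st.text(alphabet="01ab", min_size=1, max_size=30))
    @settings(max_examples=150, deadline=None)
    def test_matches_dp_oracle_and_symmetry(self, a, b):
        d = normalized_levenshtein(a, b)
        assert d == pytest.approx(dp_levenshtein(a, b) / max(len(a), len(b)))
        assert d == normalized_levenshtein(b, a)
        assert 0.0 <= d <= 1.0

    @given(st.text(alphabet="01", min_size=1, max_size=15),
           st.text(alphabet="01", min_size=1, max_size=15),
           st.text(alphabet="01", min_size=1, max_size=15))
    @settings(max_examples=60, deadline=None)
    def test_unnormalized_triangle_inequality(self, a, b, c):
        assert dp_levenshtein(a, c) <= dp_levenshtein(a, b) + dp_levenshtein(b, c)


def sig(doc_id, bits):
    return Signature(doc_id, tuple(bits))


class TestClusterDocuments:
    def test_identical_signatures_one_cluster(self):
        bits = [1, 0, 1, 1, 1] * 4
        sigs = {"a": sig("a", bits), "b": sig("b", bits)}
        clusters = cluster_documents(sigs, {"a": "s", "b": "s"})
        assert [c.members for c in clusters] == [["a", "b"]]

    def test_boundary_inclusive_at_threshold(self):
        a = [1] * 10 + [0] * 90
        b = list(a)
        for i in range(10, 20):
            b[i] = 1  # distance 10/100 = 0.10
        c = list(a)
        for i in range(10, 22):
            c[i] = 1  # distance 0.12 from a
        sources = {k: "s" for k in "abc"}
        merged = cluster_documents({"a": sig("a", a), "b": sig("b", b)}, sources)
        assert [cl.members for cl in merged] == [["a", "b"]]
        split = cluster_documents({"a": sig("a", a), "c": sig("c", c)}, sources)
        assert sorted(cl.members[0] for cl in split) == ["a", "c"]
        assert all(len(cl.members) == 1 for cl in split)

    def test_chain_transitivity(self):
        # a~b and b~c but a and c differ by 0.2: single-linkage joins all
        a = [1] * 10 + [0] * 90
        b = a[:]
        for i in range(10, 20):
            b[i] = 1
        c = b[:]
        for i in range(20, 30):
            c[i] = 1
        sigs = {"a": sig("a", a), "b": sig("b", b), "c": sig("c", c)}
        assert normalized_levenshtein(sigs["a"], sigs["c"]) > 0.10
        clusters = cluster_documents(sigs, {k: "s" for k in "abc"})
        assert [cl.members for cl in clusters] == [["a", "b", "c"]]

    def test_different_sources_never_merge(self):
        bits = [1, 1, 1, 1, 0]
        sigs = {"a": sig("a", bits), "b": sig("b", bits)}
        clusters = cluster_documents(sigs, {"a": "s1", "b": "s2"})
        assert sorted(len(c.members) for c in clusters) == [1, 1]

    def test_excluded_docs_become_trailing_singletons(self):
        bits = [1, 1, 1, 1, 0]
        sigs = {"a": sig("a", bits), "x": None}
        clusters = cluster_documents(sigs, {"a": "s", "x": "s"},
                                     rl={"a": 0.5, "x": 2.0})
        assert [c.members for c in clusters] == [["a"], ["x"]]

    def test_members_and_clusters_ordered_by_relevance(self):
        bits = [1, 1, 1, 1, 0]
        other = [0, 1, 1, 1, 1]
        sigs = {"a": sig("a", bits), "b": sig("b", bits), "z": sig("z", other)}
        assert normalized_levenshtein(bits, other) > 0.10
        clusters = cluster_documents(
            sigs, {k: "s" for k in "abz"}, rl={"a": 0.1, "b": 0.9, "z": 0.5})
        assert [c.members for c in clusters] == [["b", "a"], ["z"]]

    def test_input_order_invariance_and_union_find_oracle(self):
        import numpy as np
        rng = np.random.default_rng(11)
        n, width = 40, 60
        base = rng.integers(0, 2, size=width)
        sigs = {}
        sources = {}
        for i in range(n):
            bits = base.copy()
            flips = rng.choice(width, size=int(rng.integers(0, 12)), replace=False)
            bits[flips] = 1 - bits[flips]
            if bits.sum() < 4:
                bits[:4] = 1
            sigs[f"d{i:02d}"] = sig(f"d{i:02d}", bits.tolist())
            sources[f"d{i:02d}"] = "src" + str(i % 2)
        clusters = cluster_documents(sigs, sources)

        # oracle: brute-force union-find over all pairs
        parent = {d: d for d in sigs}
        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x
        ids = sorted(sigs)
        for x, y in itertools.combinations(ids, 2):
            if sources[x] == sources[y] and \
               normalized_levenshtein(sigs[x], sigs[y]) <= 0.10:
                parent[find(x)] = find(y)
        oracle = {}
        for d in ids:
            oracle.setdefault(find(d), set()).add(d)
        got = {frozenset(c.members) for c in clusters}
        assert got == {frozenset(m) for m in oracle.values()}

        # permuting input order leaves the clustering unchanged
        shuffled = dict(reversed(list(sigs.items())))
        again = cluster_documents(shuffled, sources)
        assert [c.members for c in again] == [c.members for c in clusters]
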