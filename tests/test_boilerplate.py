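import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import methodsminer as mm
from methodsminer.boilerplate import (
    LSHIndex,
    TokenSet,
    _signature_matrix,
    targeted_search,
)
from methodsminer.normalize import NormalizedDocument


def _ts(owner, tokens, index=0, unit="sentence"):
    return TokenSet(owner, unit, index, frozenset(tokens), tuple(tokens))


def _doc(doc_id, *sentences):
    return NormalizedDocument(id=doc_id, sentences=tuple(tuple(s) for s in sentences))


class TestContainment:
    def test_identity(self):
        s = _ts("a", ["x", "y", "z"])
        assert mm.containment(s, s) == 1.0

    def test_embedded_target_scores_one(self):
        target = _ts("b", ["p-value", "less-than", "0.05"])
        bigger = _ts("a", ["p-value", "less-than", "0.05", "w1", "w2", "w3", "w4"])
        assert mm.containment(bigger, target) == 1.0

    def test_partial_overlap(self):
        assert mm.containment(_ts("a", ["a", "b"]), _ts("b", ["b", "c"])) == 0.5

    def test_nine_of_ten_is_threshold(self):
        B = _ts("b", [f"w{i}" for i in range(10)])
        A = _ts("a", [f"w{i}" for i in range(9)] + ["other"])
        assert mm.containment(A, B) == 0.9

    def test_empty_target_errors(self):
        with pytest.raises(ValueError):
            mm.containment(_ts("a", ["x"]), TokenSet("b", "sentence", 0, frozenset()))

    def test_randomized_against_set_arithmetic_oracle(self):
        rng = np.random.default_rng(42)
        universe = [f"tok{i}" for i in range(50)]
        for _ in range(1000):
            a = frozenset(rng.choice(universe, size=rng.integers(1, 20)))
            b = frozenset(rng.choice(universe, size=rng.integers(1, 20)))
            expected = sum(1 for t in b if t in a) / len(b)
            assert mm.containment(a, b) == expected

    @given(st.sets(st.integers(0, 30), min_size=1, max_size=15),
           st.sets(st.integers(0, 30), min_size=1, max_size=15))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_range_and_asymmetry(self, a, b):
        A, B = frozenset(map(str, a)), frozenset(map(str, b))
        fwd, back = mm.containment(A, B), mm.containment(B, A)
        assert 0.0 <= fwd <= 1.0
        # the smaller set is always the easier target to cover
        if len(B) <= len(A):
            assert fwd >= back


class TestMinHash:
    def test_deterministic_given_seed(self):
        s = _ts("a", ["x", "y", "z"])
        assert mm.minhash(s, 64, seed=5) == mm.minhash(s, 64, seed=5)
        assert mm.minhash(s, 64, seed=5) != mm.minhash(s, 64, seed=6)

    def test_identical_sets_identical_signatures(self):
        a = _ts("a", ["x", "y", "z"])
        b = _ts("b", ["z", "y", "x"])
        assert mm.minhash(a, 64, 0).values == mm.minhash(b, 64, 0).values

    def test_disjoint_sets_share_almost_nothing(self):
        a = mm.minhash(_ts("a", [f"a{i}" for i in range(20)]), 256, 1)
        b = mm.minhash(_ts("b", [f"b{i}" for i in range(20)]), 256, 1)
        matches = sum(x == y for x, y in zip(a.values, b.values))
        assert matches <= 5

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            mm.minhash(_ts("a", ["x"]), k=8)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            mm.minhash(TokenSet("a", "sentence", 0, frozenset()), 64)

    def test_equality_fraction_estimates_jaccard(self):
        # symmetric Jaccard 0.5 by construction: 10 shared, 5+5 private
        common = [f"c{i}" for i in range(10)]
        A = _ts("a", common + [f"a{i}" for i in range(5)])
        B = _ts("b", common + [f"b{i}" for i in range(5)])
        fracs = [np.mean(np.array(mm.minhash(A, 256, s).values)
                         == np.array(mm.minhash(B, 256, s).values))
                 for s in range(100)]
        se = np.sqrt(0.5 * 0.5 / (256 * 100))
        assert abs(np.mean(fracs) - 0.5) <= 3 * se


class TestLSH:
    def test_band_row_mismatch_rejected(self):
        with pytest.raises(ValueError):
            LSHIndex(k=256, b=30, r=8)
        with pytest.raises(ValueError):
            mm.pairwise_scan([_ts("a", ["x", "y", "z"]), _ts("b", ["x", "y"])],
                             k=256, b=30, r=8)

    def test_indexed_set_appears_in_every_band(self):
        sets = [_ts("a", ["x", "y", "z"])]
        sig = _signature_matrix(sets, 64, 0)
        index = LSHIndex(k=64, b=8, r=8)
        index.add_all(sig)
        assert sum(0 in members for members in index.buckets.values()) == 8

    def test_scan_is_subset_of_brute_force(self):
        # weak banding (few bands) forces misses but never inventions
        rng = np.random.default_rng(3)
        universe = [f"t{i}" for i in range(30)]
        sets = [_ts(f"d{i}", rng.choice(universe, size=8)) for i in range(40)]
        bf = mm.brute_force_scan(sets, threshold=0.5)
        lsh = mm.pairwise_scan(sets, threshold=0.5, k=16, b=1, r=16, seed=3,
                               rare_token_df_max=0)
        assert set(lsh) <= set(bf)


class TestScans:
    def test_identical_sections_exact_match(self, normalizer):
        docs = [_doc("d1", ["anova", "tukey", "significant"]),
                _doc("d2", ["anova", "tukey", "significant"])]
        sets = mm.build_token_sets(docs, "section")
        for records in (mm.brute_force_scan(sets), mm.pairwise_scan(sets)):
            assert len(records) == 1
            assert records[0].score == 1.0
            assert records[0].is_exact and records[0].is_exact_raw

    def test_reordered_tokens_exact_but_not_raw(self):
        docs = [_doc("d1", ["anova", "tukey", "significant"]),
                _doc("d2", ["significant", "tukey", "anova"])]
        [record] = mm.brute_force_scan(mm.build_token_sets(docs, "section"))
        assert record.is_exact and not record.is_exact_raw

    def test_disjoint_vocabularies_no_records(self):
        docs = [_doc("d1", ["a1", "a2", "a3"]), _doc("d2", ["b1", "b2", "b3"])]
        sets = mm.build_token_sets(docs, "sentence")
        assert mm.brute_force_scan(sets) == []
        assert mm.pairwise_scan(sets) == []

    def test_same_document_never_compared(self):
        docs = [_doc("d1", ["x", "y", "z"], ["x", "y", "z"]),
                _doc("d2", ["p", "q", "r"])]
        assert mm.brute_force_scan(mm.build_token_sets(docs, "sentence")) == []

    def test_nine_of_ten_boundary_pair(self):
        a = [f"w{i}" for i in range(10)]
        b = [f"w{i}" for i in range(9)] + ["other"]
        records = mm.brute_force_scan(mm.build_token_sets(
            [_doc("d1", a), _doc("d2", b)], "sentence"), threshold=0.9)
        assert len(records) == 1 and records[0].score == 0.9

    def test_short_sentences_excluded(self):
        docs = [_doc("d1", ["x", "y"]), _doc("d2", ["x", "y"])]
        assert mm.build_token_sets(docs, "sentence") == []

    def test_deterministic_output(self):
        rng = np.random.default_rng(8)
        universe = [f"t{i}" for i in range(40)]
        docs = [_doc(f"d{i}", rng.choice(universe, size=10),
                     rng.choice(universe, size=10)) for i in range(20)]
        sets = mm.build_token_sets(docs, "sentence")
        assert mm.pairwise_scan(sets, seed=4) == mm.pairwise_scan(sets, seed=4)


class TestTargetedSearch:
    def test_exact_copies_found(self):
        target = ["p-value", "less-than", "0.05", "significant"]
        docs = [_doc(f"d{i}", ["filler", "words", "here"], target) for i in range(3)]
        docs.append(_doc("d9", ["unrelated", "sentence", "tokens"]))
        report = targeted_search(docs, target)
        assert report.potential_matches == 3
        assert report.boilerplate_count == 3
        assert report.median == 1.0

    def test_absent_target(self):
        docs = [_doc("d1", ["a", "b", "c"])]
        report = targeted_search(docs, ["x", "y"])
        assert report.potential_matches == 0 and report.boilerplate_count == 0

    def test_embedded_target_scores_one(self):
        target = ["graphpad-prism", "software"]
        docs = [_doc("d1", ["analysis", "performed", "using",
                            "graphpad-prism", "software", "version"])]
        report = targeted_search(docs, target)
        assert report.potential_matches == 1 and report.median == 1.0

    def test_mutated_copies_with_anchor_gate(self):
        # 10-token target, 2 substituted => containment exactly 0.8; the
        # 2-token anchor stays intact so the n-gram gate still fires
        template = tuple(f"b{i}" for i in range(10))
        docs = []
        for i in range(20):
            mutated, score = mm.mutate_template(template, k=2, seed=i, protected=2,
                                                novel_start=10 * i)
            assert score == 0.8
            docs.append(_doc(f"d{i}", ["noise", "tokens", "only"], mutated))
        report = targeted_search(docs, template, ngram=template[:2])
        assert report.potential_matches == 20
        assert report.boilerplate_count == 0
        assert report.median == 0.8

    def test_score_against_target_covers_whole_corpus(self):
        docs = [_doc("d1", ["a", "b", "c"]), _doc("d2", ["a", "x", "y"])]
        scores = mm.score_against_target(docs, ["a", "b"])
        assert scores[("d1", 0)] == 1.0
        assert scores[("d2", 0)] == 0.5
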