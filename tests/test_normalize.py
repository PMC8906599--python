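import string

import pytest
from hypothesis import given, settings, strategies as st

import methodsminer as mm
from methodsminer.corpus_io import Document
from methodsminer.normalize import (
    SymbolMap,
    StopList,
    TermDictionary,
    convert_symbols,
    load_symbol_map,
    load_stoplist,
    load_term_dictionary,
    remove_stopwords,
    split_sentences,
    standardize_terms,
    strip_formatting,
)

FIXTURE_TEXTS = [
    "A p-value < 0.05 was considered statistically significant.",
    "Data are presented as mean ± SEM. Differences between groups were "
    "assessed with one-way ANOVA [12] and a Tukey post hoc test.",
    "Continuous variables were expressed as mean ± standard deviation; "
    "categorical variables as frequencies and percentages (%).",
    "All statistical analysis was performed using GraphPad Prism software "
    "(version 5.0 for Windows).",
    "Chi square, chisquares and chi-squared tests vs. Fisher exact tests.",
    "At a confidence level of 95% and a precision around the estimate of 5% "
    "a minimum of 73 patients will be included.",
]


class TestConvertSymbols:
    @pytest.mark.parametrize("text,expected", [
        ("p < 0.05", "p less-than 0.05"),
        ("mean ± SEM", "mean plus-or-minus SEM"),
        ("95%", "95 percent"),
        ("p = 0.05", "p equal-to 0.05"),
    ])
    def test_paper_symbols(self, normalizer, text, expected):
        out = convert_symbols(text, normalizer.symbol_map)
        assert " ".join(out.split()) == expected

    def test_mapped_output_is_ascii(self, normalizer):
        out = convert_symbols("α ≤ β ≥ χ ×", normalizer.symbol_map)
        assert out.encode("ascii")

    def test_rejects_non_idempotent_map(self):
        with pytest.raises(ValueError):
            SymbolMap({"<": "less-than", "-": "minus"})


class TestStripFormatting:
    def test_citation_markers_removed(self):
        assert strip_formatting("ANOVA [12] was used") == "ANOVA was used"
        assert strip_formatting("as shown [1,2] before [3-5]") == "as shown before"

    def test_bracketed_text_retained_without_brackets(self):
        assert strip_formatting("(version 5.0 for windows)") == "version 5.0 for windows"

    def test_intra_word_hyphen_kept_edge_hyphen_dropped(self):
        assert strip_formatting("chi-square - test") == "chi-square test"

    def test_decimal_point_preserved_other_punctuation_dropped(self):
        assert strip_formatting("p: 0.05, n = 12.") == "p 0.05 n 12"

    def test_non_ascii_removed(self):
        assert strip_formatting("café déjà vu") == "caf dj vu"

    def test_equation_like_line_dropped(self):
        text = "The model was fitted.\ny = 1 + 2 x\nResiduals were checked."
        assert "1" not in strip_formatting(text)


class TestSplitSentences:
    def test_two_sentences(self):
        got = split_sentences("Data are mean ± SEM. P < 0.05 was significant.")
        assert len(got) == 2

    def test_decimal_not_split(self):
        assert len(split_sentences("a p-value of 0.05 was used")) == 1

    def test_empty(self):
        assert split_sentences("") == []

    def test_abbreviation_guard(self):
        got = split_sentences("Tests (e.g. ANOVA) were used. Models et al. Were not.")
        assert len(got) == 2

    def test_digit_can_start_sentence(self):
        got = split_sentences("Significance was 0.05. 73 patients were included.")
        assert len(got) == 2


class TestStopwords:
    def test_retain_list_exempt(self):
        stoplist = StopList(frozenset({"the", "between"}), frozenset({"between"}))
        got = remove_stopwords(["the", "difference", "between", "groups"], stoplist)
        assert got == ["difference", "between", "groups"]

    def test_empty_and_identity(self, normalizer):
        assert remove_stopwords([], normalizer.stoplist) == []
        tokens = ["difference", "groups", "anova"]
        assert remove_stopwords(tokens, normalizer.stoplist) == tokens

    def test_shipped_retain_set_is_exempt(self, normalizer):
        for word in ("between", "against", "before", "after", "within"):
            assert word not in normalizer.stoplist

    def test_stop_and_retained_disjoint(self, normalizer):
        assert not normalizer.stoplist.stop_words & normalizer.stoplist.retained


class TestStandardizeTerms:
    @pytest.mark.parametrize("tokens,expected", [
        (["chi", "square"], ["chi-square"]),
        (["chisquares"], ["chi-square"]),
        (["chi-squares"], ["chi-square"]),
        (["hosmer", "lemeshow"], ["hosmer-lemeshow"]),
        (["wilcoxon", "rank", "sum"], ["wilcoxon-rank-sum"]),
        (["one", "way", "anova"], ["one-way", "anova"]),
        (["intention", "to", "treat"], ["intention-to-treat"]),
    ])
    def test_variants(self, normalizer, tokens, expected):
        assert standardize_terms(tokens, normalizer.dictionary) == expected

    def test_longest_match_wins(self, normalizer):
        # "wilcoxon rank sum" must merge as one trigram, not "rank sum" alone
        got = standardize_terms(["wilcoxon", "rank", "sum", "test"], normalizer.dictionary)
        assert got == ["wilcoxon-rank-sum", "test"]

    def test_stable_under_reapplication(self, normalizer):
        for text in FIXTURE_TEXTS:
            tokens = list(normalizer.normalize_tokens(text))
            assert standardize_terms(tokens, normalizer.dictionary) == tokens

    def test_no_dictionary_key_survives(self, normalizer):
        for text in FIXTURE_TEXTS:
            tokens = normalizer.normalize_tokens(text)
            for width in (1, 2, 3):
                for i in range(len(tokens) - width + 1):
                    ngram = tuple(tokens[i:i + width])
                    canonical = normalizer.dictionary.lookup(ngram)
                    assert canonical is None or canonical == " ".join(ngram)

    def test_rejects_canonical_mapping_elsewhere(self):
        with pytest.raises(ValueError):
            TermDictionary({"chi square": "chi-square", "chi-square": "chisq"})


class TestFullPipeline:
    def test_golden_significance_sentence(self, normalizer):
        doc = Document(id="d", raw_text="A p-value < 0.05 was considered "
                                        "statistically significant.")
        norm = mm.normalize_document(doc, normalizer.symbol_map,
                                     normalizer.stoplist, normalizer.dictionary)
        assert norm.tokens == ("p-value", "less-than", "0.05", "considered",
                               "statistically", "significant")

    def test_golden_mean_sem_sentence(self, normalizer):
        assert normalizer.normalize_tokens("Data are presented as mean ± SEM.") == (
            "data", "presented", "mean", "plus-or-minus", "sem")

    def test_stop_word_only_document_is_empty(self, normalizer):
        doc = Document(id="d", raw_text="It was. They were.")
        assert normalizer(doc).sentences == ()

    @pytest.mark.parametrize("text", FIXTURE_TEXTS)
    def test_idempotent_on_fixtures(self, normalizer, text):
        once = normalizer.normalize_tokens(text)
        twice = normalizer.normalize_tokens(" ".join(once))
        assert twice == once

    @pytest.mark.parametrize("text", FIXTURE_TEXTS)
    def test_tokens_ascii_lowercase_nonempty(self, normalizer, text):
        for token in normalizer.normalize_tokens(text):
            assert token and token == token.lower() and token.encode("ascii")

    def test_tokens_equal_sentence_concatenation(self, normalizer):
        norm = normalizer(Document(id="d", raw_text=" ".join(FIXTURE_TEXTS)))
        assert norm.tokens == tuple(t for s in norm.sentences for t in s)

    @given(st.lists(st.sampled_from(
        ["the", "mean", "was", "compared", "between", "groups", "using",
         "anova", "chi", "square", "0.05", "p-value", "<", "%", "±"]),
        min_size=0, max_size=20))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_idempotence_property(self, words):
        normalizer = mm.default_normalizer()
        once = normalizer.normalize_tokens(" ".join(words))
        assert normalizer.normalize_tokens(" ".join(once)) == once

    @given(st.text(alphabet=string.ascii_letters + string.digits + " .,;()[]<>%±-",
                   max_size=80))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_arbitrary_text_yields_clean_tokens(self, text):
        normalizer = mm.default_normalizer()
        for token in normalizer.normalize_tokens(text):
            assert token and token == token.lower() and token.encode("ascii")

    def test_order_preserved(self, normalizer):
        tokens = normalizer.normalize_tokens(
            "The difference between groups was tested against the null.")
        # surviving words keep original relative order
        assert tokens == ("difference", "between", "groups", "tested",
                          "against", "null")

    def test_loaders_accept_external_files(self, tmp_path):
        sym = tmp_path / "sym.tsv"
        sym.write_text("%\tpercent\n")
        stop = tmp_path / "stop.txt"
        stop.write_text("the\nwas\n")
        terms = tmp_path / "terms.tsv"
        terms.write_text("t test\tt-test\n")
        assert load_symbol_map(sym).mapping == {"%": "percent"}
        assert "the" in load_stoplist(stop, retain_path=None).stop_words
        assert load_term_dictionary(terms).lookup(("t", "test")) == "t-test"
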