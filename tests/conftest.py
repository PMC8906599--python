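import pytest

import methodsminer as mm

ACCEPTANCE_SEED = 11


@pytest.fixture(scope="session")
def normalizer():
    return mm.default_normalizer()


@pytest.fixture(scope="session")
def acceptance_corpus(normalizer):
    """The 300-document study corpus: 5 disjoint topics, planted templates at
    containment levels {1.0, 0.95, 0.9, 0.8, 0.5}, duplicate document pairs."""
    config = mm.acceptance_corpus_config(seed=ACCEPTANCE_SEED)
    corpus, truth = mm.generate_corpus(config)
    present, _ = mm.screen_missing(corpus)
    docs = normalizer.normalize_corpus(present)
    return config, corpus, truth, docs


@pytest.fixture()
def tiny_jsonl(tmp_path):
    path = tmp_path / "tiny.jsonl"
    path.write_text(
        '{"id": "d1", "text": "Means were compared with a t-test."}\n'
        '{"id": "d2", "text": "Not applicable"}\n'
        '{"id": "d3", "text": "Data are mean \\u00b1 SEM. P < 0.05 was significant."}\n'
    )
    return path
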