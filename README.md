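# methodsminer

Meta-research tooling for mining the *statistical methods* sections of
published papers and clinical-trial registrations. Statistical methods
sections are frequently written by cut-and-pasting "boilerplate" text — the
trope *"A p-value < 0.05 was considered statistically significant"* being the
canonical example. `methodsminer` quantifies that practice: it normalizes
section text, discovers the common methodological topics, and measures how
much text is reused verbatim or near-verbatim between studies.

It is aimed at meta-researchers and statistical editors who want to audit
reporting practice in a corpus of methods sections (journal exports, registry
XML dumps, or the bundled synthetic corpora).

## What it computes

**Topics.** A corpus of `N` sections with `M` unique terms is represented by
a content matrix `P ∈ R^{M×N}` under tf-idf weighting (raw term counts times
smoothed inverse document frequency `ln((1+N)/(1+df)) + 1`, unit-L2 columns).
Topics come from non-negative matrix factorization, `P ≈ W Hᵀ` with
`W ∈ R^{M×g}` and `H ∈ R^{N×g}` non-negative, fitted by Lee–Seung
multiplicative updates on the Frobenius objective `½‖P − WHᵀ‖²_F`. A section
belongs to the topic with the maximum coefficient in its row of `H` (its
topic coherence score).

**Boilerplate.** Two tokenized texts `A` and `B` are compared with the
asymmetric Jaccard containment score

    J(A, B) = |A ∩ B| / |B|,

the fraction of the target `B`'s distinct tokens found in `A`. Scoring
relative to a target finds reused text both as a whole sentence and embedded
inside a longer one; `J ≥ 0.9` is flagged as boilerplate, and `J = 1` in both
directions is an exact cut-and-paste. All-pairs scans are accelerated with
seeded MinHash signatures and banded locality-sensitive hashing, with a
brute-force scanner as the built-in oracle: on comparable-sized units the two
return identical match sets.

**Targeted searches.** A search target is an n-gram gate (e.g. `graphpad
prism`) plus a full sentence to score against; the report gives potential
matches, the median and IQR of per-document best scores, and the boilerplate
count — one row per target.

**Synthetic corpora.** The generator plants template sentences mutated to
exact, known containment levels `(n−k)/n`, plus duplicate documents,
placeholder ("missing") sections and disjoint topic vocabularies, so every
stage of the pipeline can be validated against ground truth without any
download.

## Worked example

```bash
python analysis/01_simulate_corpus.py --seed 1
python analysis/02_normalize_corpus.py --seed 1
python analysis/03_topic_model.py --seed 1
python analysis/04_boilerplate_scan.py --seed 1
python analysis/05_targeted_search.py --seed 1
```

The drivers print, for seed 1:

```
scan corpus: 306 documents, 132 planted sentences, 6 duplicate pairs -> results/corpus/scan/corpus.jsonl
scan: 282 sections normalized (24 missing screened); median 72 words (IQR 55 to 86) -> results/normalized_scan.jsonl
adjusted Rand index vs generator labels: 1.000
section: 282 units, 6 matches (LSH 0.1s vs brute force 0.1s, record sets identical)
sentence: 1970 units, 766 matches (LSH 0.3s vs brute force 1.7s, record sets identical)
studies with an exact cut-and-paste sentence: 42 of 282
tpl-c090: 29 potential matches, median score 0.90 (IQR 0.90 to 0.90), 29 boilerplate
tpl-c080: 28 potential matches, median score 0.80 (IQR 0.80 to 0.80), 0 boilerplate
recall of planted boilerplate (containment >= 0.9): 1.000
```

Reading this: the generator planted templates at five containment levels;
topic assignment reproduces the generator's labels exactly (adjusted Rand
index 1.0); the LSH-accelerated scan returns exactly the brute-force match
set at both levels; templates mutated to containment 0.90 are all flagged as
boilerplate while the 0.80 level falls below the threshold, with medians
matching the planted `(n−k)/n` scores exactly.

The same stages are available as a CLI over real corpora
(JSONL/CSV/registry-style XML):

```bash
methodsminer simulate  --config run.toml --seed 1 --out out/
methodsminer normalize --input corpus.jsonl --out out/
methodsminer topics    --input out/normalized.jsonl --g 10 --out out/
methodsminer scan      --input out/normalized.jsonl --out out/
methodsminer search    --input out/normalized.jsonl \
    --target "A p-value < 0.05 was considered statistically significant" --out out/
methodsminer report    --input corpus.jsonl --out out/
```

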