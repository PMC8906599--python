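# Methods

This note records the models and procedures implemented in `methodsminer`,
the defaults chosen where the design was genuinely open, and what the
synthetic corpora do and do not establish about real data.

## Text normalization

Cleaning standardizes notation and statistical terminology while destroying
as little content as possible. Stages run in a fixed order; the order matters
and is a deliberate choice:

1. **Sentence segmentation** runs first, on raw text, because the
   punctuation it needs is destroyed by later stages. Boundaries are
   sentence-final punctuation followed by whitespace and an upper-case letter
   or digit, with a small abbreviation guard (`e.g.`, `i.e.`, `et al.`,
   `vs.`, …). Decimals never split because no whitespace follows the period.
2. **Symbol conversion** maps notation to words: `%` → `percent`, `<` →
   `less-than`, `±` → `plus-or-minus`, `=` → `equal-to`, `≤`/`≥`, Greek
   `α`/`β`/`χ`, `×`. Replacements are space-padded; the map is validated to
   be idempotent (no replacement contains a mapped symbol).
3. **Formatting removal**: numeric citation markers (`[12]`, `[1,2]`,
   `[3-5]`) are deleted; display-equation-like lines (no word of two or more
   letters) are dropped; remaining brackets are removed but their inner text
   kept; non-ASCII characters are removed; punctuation is stripped except
   intra-word hyphens (`chi-square`) and periods flanked by digits, so
   `0.05` and version strings like `5.0` survive as single tokens.
4. **Lower-casing and whitespace tokenization.**
5. **Stop-word removal** with a retain list. The shipped stop list is a
   standard English list (pronouns, articles, auxiliaries, apostrophe-free
   contractions, prepositions); the retain set {`between`, `against`,
   `before`, `after`, `within`, `above`, `below`, `over`, `under`, `per`,
   `not`, `no`} is exempted because removing these words changes the meaning
   of a methods description ("difference *between* groups", "tested
   *against* the null").
6. **Term standardization**: plural, unhyphenated and run-together variants
   of statistical terms collapse to a singular hyphenated canonical form
   (`chi square`, `chisquare`, `chi-squares` → `chi-square`; `hosmer
   lemeshow` → `hosmer-lemeshow`). Matching is greedy longest-match
   left-to-right over 1–3 token n-grams; the shipped dictionary (~140
   entries) also carries stop-word-free variants (`analysis variance`)
   because stop-word removal runs first. Construction verifies the mapping
   is stable under re-application.

The pipeline is idempotent at the token level, an invariant the test suite
enforces on fixtures and generated text. The shipped stop list and term
dictionary are declared approximations: the corpora this design emulates were
cleaned with unpublished lists, so token-level outputs on real text are
well-defined here but not guaranteed to match any other implementation.

## Topic model

The content matrix uses tf-idf with raw counts, smoothed idf
`ln((1+N)/(1+df)) + 1` and unit-L2 document columns — the variant was an open
choice and is fixed and documented because containment of the downstream
scores on it. Terms with document frequency below `min_df = 2` or above
`max_df_fraction = 0.95` of documents are dropped; both are package choices,
exposed as parameters.

NMF minimises `½‖P − WHᵀ‖²_F` by Lee–Seung multiplicative updates, chosen
over alternating least squares because the updates guarantee a monotone
objective, which the invariant tests rely on (tolerance 1e-12 per step).
Initialization is elementwise `|N(0,1)|` scaled by `sqrt(mean(P)/g)` from a
seeded generator — fits are bit-reproducible — with a deterministic NNDSVD
start available behind a flag. Convergence: relative objective decrease below
`tol = 1e-4`, or `max_iter = 200` (defaults). Exact low-rank recovery to
relative error ≤ 1e-6 needs the slow multiplicative tail: the factorization
checks run 30,000 capped iterations on a 40×30 rank-3 matrix, which takes
under a second.

Topic count defaults to `g = 10`, the convention for corpora of this kind;
no selection criterion is implemented (a known limitation). Document
assignment is the argmax of the `H` row with ties to the lowest index; an
all-zero row is reported as topic 0 ("unassigned") with coherence 0. Term
rankings break ties lexicographically. All tie-break rules exist for
determinism.

## Containment and scanning

`J(A, B) = |A∩B|/|B|` over distinct word tokens. For unsupervised pair
scans neither member is a designated target, so both directions are computed
and the maximum reported together with the achieving direction; this finds
embeddings either way and keeps reporting symmetric. "Exact match" means
identical normalized token sets (containment 1.0 both ways); identical
ordered token sequences are reported separately as a stricter flag, since
set-identity and raw-identity are different claims about reuse.

MinHash uses `k` seeded 64-bit multiply-shift permutations over
blake2b-hashed token strings — fixed across platforms for reproducibility.
LSH banding defaults to `k = 512`, `b = 64` bands, `r = 8` rows. The
collision threshold `(1/b)^{1/r} ≈ 0.59` is deliberately far below the 0.9
boilerplate threshold: a pair of independently mutated copies of a 10-token
template whose mutual containment is exactly 0.9 has symmetric Jaccard only
≈ 0.8, and at these parameters such a pair is missed with probability below
1e-6, versus ≈ 1e-3 at `k = 256`, `b = 32` — enough to break exhaustive-scan
agreement on a 300-document corpus. Doubling `k` buys that guarantee for a
negligible constant cost at desk scale.

LSH estimates *symmetric* Jaccard, which under-detects containment between
very different-sized texts. Mitigations: sentence-level scans compare
comparable-sized units; section-level scans additionally admit any candidate
pair sharing a token with document frequency ≤ 5 (near-duplicate sections
share rare tokens, including the generator's novel substitution tokens).
Candidates are verified exactly, so the LSH path can only miss, never
invent: its records are always a subset of the brute-force scanner's, and on
the study corpus the two are identical.

Sentences with fewer than 3 distinct tokens are excluded from scans
(near-certain spurious matches; configurable). The boilerplate threshold
defaults to 0.9.

Targeted searches take an n-gram gate and a full target sentence: documents
containing the gate contiguously are "potential matches", each scored by the
best containment of any sentence against the target set. The gate defaults
to the whole target but is separately configurable because real boilerplate
variants retain a core phrase while varying the rest — which is also why the
generator protects a template's leading anchor n-gram under mutation.

## Synthetic corpora

The generator emulates the statistical shape the analyses assume, not
natural language: tokens are drawn i.i.d. from per-topic vocabularies
(tf-idf/NMF and set-based containment are insensitive to word order, so this
is the minimal structure that exercises them). Mutation of planted templates
uses substitution only, no insertion or deletion, so expected containment
has the exact closed form `(n−k)/n` against the target; substituted tokens
are novel everywhere, so the scores are exact, not approximate. Documents
are emitted in normalized spelling, making the cleaning pipeline the
identity on them and letting ground-truth containments survive end to end.

Default conditions (chosen once, as realistic for corpora of short methods
sections): 150-token topic vocabularies (200 in the scan corpus), 4–9
sentences of 6–14 tokens per document — section lengths around the scale of
real methods sections, with cross-section token overlap low enough that
chance containment ≥ 0.9 between unrelated sections is essentially absent,
as in real corpora where direct section-level copies are rare (well under
1%). The scan corpus plants one template per containment level
{1.0, 0.95, 0.9, 0.8, 0.5} at rate 0.10 per document, 3 exact and 3
near-duplicate document pairs, and 5% placeholder sections ("Not
applicable"), emulating registry exports where the section is optional.

What passing tests on these corpora do **not** show: robustness to
paraphrase, morphology or word-order effects that survive normalization;
behaviour of the topic model on overlapping, power-law vocabularies; or the
calibration of the 0.9 threshold on real text, where token sets are noisier.
The generator's ground truth validates the machinery, not the threshold.

## Numerical and degenerate-input choices

- Quartiles everywhere use linear interpolation between order statistics
  (numpy's default), stated so test expectations are exact.
- Multiplicative-update denominators are floored at 1e-12; objective traces
  are checked non-increasing to a relative 1e-12 per step.
- Containment with an empty target raises; empty token sets cannot be
  MinHashed; an empty vocabulary after document-frequency filtering raises.
- Scans never compare units of the same document; unordered pairs are
  reported once, with the lexicographically smaller (document, unit, index)
  key as the query.
- Word counts for length statistics are whitespace-delimited tokens of the
  raw text; counts on other tokenization conventions may differ slightly.
- Missing-section screening compares the lower-cased, trimmed text against a
  configurable placeholder list ({"not applicable", "nil", "none", "n/a",
  ""} by default — the conventional set is open-ended, so the list is a
  parameter).
- Heading matching is case-insensitive substring containment against the
  frequently used statistical-section headings.

## Problem sizes

The bundled analyses use a 300-document scan corpus (~2,000 sentence units;
the brute-force sentence scan is ~2 million pair comparisons, a few seconds)
and a 500-document topic corpus, sizes at which the exhaustive oracle is
cheap enough to verify the LSH path on every run while still exercising the
candidate-pruning machinery.
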