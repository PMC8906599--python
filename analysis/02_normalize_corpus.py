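"""Clean and tokenize the simulated corpora; summarise section lengths.

Screens placeholder ("missing") sections, runs the full normalization
pipeline (symbols -> formatting -> stop words -> term standardization) and
writes normalized documents plus a length summary under results/.
"""

import argparse
from pathlib import Path

import methodsminer as mm
from methodsminer import reporting


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--corpus-dir", type=Path, default=Path("results/corpus"))
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()

    normalizer = mm.default_normalizer()
    for name in ("scan", "topics"):
        corpus = mm.read_corpus(args.corpus_dir / name / "corpus.jsonl")
        present, missing = mm.screen_missing(corpus)
        stats = mm.word_count_stats(present)
        docs = [d for d in normalizer.normalize_corpus(present) if d.sentences]
        path = args.out / f"normalized_{name}.jsonl"
        reporting.write_normalized_jsonl(docs, path, seed=args.seed)
        print(f"{name}: {len(docs)} sections normalized ({len(missing)} missing "
              f"screened); median {stats['median']:.0f} words "
              f"(IQR {stats['q1']:.0f} to {stats['q3']:.0f}) -> {path}")


if __name__ == "__main__":
    main()
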