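"""Generate the synthetic study corpora and their ground truth.

Writes the 300-document scan corpus (5 disjoint topics, boilerplate templates
planted at containment levels 1.0/0.95/0.9/0.8/0.5, duplicate document pairs,
5% placeholder sections) and the 500-document topic-recovery corpus under
results/corpus/.
"""

import argparse
from pathlib import Path

import methodsminer as mm


def main():
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/corpus"))
    args = parser.parse_args()

    scan_config = mm.acceptance_corpus_config(seed=args.seed)
    corpus, truth = mm.generate_corpus(scan_config)
    paths = mm.write_fixture(corpus, truth, args.out / "scan")
    print(f"scan corpus: {len(corpus)} documents, {len(truth.planted)} planted "
          f"sentences, {len(truth.section_pairs)} duplicate pairs -> {paths['corpus']}")

    topic_config = mm.topic_recovery_config(seed=args.seed)
    corpus2, truth2 = mm.generate_corpus(topic_config)
    paths2 = mm.write_fixture(corpus2, truth2, args.out / "topics")
    print(f"topic corpus: {len(corpus2)} documents over {topic_config.g} "
          f"disjoint topics -> {paths2['corpus']}")


if __name__ == "__main__":
    main()
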