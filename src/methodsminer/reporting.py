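"""Tabular artifacts: normalized-corpus JSONL, match tables, topic reports.

Every writer emits a header comment line carrying the tool version, the seed
and a hash of the run configuration, and writes rows in a deterministic
order, so a pipeline rerun with the same configuration is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from . import __version__
from .boilerplate import MatchRecord, TargetedSearchReport
from .normalize import NormalizedDocument
from .topics import NMFResult, TopicAssignment, top_terms

__all__ = [
    "config_hash",
    "output_header",
    "write_normalized_jsonl",
    "read_normalized_jsonl",
    "write_match_table",
    "write_targeted_report",
    "topic_word_count_summary",
    "write_topic_summary",
    "write_topic_terms",
    "write_assignments",
    "read_assignments",
    "match_rollup",
    "write_rollup",
]


def config_hash(config: Mapping) -> str:
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode("utf-8")).hexdigest()[:16]


def output_header(seed: int, cfg_hash: str) -> str:
    return f"# methodsminer {__version__} seed={seed} config={cfg_hash}\n"


def write_normalized_jsonl(docs: Iterable[NormalizedDocument], path,
                           seed: int = 0, cfg_hash: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        for doc in docs:
            record = {"id": doc.id, "sentences": [list(s) for s in doc.sentences]}
            handle.write(json.dumps(record, sort_keys=True) + "\n")


def read_normalized_jsonl(path) -> list[NormalizedDocument]:
    docs = []
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            record = json.loads(line)
            docs.append(NormalizedDocument(
                id=record["id"],
                sentences=tuple(tuple(s) for s in record["sentences"]),
            ))
    return docs


def write_match_table(records: Sequence[MatchRecord], path,
                      seed: int = 0, cfg_hash: str = "-") -> None:
    columns = ("query_id", "query_unit", "query_index", "target_id",
               "target_unit", "target_index", "score", "direction",
               "is_boilerplate", "is_exact", "is_exact_raw")
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("\t".join(columns) + "\n")
        for r in records:
            handle.write("\t".join(map(str, (
                r.query[0], r.query[1], r.query[2],
                r.target[0], r.target[1], r.target[2],
                f"{r.score:.6f}", r.direction,
                int(r.is_boilerplate), int(r.is_exact), int(r.is_exact_raw),
            ))) + "\n")


def write_targeted_report(reports: Sequence[TargetedSearchReport], path,
                          seed: int = 0, cfg_hash: str = "-") -> None:
    """TSV with one row per search target: potential matches, score quartiles
    and the boilerplate count."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("target\tngram\tpotential_matches\tmedian\tq1\tq3\t"
                     "boilerplate_count\n")
        for rep in reports:
            handle.write("\t".join((
                " ".join(rep.target), " ".join(rep.ngram),
                str(rep.potential_matches),
                f"{rep.median:.4f}", f"{rep.q1:.4f}", f"{rep.q3:.4f}",
                str(rep.boilerplate_count),
            )) + "\n")


def topic_word_count_summary(
    docs: Sequence[NormalizedDocument],
    assignments: Sequence[TopicAssignment],
) -> list[dict]:
    """Per-topic document counts and word/sentence count median (IQR)."""
    by_topic: dict[int, list[NormalizedDocument]] = {}
    topic_of = {a.doc_id: a.topic for a in assignments}
    for doc in docs:
        by_topic.setdefault(topic_of.get(doc.id, 0), []).append(doc)
    rows = []
    for topic in sorted(by_topic):
        members = by_topic[topic]
        words = np.array([len(d.tokens) for d in members])
        sents = np.array([len(d.sentences) for d in members])
        w_q1, w_med, w_q3 = np.percentile(words, [25, 50, 75])
        s_q1, s_med, s_q3 = np.percentile(sents, [25, 50, 75])
        rows.append({
            "topic": topic, "n_docs": len(members),
            "words_median": float(w_med), "words_q1": float(w_q1), "words_q3": float(w_q3),
            "sentences_median": float(s_med), "sentences_q1": float(s_q1),
            "sentences_q3": float(s_q3),
        })
    return rows


def write_topic_summary(rows: Sequence[dict], path,
                        seed: int = 0, cfg_hash: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("topic\tn_docs\twords_median\twords_q1\twords_q3\t"
                     "sentences_median\tsentences_q1\tsentences_q3\n")
        for row in rows:
            handle.write("\t".join(map(str, (
                row["topic"], row["n_docs"],
                row["words_median"], row["words_q1"], row["words_q3"],
                row["sentences_median"], row["sentences_q1"], row["sentences_q3"],
            ))) + "\n")


def write_topic_terms(result: NMFResult, path, k: int = 10,
                      seed: int = 0, cfg_hash: str = "-") -> None:
    """Ranked top-k terms per topic (the tabular stand-in for word clouds)."""
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("topic\trank\tterm\tweight\n")
        for topic in range(1, result.g + 1):
            for rank, (term, weight) in enumerate(top_terms(result, topic, k), start=1):
                handle.write(f"{topic}\t{rank}\t{term}\t{weight:.6f}\n")


def write_assignments(assignments: Sequence[TopicAssignment], path,
                      seed: int = 0, cfg_hash: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("doc_id\ttopic\tcoherence\n")
        for a in assignments:
            handle.write(f"{a.doc_id}\t{a.topic}\t{a.coherence:.6f}\n")


def read_assignments(path) -> dict[str, int]:
    topics = {}
    with open(path, encoding="utf-8") as handle:
        for line in handle:
            if line.startswith("#") or line.startswith("doc_id") or not line.strip():
                continue
            doc_id, topic, _ = line.rstrip("\n").split("\t")
            topics[doc_id] = int(topic)
    return topics


def match_rollup(
    section_records: Sequence[MatchRecord],
    sentence_records: Sequence[MatchRecord],
    doc_topics: Optional[Mapping[str, int]] = None,
) -> list[dict]:
    """Per-topic counts of studies with close/exact matches at each level.

    For each topic: the number of studies with at least one close section
    match, an exact section match, at least one close sentence match, and at
    least one exact sentence match (the bracketed "cut-and-paste" count).
    """
    def docs_with(records, exact_only):
        out: set[str] = set()
        for r in records:
            if exact_only and not r.is_exact:
                continue
            out.add(r.query[0])
            out.add(r.target[0])
        return out

    close_section = docs_with(section_records, False)
    exact_section = docs_with(section_records, True)
    close_sentence = docs_with(sentence_records, False)
    exact_sentence = docs_with(sentence_records, True)
    all_docs = close_section | close_sentence
    if doc_topics is None:
        doc_topics = {d: 0 for d in all_docs}
    topics = sorted(set(doc_topics.values()))
    rows = []
    for topic in topics:
        members = {d for d, t in doc_topics.items() if t == topic}
        rows.append({
            "topic": topic,
            "n_docs": len(members),
            "section_close": len(members & close_section),
            "section_exact": len(members & exact_section),
            "sentence_close": len(members & close_sentence),
            "sentence_exact": len(members & exact_sentence),
        })
    return rows


def write_rollup(rows: Sequence[dict], path,
                 seed: int = 0, cfg_hash: str = "-") -> None:
    with open(path, "w", encoding="utf-8") as handle:
        handle.write(output_header(seed, cfg_hash))
        handle.write("topic\tn_docs\tsection_close\tsection_exact\t"
                     "sentence_close\tsentence_exact\n")
        for row in rows:
            handle.write("\t".join(map(str, (
                row["topic"], row["n_docs"], row["section_close"],
                row["section_exact"], row["sentence_close"], row["sentence_exact"],
            ))) + "\n")
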