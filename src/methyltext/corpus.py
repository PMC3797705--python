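"""Labeled corpus container and plain-text serialization.

A labeled corpus is a list of sentences, each carrying gold concept
mentions and a positive/negative label per co-occurrence pattern.  The
on-disk format is one tab-separated record per sentence:

    doc_id <TAB> text <TAB> mentions <TAB> labels

where mentions is ";"-joined ``type|start|end|canonical`` (token spans,
half-open) and labels is ";"-joined ``gene|meth|disease|{+,-}``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from .lexicon import ConceptMention, ConceptType
from .patterns import Pattern
from .preprocess import Sentence, tokenize

__all__ = ["LabeledSentence", "write_corpus", "read_corpus"]


@dataclass
class LabeledSentence:
    sentence: Sentence
    pattern_labels: dict[Pattern, bool] = field(default_factory=dict)

    @property
    def n_patterns(self) -> int:
        return len(self.pattern_labels)

    @property
    def any_positive(self) -> bool:
        """Sentence-level label: positive if at least one pattern is."""
        return any(self.pattern_labels.values())


def write_corpus(records: Iterable[LabeledSentence], path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# methyltext corpus v1\n")
        for rec in records:
            s = rec.sentence
            mentions = ";".join(
                f"{m.concept_type.value}|{m.start}|{m.end}|{m.canonical}"
                for m in s.mentions
            )
            labels = ";".join(
                f"{p.gene}|{p.methylation_word}|{p.disease}|"
                f"{'+' if lab else '-'}"
                for p, lab in rec.pattern_labels.items()
            )
            fh.write(f"{s.doc_id}\t{s.text}\t{mentions}\t{labels}\n")


def read_corpus(path) -> list[LabeledSentence]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            doc_id, text, mentions_s, labels_s = line.rstrip("\n").split("\t")
            tokens = tokenize(text)
            mentions = []
            if mentions_s:
                for part in mentions_s.split(";"):
                    t, a, b, canonical = part.split("|")
                    a, b = int(a), int(b)
                    mentions.append(
                        ConceptMention(
                            ConceptType(t),
                            tuple(tokens[a:b]),
                            canonical,
                            (a, b),
                        )
                    )
            labels: dict[Pattern, bool] = {}
            if labels_s:
                for part in labels_s.split(";"):
                    g, mw, d, sign = part.split("|")
                    labels[Pattern(g, mw, d)] = sign == "+"
            records.append(
                LabeledSentence(
                    Sentence(doc_id, text, tokens, mentions), labels
                )
            )
    return records
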