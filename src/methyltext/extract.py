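"""End-to-end association extraction and evidence tagging.

Runs the full pipeline over user documents — sentence splitting,
tokenization, dictionary NER, pattern enumeration and hybrid
classification — and produces (i) a summary table with one row per
predicted-positive pattern and (ii) a full report in which every
recognized gene, disease and methylation mention is wrapped in typed
inline tags (rendered with colors in the HTML report).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from html import escape
from typing import Iterable, Sequence

from .classify import HybridModel, predict
from .lexicon import ConceptDictionary, ConceptType, longest_match_annotate
from .preprocess import Sentence, split_sentences, tokenize_spans

logger = logging.getLogger("methyltext")

__all__ = [
    "AssociationRecord",
    "extract",
    "annotate_document",
    "tag_text",
    "detag",
    "summary_tsv",
    "report_html",
]

_TAGS = {
    ConceptType.GENE: "GENE",
    ConceptType.DISEASE: "DISEASE",
    ConceptType.METHYLATION: "METH",
}
_TAG_RE = re.compile(r"</?(?:GENE|DISEASE|METH)>")


@dataclass
class AssociationRecord:
    """One predicted-positive pattern with its evidence sentence."""

    doc_id: str
    gene: str
    methylation_word: str
    disease: str
    sentence_text: str
    prediction: bool = True
    route: str = ""  # "dtm" or "pwm"


@dataclass
class CharMention:
    concept_type: ConceptType
    start: int  # character offsets within the document
    end: int


def annotate_document(
    doc_id: str,
    text: str,
    dictionaries: Sequence[ConceptDictionary],
) -> tuple[list[Sentence], list[CharMention]]:
    """Split, tokenize and NER-annotate one document.

    Returns the annotated sentences plus all mentions as character
    spans into the original document (for tagging).
    """
    sentences: list[Sentence] = []
    char_mentions: list[CharMention] = []
    cursor = 0
    for sent_text in split_sentences(text):
        offset = text.find(sent_text, cursor)
        if offset < 0:
            offset = cursor
        cursor = offset + len(sent_text)
        toks = tokenize_spans(sent_text)
        tokens = [t.text for t in toks]
        mentions = longest_match_annotate(tokens, dictionaries)
        sentences.append(
            Sentence(
                doc_id=doc_id,
                text=sent_text,
                tokens=tokens,
                mentions=mentions,
                char_offset=offset,
                token_spans=[(t.start, t.end) for t in toks],
            )
        )
        for m in mentions:
            char_mentions.append(
                CharMention(
                    m.concept_type,
                    offset + toks[m.start].start,
                    offset + toks[m.end - 1].end,
                )
            )
    return sentences, char_mentions


def extract(
    documents: Iterable[tuple[str, str]],
    model: HybridModel,
    dictionaries: Sequence[ConceptDictionary],
    dedup: bool = False,
) -> tuple[list[AssociationRecord], dict[str, str]]:
    """Extract predicted-positive associations from (doc_id, text) pairs.

    Returns the summary records and, per document, the tagged text.
    Sentences without a complete triple yield no summary rows but their
    mentions are still tagged.  Unreadable documents are skipped with a
    logged warning by the callers that do file I/O.
    """
    records: list[AssociationRecord] = []
    tagged: dict[str, str] = {}
    for doc_id, text in documents:
        sentences, char_mentions = annotate_document(doc_id, text, dictionaries)
        tagged[doc_id] = tag_text(text, char_mentions)
        for sent in sentences:
            labels = predict(model, sent)
            route = "dtm" if len(labels) == 1 else "pwm"
            for pattern, lab in labels.items():
                if lab:
                    records.append(
                        AssociationRecord(
                            doc_id=doc_id,
                            gene=pattern.gene,
                            methylation_word=pattern.methylation_word,
                            disease=pattern.disease,
                            sentence_text=sent.text,
                            route=route,
                        )
                    )
    if dedup:
        seen: set[tuple[str, str, str]] = set()
        unique = []
        for r in records:
            key = (r.gene, r.methylation_word, r.disease)
            if key not in seen:
                seen.add(key)
                unique.append(r)
        records = unique
    return records, tagged


def tag_text(document: str, mentions: Sequence[CharMention]) -> str:
    """Wrap mention character spans in typed tags.

    Overlapping cross-type spans nest, the longer span outside; spans
    that partially overlap a longer accepted span are dropped.  Text
    outside tags is byte-identical to the input.
    """
    spans = sorted(mentions, key=lambda m: (m.start, -(m.end - m.start)))
    accepted: list[CharMention] = []
    for m in spans:
        ok = True
        for a in accepted:
            overlap = m.start < a.end and a.start < m.end
            nested = a.start <= m.start and m.end <= a.end
            if overlap and not nested:
                ok = False
                break
        if ok:
            accepted.append(m)
    # insert closing tags before opening ones at the same offset
    inserts: list[tuple[int, int, str]] = []  # (offset, priority, text)
    for m in accepted:
        tag = _TAGS[m.concept_type]
        inserts.append((m.start, 1, f"<{tag}>"))
        inserts.append((m.end, 0, f"</{tag}>"))
    inserts.sort(key=lambda t: (t[0], t[1]))
    out = []
    pos = 0
    for offset, _, txt in inserts:
        out.append(document[pos:offset])
        out.append(txt)
        pos = offset
    out.append(document[pos:])
    return "".join(out)


def detag(tagged: str) -> str:
    """Strip typed tags, recovering the original document exactly."""
    return _TAG_RE.sub("", tagged)


# ---------------------------------------------------------------------------
# Output formats
# ---------------------------------------------------------------------------

def summary_tsv(records: Sequence[AssociationRecord]) -> str:
    lines = [
        "# methyltext summary v1",
        "doc_id\tgene\tmethylation_word\tdisease\tsentence",
    ]
    for r in records:
        lines.append(
            f"{r.doc_id}\t{r.gene}\t{r.methylation_word}\t{r.disease}\t"
            f"{r.sentence_text}"
        )
    return "\n".join(lines) + "\n"


_HTML_STYLE = """
<style>
 .gene {background:#cfe8ff;} .disease {background:#ffd3d3;}
 .meth {background:#d6f5d6;}
 body {font-family:sans-serif; max-width:60em; margin:2em auto;}
 .legend span {padding:0 .4em; margin-right:1em;}
</style>
"""

_CLASS = {"GENE": "gene", "DISEASE": "disease", "METH": "meth"}


def report_html(tagged_docs: dict[str, str]) -> str:
    """Full report: tagged documents rendered with per-type colors."""
    body = [
        "<!-- methyltext report v1 -->",
        "<html><head><meta charset='utf-8'>",
        _HTML_STYLE,
        "</head><body>",
        "<div class='legend'><span class='gene'>gene</span>"
        "<span class='disease'>disease</span>"
        "<span class='meth'>methylation word</span></div>",
    ]
    for doc_id, tagged in tagged_docs.items():
        html = escape(tagged)
        for tag, cls in _CLASS.items():
            html = html.replace(
                escape(f"<{tag}>"), f"<span class='{cls}'>"
            ).replace(escape(f"</{tag}>"), "</span>")
        body.append(f"<h2>{escape(doc_id)}</h2><p>{html}</p>")
    body.append("</body></html>")
    return "\n".join(body)
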