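"""Concept dictionaries and dictionary-based longest-match NER.

Three manually-compiled term lists — genes, diseases and methylation
words — drive entity recognition.  A dictionary stores every surface
variant of a term (e.g. "Type 1 Diabetes", "Diabetes Type-1") mapped to
one canonical form, so downstream pattern identity unifies variants.

Recognition scans each sentence left to right, extending a candidate
match word by word for as long as the growing sequence is a prefix of
some dictionary entry, emits the longest complete entry found, and
resumes scanning after it (leftmost-longest).  The three dictionaries
are applied independently, so a span may be annotated with more than
one concept type, but mentions of the same type never overlap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .preprocess import tokenize

__all__ = [
    "ConceptType",
    "ConceptDictionary",
    "ConceptMention",
    "load_dictionary",
    "build_dictionary",
    "longest_match_annotate",
]


class ConceptType(enum.Enum):
    GENE = "gene"
    DISEASE = "disease"
    METHYLATION = "methylation"


@dataclass(frozen=True)
class ConceptMention:
    """A recognized concept span within a sentence.

    ``token_span`` is half-open ``[start, end)`` over the sentence's raw
    token sequence; ``surface`` is exactly those tokens.
    """

    concept_type: ConceptType
    surface: tuple[str, ...]
    canonical: str
    token_span: tuple[int, int]

    @property
    def start(self) -> int:
        return self.token_span[0]

    @property
    def end(self) -> int:
        return self.token_span[1]


def _case_sensitive(term_tokens: Sequence[str]) -> bool:
    """Short upper/mixed-case symbols (gene-symbol style) need exact case."""
    joined = "".join(term_tokens)
    return len(joined) <= 5 and any(c.isupper() for c in joined)


class ConceptDictionary:
    """A token-sequence trie over the surface variants of one concept type."""

    def __init__(self, concept_type: ConceptType):
        self.concept_type = concept_type
        self._trie: dict = {}
        self.canonical_map: dict[tuple[str, ...], str] = {}

    def __len__(self) -> int:
        return len(self.canonical_map)

    def add(self, term: str, canonical: str | None = None) -> None:
        toks = tuple(tokenize(term))
        if not toks:
            raise ValueError(f"empty dictionary term: {term!r}")
        canonical = canonical if canonical is not None else term.strip()
        node = self._trie
        for t in toks:
            node = node.setdefault(t.lower(), {})
        node.setdefault("\0entries", []).append(
            (toks, _case_sensitive(toks), canonical)
        )
        self.canonical_map[toks] = canonical

    def match_at(
        self, tokens: Sequence[str], start: int
    ) -> tuple[int, str] | None:
        """Longest entry starting at ``start``: returns (end, canonical)."""
        node = self._trie
        best: tuple[int, str] | None = None
        i = start
        while i < len(tokens):
            key = tokens[i].lower()
            if key not in node:
                break
            node = node[key]
            i += 1
            for entry_toks, cs, canonical in node.get("\0entries", ()):
                if cs and tuple(tokens[start:i]) != entry_toks:
                    continue
                best = (i, canonical)
                break
        return best


def build_dictionary(
    terms: Iterable[str | tuple[str, str]], concept_type: ConceptType
) -> ConceptDictionary:
    """Build a dictionary from terms or (term, canonical) pairs."""
    d = ConceptDictionary(concept_type)
    for item in terms:
        if isinstance(item, str):
            d.add(item)
        else:
            term, canonical = item
            d.add(term, canonical)
    if len(d) == 0:
        raise ValueError(f"empty {concept_type.value} dictionary")
    return d


def load_dictionary(path, concept_type: ConceptType) -> ConceptDictionary:
    """Load a term list: one term per line, optional TAB + canonical form,
    '#' comments, UTF-8."""
    entries: list[tuple[str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            if "\t" in line:
                term, canonical = line.split("\t", 1)
                entries.append((term.strip(), canonical.strip()))
            else:
                entries.append((line.strip(), line.strip()))
    if not entries:
        raise ValueError(f"dictionary file {path} contains no terms")
    return build_dictionary(entries, concept_type)


def longest_match_annotate(
    tokens: Sequence[str],
    dictionaries: Iterable[ConceptDictionary],
) -> list[ConceptMention]:
    """Annotate a token sequence with leftmost-longest dictionary matches.

    Each dictionary is scanned independently; after emitting a mention
    the scan resumes at the token following it, so same-type mentions
    never overlap.  Results are merged in sentence order (ties by longer
    span first, then by concept type).
    """
    mentions: list[ConceptMention] = []
    for d in dictionaries:
        i = 0
        while i < len(tokens):
            hit = d.match_at(tokens, i)
            if hit is None:
                i += 1
                continue
            end, canonical = hit
            mentions.append(
                ConceptMention(
                    concept_type=d.concept_type,
                    surface=tuple(tokens[i:end]),
                    canonical=canonical,
                    token_span=(i, end),
                )
            )
            i = end
    mentions.sort(key=lambda m: (m.start, -m.end, m.concept_type.value))
    return mentions
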