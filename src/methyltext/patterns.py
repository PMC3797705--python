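"""Co-occurrence patterns, pattern orders and sentence segmentation.

A *pattern* is a (gene, methylation word, disease) triple whose three
concepts co-occur in one sentence; the *pattern order* is the left-to-
right permutation in which the three concept mentions appear (six
possibilities).  Each concrete occurrence of a pattern splits the
sentence into four segments — before the first mention, between first
and second, between second and third, and after the third — which feed
the position-weight-matrix representation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

from . import porter
from .lexicon import ConceptMention, ConceptType
from .preprocess import DEFAULT_STOPWORDS, Sentence

__all__ = [
    "Pattern",
    "PatternInstance",
    "ORDER_PERMUTATIONS",
    "PERMUTATION_ORDERS",
    "enumerate_patterns",
    "enumerate_occurrences",
    "segment",
    "processed_view",
]

# order_id -> left-to-right concept permutation
ORDER_PERMUTATIONS: dict[int, tuple[ConceptType, ConceptType, ConceptType]] = {
    1: (ConceptType.DISEASE, ConceptType.GENE, ConceptType.METHYLATION),
    2: (ConceptType.DISEASE, ConceptType.METHYLATION, ConceptType.GENE),
    3: (ConceptType.GENE, ConceptType.DISEASE, ConceptType.METHYLATION),
    4: (ConceptType.GENE, ConceptType.METHYLATION, ConceptType.DISEASE),
    5: (ConceptType.METHYLATION, ConceptType.DISEASE, ConceptType.GENE),
    6: (ConceptType.METHYLATION, ConceptType.GENE, ConceptType.DISEASE),
}
PERMUTATION_ORDERS = {perm: oid for oid, perm in ORDER_PERMUTATIONS.items()}


@dataclass(frozen=True)
class Pattern:
    """Identity of a co-occurring triple, keyed by canonical terms."""

    gene: str
    methylation_word: str
    disease: str

    def canonical_of(self, ctype: ConceptType) -> str:
        return {
            ConceptType.GENE: self.gene,
            ConceptType.METHYLATION: self.methylation_word,
            ConceptType.DISEASE: self.disease,
        }[ctype]


@dataclass(frozen=True)
class PatternInstance:
    """One ordered occurrence of a pattern in a sentence.

    ``mention_triple`` holds the three delimiting mentions in sentence
    order; ``segments`` are the four processed token runs around them.
    """

    pattern: Pattern
    order_id: int
    mention_triple: tuple[ConceptMention, ConceptMention, ConceptMention]
    segments: tuple[tuple[str, ...], ...]


def processed_view(
    sentence: Sentence,
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
    stemming: bool = True,
) -> list[str | None]:
    """Per-token processed form aligned with the raw token sequence.

    Tokens covered by any concept mention keep their (lower-cased)
    surface and are exempt from stemming and stop-word removal; other
    tokens are lower-cased, stop-word/number filtered (``None`` when
    removed) and Porter-stemmed when ``stemming`` is on.
    """
    mention_idx: set[int] = set()
    for m in sentence.mentions:
        mention_idx.update(range(m.start, m.end))
    view: list[str | None] = []
    for i, tok in enumerate(sentence.tokens):
        low = tok.lower()
        if i in mention_idx:
            view.append(low)
        elif low in stoplist or not any(c.isalpha() for c in tok):
            view.append(None)
        else:
            view.append(porter.stem(low) if stemming else low)
    return view


def enumerate_patterns(sentence: Sentence) -> set[Pattern]:
    """All distinct canonical triples co-occurring in the sentence."""
    by_type: dict[ConceptType, set[str]] = {t: set() for t in ConceptType}
    for m in sentence.mentions:
        by_type[m.concept_type].add(m.canonical)
    if not all(by_type[t] for t in ConceptType):
        return set()
    return {
        Pattern(g, mw, d)
        for g in by_type[ConceptType.GENE]
        for mw in by_type[ConceptType.METHYLATION]
        for d in by_type[ConceptType.DISEASE]
    }


def enumerate_occurrences(
    sentence: Sentence,
    pattern: Pattern,
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
    stemming: bool = True,
) -> list[PatternInstance]:
    """Every ordered occurrence of ``pattern`` in ``sentence``.

    One instance is produced per combination of one gene mention, one
    methylation mention and one disease mention carrying the pattern's
    canonical terms; the order is induced by the mentions' positions.
    Combinations with coinciding start positions (degenerate cross-type
    overlaps) are skipped.
    """
    if pattern not in enumerate_patterns(sentence):
        raise ValueError(f"pattern {pattern} does not occur in sentence")
    view = processed_view(sentence, stoplist, stemming)
    per_type = {
        t: [
            m
            for m in sentence.mentions
            if m.concept_type is t and m.canonical == pattern.canonical_of(t)
        ]
        for t in ConceptType
    }
    instances = []
    for g, mw, d in itertools.product(
        per_type[ConceptType.GENE],
        per_type[ConceptType.METHYLATION],
        per_type[ConceptType.DISEASE],
    ):
        triple = sorted((g, mw, d), key=lambda m: m.start)
        starts = [m.start for m in triple]
        if len(set(starts)) < 3:
            continue
        order_id = PERMUTATION_ORDERS[tuple(m.concept_type for m in triple)]
        instances.append(
            PatternInstance(
                pattern=pattern,
                order_id=order_id,
                mention_triple=tuple(triple),
                segments=_segments(sentence, tuple(triple), view),
            )
        )
    return instances


def _segments(
    sentence: Sentence,
    triple: tuple[ConceptMention, ConceptMention, ConceptMention],
    view: Sequence[str | None],
) -> tuple[tuple[str, ...], ...]:
    m1, m2, m3 = triple
    bounds = [
        (0, m1.start),
        (m1.end, m2.start),
        (m2.end, m3.start),
        (m3.end, len(sentence.tokens)),
    ]
    segs = []
    for lo, hi in bounds:
        segs.append(
            tuple(view[i] for i in range(lo, max(lo, hi)) if view[i] is not None)
        )
    return tuple(segs)


def segment(
    sentence: Sentence,
    instance: PatternInstance,
) -> tuple[tuple[str, ...], ...]:
    """The four processed token runs delimited by the instance's mentions."""
    return instance.segments
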