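"""Sentence splitting, tokenization, stop-word removal, stemming and
information-gain keyword selection.

The pre-processing pipeline runs in a fixed order: sentence boundary
detection, tokenization, concept-mention recognition, stop-word removal,
stemming, keyword selection.  Mentions are recognised on the raw token
sequence and frozen *before* stop-word removal and stemming, so entity
surface forms survive intact; only ordinary words are stemmed and
lower-cased for the vocabulary-based representations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from . import porter

__all__ = [
    "Sentence",
    "KeywordSet",
    "Token",
    "split_sentences",
    "tokenize",
    "tokenize_spans",
    "remove_stopwords",
    "stem",
    "select_keywords",
    "information_gain",
    "load_stopwords",
    "DEFAULT_STOPWORDS",
    "DEFAULT_ABBREVIATIONS",
]

# Abbreviations whose trailing period never ends a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "al.", "et al.", "fig.", "figs.", "e.g.", "i.e.", "vs.", "cf.",
        "dr.", "prof.", "no.", "ca.", "approx.", "resp.", "etc.",
    }
)

# A compact English stop list (function words + a few corpus-generic
# verbs).  Kept deliberately small: discriminative content words must
# survive for the class dictionaries.
DEFAULT_STOPWORDS = frozenset(
    """a an the and or but nor so yet for of in on at to from by with
    without within into onto about as is are was were be been being am
    do does did done have has had having will would shall should can
    could may might must that this these those it its their his her
    they them he she we you i our your my me us him not no than then
    there here when where which who whom whose what while if because
    although though since until unless also both each either neither
    such same other another any some all most more less very too only
    just between among over under after before during through per
    via""".split()
)


@dataclass(frozen=True)
class Token:
    """A token together with its character span in the source string."""

    text: str
    start: int
    end: int


@dataclass
class Sentence:
    """A sentence carrying its raw text, tokens and concept mentions.

    ``mentions`` is filled by :func:`methyltext.lexicon.longest_match_annotate`;
    ``label`` (pattern-level labels live on the corpus record) is optional
    sentence metadata used by the classifiers.
    """

    doc_id: str
    text: str
    tokens: list[str]
    mentions: list = field(default_factory=list)
    char_offset: int = 0  # offset of the sentence within its document
    token_spans: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class KeywordSet:
    keywords: list[str]
    gains: list[float]

    def __len__(self) -> int:
        return len(self.keywords)


# ---------------------------------------------------------------------------
# Sentence boundary detection
# ---------------------------------------------------------------------------

_TERMINATORS = ".!?"
_CLOSERS = ")]”\"'"


def split_sentences(
    text: str,
    abbreviations: Iterable[str] = DEFAULT_ABBREVIATIONS,
) -> list[str]:
    """Split a document into sentences.

    Boundaries occur at '.', '!' or '?' followed by whitespace, except
    when the period terminates a known abbreviation or falls inside an
    open parenthesized/bracketed span.
    """
    abbrevs = {a.lower() for a in abbreviations}
    sentences: list[str] = []
    start = 0
    depth = 0
    i = 0
    n = len(text)
    while i < n:
        c = text[i]
        if c in "([":
            depth += 1
        elif c in ")]":
            depth = max(0, depth - 1)
        elif c in _TERMINATORS and depth == 0:
            # allow a closing quote/bracket between terminator and space
            j = i + 1
            while j < n and text[j] in _CLOSERS:
                j += 1
            if j >= n or text[j].isspace():
                if c == "." and _is_abbreviation(text, i, abbrevs):
                    i += 1
                    continue
                sent = text[start:j].strip()
                if sent:
                    sentences.append(sent)
                start = j
                i = j
                continue
        i += 1
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return sentences


def _is_abbreviation(text: str, dot: int, abbrevs: set[str]) -> bool:
    # the word ending at `dot` (inclusive), lower-cased
    k = dot
    while k > 0 and not text[k - 1].isspace():
        k -= 1
    word = text[k : dot + 1].lower()
    if word in abbrevs:
        return True
    # two-word abbreviations such as "et al."
    if k > 0:
        j = k - 1
        while j > 0 and not text[j - 1].isspace():
            j -= 1
        if (text[j:k].lower().strip() + " " + word) in abbrevs:
            return True
    # dotted initialisms ("U.S.", "i.e.")
    if "." in word.rstrip("."):
        return True
    return False


# ---------------------------------------------------------------------------
# Tokenization
# ---------------------------------------------------------------------------

_PAIRED = {
    '"': '"',
    "'": "'",
    "(": ")",
    ")": "(",
    "[": "]",
    "]": "[",
    "<": ">",
    ">": "<",
}


def tokenize_spans(sentence: str) -> list[Token]:
    """Tokenize, returning tokens with character spans.

    Word-boundary rules: whitespace, '!' and '?' are always boundaries;
    a period followed by whitespace (or end of input) is a boundary;
    a quote/bracket character attached to the start or end of a word is
    a boundary unless the word carries the matching character in its
    interior (so the parentheses of ``P14(ARF)`` stay inside the token).
    """
    tokens: list[Token] = []
    n = len(sentence)
    i = 0
    while i < n:
        if sentence[i].isspace() or sentence[i] in "!?":
            i += 1
            continue
        j = i
        while j < n and not (sentence[j].isspace() or sentence[j] in "!?"):
            j += 1
        start, end = i, j
        # strip a sentence/clause-final period run (period + whitespace rule)
        while end > start and sentence[end - 1] == "." and (
            end == n or sentence[end].isspace() or sentence[end] in "!?"
        ):
            end -= 1
        start, end = _strip_unmatched(sentence, start, end)
        if end > start:
            tokens.append(Token(sentence[start:end], start, end))
        i = j
    return tokens


def _strip_unmatched(s: str, start: int, end: int) -> tuple[int, int]:
    changed = True
    while changed and end > start:
        changed = False
        interior = s[start + 1 : end - 1]  # strict interior ("middle")
        c = s[start]
        if c in _PAIRED and _PAIRED[c] not in interior:
            start += 1
            changed = True
            continue
        c = s[end - 1]
        if c in _PAIRED and _PAIRED[c] not in interior:
            end -= 1
            changed = True
        # trailing plain punctuation (comma, colon, semicolon, period
        # mid-strip) is also a boundary
        while end > start and s[end - 1] in ",;:.":
            end -= 1
            changed = True
    return start, end


def tokenize(sentence: str) -> list[str]:
    return [t.text for t in tokenize_spans(sentence)]


# ---------------------------------------------------------------------------
# Stop words / stemming
# ---------------------------------------------------------------------------

def load_stopwords(path) -> frozenset[str]:
    """Read a stop-word list, one word per line, '#' comments allowed."""
    words = set()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                words.add(line.lower())
    return frozenset(words)


def remove_stopwords(
    tokens: Sequence[str],
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
    protected: Iterable[int] = (),
) -> list[str]:
    """Order-preserving stop-word filter.

    Tokens at ``protected`` indices (concept-mention tokens) are never
    removed.  Tokens with no alphabetic character (bare numbers,
    percentages) are dropped like stop words.
    """
    protected = set(protected)
    out = []
    for i, tok in enumerate(tokens):
        if i in protected:
            out.append(tok)
        elif tok.lower() not in stoplist and any(ch.isalpha() for ch in tok):
            out.append(tok)
    return out


def stem(token: str) -> str:
    """Porter stem of a single (ordinary, non-mention) token."""
    return porter.stem(token.lower())


# ---------------------------------------------------------------------------
# Information-gain keyword selection
# ---------------------------------------------------------------------------

def _entropy(counts: Sequence[int]) -> float:
    total = sum(counts)
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts:
        if c:
            p = c / total
            h -= p * math.log2(p)
    return h


def information_gain(
    presence: Sequence[bool], labels: Sequence[bool]
) -> float:
    """IG of a word's presence/absence for a binary sentence label.

    IG(w) = H(C) - P(w) H(C|w) - P(not w) H(C|not w), base-2 logs with
    the 0*log0 = 0 convention.
    """
    n = len(labels)
    pos = sum(labels)
    h_c = _entropy([pos, n - pos])
    with_w = [lab for p, lab in zip(presence, labels) if p]
    without_w = [lab for p, lab in zip(presence, labels) if not p]
    h_cond = 0.0
    for subset in (with_w, without_w):
        if subset:
            k = sum(subset)
            h_cond += (len(subset) / n) * _entropy([k, len(subset) - k])
    return h_c - h_cond


def select_keywords(
    sentences: Sequence[Sequence[str]],
    labels: Sequence[bool],
    k: int,
) -> KeywordSet:
    """Top-k vocabulary words by information gain.

    ``sentences`` are processed token sequences (post stop-word removal
    and stemming, lower-cased).  Ties in gain break alphabetically.  If
    ``k`` exceeds the vocabulary size the full vocabulary is returned.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if not (any(labels) and not all(labels)):
        raise ValueError("need at least one sentence of each class")
    vocab = sorted({w.lower() for toks in sentences for w in toks})
    sets = [frozenset(w.lower() for w in toks) for toks in sentences]
    scored = [
        (information_gain([w in s for s in sets], labels), w) for w in vocab
    ]
    scored.sort(key=lambda t: (-t[0], t[1]))
    top = scored[: min(k, len(scored))]
    return KeywordSet([w for _, w in top], [g for g, _ in top])
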