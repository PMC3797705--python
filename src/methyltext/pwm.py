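"""Class dictionaries, position weight matrices and pattern scoring.

The PWM representation aligns sentences along the three concept
mentions of a pattern occurrence and tallies, per (class, pattern
order), how often each class-dictionary word falls into each of the
four segments.  Column-normalizing a matrix turns the tallies into
weights; an occurrence is scored by taking, in each segment, the
maximum weight among its words and summing the four segment values.
A pattern in a sentence is represented by twelve such scores: one per
(class, order) pair, summed over multiple occurrences with the same
order.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .patterns import (
    ORDER_PERMUTATIONS,
    Pattern,
    PatternInstance,
    enumerate_occurrences,
)
from .preprocess import DEFAULT_STOPWORDS, Sentence

__all__ = [
    "POS",
    "NEG",
    "ClassDictionaries",
    "PWM",
    "FeatureVector",
    "build_class_dictionaries",
    "build_pwms",
    "normalize",
    "score_instance",
    "featurize",
    "save_pwms",
    "load_pwms",
]

POS = "pos"
NEG = "neg"
N_SEGMENTS = 4
N_FEATURES = 12


@dataclass
class ClassDictionaries:
    """Per-class vocabularies from document-frequency comparison.

    A word w with per-class sentence frequencies F_pos(w) and F_neg(w)
    belongs to the positive dictionary when F_pos > F_neg, to the
    negative one when F_neg > F_pos, and to both when the frequencies
    are equal (and nonzero).
    """

    positive: frozenset[str]
    negative: frozenset[str]
    f_pos: dict[str, float] = field(default_factory=dict)
    f_neg: dict[str, float] = field(default_factory=dict)

    def words(self, class_label: str) -> frozenset[str]:
        return self.positive if class_label == POS else self.negative


@dataclass
class PWM:
    """Word-by-segment weight matrix for one (class, pattern order).

    ``matrix`` has one row per class-dictionary word and exactly four
    columns; raw matrices hold counts, normalized ones column-stochastic
    weights (all-zero columns stay zero).
    """

    class_label: str
    order_id: int
    row_index: dict[str, int]
    matrix: np.ndarray
    normalized: bool = False

    def weight(self, word: str, segment: int) -> float:
        i = self.row_index.get(word)
        return 0.0 if i is None else float(self.matrix[i, segment])


@dataclass
class FeatureVector:
    """Twelve PWM scores for one pattern in one sentence.

    Slots 0-5 are the positive-PWM scores for orders 1-6, slots 6-11
    the negative-PWM scores for orders 1-6.
    """

    scores: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if self.scores.shape != (N_FEATURES,):
            raise ValueError("feature vector must have exactly 12 scores")


def build_class_dictionaries(
    sentence_words: Sequence[Iterable[str]],
    labels: Sequence[bool],
) -> ClassDictionaries:
    """Build the positive/negative vocabularies from labeled sentences.

    ``sentence_words`` holds each training sentence's processed words;
    ``labels`` the sentence-level class (True = positive).  Frequencies
    are document frequencies: fraction of class sentences containing
    the word.  Words never seen are in neither dictionary.
    """
    n_pos = sum(labels)
    n_neg = len(labels) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented in training data")
    df_pos: dict[str, int] = {}
    df_neg: dict[str, int] = {}
    for words, lab in zip(sentence_words, labels):
        target = df_pos if lab else df_neg
        for w in set(words):
            target[w] = target.get(w, 0) + 1
    vocab = set(df_pos) | set(df_neg)
    f_pos = {w: df_pos.get(w, 0) / n_pos for w in vocab}
    f_neg = {w: df_neg.get(w, 0) / n_neg for w in vocab}
    positive = frozenset(w for w in vocab if f_pos[w] >= f_neg[w])
    negative = frozenset(w for w in vocab if f_neg[w] >= f_pos[w])
    return ClassDictionaries(positive, negative, f_pos, f_neg)


def _empty_pwms(dicts: ClassDictionaries) -> dict[tuple[str, int], PWM]:
    pwms = {}
    for label in (POS, NEG):
        words = sorted(dicts.words(label))
        for order_id in ORDER_PERMUTATIONS:
            pwms[(label, order_id)] = PWM(
                class_label=label,
                order_id=order_id,
                row_index={w: i for i, w in enumerate(words)},
                matrix=np.zeros((len(words), N_SEGMENTS)),
            )
    return pwms


def build_pwms(
    instances: Iterable[tuple[PatternInstance, bool]],
    dicts: ClassDictionaries,
) -> dict[tuple[str, int], PWM]:
    """Tally raw PWMs from labeled pattern occurrences.

    For each occurrence, the PWM of (its label, its order) is selected
    and, for every word of segment j present in that class's
    dictionary, cell (word, j) is incremented — once per token
    occurrence.
    """
    pwms = _empty_pwms(dicts)
    for inst, lab in instances:
        label = POS if lab else NEG
        pwm = pwms[(label, inst.order_id)]
        for j, seg in enumerate(inst.segments):
            for w in seg:
                i = pwm.row_index.get(w)
                if i is not None:
                    pwm.matrix[i, j] += 1
    return pwms


def normalize(pwm: PWM, pseudocount: float = 0.0) -> PWM:
    """Column-normalize a raw PWM; all-zero columns remain zero.

    ``pseudocount`` adds optional additive smoothing to every cell
    before normalizing (default 0: raw frequencies).
    """
    if pwm.normalized:
        raise ValueError("PWM is already normalized")
    matrix = pwm.matrix + pseudocount if pseudocount else pwm.matrix
    sums = matrix.sum(axis=0)
    out = np.divide(matrix, sums, out=np.zeros_like(matrix), where=sums > 0)
    return PWM(pwm.class_label, pwm.order_id, dict(pwm.row_index), out, True)


def score_instance(
    pwm: PWM, instance: PatternInstance, aggregation: str = "max"
) -> float:
    """Score an occurrence against a normalized PWM of the same order.

    Per segment, its words' weights are aggregated — by default the
    maximum (0 for an empty segment or when no word is a PWM row);
    ``aggregation="sum"`` is available as an alternative hook — and the
    four segment values are summed.
    """
    if not pwm.normalized:
        raise ValueError("PWM must be normalized before scoring")
    if pwm.order_id != instance.order_id:
        raise ValueError(
            f"order mismatch: PWM order {pwm.order_id}, "
            f"instance order {instance.order_id}"
        )
    if aggregation not in ("max", "sum"):
        raise ValueError(f"unknown aggregation: {aggregation!r}")
    agg = max if aggregation == "max" else sum
    total = 0.0
    for j, seg in enumerate(instance.segments):
        weights = [pwm.weight(w, j) for w in seg]
        total += agg(weights) if weights else 0.0
    return total


def featurize(
    sentence: Sentence,
    pattern: Pattern,
    pwms: dict[tuple[str, int], PWM],
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
    stemming: bool = True,
    label: str | None = None,
) -> FeatureVector:
    """Twelve-score feature vector for one pattern in one sentence.

    Every occurrence of the pattern is scored against the positive and
    negative PWMs of its order; scores accumulate by summation into the
    (class, order) slot, so an order with several occurrences sums
    their scores and an order with none stays 0.
    """
    scores = np.zeros(N_FEATURES)
    for inst in enumerate_occurrences(sentence, pattern, stoplist, stemming):
        o = inst.order_id - 1
        scores[o] += score_instance(pwms[(POS, inst.order_id)], inst)
        scores[6 + o] += score_instance(pwms[(NEG, inst.order_id)], inst)
    return FeatureVector(scores, label)


# ---------------------------------------------------------------------------
# Persistence: one TSV per matrix plus a manifest with dictionary checksums
# ---------------------------------------------------------------------------

def _dict_checksum(words: Iterable[str]) -> str:
    h = hashlib.sha256()
    for w in sorted(words):
        h.update(w.encode("utf-8"))
        h.update(b"\n")
    return h.hexdigest()


def save_pwms(
    pwms: dict[tuple[str, int], PWM], dicts: ClassDictionaries, outdir
) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}
    for (label, order_id), pwm in sorted(pwms.items()):
        name = f"pwm_{label}_{order_id}.tsv"
        words = sorted(pwm.row_index, key=pwm.row_index.get)
        with open(outdir / name, "w", encoding="utf-8") as fh:
            fh.write(f"# class\t{label}\n# order\t{order_id}\n")
            for w in words:
                row = pwm.matrix[pwm.row_index[w]]
                fh.write(w + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        files[f"{label}_{order_id}"] = name
    manifest = {
        "files": files,
        "normalized": all(p.normalized for p in pwms.values()),
        "dict_checksums": {
            POS: _dict_checksum(dicts.positive),
            NEG: _dict_checksum(dicts.negative),
        },
    }
    (outdir / "pwm_manifest.json").write_text(json.dumps(manifest, indent=1))


def load_pwms(indir) -> dict[tuple[str, int], PWM]:
    indir = Path(indir)
    manifest = json.loads((indir / "pwm_manifest.json").read_text())
    pwms = {}
    for key, name in manifest["files"].items():
        label, order_s = key.rsplit("_", 1)
        order_id = int(order_s)
        words, rows = [], []
        with open(indir / name, encoding="utf-8") as fh:
            for line in fh:
                if line.startswith("#"):
                    continue
                parts = line.rstrip("\n").split("\t")
                words.append(parts[0])
                rows.append([float(v) for v in parts[1:]])
        matrix = (
            np.asarray(rows) if rows else np.zeros((0, N_SEGMENTS))
        )
        pwms[(label, order_id)] = PWM(
            label,
            order_id,
            {w: i for i, w in enumerate(words)},
            matrix,
            manifest["normalized"],
        )
    return pwms
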