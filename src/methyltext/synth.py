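"""Seeded synthetic labeled corpora for end-to-end testing.

The generator emulates the shape of a hand-curated relation-extraction
corpus: sentences built as ``<filler> CONCEPT <filler> CONCEPT ...``
over all six concept orders, where filler words are drawn from
class-conditional vocabularies.  ``vocab_separation`` controls how
class-specific the fillers are: at 1.0 positive and negative patterns
use disjoint vocabularies (a learnable signal), at 0.0 both classes
draw from the same mixture (no signal, classifier should fall back to
the class prior).

Each pattern is rendered as a clause ``<f1> C1 <f2> C2 <f3> C3 <f4>``
whose concepts appear in one of the six orders; a multi-pattern
sentence concatenates two or three such clauses with independent
labels and distinct genes, so each gold pattern keeps two interior
segments of its own class vocabulary while the flanking segments mix
with neighbouring clauses — emulating sentences like "M of G1 ... in
D, but not in G2".  Because pattern enumeration takes the cross
product of all mention canonicals, a multi-clause sentence also
contains unlabeled cross-clause triples; gold labels cover only the
intended clauses, and evaluation is restricted to gold patterns.

The generator emits gold mentions and labels directly, so entity
recognition and classification are testable independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .lexicon import ConceptDictionary, ConceptMention, ConceptType, build_dictionary
from .corpus import LabeledSentence
from .patterns import ORDER_PERMUTATIONS, Pattern
from .preprocess import Sentence

__all__ = [
    "SynthConfig",
    "generate",
    "toy_dictionaries",
    "TOY_GENES",
    "TOY_DISEASES",
    "TOY_METHYLATION",
    "POSITIVE_VOCAB",
    "NEGATIVE_VOCAB",
]

TOY_GENES = [
    "BRCA1", "MLH1", "CDKN2A", "MGMT", "GSTP1",
    "RASSF1A", "APC", "DAPK1", "MIR203", "FILIP1L",
]

# (surface variant, canonical) pairs: variants unify to one disease
TOY_DISEASES = [
    ("breast cancer", "breast cancer"),
    ("ovarian cancer", "ovarian cancer"),
    ("colorectal cancer", "colorectal cancer"),
    ("lung cancer", "lung cancer"),
    ("gastric cancer", "gastric cancer"),
    ("multiple myeloma", "multiple myeloma"),
    ("MM", "multiple myeloma"),
    ("leukemia", "leukemia"),
    ("glioma", "glioma"),
]

TOY_METHYLATION = [
    "methylated", "methylation", "hypermethylated",
    "hypermethylation", "unmethylated", "demethylated",
]

# 60-word class-conditional filler vocabularies; cross-class stem
# disjointness is asserted by the test suite.
POSITIVE_VOCAB = [
    "silenced", "aberrant", "frequently", "promoter", "detected",
    "observed", "significantly", "tumor", "primary", "carcinoma",
    "malignant", "progression", "metastasis", "prognosis", "diagnostic",
    "biomarker", "epigenetic", "silencing", "inactivation",
    "downregulated", "reduced", "loss", "correlated", "associated",
    "island", "dense", "heavily", "marked", "elevated", "recurrent",
    "invasive", "aggressive", "advanced", "stage", "grade", "poor",
    "survival", "outcome", "predicts", "overall", "cohort", "patients",
    "specimens", "biopsies", "resected", "examined", "exhibited",
    "displayed", "showed", "revealed", "confirmed", "consistent",
    "strongly", "robust", "substantial", "widespread", "prevalent",
    "enriched", "pronounced", "striking",
]

NEGATIVE_VOCAB = [
    "absent", "unchanged", "lacked", "failed", "rarely", "normal",
    "control", "benign", "adjacent", "unaffected", "weakly", "negative",
    "undetectable", "retained", "preserved", "intact", "baseline",
    "comparable", "similar", "equivalent", "insignificant",
    "negligible", "minimal", "sporadic", "occasional", "infrequent",
    "scarce", "low", "background", "healthy", "donors", "volunteers",
    "matched", "reference", "standard", "routine", "typical",
    "ordinary", "stable", "constant", "persistent", "unaltered",
    "unmodified", "untreated", "placebo", "mock", "sham", "vehicle",
    "wildtype", "parental", "nonmalignant", "noncancerous", "quiescent",
    "dormant", "resting", "idle", "null", "void", "blank", "plain",
]


def toy_dictionaries() -> tuple[
    ConceptDictionary, ConceptDictionary, ConceptDictionary
]:
    """The (gene, disease, methylation) dictionaries the generator uses."""
    return (
        build_dictionary(TOY_GENES, ConceptType.GENE),
        build_dictionary(TOY_DISEASES, ConceptType.DISEASE),
        build_dictionary(TOY_METHYLATION, ConceptType.METHYLATION),
    )


@dataclass
class SynthConfig:
    """Study conditions for corpus generation.

    Defaults mirror the curated corpus this emulates: a 51/49
    positive/negative pattern balance, and a multi-pattern sentence
    probability chosen so the expected patterns-per-sentence ratio is
    about 2.28 (multi-pattern sentences carry 2-3 triples).
    """

    n_sentences: int = 400
    p_multi_pattern: float = 0.85
    class_balance: float = 0.51
    vocab_separation: float = 1.0
    seed: int = 0
    p_extra_methylation: float = 0.25  # extra occurrence in single-pattern sentences
    genes: list[str] = field(default_factory=lambda: list(TOY_GENES))
    diseases: list = field(default_factory=lambda: list(TOY_DISEASES))
    methylation_words: list[str] = field(
        default_factory=lambda: list(TOY_METHYLATION)
    )

    def __post_init__(self) -> None:
        for p in (self.p_multi_pattern, self.class_balance,
                  self.vocab_separation, self.p_extra_methylation):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.n_sentences < 10:
            raise ValueError("n_sentences must be >= 10")
        if not (self.genes and self.diseases and self.methylation_words):
            raise ValueError("toy dictionaries must be non-empty")


def _fillers(rng, label: bool, separation: float, max_len: int = 6) -> list[str]:
    n = min(int(rng.poisson(2)), max_len)
    p_own = (1.0 + separation) / 2.0
    own = POSITIVE_VOCAB if label else NEGATIVE_VOCAB
    other = NEGATIVE_VOCAB if label else POSITIVE_VOCAB
    return [
        str(rng.choice(own if rng.random() < p_own else other))
        for _ in range(n)
    ]


def generate(config: SynthConfig) -> list[LabeledSentence]:
    """Generate a labeled corpus; deterministic given ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    records = []
    for i in range(config.n_sentences):
        multi = rng.random() < config.p_multi_pattern
        k = int(rng.integers(2, 4)) if multi else 1
        labels = [bool(rng.random() < config.class_balance) for _ in range(k)]
        gene_idx = rng.choice(len(config.genes), size=k, replace=False)
        genes = [config.genes[j] for j in gene_idx]

        tokens: list[str] = []
        mentions: list[ConceptMention] = []

        def emit_concept(ctype: ConceptType, surface: str, canonical: str):
            toks = surface.split()
            start = len(tokens)
            tokens.extend(toks)
            mentions.append(
                ConceptMention(ctype, tuple(toks), canonical,
                               (start, start + len(toks)))
            )

        sep = config.vocab_separation
        pattern_labels: dict[Pattern, bool] = {}
        for j in range(k):
            # one clause per pattern: fillers of its own class around a
            # full (gene, methylation word, disease) triple
            disease_surface, disease_canon = config.diseases[
                int(rng.integers(len(config.diseases)))
            ]
            meth = config.methylation_words[
                int(rng.integers(len(config.methylation_words)))
            ]
            order = ORDER_PERMUTATIONS[int(rng.integers(1, 7))]
            for ctype in order:
                tokens.extend(_fillers(rng, labels[j], sep))
                if ctype is ConceptType.GENE:
                    emit_concept(ctype, genes[j], genes[j])
                elif ctype is ConceptType.METHYLATION:
                    emit_concept(ctype, meth, meth)
                else:
                    emit_concept(ctype, disease_surface, disease_canon)
            tokens.extend(_fillers(rng, labels[j], sep))
            if not multi and rng.random() < config.p_extra_methylation:
                # second occurrence of the same methylation word
                emit_concept(ConceptType.METHYLATION, meth, meth)
                tokens.extend(_fillers(rng, labels[j], sep))
            pattern_labels[Pattern(genes[j], meth, disease_canon)] = labels[j]

        sentence = Sentence(
            doc_id=f"synth{i:04d}",
            text=" ".join(tokens),
            tokens=tokens,
            mentions=mentions,
        )
        records.append(LabeledSentence(sentence, pattern_labels))
    return records
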