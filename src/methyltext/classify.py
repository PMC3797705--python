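"""Hybrid sentence/pattern classification.

Two sub-models are trained: a DTM-based sentence classifier for
sentences containing exactly one pattern, and a PWM-feature pattern
classifier for sentences containing several.  A seeded 30% split of
the training sentences (set P) builds the class dictionaries and the
twelve PWMs; the remainder (set C) trains the two sub-models.  At
prediction time a sentence is routed by its pattern count: zero
patterns are discarded, one pattern goes through the DTM route (the
sentence label becomes the pattern's label), several go through the
PWM route with an independent label per pattern.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import KNeighborsClassifier
from sklearn.tree import DecisionTreeClassifier

from .corpus import LabeledSentence
from .dtm import DTMMode, DTMModel
from .patterns import Pattern, enumerate_patterns, processed_view
from .preprocess import DEFAULT_STOPWORDS, Sentence, select_keywords
from .pwm import (
    ClassDictionaries,
    build_class_dictionaries,
    build_pwms,
    featurize,
    load_pwms,
    normalize,
    save_pwms,
)
from .patterns import enumerate_occurrences

__all__ = [
    "ClassifierConfig",
    "HybridModel",
    "ConfusionCounts",
    "train_hybrid",
    "predict",
    "evaluate",
    "metrics_from_counts",
    "cross_validate",
    "save_model",
    "load_model",
]


@dataclass
class ClassifierConfig:
    """Algorithm and hyperparameters shared by the two sub-models.

    The default is a random forest with 15 trees; a CART decision tree
    and KNN are available as baselines.  ``n_keywords`` bounds the DTM
    vocabulary (information-gain selection), ``pwm_split`` is the
    fraction of training sentences set aside to build the PWMs, and
    ``stemming`` toggles Porter stemming in the vocabulary pipeline.
    """

    algorithm: str = "random_forest"
    n_trees: int = 15
    knn_neighbors: int = 3
    n_keywords: int = 512
    pwm_split: float = 0.3
    dtm_mode: str = DTMMode.TFIDF_Z.value
    stemming: bool = True
    seed: int = 0


def _make_classifier(config: ClassifierConfig):
    if config.algorithm == "random_forest":
        return RandomForestClassifier(
            n_estimators=config.n_trees, random_state=config.seed
        )
    if config.algorithm == "decision_tree":
        return DecisionTreeClassifier(random_state=config.seed)
    if config.algorithm == "knn":
        return KNeighborsClassifier(n_neighbors=config.knn_neighbors)
    raise ValueError(f"unknown algorithm: {config.algorithm!r}")


@dataclass
class HybridModel:
    config: ClassifierConfig
    dicts: ClassDictionaries
    pwms: dict
    keywords: list[str]
    dtm_model: DTMModel
    dtm_clf: object
    pwm_clf: object
    stoplist: frozenset[str] = DEFAULT_STOPWORDS


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def update(self, predicted: bool, truth: bool) -> None:
        if truth:
            if predicted:
                self.tp += 1
            else:
                self.fn += 1
        else:
            if predicted:
                self.fp += 1
            else:
                self.tn += 1


def _sentence_words(
    rec: LabeledSentence, stoplist: frozenset[str], stemming: bool
) -> list[str]:
    view = processed_view(rec.sentence, stoplist, stemming)
    return [w for w in view if w is not None]


def _pwm_training_instances(
    records: Sequence[LabeledSentence],
    stoplist: frozenset[str],
    stemming: bool,
):
    for rec in records:
        for pattern, lab in rec.pattern_labels.items():
            for inst in enumerate_occurrences(
                rec.sentence, pattern, stoplist, stemming
            ):
                yield inst, lab


def train_hybrid(
    corpus: Sequence[LabeledSentence],
    config: ClassifierConfig | None = None,
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
) -> HybridModel:
    """Train the hybrid model on a labeled corpus.

    A seeded random ``pwm_split`` fraction of sentences (set P) builds
    the class dictionaries and PWMs; it feeds neither sub-model, so no
    vocabulary leaks between the representation and the classifiers.
    """
    config = config or ClassifierConfig()
    rng = np.random.default_rng(config.seed)
    idx = rng.permutation(len(corpus))
    n_p = int(round(config.pwm_split * len(corpus)))
    p_set = [corpus[i] for i in idx[:n_p]]
    c_set = [corpus[i] for i in idx[n_p:]]

    for name, subset in (("P (PWM-building)", p_set), ("C (training)", c_set)):
        labs = {rec.any_positive for rec in subset}
        if labs != {True, False}:
            raise ValueError(
                f"set {name} lacks one class "
                f"({len(subset)} sentences, labels seen: {sorted(labs)})"
            )

    stemming = config.stemming
    dicts = build_class_dictionaries(
        [_sentence_words(r, stoplist, stemming) for r in p_set],
        [r.any_positive for r in p_set],
    )
    raw = build_pwms(
        _pwm_training_instances(p_set, stoplist, stemming), dicts
    )
    pwms = {key: normalize(p) for key, p in raw.items()}

    singles = [r for r in c_set if r.n_patterns == 1]
    multis = [r for r in c_set if r.n_patterns >= 2]
    if not singles or not multis:
        raise ValueError(
            "set C must contain both single-pattern and multi-pattern "
            f"sentences (got {len(singles)} single, {len(multis)} multi)"
        )

    # DTM route: sentence-level model on single-pattern sentences
    single_words = [_sentence_words(r, stoplist, stemming) for r in singles]
    single_labels = [r.any_positive for r in singles]
    kws = select_keywords(single_words, single_labels, config.n_keywords)
    dtm_model = DTMModel(
        keywords=list(kws.keywords), mode=DTMMode(config.dtm_mode)
    )
    x_dtm = dtm_model.fit_transform(single_words)
    dtm_clf = _make_classifier(config)
    dtm_clf.fit(x_dtm, np.asarray(single_labels))

    # PWM route: pattern-level model on multi-pattern sentences
    x_pwm, y_pwm = [], []
    for rec in multis:
        for pattern, lab in rec.pattern_labels.items():
            fv = featurize(rec.sentence, pattern, pwms, stoplist, stemming)
            x_pwm.append(fv.scores)
            y_pwm.append(lab)
    pwm_clf = _make_classifier(config)
    pwm_clf.fit(np.vstack(x_pwm), np.asarray(y_pwm))

    return HybridModel(
        config=config,
        dicts=dicts,
        pwms=pwms,
        keywords=list(kws.keywords),
        dtm_model=dtm_model,
        dtm_clf=dtm_clf,
        pwm_clf=pwm_clf,
        stoplist=stoplist,
    )


def predict(model: HybridModel, sentence: Sentence) -> dict[Pattern, bool]:
    """Label every pattern of a sentence through exactly one route."""
    patterns = enumerate_patterns(sentence)
    if not patterns:
        return {}
    stemming = model.config.stemming
    if len(patterns) == 1:
        view = processed_view(sentence, model.stoplist, stemming)
        row = model.dtm_model.transform([w for w in view if w is not None])
        lab = bool(model.dtm_clf.predict(row.reshape(1, -1))[0])
        return {next(iter(patterns)): lab}
    out = {}
    for pattern in sorted(
        patterns, key=lambda p: (p.gene, p.methylation_word, p.disease)
    ):
        fv = featurize(sentence, pattern, model.pwms, model.stoplist, stemming)
        out[pattern] = bool(model.pwm_clf.predict(fv.scores.reshape(1, -1))[0])
    return out


def evaluate(
    predictions: Sequence[bool], truth: Sequence[bool]
) -> tuple[dict[str, float], ConfusionCounts]:
    """Confusion-matrix metrics; zero-denominator ratios come out NaN."""
    if len(predictions) != len(truth):
        raise ValueError("prediction/truth length mismatch")
    counts = ConfusionCounts()
    for p, t in zip(predictions, truth):
        counts.update(bool(p), bool(t))
    return metrics_from_counts(counts), counts


def _ratio(num: int, den: int) -> float:
    return num / den if den else math.nan


def metrics_from_counts(c: ConfusionCounts) -> dict[str, float]:
    precision = _ratio(c.tp, c.tp + c.fp)
    recall = _ratio(c.tp, c.tp + c.fn)
    if math.isnan(precision) or math.isnan(recall) or precision + recall == 0:
        fscore = math.nan
    else:
        fscore = 2 * precision * recall / (precision + recall)
    return {
        "accuracy": _ratio(c.tp + c.tn, c.total),
        "precision": precision,
        "recall": recall,
        "specificity": _ratio(c.tn, c.tn + c.fp),
        "fscore": fscore,
    }


def cross_validate(
    corpus: Sequence[LabeledSentence],
    folds: int = 10,
    config: ClassifierConfig | None = None,
    stoplist: frozenset[str] = DEFAULT_STOPWORDS,
) -> dict:
    """Sentence-level stratified k-fold cross-validation.

    Folds are assigned at the sentence level (patterns of one sentence
    never straddle folds), stratified by the sentence's any-positive
    label.  Dictionaries, PWMs and keywords are re-derived inside each
    training fold.  Returns per-fold metrics, pooled counts and mean
    metrics (NaN metrics excluded from means).
    """
    config = config or ClassifierConfig()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(config.seed)
    pos_idx = [i for i, r in enumerate(corpus) if r.any_positive]
    neg_idx = [i for i, r in enumerate(corpus) if not r.any_positive]
    if folds > min(len(pos_idx), len(neg_idx)):
        raise ValueError("more folds than sentences in the smaller class")
    assignment = np.empty(len(corpus), dtype=int)
    for stratum in (pos_idx, neg_idx):
        order = rng.permutation(stratum)
        for rank, i in enumerate(order):
            assignment[i] = rank % folds

    per_fold = []
    pooled = ConfusionCounts()
    for f in range(folds):
        train = [r for i, r in enumerate(corpus) if assignment[i] != f]
        test = [r for i, r in enumerate(corpus) if assignment[i] == f]
        model = train_hybrid(train, config, stoplist)
        counts = ConfusionCounts()
        for rec in test:
            pred = predict(model, rec.sentence)
            for pattern, lab in rec.pattern_labels.items():
                if pattern in pred:
                    counts.update(pred[pattern], lab)
        per_fold.append(metrics_from_counts(counts))
        for attr in ("tp", "fp", "tn", "fn"):
            setattr(pooled, attr, getattr(pooled, attr) + getattr(counts, attr))

    mean = {}
    for key in per_fold[0]:
        vals = [m[key] for m in per_fold if not math.isnan(m[key])]
        mean[key] = sum(vals) / len(vals) if vals else math.nan
    return {
        "per_fold": per_fold,
        "mean": mean,
        "pooled_counts": pooled,
        "pooled": metrics_from_counts(pooled),
    }


# ---------------------------------------------------------------------------
# Model persistence: directory bundle
# ---------------------------------------------------------------------------

def save_model(model: HybridModel, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_pwms(model.pwms, model.dicts, outdir / "pwms")
    (outdir / "keywords.txt").write_text(
        "\n".join(model.keywords) + "\n", encoding="utf-8"
    )
    (outdir / "stopwords.txt").write_text(
        "\n".join(sorted(model.stoplist)) + "\n", encoding="utf-8"
    )
    for label, words in ((("positive"), model.dicts.positive),
                         (("negative"), model.dicts.negative)):
        (outdir / f"class_dict_{label}.txt").write_text(
            "\n".join(sorted(words)) + "\n", encoding="utf-8"
        )
    joblib.dump(
        {
            "dtm_model": model.dtm_model,
            "dtm_clf": model.dtm_clf,
            "pwm_clf": model.pwm_clf,
            "f_pos": model.dicts.f_pos,
            "f_neg": model.dicts.f_neg,
        },
        outdir / "classifiers.joblib",
    )
    (outdir / "config.json").write_text(
        json.dumps(asdict(model.config), indent=1)
    )


def load_model(indir) -> HybridModel:
    indir = Path(indir)
    config = ClassifierConfig(**json.loads((indir / "config.json").read_text()))
    bundle = joblib.load(indir / "classifiers.joblib")
    pwms = load_pwms(indir / "pwms")
    pos = frozenset(
        (indir / "class_dict_positive.txt").read_text().split()
    )
    neg = frozenset(
        (indir / "class_dict_negative.txt").read_text().split()
    )
    stoplist = frozenset(
        (indir / "stopwords.txt").read_text(encoding="utf-8").split()
    )
    keywords = (indir / "keywords.txt").read_text(encoding="utf-8").split()
    return HybridModel(
        config=config,
        dicts=ClassDictionaries(pos, neg, bundle["f_pos"], bundle["f_neg"]),
        pwms=pwms,
        keywords=keywords,
        dtm_model=bundle["dtm_model"],
        dtm_clf=bundle["dtm_clf"],
        pwm_clf=bundle["pwm_clf"],
        stoplist=stoplist,
    )
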