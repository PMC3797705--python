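import itertools
from collections import Counter

import numpy as np
import pytest

from methyltext.lexicon import ConceptType
from methyltext.patterns import (
    PERMUTATION_ORDERS,
    Pattern,
    enumerate_occurrences,
)
from methyltext.pwm import (
    NEG,
    POS,
    PWM,
    FeatureVector,
    build_class_dictionaries,
    build_pwms,
    featurize,
    load_pwms,
    normalize,
    save_pwms,
    score_instance,
)
from methyltext.classify import _pwm_training_instances, _sentence_words
from methyltext.preprocess import DEFAULT_STOPWORDS
from methyltext.synth import SynthConfig, generate


class TestClassDictionaries:
    def test_majority_frequency_assigns_single_class(self):
        pos = [["alpha"]] * 3 + [["beta"]] * 7
        neg = [["alpha"]] * 1 + [["beta"]] * 9
        d = build_class_dictionaries(pos + neg, [True] * 10 + [False] * 10)
        assert "alpha" in d.positive and "alpha" not in d.negative
        assert d.f_pos["alpha"] == pytest.approx(0.3)
        assert d.f_neg["alpha"] == pytest.approx(0.1)

    def test_equal_frequency_joins_both(self):
        pos = [["w"]] * 2 + [["x"]] * 8
        neg = [["w"]] * 2 + [["x"]] * 8
        d = build_class_dictionaries(pos + neg, [True] * 10 + [False] * 10)
        assert "w" in d.positive and "w" in d.negative

    def test_vocabulary_partition(self):
        corpus = generate(SynthConfig(n_sentences=60, seed=3))
        words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
        labels = [r.any_positive for r in corpus]
        d = build_class_dictionaries(words, labels)
        vocab = {w for ws in words for w in ws}
        assert d.positive | d.negative == vocab
        both = d.positive & d.negative
        assert all(d.f_pos[w] == d.f_neg[w] for w in both)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            build_class_dictionaries([["a"], ["b"]], [True, True])


class TestBuildPwms:
    def test_twelve_matrices_four_columns(self):
        corpus = generate(SynthConfig(n_sentences=30, seed=2))
        words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
        d = build_class_dictionaries(words, [r.any_positive for r in corpus])
        pwms = build_pwms(_pwm_training_instances(corpus, DEFAULT_STOPWORDS, True), d)
        assert len(pwms) == 12
        assert {k[0] for k in pwms} == {POS, NEG}
        assert {k[1] for k in pwms} == {1, 2, 3, 4, 5, 6}
        for (label, _), pwm in pwms.items():
            assert pwm.matrix.shape[1] == 4
            assert set(pwm.row_index) == set(d.words(label))

    def test_empty_training_set_gives_zero_matrices(self):
        d = build_class_dictionaries([["a"], ["b"]], [True, False])
        pwms = build_pwms([], d)
        assert all(np.all(p.matrix == 0) for p in pwms.values())

    def test_counts_match_brute_force_tally(self):
        """PWM cells equal an independent (word, segment, order, class)
        tally computed straight from gold mention combinations."""
        corpus = generate(SynthConfig(n_sentences=60, seed=11))
        words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
        d = build_class_dictionaries(words, [r.any_positive for r in corpus])
        pwms = build_pwms(_pwm_training_instances(corpus, DEFAULT_STOPWORDS, True), d)

        tally = Counter()  # (class, order, word, segment) -> count
        from methyltext.patterns import processed_view

        for rec in corpus:
            s = rec.sentence
            view = processed_view(s)
            for pattern, lab in rec.pattern_labels.items():
                per_type = {
                    t: [
                        m for m in s.mentions
                        if m.concept_type is t
                        and m.canonical == pattern.canonical_of(t)
                    ]
                    for t in ConceptType
                }
                for combo in itertools.product(
                    per_type[ConceptType.GENE],
                    per_type[ConceptType.METHYLATION],
                    per_type[ConceptType.DISEASE],
                ):
                    trip = sorted(combo, key=lambda m: m.start)
                    if len({m.start for m in trip}) < 3:
                        continue
                    order = PERMUTATION_ORDERS[
                        tuple(m.concept_type for m in trip)
                    ]
                    label = POS if lab else NEG
                    ranges = [
                        (0, trip[0].start),
                        (trip[0].end, trip[1].start),
                        (trip[1].end, trip[2].start),
                        (trip[2].end, len(s.tokens)),
                    ]
                    for j, (lo, hi) in enumerate(ranges):
                        for i in range(lo, hi):
                            w = view[i]
                            if w is not None and w in d.words(label):
                                tally[(label, order, w, j)] += 1

        for (label, order), pwm in pwms.items():
            for w, r in pwm.row_index.items():
                for j in range(4):
                    assert pwm.matrix[r, j] == tally[(label, order, w, j)]


class TestNormalize:
    def test_column_normalization(self):
        matrix = np.array(
            [[2.0, 0.0, 1.0, 0.0], [1.0, 0.0, 0.0, 0.0], [1.0, 0.0, 0.0, 0.0]]
        )
        pwm = PWM(POS, 1, {"a": 0, "b": 1, "c": 2}, matrix)
        out = normalize(pwm)
        assert out.matrix[:, 0] == pytest.approx([0.5, 0.25, 0.25])
        # all-zero columns stay zero
        assert np.all(out.matrix[:, 1] == 0)
        assert out.normalized

    def test_random_matrices_become_column_stochastic(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m = rng.integers(0, 5, size=(6, 4)).astype(float)
            out = normalize(PWM(NEG, 2, {str(i): i for i in range(6)}, m))
            sums = out.matrix.sum(axis=0)
            raw = m.sum(axis=0)
            assert np.allclose(sums[raw > 0], 1.0, atol=1e-9)
            assert np.all(sums[raw == 0] == 0)

    def test_double_normalization_rejected(self):
        pwm = normalize(PWM(POS, 1, {"a": 0}, np.ones((1, 4))))
        with pytest.raises(ValueError):
            normalize(pwm)


def _worked_example_pwm():
    """Normalized positive PWM for order (Gene, MethWord, Disease) holding
    the worked example's printed weights."""
    rows = {
        "promoter": 0, "found": 1, "approximately": 2, "cell": 3,
        "controls": 4, "lines": 5, "methylated": 6, "normal": 7,
    }
    m = np.zeros((8, 4))
    m[rows["promoter"], 0] = 0.2336
    m[rows["found"], 1] = 0.619
    m[rows["approximately"], 2] = 0.1724
    m[rows["cell"], 3] = 0.0603
    m[rows["controls"], 3] = 0.0
    m[rows["lines"], 3] = 0.0822
    m[rows["methylated"], 3] = 0.1224
    m[rows["normal"], 3] = 0.1315
    return PWM(POS, 4, rows, m, normalized=True)


class TestScoreInstance:
    def test_worked_example_score(self, mir203_sentence):
        pattern = Pattern("MIR203", "methylated", "multiple myeloma")
        insts = enumerate_occurrences(mir203_sentence, pattern, stemming=False)
        inst = next(i for i in insts if i.order_id == 4)
        score = score_instance(_worked_example_pwm(), inst)
        assert score == pytest.approx(0.2336 + 0.619 + 0.1724 + 0.1315)
        assert score == pytest.approx(1.1565)

    def test_empty_segments_score_zero(self, toy_dicts):
        from methyltext.extract import annotate_document

        s, _ = annotate_document("d", "BRCA1 methylated breast cancer", toy_dicts)
        inst = enumerate_occurrences(
            s[0], Pattern("BRCA1", "methylated", "breast cancer")
        )[0]
        pwm = PWM(POS, 4, {}, np.zeros((0, 4)), normalized=True)
        assert score_instance(pwm, inst) == 0.0

    def test_matches_exhaustive_max_then_sum_oracle(self):
        corpus = generate(SynthConfig(n_sentences=40, seed=13))
        words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
        d = build_class_dictionaries(words, [r.any_positive for r in corpus])
        raw = build_pwms(_pwm_training_instances(corpus, DEFAULT_STOPWORDS, True), d)
        pwms = {k: normalize(p) for k, p in raw.items()}
        for rec in corpus[:15]:
            for pattern in rec.pattern_labels:
                for inst in enumerate_occurrences(rec.sentence, pattern):
                    for label in (POS, NEG):
                        pwm = pwms[(label, inst.order_id)]
                        expected = 0.0
                        for j, seg in enumerate(inst.segments):
                            vals = [
                                pwm.matrix[pwm.row_index[w], j]
                                for w in seg if w in pwm.row_index
                            ]
                            expected += max(vals) if vals else 0.0
                        assert score_instance(pwm, inst) == pytest.approx(expected)

    def test_order_mismatch_rejected(self, mir203_sentence):
        pattern = Pattern("MIR203", "methylated", "multiple myeloma")
        inst = next(
            i for i in enumerate_occurrences(mir203_sentence, pattern)
            if i.order_id == 3
        )
        with pytest.raises(ValueError):
            score_instance(_worked_example_pwm(), inst)

    def test_unnormalized_pwm_rejected(self, mir203_sentence):
        pattern = Pattern("MIR203", "methylated", "multiple myeloma")
        inst = enumerate_occurrences(mir203_sentence, pattern)[0]
        raw = PWM(POS, inst.order_id, {"promoter": 0}, np.ones((1, 4)))
        with pytest.raises(ValueError):
            score_instance(raw, inst)


class TestFeaturize:
    def _trained_pwms(self, corpus):
        words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
        d = build_class_dictionaries(words, [r.any_positive for r in corpus])
        raw = build_pwms(_pwm_training_instances(corpus, DEFAULT_STOPWORDS, True), d)
        return {k: normalize(p) for k, p in raw.items()}

    def test_vector_length_and_slot_layout(self, toy_dicts):
        corpus = generate(SynthConfig(n_sentences=50, seed=21))
        pwms = self._trained_pwms(corpus)
        rec = corpus[0]
        pattern = next(iter(rec.pattern_labels))
        fv = featurize(rec.sentence, pattern, pwms)
        assert fv.scores.shape == (12,)
        orders = {
            i.order_id for i in enumerate_occurrences(rec.sentence, pattern)
        }
        for o in range(1, 7):
            if o not in orders:
                assert fv.scores[o - 1] == 0 and fv.scores[5 + o] == 0

    def test_repeated_order_scores_sum(self, toy_dicts):
        from methyltext.extract import annotate_document

        corpus = generate(SynthConfig(n_sentences=50, seed=21))
        pwms = self._trained_pwms(corpus)
        s, _ = annotate_document(
            "d",
            "MGMT was hypermethylated in glioma and glioma specimens",
            toy_dicts,
        )
        pattern = Pattern("MGMT", "hypermethylated", "glioma")
        insts = enumerate_occurrences(s[0], pattern)
        assert len(insts) == 2 and all(i.order_id == 4 for i in insts)
        fv = featurize(s[0], pattern, pwms)
        expected = sum(score_instance(pwms[(POS, 4)], i) for i in insts)
        assert fv.scores[3] == pytest.approx(expected)

    def test_cosentential_patterns_get_distinct_vectors(self, toy_dicts):
        from methyltext.extract import annotate_document

        corpus = generate(SynthConfig(n_sentences=50, seed=21))
        pwms = self._trained_pwms(corpus)
        s, _ = annotate_document(
            "d",
            "We found that methylation of the BRCA1 promoter was detectable "
            "in leukemia but absent in APC promoter",
            toy_dicts,
        )
        p1 = Pattern("BRCA1", "methylation", "leukemia")
        p2 = Pattern("APC", "methylation", "leukemia")
        fv1 = featurize(s[0], p1, pwms)
        fv2 = featurize(s[0], p2, pwms)
        assert not np.allclose(fv1.scores, fv2.scores)

    def test_score_bounds(self):
        corpus = generate(SynthConfig(n_sentences=50, seed=21))
        pwms = self._trained_pwms(corpus)
        for rec in corpus[:20]:
            for pattern in rec.pattern_labels:
                fv = featurize(rec.sentence, pattern, pwms)
                occ = enumerate_occurrences(rec.sentence, pattern)
                per_order = Counter(i.order_id for i in occ)
                cap = 4 * max(per_order.values())
                assert np.all(fv.scores >= 0)
                assert np.all(fv.scores <= cap + 1e-9)

    def test_bad_vector_length_rejected(self):
        with pytest.raises(ValueError):
            FeatureVector(np.zeros(11))


def test_pwm_persistence_round_trip(tmp_path):
    corpus = generate(SynthConfig(n_sentences=30, seed=4))
    words = [_sentence_words(r, DEFAULT_STOPWORDS, True) for r in corpus]
    d = build_class_dictionaries(words, [r.any_positive for r in corpus])
    raw = build_pwms(_pwm_training_instances(corpus, DEFAULT_STOPWORDS, True), d)
    pwms = {k: normalize(p) for k, p in raw.items()}
    save_pwms(pwms, d, tmp_path)
    loaded = load_pwms(tmp_path)
    assert set(loaded) == set(pwms)
    for key, pwm in pwms.items():
        other = loaded[key]
        assert other.normalized
        assert other.row_index == pwm.row_index
        assert np.allclose(other.matrix, pwm.matrix, atol=1e-9)
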