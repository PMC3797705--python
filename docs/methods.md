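# Methods

## Model

The unit of classification is the *pattern*: a (gene, methylation word,
disease) triple whose three concepts co-occur in one sentence, keyed by
canonical dictionary forms so that surface variants ("MM", "multiple
myeloma") unify. Each concrete occurrence of a pattern — one choice of
one mention per concept — induces a pattern order (one of the six
permutations) and a decomposition of the sentence into four segments.
Mentions of other entities, and unchosen mentions of the same
entities, remain ordinary segment words.

Two representations feed a hybrid classifier:

* **PWM features.** Per (class, order), a word-by-4-segment matrix of
  raw segment counts over class-dictionary words, column-normalized
  (all-zero columns stay zero). An occurrence is scored by summing the
  per-segment maxima of its words' weights; a pattern's 12-vector holds
  the positive and negative scores per order, summed over occurrences
  of the same order. With a single occurrence each score lies in
  [0, 4]; k occurrences of one order bound it by 4k.
* **DTM features.** Sentence rows over the top-k information-gain
  keywords (`IG(w) = H(C) − P(w)H(C|w) − P(¬w)H(C|¬w)`, base-2,
  0·log 0 ≡ 0, ties broken alphabetically), in binary, frequency, or
  TF-IDF (`tf · ln(N/df)`, no smoothing) + per-column z-score form.
  IDF, means and standard deviations are frozen on the training rows;
  constant columns map to 0.

Routing: 0 patterns → discarded; 1 pattern → DTM sentence classifier,
its label assigned to the pattern; ≥2 patterns → PWM pattern
classifier, one independent label per pattern.

## Assumptions

* Associations are intra-sentential; cross-sentence relations are out
  of scope.
* Dictionary NER is exact longest matching — no fuzzy matching,
  abbreviation expansion or disambiguation. Matching is
  case-insensitive except for short (≤5 character) upper/mixed-case
  terms, which are gene-symbol-like and require exact case to avoid
  false hits on common words.
* Sentence class for dictionary building and DTM training is
  "any pattern positive". At prediction time the DTM route only ever
  sees single-pattern sentences, so the rule is unambiguous there.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `ClassifierConfig.algorithm` | `random_forest` | sub-model family; `decision_tree` and `knn` are baselines |
| `n_trees` | 15 | forest size for both sub-models |
| `n_keywords` | 512 | DTM vocabulary size (128/256/512 are sensible) |
| `pwm_split` | 0.30 | fraction of training sentences (set P) used to build dictionaries and PWMs |
| `dtm_mode` | `tfidf_z` | DTM variant for the sentence route (frequency suits naive-Bayes-style models, binary suits rule learners) |
| `stemming` | on | Porter stemming of non-mention vocabulary tokens |
| `seed` | 0 | drives the P-split, fold assignment and forests |

Set P feeds neither sub-model, so representation statistics cannot leak
into classifier training; inside cross-validation, dictionaries, PWMs
and keywords are re-derived within each training fold.

## Numerical and procedural choices

* No pseudocounts in PWMs; an additive-smoothing hook exists but
  defaults to 0. Words absent from a PWM's rows contribute weight 0 and
  never win a segment max unless every candidate is 0.
* Zero-frequency words belong to neither class dictionary; the
  equal-frequency rule applies only to observed words.
* Counting is per token occurrence: a word appearing twice in one
  segment adds 2 to its cell.
* Accuracy is (TP+TN)/total; ratios with zero denominators are reported
  as NaN and excluded from cross-validation means.
* Tokenization: whitespace/!/? always break; a period breaks before
  whitespace; brackets and quotes attached to a word break only when
  the matching character is absent from the word's interior (so
  `P14(ARF)` keeps its parentheses). Tokens with no alphabetic
  character (bare numbers, percentages) are dropped with the stop
  words — the segment vocabulary is meant to carry lexical, not
  numeric, signal.
* Sentence splitting uses an abbreviation-aware rule set (configurable
  list: "et al.", "Fig.", "e.g.", ...; dotted initialisms never break;
  no break inside an open bracket span). The Porter stemmer is
  implemented in-package and validated against the algorithm's
  published vectors.
* Stemming is toggleable per representation because entity-adjacent
  vocabulary is sometimes more informative unstemmed; mention surfaces
  are never stemmed so pattern identity rests on canonical forms.
* Degenerate occurrence combinations whose mentions share a start
  position (cross-type overlaps) are skipped. Evidence tagging nests
  contained cross-type spans (longer outside) and drops partial
  overlaps; detagging restores the input byte-for-byte.

## Synthetic corpus

Real curated corpora with mention-level annotation are not
redistributable, so `methyltext.synth` generates one. Each pattern is
rendered as a clause `<f1> C1 <f2> C2 <f3> C3 <f4>` in one of the six
orders, with filler runs of Poisson(2) length (truncated at 6) drawn
from 60-word class-conditional vocabularies: with probability
(1+s)/2 from the pattern's own class, else from the other, where s is
`vocab_separation`. At s=1 the classes use disjoint (stem-disjoint)
vocabularies; at s=0 both draw from the same mixture and carry no
signal. Multi-pattern sentences concatenate 2–3 clauses with distinct
genes and independent labels; single-pattern sentences optionally
repeat the methylation word (probability 0.25) to exercise
multi-occurrence scoring.

Defaults are fixed at a 51/49 positive/negative pattern balance and a
multi-pattern probability of 0.85, chosen so the expected
patterns-per-sentence ratio matches the ≈2.28 typical of curated
methylation corpora (multi-pattern sentences average 2.5 triples:
1·(1−p) + 2.5·p ≈ 2.28 at p = 0.85). The default corpus size is 400
sentences — small enough for exhaustive oracles and fast
cross-validation, large enough for stable fold metrics.

What the generator does **not** emulate: real syntax and discourse
(negation, coordination scope, anaphora), dictionary noise (ambiguous
gene symbols, missing variants), class-conditional sentence length
effects, and correlated labels across sentences of one abstract.
Passing tests on this corpus therefore demonstrate that the pipeline's
machinery — NER, segmentation, PWM/DTM statistics, routing and
evaluation — is correct and that the representations can carry a
lexical class signal; they say nothing about accuracy on real
literature, which depends on dictionary quality and corpus curation.
Cross-clause triples in multi-clause sentences are real co-occurrences
but carry no gold label; evaluation is restricted to gold patterns.

## Known limitations

* Dictionary coverage bounds recall: an unlisted surface form is
  invisible to the pipeline.
* The shipped concept dictionaries are small demonstration lists, not
  curated resources.
* The DTM route cannot separate mixed-label sentences by construction;
  the hybrid design routes such sentences to the PWM model only when
  more than one pattern is actually recognized.
* Per-segment max aggregation ignores how many informative words a
  segment holds; alternative aggregations (sum, product) are left as a
  configuration hook and not implemented.
* The command-line `evaluate`/`train` protocol assumes the corpus file
  carries gold mentions; extraction from raw text relies on NER and
  inherits its errors.
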