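# methyltext

Aberrant DNA methylation of specific genes is a recurring finding across
cancers and other diseases, and most of the evidence lives in free-text
abstracts. `methyltext` mines such text for **(gene, methylation word,
disease)** associations: it recognizes the three concept types with
dictionary-based longest matching, treats every co-occurring triple in a
sentence (a *pattern*) as a candidate association, and classifies each
pattern as a true (positive) or false (negative) association. It is
aimed at curators building methylation–disease resources and at text
miners interested in order-aware sentence representations.

## The method

**Patterns and orders.** Only triples whose three concepts co-occur in
one sentence are considered. The left-to-right permutation of the three
mentions is the *pattern order*; with three concepts there are six
orders. The three mentions split the sentence into four segments:

```
<segment 1> <gene> <segment 2> <methylation word> <segment 3> <disease> <segment 4>
```

**Position weight matrices over words.** For each class c ∈ {positive,
negative} and each order o, a PWM `W^(c,o)` has one row per word of the
class-c vocabulary and one column per segment. Training increments
`W[w, j]` once per occurrence of word w in segment j of a labeled
pattern occurrence with class c and order o; columns are then
normalized to sum to 1. The class vocabularies come from per-class
document frequencies: word w is positive-class if `F_pos(w) > F_neg(w)`,
negative-class if the inequality reverses, and both if equal. A pattern
occurrence is scored against a PWM of its order by

```
score = Σ_j  max_{w ∈ segment j}  W[w, j]          (j = 1..4)
```

and a pattern in a sentence is represented by **12 features**: its
summed scores against the six positive and six negative PWMs, one slot
per (class, order). Because each pattern is scored through its own
mentions, two patterns in the same sentence get different vectors — a
positive and a negative association can be separated within one
sentence, which a bag-of-words model cannot do.

**Document-term matrix.** Sentences are also represented over
information-gain-selected keywords, as binary, frequency, or
TF-IDF (`tf · ln(N/df)`) with per-column z-scoring.

**Hybrid classification.** A random forest (15 trees by default) over
the DTM rows classifies sentences with exactly one pattern; a second
random forest over the 12 PWM features classifies each pattern of
sentences with several. Sentences without patterns are discarded. A
seeded 30% sentence split builds the dictionaries and PWMs; the
remainder trains the two sub-models.

Pre-processing runs in a fixed order: sentence splitting, tokenization
(punctuation attached to names like `P14(ARF)` stays inside the token),
dictionary NER, stop-word removal, Porter stemming, keyword selection.
Entity surfaces are frozen before stemming.

## Worked example

Labeled corpora with curated mentions are not redistributable, so the
package ships a seeded generator that emulates one: clause-structured
sentences over toy gene/disease/methylation dictionaries with
class-conditional filler vocabularies (see `docs/methods.md`).

```python
from methyltext import SynthConfig, generate, ClassifierConfig, cross_validate

corpus = generate(SynthConfig(n_sentences=400, seed=1))
result = cross_validate(corpus, folds=10, config=ClassifierConfig(seed=1))
for name, value in result["pooled"].items():
    print(f"{name:12s} {value:.3f}")
```

prints the pooled 10-fold metrics over all gold patterns:

```
accuracy     0.897
precision    0.900
recall       0.900
specificity  0.894
fscore       0.900
```

i.e. with fully class-separated filler vocabularies the hybrid model
recovers about 90% of pattern labels. Extraction over new text:

```python
from methyltext import train_hybrid
from methyltext.extract import extract, summary_tsv
from methyltext.synth import toy_dictionaries

model = train_hybrid(corpus, ClassifierConfig(seed=1))
doc = ("Promoter of MIR203 was found methylated in multiple myeloma "
       "cell lines but not methylated in normal controls.")
records, tagged = extract([("pm21693594", doc)], model, toy_dictionaries())
print(summary_tsv(records))
print(tagged["pm21693594"])
```

```
# methyltext summary v1
doc_id	gene	methylation_word	disease	sentence
pm21693594	MIR203	methylated	multiple myeloma	Promoter of MIR203 was found methylated in ...

Promoter of <GENE>MIR203</GENE> was found <METH>methylated</METH> in
<DISEASE>multiple myeloma</DISEASE> cell lines but not
<METH>methylated</METH> in normal controls.
```

The summary table has one row per predicted-positive pattern with its
evidence sentence and document id; the full report tags every mention
(rendered with colors in HTML). The same pipeline is available from the
shell: `methyltext synth | train | evaluate | extract` (see
`methyltext --help`); `extract` also accepts MEDLINE-format abstract
files (PMID/TI/AB fields).

## Corpus file format

One tab-separated record per sentence: `doc_id`, sentence text,
`;`-joined mentions as `type|start|end|canonical` (token spans,
half-open), and `;`-joined pattern labels as `gene|meth|disease|{+,-}`.

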