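# Methods

## The task and the data model

The pipeline classifies interview *records* — all sentences a subject
utters in answer to one interviewer question — by whether they express a
latent need. Three fields matter and are kept strictly apart:

- `marker_flag`: a mechanical candidate indicator, true when the record
  contains one of the expectation adverbs in the marker lexicon
  (default: あるといい, いい, やっぱり, やっぱ, やはり). Marker matching
  is a plain substring test on the raw text: the lexicon is given as
  surface strings, and a short marker embedded in a longer expression
  (いい inside あるといい) must still flag. A token-level matching mode
  exists for analyzers that produce reliable surfaces.
- `annotator_labels`: raw judgements of independent human reviewers.
  `reconcile_labels` promotes unanimous judgements to the gold label and
  reports disagreements for human resolution; it never votes.
- `label`: the gold latent-need label (`yes`/`no`). Classifiers train on
  this field only — the marker is an annotation aid, not a target.

## Tokenization and counting

Tokenization is pluggable behind one contract (text → surface/POS/base
triples). The MeCab adapter (fugashi or mecab-python3) is used when such
a backend is installed; the fixture tokenizer reads pre-tagged
`surface/POS[/base]` text and is what the synthetic generator emits, so
the full pipeline and test suite run without a Japanese analyzer.

Counting unit defaults to **nouns** (POS first field 名詞), since the
downstream document vectors are built over nouns; an `all_morphemes`
mode is available. The morpheme key is the dictionary (base) form when
the analyzer provides one, else the surface, NFC-normalized — this
stabilizes counts across inflection. Per-class count tables carry μ and
σ of the count distribution over the class vocabulary. σ is the
**population** standard deviation (ddof = 0): the vocabulary is the
complete observed distribution being standardized, not a sample from a
larger population; a `ddof=1` variant is exposed for the sample reading.

## Z-score selection

Per class, `Z(m) = (x(m) − μ)/σ`; the selection statistic is
`|Z_A(m) − Z_B(m)|` over the union vocabulary, computed literally as
√((Z_A−Z_B)²) and tested against the algebraic identity. A morpheme
absent from one class receives that class's Z-score at count zero,
(0 − μ)/σ — class-exclusive words are maximally discriminative and must
remain scoreable rather than be dropped. A class with zero count
variance yields all-zero Z-scores with a logged warning; only when both
classes are degenerate is selection impossible and an error raised.

The exclusion threshold "below 25 % of the total" admits three readings,
all implemented:

- `fraction_of_max` (default): threshold = fraction × max score. On
  heavy-tailed count data this excludes aggressively, which is the
  method's stated purpose (removing idiosyncratic noise).
- `quantile`: nearest-rank quantile of the scores (a bottom-quartile cut
  at the default 0.25).
- `absolute`: the fraction value used directly on the score scale.

Ties at the threshold are always kept (exclusion is strict `<`), and
`fraction = 0` keeps everything under every strategy. The default
strategy is a documented choice among ambiguous readings, not a claim
about the original runs; reports embed the strategy and fraction used.

## Vectorization, balancing, splitting

TF–IDF has two dialects. `smooth` (default) is the common-library
standard — idf = ln((1+N)/(1+df)) + 1 with L2 row normalization,
computed by scikit-learn's `TfidfTransformer` — and is the likeliest
match to the original experiments. `raw` is the literal
"tf × inverse document frequency" reading, tf · ln(N/df), unnormalized.
Records sharing no term with the kept vocabulary become zero rows
(logged), never errors.

Undersampling keeps every minority-class record and a seeded uniform
subset of the majority class of equal size. The 70/30 split is
stratified by label with per-class test counts of
⌈0.3 × class size⌉ — this rounding reproduces 686 → 480/206 and
126 → 88/38 exactly, which is why it was adopted. All stage seeds derive
from one top-level seed via `(seed·1000003 + crc32(stage)) mod 2³¹`, so
a run is fully reproducible from one integer.

Two fitting modes exist because the original method order computes
selection and idf on the whole labelled corpus *before* balancing and
splitting. `faithful` (default) reproduces that order; its test
fold has influenced feature fitting (label-independent leakage, a known
property of the design). `strict` fits selection and idf on the training
fold only. Reports state the mode.

## Classifiers

Multinomial naive Bayes (add-one smoothing), SVM (linear kernel —
the convention for TF–IDF text classification — C = 1.0, RBF available
via hyperparameters), and random forest (100 trees, seeded), all via
scikit-learn behind a family/spec surface. The multinomial NB variant on
TF–IDF inputs is itself a choice (Bernoulli would discard weights).
No tuning or cross-validation: the comparison is between single fits
with and without selection, at fixed defaults recorded in every report.
Trained models refuse matrices whose vocabulary fingerprint differs from
the one they were fitted on.

## Evaluation

Positive class is "latent need = yes" throughout. Accuracy, precision,
recall, F = 2PR/(P+R) from the 2×2 confusion matrix; zero denominators
set an explicit flag and report 0 rather than raising. Display rounding
is half away from zero at two decimals, the precision of the published
tables the report layout mirrors. The bundled reference tables
(`refdata.py`) contain the original study's twelve confusion matrices
and published metrics; recomputing the metrics from the matrices
reproduces every published value at two decimals. The published
random-forest table carried an SVM title by an apparent editorial slip;
it is keyed `random_forest` here, as the surrounding results text
identifies it.

## Synthetic corpora

The generator emulates the structure the method assumes, not Japanese
discourse: tokens are symbolic noun tags in the fixture format.
Background words follow a Zipf law (exponent 1.1) shared by both
classes; a small planted set of discriminative words sits at twice the
mean background weight (so both classes observe them reliably) and is
upweighted by `effect` (≥ 1) in the needs class; idiosyncratic words are
each confined to a single record with 1–3 occurrences — deliberately
generating the one-off noise the selection step claims to remove.
Record lengths are negative-binomial (mean 25, dispersion 5, floor 1).
Yes-records embed a marker adverb (tagged 副詞, so it never enters the
noun vocabulary) with probability 0.9, no-records with probability 0.05,
making the marker an imperfect candidate indicator as in real
annotation. Defaults reproduce the caregiver stratum of the original
study (343 needs / 7231 no-needs records); `patient_stratum()` gives
63/2010.

What passing tests show — and do not show: the pipeline recovers planted
word-frequency signal and beats chance on corpora whose classes differ
by iid unigram rates. Real interview transcripts differ in ways the
generator does not model (grammar, discourse structure, topic drift,
correlated word usage, annotation noise), so synthetic results bound
implementation correctness, not real-world performance.

Problem sizes used in the shipped checks were chosen to make the
statistics stable at desk scale: recovery at 200 records per class and
effect 3 (where ≥ 50 % of planted words must reach the top score
decile), and the end-to-end comparison at 250 per class and effect 5
(strong signal; every family must exceed F = 0.65 and the all-yes
baseline on the held-out fold).

## Numerical choices and edge cases

- σ = 0 classes: warn-and-zero, not error (see above).
- Threshold ties: kept. Selection is deterministic for fixed input.
- Split rounding: per-class ceiling, with a 9-decimal pre-round so that
  binary float artifacts (0.3 × 10 → 3.0000000000000004) cannot inflate
  a ceiling.
- Rounding for display: half away from zero, two decimals, via decimal
  arithmetic rather than binary-float `round`.
- Empty test sets predict to empty lists; single-class training data is
  an error.

## Known limitations

- Substring marker matching over-flags records where a marker string
  occurs inside unrelated words; the original annotation resolved such
  cases by human review, which this package represents as label fields,
  not by re-performing it.
- The selection-threshold semantics ("25 % of the total") is ambiguous
  at the source; all three readings are provided, but none is certain to
  match the original computation.
- `faithful` mode leaks test-fold document frequencies into
  feature fitting by design fidelity; use `strict` for honest
  generalization estimates.
- With `fraction_of_max` on heavy-tailed synthetic data the kept
  vocabulary can be very small; the quantile strategy gives gentler,
  size-predictable retention.
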