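# Methods

This note documents the models, the synthetic data they are exercised on,
the defaults and the numerical conventions, in enough detail to rederive
every computed quantity. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The synthetic EHR generator

### Generative model

A record is sampled as follows. A primary disease class is drawn from the
class priors; with class-specific probability a comorbid secondary class
is added (its phenotypes are emitted at 0.6 × their native rates, and the
secondary label is recorded; the primary label remains the prediction
target). Each concept in the vocabulary is then emitted independently with
the class's emission probability, attributes are sampled per mention, and
each mention is rendered through a sentence template into its home section
(chief complaint, history of present illness, physical examination,
imaging findings, lab findings), with the sentence order shuffled within a
section. Rendering records a gold character span, category and attribute
map for every mention. All randomness flows from a single seed through one
`numpy` generator, so equal configurations give byte-identical corpora.

The vocabulary has 100+ concepts across all six entity categories:

* **Shared symptoms** (cough, fever, dyspnea, ...) emitted by ≥5 classes
  at rates ≥0.3. At overlap `o`, a class's rate is `(1−o)·base + o·mean`,
  so `o=1` equalizes shared-symptom rates across the classes that list
  them.
* **Signature concepts**, five per class at emission 0.85. At overlap
  `o>0` each class's signatures leak into a designated confusion partner
  at `0.3·o` (pulmonary infection ↔ COPD, lung cancer ↔ tuberculosis,
  ...), reproducing the clinically observed confusability; at `o=0`
  signatures are class-exclusive.
* **Composite findings** (pulmonary nodule, lung mass) emitted at 0.8 by
  both lung cancer and tuberculosis — the shared radiological presentation
  behind the two-step diagnostic path.
* **Attribute-signal concepts**, each emitted at 0.8 by a pair of classes
  that differ mainly in assertion: `P(negated) = negation_rate · w` with
  `w = 0.05` in the class where the finding is typically present and
  `w = 0.95` in its partner. Shared symptoms carry a generic `w = 0.25`.
  The global `negation_rate` (default 0.6) therefore scales all negation;
  at 0 no span is negated.
* **Polysemous surfaces**: pairs of concepts (an image finding and a lab
  test) that share the same surface strings; the sense is determined by
  the section in which the mention is rendered. These exist to give
  category-aware normalization information that a flattened bag of tokens
  cannot recover; the default corpus does not emit them.

Each concept has several lexically disjoint surface forms (curated
clinical synonyms plus deterministically generated pseudo-Latin terms),
emulating the surface variability that terminology standardization
collapses. Two template dialects exercise both tokenizer contracts:
`latin-pseudo` (whitespace-delimited) and `zh-pseudo` (continuous script
rendered from a CJK character bank, no delimiters; negation and modifier
triggers are single- or two-character prefixes).

Defaults: class priors qualitatively mirror an imbalanced admissions
corpus (largest class ≈ 0.20 = COPD, smallest ≈ 0.02 = pulmonary
hypertension); `overlap = 0.1`; `distractor_rate = 0.1` (up to two
mentions drawn from other classes' concepts); `negation_rate = 0.6`;
comorbidity infection→COPD 0.25 and COPD→infection 0.15. The corpus is
split 80/20 by largest-remainder allocation stratified on the primary
label, so the total test share is exactly 20% and per-class test counts
deviate from 4:1 by less than one record.

### The attribute-signal probe corpus

The representation ablation needs a corpus in which the three feature
families are *informationally* separated, not merely statistically. Its
profiles are built so that:

1. the ten classes form five pairs with *identical* emission profiles;
   inside a pair only the assertion distribution of one discriminative
   concept differs (w = 0.03 vs 0.97). Concept presence cannot separate
   pair members; assertion-aware features can.
2. between pair groups, the dominant evidence is carried by the polysemous
   surfaces: every class emits every polysemous surface at the same rate
   (0.7), and a binary code over the groups decides whether the mention
   appears in the imaging or the lab section. Token counts are therefore
   exactly label-independent, while category-resolved concepts encode the
   group. Signature concepts remain only as faint flavour (0.08,
   pair-symmetric), and the pair concepts are emitted by every class.
3. expected negation-trigger counts are balanced across all classes by
   tuning each class's generic negation weight, so raw trigger frequencies
   carry no label signal either; only the *binding* of negation to a
   specific concept is informative.

This construction is what licenses the qualitative claim the ablation
reproduces: fine-grained assertion-aware features outperform coarse
concept presence, which outperforms a bag-of-words text baseline.

### What the generator does not emulate

Realistic clinical language, discourse structure, numeric laboratory
values, nested or discontinuous mentions, misspellings, inter-annotator
disagreement, and concept drift between sites. Passing tests demonstrate
that the pipeline's machinery is correct and that the representation
effects exist when their preconditions hold; they say nothing about
absolute performance on real records.

## 2. Entity recognition

Tokenization is contract-based: `whitespace` splits on whitespace runs,
`character` emits one token per non-space character (the
continuous-script-compatible mode). BIO encoding requires spans to align
to token boundaries and to be non-overlapping; decoding turns maximal
`B-x (I-x)*` runs into spans and repairs a stray `I-x` to `B-x` (it opens
a new span) — a deliberate, documented repair rule.

The tagger is an exact linear-chain CRF over 13 tags. Emissions come from
a linear scorer over hashed lexical features (token identity, cased and
lowered; 3-character prefix and suffix; digit flag; token identities at
offsets ±1, ±2; 2^18 hash buckets via CRC-32). Transitions, start and end
potentials are dense. Training maximizes the conditional log-likelihood
by per-sequence adagrad ascent (base step 0.5) on deduplicated sequences
weighted by multiplicity — templated clinical text repeats heavily, and
dedup makes training cost scale with unique sentences. After each epoch
the training loss is re-evaluated: an epoch that worsens it is rolled
back and the step size halved, so the loss over accepted epochs is
non-increasing. Early stopping monitors token accuracy on a held-out 10%
of unique sequences (patience 2, at most 6–8 epochs). With zero epochs the
model equals its all-zero initialization. All stochastic steps take an
explicit seed; the package default is 20190401.

Numerical conventions: the forward recursion and Viterbi run in log space;
Viterbi ties break toward the lowest tag index at every backtrack step, so
decoding is deterministic. Invalid BIO transitions (into `I-x` from
anything but `B-x`/`I-x`) are soft by default; an optional hard mask sets
them to −10^30 (a large finite value avoids `inf − inf` in the
recursions). Span evaluation is exact-match on (section, offsets,
category) — partial-overlap credit was rejected for determinism — with
per-category P/R/F1 and an unweighted macro over categories present in the
gold standard.

## 3. Normalization and deep phenotyping

Surface normalization applies NFKC (mapping full-width characters to
half-width), case folding, surrounding-punctuation stripping and
whitespace collapsing, iterated to a fixpoint so the function is
idempotent by construction. The lexicon maps (normalized surface,
category) → concept id; duplicate rows and conflicting preferred names are
load-time errors; unmapped surfaces are counted and dropped from feature
construction.

Attribute attachment is deliberately deterministic rather than mined: a
trigger occurrence assigns its value to the *nearest* phenotype-bearing
span in the rule's direction within `scope_window` tokens and the same
sentence; a span keeps at most one value per attribute (nearest trigger
wins; exact ties go to the preceding trigger); unattachable triggers are
dropped and counted. Trigger matching concatenates normalized token
surfaces, which makes multi-character triggers work identically for word
and character tokenization. The attribute schema has ten configurable
slots (assertion, severity, temporality, duration, laterality, body site,
trend, frequency, trigger, quantifier); the bundled rules and generator
exercise assertion, severity and temporality.

Feature encodings: coarse = binary concept presence over a fixed
vocabulary. Fine = a presence block plus one indicator per concept ×
(attribute, value) pair; dimension `C + C·Σ_a |values_a|`. The encoding is
assertion-aware: a negated mention sets its `assertion=negated` indicator
and leaves the bare presence bit clear, so fine restricted to the presence
block equals coarse exactly when nothing is negated.

## 4. Classification

SMOTE: synthetic minority samples `x_i + λ(x_nn − x_i)` with
`λ ~ U(0,1)` and `x_nn` among the `k = 5` nearest same-class neighbours
(Euclidean); every class is raised to the majority count; originals are
preserved verbatim; a single-sample class is an error naming the class.
Neither k nor the target is prescribed by a source, so both are
configurable. SMOTE lives inside the classifier's `fit`, which is what
structurally confines it to training folds under cross-validation.

The classifier contract is any seeded probabilistic multi-class learner;
the default is LightGBM (200 trees, learning rate 0.1, 31 leaves,
min_child_samples 5, single thread, deterministic mode). Probabilities
are reported over a fixed 10-class universe (absent classes get zero
mass) and renormalized; rankings sort by descending probability with ties
broken by ascending class id.

Two-step path: stage 1 classifies into 9 merged classes with lung cancer
and tuberculosis pooled as "lung space-occupying lesions"; when the
composite class is ranked first, a binary subclassifier over fine features
(trained on cancer/TB records only) supplies the reported subtype label;
otherwise the ranking is unchanged. The refinement triggers on composite
top-1 only — the trigger condition was an open design point and this is
the narrowest reading. The default pipeline classifies the ten diseases
directly; the two-step path is optional because a ranking over a mixed
(9 merged + 2 subtype) space would not admit a single coherent
probability vector.

## 5. Evaluation battery

* `prf_from_counts`: P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R);
  undefined ratios return 0 with an explicit flag. Macro averages are
  unweighted means over classes present in the gold standard. Note that a
  macro F1 (mean of per-class F1s) deliberately does not satisfy the
  harmonic-mean identity of the macro P and macro R.
* **Top-k credit rule** (k > 1): a record is a true positive for its true
  class when the true class appears anywhere in the top k; otherwise it is
  a false negative for the true class and a false positive for the
  first-ranked class. This "containment credit" reading was chosen
  because it is the standard one and it makes both precision and recall
  rise from top-1 to top-3; per-class top-k recall is provably monotone in
  k. Confusion matrices follow the same rule (top-k column = true class
  when contained, else first-ranked class), so entries always sum to the
  record count.
* **AUROC**: one-vs-rest via the Mann–Whitney rank statistic with average
  ranks (ties get half credit); degenerate classes are excluded from the
  unweighted macro with a warning.
* **Bootstrap**: record-level resampling with replacement (default
  B = 1000, percentiles 2.5/97.5, seeded); stratified resampling was
  rejected in favour of plain resampling of the test set. Resamples where
  the statistic is undefined are skipped; more than 10% undefined is an
  error.
* **Cross-validation**: stratified k-fold (default 10) with shuffling;
  infeasible stratification (a class smaller than the fold count) is an
  explicit error; per-fold metrics are reported with their mean and sample
  standard deviation (ddof = 1).
* **Wilcoxon signed-rank**: zero differences dropped; statistic W+ = sum
  of positive-difference ranks with average ranks for tied magnitudes;
  exact null by enumerating all 2^n sign assignments for n ≤ 12, otherwise
  a normal approximation with tie correction
  (σ² = n(n+1)(2n+1)/24 − Σ(t³−t)/48) and continuity correction (zero at
  W+ = n(n+1)/4, matching the exact p of 1). Two-sided by default;
  one-sided alternatives available.

## 6. Ablation design

Three arms share one corpus and one stratified fold partition (verified by
a fold-assignment hash): `baseline-bow` (unigram counts over the
concatenated section text — the desk-scale stand-in for a deep text
classifier baseline), `coarse`, and `fine`. The entity recognizer used by
the feature arms is trained on a *separate* 600-record annotated corpus
drawn from the same generative model with an independent seed, mirroring
the practice of annotating a dedicated NER corpus and preventing
validation folds from leaking into NER training; the trained tagger is
shared across arms and replicates. Reported: per-arm per-fold macro F1 at
top-1 and top-3, arm means, pairwise deltas, and fold-paired two-sided
Wilcoxon p-values. A label-shuffle null control drops every arm to chance
and de-rejects the pairwise tests. Replicates regenerate the corpus with
derived seeds and compare arms on the corpus's own 80/20 split.

The probe corpus keeps the default imbalanced priors at n = 800 — large
enough that the rarest class (prior ≈ 0.02, ~17 expected records)
supports the stratified folds — and the acceptance battery runs 5
replicates (the full 20-replicate run is
`run_ablation_replicates(config, n_replicates=20)`).

## 7. Problem sizes and determinism

The acceptance battery uses the 2000-record default corpus for the
end-to-end learnability check and n = 800 for the ablation; the package's
own tests use 300–2000-record corpora. Every stage seeds its randomness
from a single master seed via fixed derivations, and configuration hashes
(SHA-256 of the canonical config JSON) are recorded in run manifests
together with all derived seeds, so identical configurations reproduce
identical outputs byte for byte (timestamps live only in logs).

## 8. Known limitations

The emission scorer is lexical; there is no recurrent or transformer
encoder, so absolute NER numbers on natural text would be lower. The
lexicon is exact-match after normalization (no fuzzy matching, no real
UMLS/ICD integration). Attribute attachment is rule-based and windowed;
long-range or discourse-level assertion is out of scope. Probabilities
are not calibrated. The synthetic corpus's separability means absolute
metric values are optimistic; only the *relative* statements (ablation
ordering, monotonicity, oracle equivalences) are intended to transfer.
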