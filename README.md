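# respdx

Ranked differential diagnosis of respiratory diseases from sectioned
clinical notes, built as a fully inspectable pipeline: clinical named-entity
recognition with an exact linear-chain CRF, terminology normalization with
deep-phenotype attributes (assertion/negation, severity, temporality, ...),
SMOTE-rebalanced gradient-boosted classification over ten disease classes
with top-k output, and a complete evaluation battery (top-1/top-3
precision/recall/F1, confusion matrices, one-vs-rest AUROC with percentile
bootstrap intervals, stratified 10-fold cross-validation, Wilcoxon
signed-rank comparisons).

The package is aimed at clinical-NLP researchers who want a desk-scale,
reproducible harness for studying how *representation granularity* affects
diagnostic classification: a bag-of-words text baseline, coarse
concept-presence features, and fine-grained assertion-aware
concept-by-attribute features are compared on identical cross-validation
folds. Real clinical corpora are access-controlled, so the package ships a
synthetic sectioned-EHR generator with known generative structure (gold
entity spans, gold attributes, gold diagnoses) that makes every stage
testable end to end.

## The models in brief

**Sequence labeling.** Entity mentions in six categories (disease names,
symptoms, quantitative and qualitative tests, image findings, medications,
surgical procedures) are tagged with a BIO schema (13 tags). A path
y over L tokens is scored by a linear-chain CRF,

    s(y) = start[y_1] + Σ_t E[t, y_t] + Σ_t T[y_{t-1}, y_t] + end[y_L],

with emissions E from a hashed-feature linear scorer trained jointly with
T by gradient ascent on the conditional log-likelihood log p(y|x) =
s(y) − log Z, where log Z comes from the forward recursion and decoding
from Viterbi (deterministic tie-breaks). Forward and Viterbi are verified
against exhaustive path enumeration.

**Deep phenotyping.** Mentions are normalized to canonical concepts by
category-scoped lexicon lookup (synonyms collapse to one concept id) and
attributes are attached by trigger rules: the nearest phenotype-bearing
span within a token window, never across a sentence boundary. The fine
representation encodes concept × attribute-value indicators and is
assertion-aware: "denies hemoptysis" sets the negated indicator, not the
presence indicator.

**Classification.** x_new = x_i + λ(x_nn − x_i), λ ~ U(0,1), interpolates
synthetic minority samples inside training folds only (SMOTE); a seeded
LightGBM classifier produces per-class probabilities; predictions are
ranked with deterministic tie-breaks for top-k evaluation. An optional
two-step path first pools lung cancer and pulmonary tuberculosis into a
composite "lung space-occupying lesions" class and refines composite top-1
calls with a dedicated binary subclassifier.

## Worked example

Run the full pipeline on a deliberately ambiguous corpus (600 records,
high symptom overlap between classes, 30% distractor mentions):

```python
from respdx.pipeline import PipelineConfig, run_pipeline

config = PipelineConfig(n_records=600, overlap=0.6, distractor_rate=0.3,
                        bootstrap_B=200, seed=7)
result = run_pipeline(config)
print(result.metrics["ner_span_prf"]["macro"])   # (1.0, 1.0, 1.0)
print(result.metrics["top1"]["macro"])
# {'precision': 0.964, 'recall': 0.958, 'f1': 0.959}
print(result.metrics["top3"]["macro"])
# {'precision': 1.0, 'recall': 1.0, 'f1': 1.0}
print(result.metrics["macro_auroc"])             # 0.999, CI [0.996, 1.0]
```

Reading: the tagger recovers every gold span exactly (surfaces are
templated, so span-level F1 reaches 1.0); even with heavy class overlap
the fine-grained classifier places the true disease first for ~96% macro
F1, and the correct diagnosis is always within the top 3. The macro AUROC
interval comes from 200 record-level bootstrap resamples.

The representation ablation on the attribute-signal corpus (negation flips
class meaning; token counts carry no label signal by construction):

```bash
respdx ablate --n-records 800 --folds 10 --seed 11
```

prints per-arm top-1 macro F1 means near 0.25 (bag-of-words), 0.49
(coarse) and 0.66 (fine), with fold-paired Wilcoxon p ≈ 0.002 for fine vs
coarse — the qualitative ordering fine > coarse > baseline that motivates
fine-grained phenotyping.

The same functionality is exposed on the command line: `respdx synth`,
`respdx ner train|predict|eval`, `respdx diagnose train|predict`,
`respdx eval`, `respdx ablate`, `respdx run-all` (see `--help` on each).

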