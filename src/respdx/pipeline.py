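"""End-to-end orchestration: generate -> NER -> normalize -> features ->
(SMOTE) -> classify -> evaluate, plus the three-arm ablation design.

The ablation compares, on identical cross-validation folds:

* ``baseline-bow`` — bag-of-words over the raw note text (the desk-scale
  stand-in for a deep text classifier baseline), same classifier;
* ``coarse``       — concept-presence features after entity recognition
  and terminology normalization;
* ``fine``         — assertion-aware concept x attribute features.

Entity recognition for the feature-based arms is trained on a separate
annotated corpus (drawn from the same generative model with an independent
seed) and applied to the analysis corpus, so validation folds never leak
into NER training.  SMOTE lives inside the classifier's ``fit`` and
therefore only ever sees training folds.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer

from . import diseases
from .diagnose import DiagnosisClassifier, _rank_entries
from .evaluate import (
    BootstrapSpec,
    CVSpec,
    TopKOutcome,
    bootstrap_ci,
    confusion_matrix,
    roc_auc_ovr,
    topk_metrics,
    wilcoxon_signed_rank,
)
from .io import record_sequences, write_corpus_jsonl
from .ner import CRFTagger, predict_entities, span_prf, tokenize
from .normalize import (
    FineVectorizer,
    CoarseVectorizer,
    attach_attributes_counted,
    map_to_concept,
)
from .synth import (
    AnnotatedRecord,
    SynthConfig,
    build_attribute_signal_profiles,
    build_default_profiles,
    default_attribute_rules,
    default_lexicon,
    generate_corpus,
)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "AblationReport",
    "run_pipeline",
    "run_ablation",
    "run_ablation_replicates",
]

REPRESENTATIONS = ("baseline-bow", "coarse", "fine")


def _derive_seed(seed: int, offset: int) -> int:
    return int((seed * 1_000_003 + offset) % (2**31 - 1))


@dataclass(frozen=True)
class PipelineConfig:
    """Everything that determines a run; hashable into a manifest."""

    n_records: int = 2000
    overlap: float = 0.1
    negation_rate: float = 0.6
    distractor_rate: float = 0.1
    template_language: str = "latin-pseudo"
    profile_kind: str = "default"  # default | attribute-signal
    representation: str = "fine"
    smote: bool = True
    use_gold_spans: bool = False
    topk: int = 3
    bootstrap_B: int = 1000
    ner_max_epochs: int = 6
    ner_train_records: int = 600
    n_estimators: int = 200
    seed: int = 20190401
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.representation not in REPRESENTATIONS:
            raise ValueError(f"representation must be one of {REPRESENTATIONS}")
        if self.profile_kind not in ("default", "attribute-signal"):
            raise ValueError(f"unknown profile_kind {self.profile_kind!r}")

    def synth_config(self, n_records: int | None = None, seed_offset: int = 0) -> SynthConfig:
        return SynthConfig(
            n_records=n_records or self.n_records,
            negation_rate=self.negation_rate,
            distractor_rate=self.distractor_rate,
            template_language=self.template_language,
            overlap=self.overlap,
            seed=_derive_seed(self.seed, seed_offset),
        )

    def profiles(self):
        if self.profile_kind == "attribute-signal":
            return build_attribute_signal_profiles(self.overlap)
        return build_default_profiles(self.overlap)

    def manifest(self, extra: dict | None = None) -> dict:
        cfg = asdict(self)
        blob = json.dumps(cfg, sort_keys=True).encode()
        man = {
            "config": cfg,
            "config_sha256": hashlib.sha256(blob).hexdigest(),
            "seeds": {
                "corpus": _derive_seed(self.seed, 0),
                "ner_corpus": _derive_seed(self.seed, 1),
                "ner_train": _derive_seed(self.seed, 2),
                "classifier": _derive_seed(self.seed, 3),
                "bootstrap": _derive_seed(self.seed, 4),
            },
        }
        if extra:
            man.update(extra)
        return man


@dataclass
class PipelineResult:
    metrics: dict
    manifest: dict
    outcomes: list[TopKOutcome]
    ner_span_prf: dict | None = None


def _train_ner(config: PipelineConfig) -> CRFTagger:
    """Train the tagger on an auxiliary annotated corpus (independent seed)."""
    synth = config.synth_config(n_records=config.ner_train_records, seed_offset=1)
    profiles = config.profiles()
    train, _ = generate_corpus(synth, profiles)
    dialect = synth.tokenizer_dialect
    X, y = [], []
    for r in train:
        for tokens, tags in record_sequences(r, dialect):
            X.append([t.text for t in tokens])
            y.append(tags)
    tagger = CRFTagger(
        max_epochs=config.ner_max_epochs, seed=_derive_seed(config.seed, 2)
    )
    tagger.fit(X, y)
    return tagger


def _record_phenotypes(
    record: AnnotatedRecord,
    spans,
    lexicon,
    rules,
    dialect: str,
) -> tuple[list, int, int]:
    """Normalize one record's spans; returns (phenotypes, unmapped, dropped)."""
    phenos = []
    unmapped = 0
    dropped = 0
    by_section: dict[str, list] = {}
    for s in spans:
        by_section.setdefault(s.section, []).append(s)
    for section, sec_spans in sorted(by_section.items()):
        tokens = tokenize(record.sections[section], dialect)
        sec_sorted = sorted(sec_spans, key=lambda s: (s.start, s.end))
        concept_for_span = {}
        for i, s in enumerate(sec_sorted):
            cid = map_to_concept(s, lexicon)
            if cid is None:
                unmapped += 1
                cid = f"unmapped:{s.surface}"
            concept_for_span[i] = cid
        sec_phenos, d = attach_attributes_counted(
            sec_sorted, rules, tokens, concept_for_span
        )
        dropped += d
        phenos.extend(p for p in sec_phenos
                      if not p.concept_id.startswith("unmapped:"))
    return phenos, unmapped, dropped


def _phenotype_features(
    config: PipelineConfig,
    train: Sequence[AnnotatedRecord],
    test: Sequence[AnnotatedRecord],
    tagger: CRFTagger | None,
):
    """Spans -> phenotypes -> feature matrices for both splits."""
    dialect = "whitespace" if config.template_language == "latin-pseudo" else "character"
    lexicon = default_lexicon(config.template_language)
    rules = default_attribute_rules(config.template_language)
    telemetry = {"unmapped_surfaces": 0, "dropped_triggers": 0}

    def spans_of(record):
        if config.use_gold_spans or tagger is None:
            return record.gold_spans
        return predict_entities(record, tagger, dialect)

    pheno_rows = {}
    for split, records in (("train", train), ("test", test)):
        rows = []
        for r in records:
            phenos, unmapped, dropped = _record_phenotypes(
                r, spans_of(r), lexicon, rules, dialect
            )
            telemetry["unmapped_surfaces"] += unmapped
            telemetry["dropped_triggers"] += dropped
            rows.append(phenos)
        pheno_rows[split] = rows

    concepts = lexicon.concept_ids
    if config.representation == "coarse":
        vec = CoarseVectorizer(concepts=concepts).fit(pheno_rows["train"])
    else:
        vec = FineVectorizer(concepts=concepts).fit(pheno_rows["train"])
    X_train = vec.transform(pheno_rows["train"])
    X_test = vec.transform(pheno_rows["test"])
    return X_train, X_test, vec, telemetry


def _bow_features(
    config: PipelineConfig,
    train: Sequence[AnnotatedRecord],
    test: Sequence[AnnotatedRecord],
):
    analyzer = "word" if config.template_language == "latin-pseudo" else "char"
    vec = CountVectorizer(
        analyzer=analyzer, token_pattern=r"(?u)\b\w+\b" if analyzer == "word" else None,
        lowercase=True,
    )
    joiner = " \n ".join if config.template_language == "latin-pseudo" else "\n".join

    def texts(records):
        return [joiner([r.sections[s] for s in sorted(r.sections)]) for r in records]

    X_train = vec.fit_transform(texts(train)).toarray().astype(float)
    X_test = vec.transform(texts(test)).toarray().astype(float)
    return X_train, X_test, vec


def _outcomes_from_proba(
    records: Sequence[AnnotatedRecord], proba: np.ndarray, classes: Sequence[int]
) -> list[TopKOutcome]:
    out = []
    for r, p in zip(records, proba):
        entries = _rank_entries(list(classes), list(p))
        out.append(
            TopKOutcome(
                record_id=r.record_id,
                true_class=r.primary_label,
                ranked=tuple(c for c, _ in entries),
            )
        )
    return out


def _evaluate_split(
    records: Sequence[AnnotatedRecord],
    proba: np.ndarray,
    classes: Sequence[int],
    bootstrap_B: int,
    seed: int,
) -> tuple[dict, list[TopKOutcome]]:
    outcomes = _outcomes_from_proba(records, proba, classes)
    y_true = [r.primary_label for r in records]
    top1 = topk_metrics(outcomes, 1, classes)
    top3 = topk_metrics(outcomes, 3, classes)
    aucs, macro_auc = roc_auc_ovr(y_true, proba, classes)
    idx = np.arange(len(records))

    def macro_auc_stat(sample_idx):
        s = np.asarray(sample_idx, dtype=int)
        _, m = roc_auc_ovr(np.asarray(y_true)[s], proba[s], classes)
        return m

    import warnings as _w

    with _w.catch_warnings():
        _w.simplefilter("ignore")
        point, lo, hi = bootstrap_ci(
            macro_auc_stat, list(idx), BootstrapSpec(B=bootstrap_B, seed=seed)
        )
    metrics = {
        "top1": top1,
        "top3": top3,
        "auroc_per_class": {int(c): aucs[c] for c in classes},
        "macro_auroc": macro_auc,
        "macro_auroc_ci": [lo, hi],
        "confusion_top1": confusion_matrix(outcomes, 1).tolist(),
        "confusion_top3": confusion_matrix(outcomes, 3).tolist(),
        "n_test": len(records),
    }
    return metrics, outcomes


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline once and evaluate on the held-out split."""
    profiles = config.profiles()
    train, test = generate_corpus(config.synth_config(seed_offset=0), profiles)
    dialect = "whitespace" if config.template_language == "latin-pseudo" else "character"
    stages = ["synth"]
    telemetry: dict = {}
    ner_prf = None

    if config.representation == "baseline-bow":
        X_train, X_test, _ = _bow_features(config, train, test)
        stages.append("bow-features")
    else:
        tagger = None
        if not config.use_gold_spans:
            tagger = _train_ner(config)
            stages.append("ner-train")
            pred = [predict_entities(r, tagger, dialect) for r in test]
            gold = [r.gold_spans for r in test]
            ner_prf = {
                cat: list(vals) for cat, vals in span_prf(gold, pred).items()
            }
        X_train, X_test, _, telemetry = _phenotype_features(config, train, test, tagger)
        stages.extend(["normalize", f"{config.representation}-features"])

    clf = DiagnosisClassifier(
        classes=range(diseases.N_CLASSES),
        smote=config.smote,
        n_estimators=config.n_estimators,
        seed=_derive_seed(config.seed, 3),
    )
    clf.fit(X_train, [r.primary_label for r in train])
    stages.append("classify" + ("+smote" if config.smote else ""))
    proba = clf.predict_proba(X_test)
    metrics, outcomes = _evaluate_split(
        test, proba, list(range(diseases.N_CLASSES)),
        config.bootstrap_B, _derive_seed(config.seed, 4),
    )
    if ner_prf is not None:
        metrics["ner_span_prf"] = ner_prf
    stages.append("evaluate")

    manifest = config.manifest({"stages": stages, "telemetry": telemetry})
    result = PipelineResult(
        metrics=metrics, manifest=manifest, outcomes=outcomes, ner_span_prf=ner_prf
    )
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_corpus_jsonl(train, out / "train.jsonl")
        write_corpus_jsonl(test, out / "test.jsonl")
        (out / "metrics.json").write_text(
            json.dumps(metrics, indent=2, sort_keys=True), encoding="utf-8"
        )
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
        )
    return result


# ---------------------------------------------------------------------------
# ablation
# ---------------------------------------------------------------------------


@dataclass
class AblationReport:
    """Fold-paired comparison of the three representation arms."""

    per_arm_fold_f1_top1: dict[str, list[float]]
    per_arm_fold_f1_top3: dict[str, list[float]]
    arm_means_top1: dict[str, float]
    arm_means_top3: dict[str, float]
    deltas_top1: dict[str, float]
    deltas_top3: dict[str, float]
    wilcoxon_p: dict[str, float]
    fold_hash: str
    manifest: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _fold_macro_f1(outcomes: list[TopKOutcome], classes) -> tuple[float, float]:
    t1 = topk_metrics(outcomes, 1, classes)["macro"]["f1"]
    t3 = topk_metrics(outcomes, 3, classes)["macro"]["f1"]
    return t1, t3


def run_ablation(
    config: PipelineConfig,
    cv: CVSpec | None = None,
    shuffle_labels: bool = False,
    tagger: CRFTagger | None = None,
) -> AblationReport:
    """Train and evaluate all three arms on identical stratified folds.

    ``shuffle_labels`` permutes the labels once before folding (a null
    control: every arm should fall to chance and pairwise tests should not
    reject).  A pre-trained ``tagger`` may be supplied to share NER cost
    across replicates; otherwise one is trained on the auxiliary corpus.
    """
    cv = cv or CVSpec(folds=10, seed=_derive_seed(config.seed, 7))
    profiles = config.profiles()
    train, test = generate_corpus(config.synth_config(seed_offset=0), profiles)
    records = train + test
    y = np.array([r.primary_label for r in records])
    if shuffle_labels:
        rng = np.random.default_rng(_derive_seed(config.seed, 8))
        y = y[rng.permutation(len(y))]

    if tagger is None and not config.use_gold_spans:
        tagger = _train_ner(config)

    arm_X: dict[str, np.ndarray] = {}
    bow_cfg = replace(config, representation="baseline-bow")
    Xb_train, Xb_test, _ = _bow_features(bow_cfg, train, test)
    arm_X["baseline-bow"] = np.vstack([Xb_train, Xb_test])
    for arm in ("coarse", "fine"):
        arm_cfg = replace(config, representation=arm)
        Xt, Xs, _, _ = _phenotype_features(arm_cfg, train, test, tagger)
        arm_X[arm] = np.vstack([Xt, Xs])

    from sklearn.model_selection import StratifiedKFold

    splitter = StratifiedKFold(n_splits=cv.folds, shuffle=True, random_state=cv.seed)
    folds = list(splitter.split(np.zeros(len(y)), y))
    fold_hash = hashlib.sha256(
        json.dumps([sorted(map(int, v)) for _, v in folds]).encode()
    ).hexdigest()

    classes = list(range(diseases.N_CLASSES))
    f1_top1: dict[str, list[float]] = {a: [] for a in REPRESENTATIONS}
    f1_top3: dict[str, list[float]] = {a: [] for a in REPRESENTATIONS}
    for train_idx, val_idx in folds:
        for arm in REPRESENTATIONS:
            X = arm_X[arm]
            clf = DiagnosisClassifier(
                classes=classes, smote=config.smote,
                n_estimators=config.n_estimators,
                seed=_derive_seed(config.seed, 3),
            )
            clf.fit(X[train_idx], y[train_idx])
            proba = clf.predict_proba(X[val_idx])
            outcomes = [
                TopKOutcome(
                    record_id=records[i].record_id,
                    true_class=int(y[i]),
                    ranked=tuple(
                        c for c, _ in _rank_entries(classes, list(p))
                    ),
                )
                for i, p in zip(val_idx, proba)
            ]
            t1, t3 = _fold_macro_f1(outcomes, classes)
            f1_top1[arm].append(t1)
            f1_top3[arm].append(t3)

    means1 = {a: float(np.mean(v)) for a, v in f1_top1.items()}
    means3 = {a: float(np.mean(v)) for a, v in f1_top3.items()}
    deltas1 = {
        "fine-coarse": means1["fine"] - means1["coarse"],
        "coarse-baseline": means1["coarse"] - means1["baseline-bow"],
        "fine-baseline": means1["fine"] - means1["baseline-bow"],
    }
    deltas3 = {
        "fine-coarse": means3["fine"] - means3["coarse"],
        "coarse-baseline": means3["coarse"] - means3["baseline-bow"],
        "fine-baseline": means3["fine"] - means3["baseline-bow"],
    }
    wilcoxon = {}
    for name, (a, b) in {
        "fine-vs-coarse": ("fine", "coarse"),
        "coarse-vs-baseline": ("coarse", "baseline-bow"),
        "fine-vs-baseline": ("fine", "baseline-bow"),
    }.items():
        try:
            _, p = wilcoxon_signed_rank(f1_top1[a], f1_top1[b])
        except ValueError:
            p = 1.0
        wilcoxon[name] = p

    return AblationReport(
        per_arm_fold_f1_top1=f1_top1,
        per_arm_fold_f1_top3=f1_top3,
        arm_means_top1=means1,
        arm_means_top3=means3,
        deltas_top1=deltas1,
        deltas_top3=deltas3,
        wilcoxon_p=wilcoxon,
        fold_hash=fold_hash,
        manifest=config.manifest({"shuffle_labels": shuffle_labels}),
    )


def run_ablation_replicates(
    config: PipelineConfig, n_replicates: int = 5
) -> dict:
    """Seeded replicates of the arm ordering on fresh corpora.

    Each replicate regenerates the corpus with a new seed and compares the
    arms on the corpus's own 80/20 split (cheaper than full CV); the shared
    NER model is trained once on the auxiliary corpus.  Returns the count
    of replicates with the strict ordering fine > coarse > baseline on
    top-1 macro F1.
    """
    tagger = None if config.use_gold_spans else _train_ner(config)
    classes = list(range(diseases.N_CLASSES))
    orderings = []
    per_replicate = []
    for rep in range(n_replicates):
        rep_cfg = replace(config, seed=_derive_seed(config.seed, 100 + rep))
        profiles = rep_cfg.profiles()
        train, test = generate_corpus(rep_cfg.synth_config(seed_offset=0), profiles)
        y_train = [r.primary_label for r in train]
        scores = {}
        for arm in REPRESENTATIONS:
            arm_cfg = replace(rep_cfg, representation=arm)
            if arm == "baseline-bow":
                Xt, Xs, _ = _bow_features(arm_cfg, train, test)
            else:
                Xt, Xs, _, _ = _phenotype_features(arm_cfg, train, test, tagger)
            clf = DiagnosisClassifier(
                classes=classes, smote=config.smote,
                n_estimators=config.n_estimators,
                seed=_derive_seed(rep_cfg.seed, 3),
            )
            clf.fit(Xt, y_train)
            proba = clf.predict_proba(Xs)
            outcomes = _outcomes_from_proba(test, proba, classes)
            scores[arm], _ = _fold_macro_f1(outcomes, classes)
        per_replicate.append(scores)
        orderings.append(
            scores["fine"] > scores["coarse"] > scores["baseline-bow"]
        )
    return {
        "n_replicates": n_replicates,
        "ordering_holds": int(sum(orderings)),
        "per_replicate": per_replicate,
    }
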