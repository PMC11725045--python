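"""Evaluation battery for ranked multi-class diagnosis.

Implements top-1/top-3 precision, recall and F1 with macro averaging,
confusion matrices, one-vs-rest ROC AUC via the rank statistic, percentile
bootstrap confidence intervals, stratified k-fold cross-validation with
leakage-safe wiring, and the Wilcoxon signed-rank test (exact null by
enumeration for small n, tie-corrected normal approximation otherwise).

Top-k credit rule (k > 1): a record counts as a true positive for its true
class when the true class appears anywhere in the top k; otherwise it is a
false negative for the true class and a false positive for the first-ranked
class.  This "containment credit" reading makes both precision and recall
rise from top-1 to top-3 and leaves per-class top-k recall monotone in k.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from . import diseases

__all__ = [
    "TopKOutcome",
    "MetricReport",
    "BootstrapSpec",
    "CVSpec",
    "prf_from_counts",
    "topk_metrics",
    "confusion_matrix",
    "roc_auc_ovr",
    "bootstrap_ci",
    "kfold_cv",
    "wilcoxon_signed_rank",
]


@dataclass(frozen=True)
class TopKOutcome:
    """One record's ranked prediction against its true class."""

    record_id: str
    true_class: int
    ranked: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.ranked)) != len(self.ranked):
            raise ValueError("ranked classes must be distinct")


@dataclass
class MetricReport:
    """Per-class and macro P/R/F1 at top-1 and top-3, AUROCs, confusions."""

    per_class: dict[int, dict[str, float]] = field(default_factory=dict)
    macro: dict[str, float] = field(default_factory=dict)
    auroc: dict[int, float] = field(default_factory=dict)
    auroc_ci: dict[int, tuple[float, float]] = field(default_factory=dict)
    macro_auroc: float | None = None
    confusion_top1: np.ndarray | None = None
    confusion_top3: np.ndarray | None = None

    def to_dict(self) -> dict:
        out = {
            "per_class": {str(k): v for k, v in self.per_class.items()},
            "macro": self.macro,
            "auroc": {str(k): v for k, v in self.auroc.items()},
            "auroc_ci": {str(k): list(v) for k, v in self.auroc_ci.items()},
            "macro_auroc": self.macro_auroc,
        }
        if self.confusion_top1 is not None:
            out["confusion_top1"] = self.confusion_top1.tolist()
        if self.confusion_top3 is not None:
            out["confusion_top3"] = self.confusion_top3.tolist()
        return out


@dataclass(frozen=True)
class BootstrapSpec:
    B: int = 1000
    percentiles: tuple[float, float] = (2.5, 97.5)
    seed: int = 20190401

    def __post_init__(self) -> None:
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass(frozen=True)
class CVSpec:
    folds: int = 10
    stratified: bool = True
    seed: int = 20190401

    def __post_init__(self) -> None:
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def prf_from_counts(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    """Precision, recall, F1 from counts; undefined ratios return 0 and set
    the fourth element (the undefined flag)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    undefined = False
    if tp + fp == 0:
        p, undefined = 0.0, True
    else:
        p = tp / (tp + fp)
    if tp + fn == 0:
        r, undefined = 0.0, True
    else:
        r = tp / (tp + fn)
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1, undefined


def _topk_counts(
    outcomes: Sequence[TopKOutcome], k: int, classes: Sequence[int]
) -> dict[int, tuple[int, int, int]]:
    tp = {c: 0 for c in classes}
    fp = {c: 0 for c in classes}
    fn = {c: 0 for c in classes}
    for o in outcomes:
        if len(o.ranked) < k:
            raise ValueError(f"k={k} exceeds ranking length {len(o.ranked)}")
        top = o.ranked[:k]
        if o.true_class in top:
            tp[o.true_class] += 1
        else:
            fn[o.true_class] += 1
            fp[o.ranked[0]] += 1
    return {c: (tp[c], fp[c], fn[c]) for c in classes}


def topk_metrics(
    outcomes: Sequence[TopKOutcome], k: int, classes: Sequence[int] | None = None
) -> dict:
    """Per-class and macro P/R/F1 at rank ``k`` under the containment rule.

    At k=1 this reduces to standard multi-class metrics on the first-ranked
    class.  Macro values are unweighted means over classes present in gold.
    """
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    if classes is None:
        classes = sorted(
            {o.true_class for o in outcomes} | {c for o in outcomes for c in o.ranked}
        )
    counts = _topk_counts(outcomes, k, classes)
    gold_classes = {o.true_class for o in outcomes}
    per_class = {}
    macro_rows = []
    for c in classes:
        p, r, f1, undef = prf_from_counts(*counts[c])
        per_class[c] = {"precision": p, "recall": r, "f1": f1, "undefined": undef}
        if c in gold_classes:
            macro_rows.append((p, r, f1))
    arr = np.array(macro_rows)
    macro = {
        "precision": float(arr[:, 0].mean()),
        "recall": float(arr[:, 1].mean()),
        "f1": float(arr[:, 2].mean()),
    }
    return {"k": k, "per_class": per_class, "macro": macro}


def confusion_matrix(
    outcomes: Sequence[TopKOutcome], k: int = 1, n_classes: int = diseases.N_CLASSES
) -> np.ndarray:
    """Row = true class.  For k=1 the column is the first-ranked class; for
    k>1 the column is the true class when it appears in the top k (the
    containment credit), else the first-ranked class."""
    if not outcomes:
        raise ValueError("outcomes must be non-empty")
    M = np.zeros((n_classes, n_classes), dtype=int)
    for o in outcomes:
        if len(o.ranked) < k:
            raise ValueError(f"k={k} exceeds ranking length {len(o.ranked)}")
        col = o.true_class if (k > 1 and o.true_class in o.ranked[:k]) else o.ranked[0]
        M[o.true_class, col] += 1
    return M


def roc_auc_ovr(
    true_classes: Sequence[int],
    proba: np.ndarray,
    classes: Sequence[int] | None = None,
) -> tuple[dict[int, float], float]:
    """One-vs-rest AUC per class via the Mann-Whitney rank statistic (ties
    get half credit); macro is the unweighted mean over defined classes.

    Degenerate classes (no positive or no negative example) are excluded
    from the macro with a warning and reported as NaN.
    """
    y = np.asarray(true_classes)
    proba = np.asarray(proba, dtype=float)
    if classes is None:
        classes = list(range(proba.shape[1]))
    aucs: dict[int, float] = {}
    defined = []
    for j, c in enumerate(classes):
        pos = y == c
        n_pos = int(pos.sum())
        n_neg = int(len(y) - n_pos)
        if n_pos == 0 or n_neg == 0:
            warnings.warn(f"AUC undefined for class {c}; excluded from macro")
            aucs[c] = float("nan")
            continue
        ranks = rankdata(proba[:, j])  # average ranks -> half credit for ties
        auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
        aucs[c] = float(auc)
        defined.append(auc)
    macro = float(np.mean(defined)) if defined else float("nan")
    return aucs, macro


def bootstrap_ci(
    statistic: Callable[[Sequence], float],
    outcomes: Sequence,
    spec: BootstrapSpec | None = None,
) -> tuple[float, float, float]:
    """Percentile bootstrap interval for ``statistic`` over record-level
    resamples drawn with replacement.

    Returns (point estimate, lower, upper).  Resamples on which the
    statistic is undefined (NaN or raising) are skipped; more than 10%
    undefined raises.
    """
    if len(outcomes) == 0:
        raise ValueError("outcomes must be non-empty")
    spec = spec or BootstrapSpec()
    rng = np.random.default_rng(spec.seed)
    point = float(statistic(outcomes))
    n = len(outcomes)
    values = []
    bad = 0
    for _ in range(spec.B):
        idx = rng.integers(0, n, size=n)
        sample = [outcomes[i] for i in idx]
        try:
            v = float(statistic(sample))
        except (ValueError, ZeroDivisionError):
            v = float("nan")
        if math.isnan(v):
            bad += 1
        else:
            values.append(v)
    if bad > 0.1 * spec.B:
        raise ValueError(
            f"statistic undefined on {bad}/{spec.B} bootstrap resamples"
        )
    lo, hi = np.percentile(values, spec.percentiles)
    return point, float(lo), float(hi)


def kfold_cv(
    pipeline_factory: Callable[[], object],
    X: np.ndarray,
    y: Sequence[int],
    metric_fn: Callable[[Sequence[int], np.ndarray], Mapping[str, float]],
    spec: CVSpec | None = None,
) -> tuple[list[dict[str, float]], dict[str, float], dict[str, float], list[np.ndarray]]:
    """Stratified k-fold cross-validation.

    ``pipeline_factory`` must return a fresh estimator with ``fit`` and
    ``predict_proba``; any resampling (e.g. SMOTE) must live inside its
    ``fit`` so it only ever sees training folds.  ``metric_fn`` maps
    (true labels, probability matrix) of one validation fold to a metric
    dict.  Returns per-fold metrics, their mean, their sample standard
    deviation, and the validation index arrays.
    """
    spec = spec or CVSpec()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    _, counts = np.unique(y, return_counts=True)
    if spec.stratified and counts.min() < spec.folds:
        raise ValueError(
            f"smallest class has {counts.min()} records; stratified "
            f"{spec.folds}-fold CV is infeasible"
        )
    splitter = StratifiedKFold(
        n_splits=spec.folds, shuffle=True, random_state=spec.seed
    )
    per_fold: list[dict[str, float]] = []
    fold_indices: list[np.ndarray] = []
    for train_idx, val_idx in splitter.split(X, y):
        model = pipeline_factory()
        model.fit(X[train_idx], y[train_idx])
        proba = model.predict_proba(X[val_idx])
        per_fold.append(dict(metric_fn(y[val_idx], proba)))
        fold_indices.append(val_idx)
    keys = per_fold[0].keys()
    mean = {k: float(np.mean([m[k] for m in per_fold])) for k in keys}
    sd = {k: float(np.std([m[k] for m in per_fold], ddof=1)) for k in keys}
    return per_fold, mean, sd, fold_indices


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = rankdata(np.abs(d))  # average ranks for tied |differences|
    w_plus = float(ranks[d > 0].sum())
    return w_plus, ranks


def wilcoxon_signed_rank(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    mode: str = "auto",
) -> tuple[float, float]:
    """Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped.  The reported statistic is W+, the sum of
    ranks of positive differences (``y`` subtracted from ``x``), with
    average ranks for ties.  The null distribution is enumerated exactly
    for n <= 12 (``mode='auto'`` or ``'exact'``); larger samples use the
    normal approximation with tie correction and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must be paired vectors of equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    if alternative not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown alternative {alternative!r}")
    w_plus, ranks = _signed_rank_statistic(d)
    if mode == "auto":
        mode = "exact" if n <= 12 else "approx"

    if mode == "exact":
        # enumerate all 2^n sign assignments over the observed |d| ranks
        totals = np.zeros(2**n)
        for bits in range(2**n):
            s = 0.0
            for i in range(n):
                if bits >> i & 1:
                    s += ranks[i]
            totals[bits] = s
        eps = 1e-9
        if alternative == "greater":
            p = float(np.mean(totals >= w_plus - eps))
        elif alternative == "less":
            p = float(np.mean(totals <= w_plus + eps))
        else:
            p_hi = float(np.mean(totals >= w_plus - eps))
            p_lo = float(np.mean(totals <= w_plus + eps))
            p = min(1.0, 2 * min(p_hi, p_lo))
        return w_plus, p

    mean = n * (n + 1) / 4
    tie_counts = np.unique(np.abs(d), return_counts=True)[1]
    var = n * (n + 1) * (2 * n + 1) / 24 - np.sum(
        tie_counts**3 - tie_counts
    ) / 48
    sd = math.sqrt(var)
    if sd == 0:
        raise ValueError("zero variance (all differences tied at one value)")
    if alternative == "greater":
        z = (w_plus - mean - 0.5) / sd
        p = 1 - _norm_cdf(z)
    elif alternative == "less":
        z = (w_plus - mean + 0.5) / sd
        p = _norm_cdf(z)
    else:
        diff = w_plus - mean
        z = (diff - 0.5 * np.sign(diff)) / sd
        p = 2 * (1 - _norm_cdf(abs(float(z))))
    return w_plus, float(min(1.0, p))


def _norm_cdf(z: float) -> float:
    return 0.5 * (1 + math.erf(z / math.sqrt(2)))
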