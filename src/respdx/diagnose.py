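"""Ranked disease classification from clinical feature vectors.

The classification stage is: optional SMOTE rebalancing of the training
fold, a seeded gradient-boosted multi-class classifier (LightGBM), and a
probability-ranked top-k output over the ten disease classes.  An optional
two-step path first groups lung cancer and pulmonary tuberculosis into a
composite "lung space-occupying lesions" class and refines a composite
top-1 call with a dedicated binary subclassifier over fine-grained
features — mirroring how pulmonary nodules and masses are worked up in
practice.

SMOTE here is the classic interpolation scheme: each synthetic minority
sample is ``x_i + lambda * (x_nn - x_i)`` with ``lambda ~ Uniform(0,1)``
and ``x_nn`` one of the ``k`` nearest same-class neighbours (Euclidean).
It must only ever see training folds; the cross-validation wiring in
:mod:`respdx.evaluate` and the pipeline enforce that.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from lightgbm import LGBMClassifier
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.neighbors import NearestNeighbors

from . import diseases

__all__ = [
    "FeatureMatrix",
    "SMOTEConfig",
    "Ranking",
    "TwoStepConfig",
    "smote_oversample",
    "DiagnosisClassifier",
    "fit_classifier",
    "predict_topk",
    "TwoStepRefiner",
    "two_step_refine",
]


@dataclass
class FeatureMatrix:
    """Aligned records x features design matrix with labels."""

    X: np.ndarray
    y: np.ndarray
    feature_names: list[str]
    record_ids: list[str]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape[0] != self.y.shape[0] or self.X.shape[0] != len(self.record_ids):
            raise ValueError("rows of X, y and record_ids must align")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("feature_names must match X columns")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains non-finite entries")


@dataclass(frozen=True)
class SMOTEConfig:
    k_neighbors: int = 5
    target: str = "equalize"  # balance every class up to the majority count
    seed: int = 20190401

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_oversample(matrix: FeatureMatrix, config: SMOTEConfig | None = None) -> FeatureMatrix:
    """Oversample minority classes by nearest-neighbour interpolation.

    Original rows are preserved verbatim (and first); synthetic rows are
    appended until every class reaches the majority count.  Already
    balanced input is returned unchanged.  A class with a single sample
    cannot be interpolated and raises an error naming it.
    """
    config = config or SMOTEConfig()
    classes, counts = np.unique(matrix.y, return_counts=True)
    target = counts.max()
    if np.all(counts == target):
        return FeatureMatrix(
            matrix.X.copy(), matrix.y.copy(), list(matrix.feature_names),
            list(matrix.record_ids),
        )
    rng = np.random.default_rng(config.seed)
    new_X = [matrix.X]
    new_y = [matrix.y]
    new_ids = list(matrix.record_ids)
    for cls, count in zip(classes, counts):
        need = int(target - count)
        if need == 0:
            continue
        if count < 2:
            raise ValueError(
                f"class {int(cls)} has a single sample; SMOTE needs >= 2"
            )
        Xc = matrix.X[matrix.y == cls]
        k = min(config.k_neighbors, count - 1)
        nn = NearestNeighbors(n_neighbors=k + 1).fit(Xc)
        neigh = nn.kneighbors(Xc, return_distance=False)[:, 1:]
        base = rng.integers(0, count, size=need)
        pick = rng.integers(0, k, size=need)
        lam = rng.uniform(0.0, 1.0, size=need)
        xi = Xc[base]
        xn = Xc[neigh[base, pick]]
        new_X.append(xi + lam[:, None] * (xn - xi))
        new_y.append(np.full(need, cls))
        new_ids.extend(f"smote-{int(cls)}-{j:05d}" for j in range(need))
    return FeatureMatrix(
        np.vstack(new_X), np.concatenate(new_y), list(matrix.feature_names), new_ids
    )


@dataclass
class Ranking:
    """Probability-ranked classes for one record.

    Entries are (class_id, probability), sorted by descending probability
    with ties broken by ascending class id; probabilities sum to 1.
    """

    record_id: str
    entries: list[tuple[int, float]]

    def __post_init__(self) -> None:
        probs = [p for _, p in self.entries]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("probabilities must lie in [0,1]")
        if abs(sum(probs) - 1.0) > 1e-6:
            raise ValueError(f"probabilities must sum to 1, got {sum(probs)}")
        for (c1, p1), (c2, p2) in zip(self.entries, self.entries[1:]):
            if p1 < p2 or (p1 == p2 and c1 > c2):
                raise ValueError("entries must be sorted by (-prob, class_id)")

    @property
    def top1(self) -> int:
        return self.entries[0][0]

    def top(self, k: int) -> list[int]:
        return [c for c, _ in self.entries[:k]]


def _rank_entries(class_ids: Sequence[int], probs: Sequence[float]) -> list[tuple[int, float]]:
    order = sorted(range(len(class_ids)), key=lambda i: (-probs[i], class_ids[i]))
    return [(int(class_ids[i]), float(probs[i])) for i in order]


class DiagnosisClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted multi-class disease classifier with optional SMOTE.

    A thin, seeded wrapper around :class:`lightgbm.LGBMClassifier` that
    (a) applies SMOTE to its *own training data only* when ``smote`` is
    on, and (b) reports probabilities over a fixed class universe so that
    rankings always cover all diseases even if a class is absent from a
    training fold.

    Parameters follow scikit-learn conventions; the contract admits any
    probabilistic multi-class learner, with gradient-boosted trees as the
    default.
    """

    def __init__(
        self,
        classes: Sequence[int] | None = None,
        smote: bool = True,
        smote_k: int = 5,
        n_estimators: int = 200,
        learning_rate: float = 0.1,
        num_leaves: int = 31,
        min_child_samples: int = 5,
        seed: int = 20190401,
    ):
        self.classes = classes
        self.smote = smote
        self.smote_k = smote_k
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.num_leaves = num_leaves
        self.min_child_samples = min_child_samples
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        present = np.unique(y)
        if present.size < 2:
            raise ValueError("need at least 2 classes to fit a classifier")
        self.classes_ = np.array(
            sorted(self.classes) if self.classes is not None else present
        )
        if self.smote:
            fm = FeatureMatrix(
                X, y, [f"f{i}" for i in range(X.shape[1])],
                [f"r{i}" for i in range(X.shape[0])],
            )
            fm = smote_oversample(fm, SMOTEConfig(k_neighbors=self.smote_k, seed=self.seed))
            X, y = fm.X, fm.y
        # objective left to the wrapper: multiclass for >2 classes, binary
        # for the two-step subtype classifier
        self.booster_ = LGBMClassifier(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            num_leaves=self.num_leaves,
            min_child_samples=self.min_child_samples,
            random_state=self.seed,
            deterministic=True,
            n_jobs=1,
            verbose=-1,
        )
        self.booster_.fit(X, y)
        return self

    def predict_proba(self, X) -> np.ndarray:
        import warnings

        X = np.asarray(X, dtype=float)
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message="X does not have valid feature names"
            )
            raw = self.booster_.predict_proba(X)
        out = np.zeros((X.shape[0], len(self.classes_)))
        col = {int(c): i for i, c in enumerate(self.classes_)}
        for j, c in enumerate(self.booster_.classes_):
            out[:, col[int(c)]] = raw[:, j]
        # numerical hygiene: renormalize
        out /= out.sum(axis=1, keepdims=True)
        return out

    def predict(self, X) -> np.ndarray:
        proba = self.predict_proba(X)
        # ties broken toward the lower class id (argmax returns first max)
        return self.classes_[np.argmax(proba, axis=1)]


def fit_classifier(matrix: FeatureMatrix, **params) -> DiagnosisClassifier:
    """Fit the default gradient-boosted classifier on a feature matrix."""
    clf = DiagnosisClassifier(**params)
    clf.fit(matrix.X, matrix.y)
    return clf


def predict_topk(
    model: DiagnosisClassifier, x: np.ndarray, k: int, record_id: str = ""
) -> Ranking:
    """Ranked diagnoses for one feature vector.

    The returned :class:`Ranking` carries the full probability-sorted class
    list (so probabilities sum to 1); ``ranking.top(k)`` is the requested
    k-prefix, and the k=1 prefix is by construction a prefix of the k=3 one.
    """
    n = len(model.classes_)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    probs = model.predict_proba(np.asarray(x, dtype=float).reshape(1, -1))[0]
    entries = _rank_entries(list(model.classes_), list(probs))
    return Ranking(record_id=record_id, entries=entries)


@dataclass
class TwoStepConfig:
    enabled: bool = False
    subtypes: tuple[int, int] = diseases.COMPOSITE_MEMBERS
    subclassifier: "DiagnosisClassifier | None" = None

    def __post_init__(self) -> None:
        if tuple(sorted(self.subtypes)) != tuple(sorted(diseases.COMPOSITE_MEMBERS)):
            raise ValueError(
                "two-step subtypes are fixed to lung cancer and pulmonary tuberculosis"
            )


class TwoStepRefiner:
    """Binary lung-cancer vs tuberculosis subclassifier over fine features."""

    def __init__(self, **params):
        params.setdefault("classes", diseases.COMPOSITE_MEMBERS)
        self.clf = DiagnosisClassifier(**params)
        self.fitted_ = False

    def fit(self, X_fine, y) -> "TwoStepRefiner":
        y = np.asarray(y, dtype=int)
        keep = np.isin(y, diseases.COMPOSITE_MEMBERS)
        self.clf.fit(np.asarray(X_fine)[keep], y[keep])
        self.fitted_ = True
        return self

    def predict_subtype(self, x_fine) -> tuple[int, float]:
        proba = self.clf.predict_proba(np.asarray(x_fine).reshape(1, -1))[0]
        entries = _rank_entries(list(self.clf.classes_), list(proba))
        return entries[0][0], entries[0][1]


def two_step_refine(
    ranking: Ranking, x_fine: np.ndarray, config: TwoStepConfig
) -> tuple[Ranking, int]:
    """Refine a composite top-1 call into lung cancer vs tuberculosis.

    ``ranking`` is a stage-1 ranking over the merged class space in which
    the composite lesion class carries id :data:`diseases.COMPOSITE_LESION`.
    When the composite class is ranked first, the binary subclassifier
    picks the reported subtype label; otherwise the ranking and its top-1
    label are returned unchanged.

    Returns the (possibly unchanged) ranking and the reported top-1 label.
    """
    if ranking.top1 != diseases.COMPOSITE_LESION:
        return ranking, ranking.top1
    if not config.enabled or config.subclassifier is None:
        raise ValueError("two-step refinement requested without a trained subclassifier")
    sub = config.subclassifier
    if isinstance(sub, TwoStepRefiner):
        if not sub.fitted_:
            raise ValueError("two-step subclassifier is untrained")
        sub = sub.clf
    elif not hasattr(sub, "booster_"):
        raise ValueError("two-step subclassifier is untrained")
    proba = sub.predict_proba(np.asarray(x_fine, dtype=float).reshape(1, -1))[0]
    entries = _rank_entries(list(sub.classes_), list(proba))
    return ranking, entries[0][0]
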