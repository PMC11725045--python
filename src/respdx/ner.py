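"""Clinical named-entity recognition with a linear-chain CRF.

Six entity categories (disease names, symptoms, quantitative/qualitative
tests, image findings, medications, surgical procedures) are tagged with a
BIO schema: one B-/I- tag pair per category plus O, 13 tags in total.

The sequence model is an exact linear-chain conditional random field.  A
path ``y`` over ``L`` tokens scores

    s(y) = start[y_0] + sum_t E[t, y_t] + sum_t T[y_{t-1}, y_t] + end[y_{L-1}]

where ``E`` are per-token emission log-potentials produced by a pluggable
scorer and ``T`` are tag-transition log-potentials.  The normalizer
``log Z`` is computed by the forward recursion in log space; decoding uses
Viterbi with deterministic tie-breaking (lowest tag index wins).

The default emission scorer is a featurized linear model over hashed
lexical features (token identity, prefixes/suffixes, a +/-2 token window),
trained jointly with the transition parameters by gradient ascent on the
conditional log-likelihood.  It is deterministic given a seed and fast on
a single CPU.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

__all__ = [
    "ENTITY_CATEGORIES",
    "TagSchema",
    "Token",
    "EntitySpan",
    "CRFModel",
    "CRFTagger",
    "AnnotationError",
    "tokenize",
    "bio_encode",
    "bio_decode",
    "path_score",
    "forward_logZ",
    "viterbi",
    "train_crf",
    "predict_entities",
    "span_prf",
]

ENTITY_CATEGORIES = (
    "disease_name",
    "symptom",
    "test",
    "image_finding",
    "medication",
    "procedure",
)

#: log-potential used for hard-masked (forbidden) transitions.  A large
#: finite value avoids inf-inf NaNs in the log-space recursions.
NEG_INF = -1e30


class AnnotationError(ValueError):
    """Raised for invalid span annotations (overlap, token misalignment)."""


@dataclass(frozen=True)
class TagSchema:
    """BIO tag inventory: index 0 is O, then B-x, I-x per category in order."""

    categories: tuple[str, ...] = ENTITY_CATEGORIES

    @property
    def tags(self) -> tuple[str, ...]:
        out = ["O"]
        for c in self.categories:
            out.extend((f"B-{c}", f"I-{c}"))
        return tuple(out)

    @property
    def n_tags(self) -> int:
        return 2 * len(self.categories) + 1

    def index(self, tag: str) -> int:
        try:
            return self.tags.index(tag)
        except ValueError:
            raise ValueError(f"unknown tag symbol: {tag!r}") from None

    def invalid_transition_mask(self) -> np.ndarray:
        """Boolean (T, T) matrix, True where i -> j is an invalid BIO move.

        I-x may only follow B-x or I-x of the same category.
        """
        tags = self.tags
        mask = np.zeros((len(tags), len(tags)), dtype=bool)
        for j, tj in enumerate(tags):
            if not tj.startswith("I-"):
                continue
            cat = tj[2:]
            for i, ti in enumerate(tags):
                if ti not in (f"B-{cat}", f"I-{cat}"):
                    mask[i, j] = True
        return mask


@dataclass(frozen=True)
class Token:
    text: str
    start: int
    end: int


@dataclass(frozen=True)
class EntitySpan:
    """Character-offset mention (0-based, half-open) in one record section."""

    section: str
    start: int
    end: int
    category: str
    surface: str
    #: gold-only attribute map (e.g. {"assertion": "negated"}); predictions
    #: carry None here and receive attributes from the normalize stage.
    attributes: tuple[tuple[str, str], ...] | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"empty span {self.start}:{self.end}")

    def key(self) -> tuple[str, int, int, str]:
        return (self.section, self.start, self.end, self.category)

    def attribute_dict(self) -> dict[str, str]:
        return dict(self.attributes or ())


def tokenize(text: str, dialect: str = "whitespace") -> list[Token]:
    """Split ``text`` into offset-carrying tokens.

    ``whitespace`` splits on runs of whitespace; ``character`` emits one
    token per non-whitespace character (the contract compatible with
    continuous-script clinical text).  Concatenating token slices in order
    reproduces the non-delimiter content.
    """
    tokens: list[Token] = []
    if dialect == "whitespace":
        i, n = 0, len(text)
        while i < n:
            if text[i].isspace():
                i += 1
                continue
            j = i
            while j < n and not text[j].isspace():
                j += 1
            tokens.append(Token(text[i:j], i, j))
            i = j
    elif dialect == "character":
        for i, ch in enumerate(text):
            if not ch.isspace():
                tokens.append(Token(ch, i, i + 1))
    else:
        raise ValueError(f"unknown tokenizer dialect: {dialect!r}")
    return tokens


def bio_encode(spans: Sequence[EntitySpan], tokens: Sequence[Token]) -> list[str]:
    """Encode character spans as token-level BIO tags.

    Spans must be non-overlapping and must align exactly to token
    boundaries; violations raise :class:`AnnotationError` naming the spans.
    """
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    for a, b in zip(ordered, ordered[1:]):
        if b.start < a.end:
            raise AnnotationError(f"overlapping spans {a} and {b}")
    tags = ["O"] * len(tokens)
    starts = {t.start: k for k, t in enumerate(tokens)}
    ends = {t.end: k for k, t in enumerate(tokens)}
    for span in ordered:
        if span.start not in starts or span.end not in ends:
            raise AnnotationError(f"span {span} does not align to token boundaries")
        first, last = starts[span.start], ends[span.end]
        tags[first] = f"B-{span.category}"
        for k in range(first + 1, last + 1):
            tags[k] = f"I-{span.category}"
    return tags


def bio_decode(
    tags: Sequence[str],
    tokens: Sequence[Token],
    section: str = "",
    text: str | None = None,
    schema: TagSchema | None = None,
) -> list[EntitySpan]:
    """Decode BIO tags back into character spans.

    Maximal ``B-x (I-x)*`` runs become one span each.  A stray ``I-x`` not
    preceded by ``B-x``/``I-x`` of the same category is repaired to ``B-x``
    (it opens a new span) — the documented repair rule.
    """
    schema = schema or TagSchema()
    valid = set(schema.tags)
    spans: list[EntitySpan] = []
    open_cat: str | None = None
    open_first = 0
    for k, tag in enumerate(list(tags) + ["O"]):
        if k < len(tags) and tag not in valid:
            raise ValueError(f"unknown tag symbol: {tag!r}")
        cont = tag.startswith("I-") and open_cat == tag[2:]
        if cont:
            continue
        if open_cat is not None:
            start = tokens[open_first].start
            end = tokens[k - 1].end
            surface = (
                text[start:end]
                if text is not None
                else " ".join(t.text for t in tokens[open_first:k])
            )
            spans.append(EntitySpan(section, start, end, open_cat, surface))
            open_cat = None
        if tag.startswith("B-") or tag.startswith("I-"):
            open_cat = tag[2:]
            open_first = k
    return spans


class EmissionScorer(Protocol):
    """Contract for emission models: token sequence -> (L, T) log-potentials."""

    def scores(self, tokens: Sequence[str]) -> np.ndarray: ...


def _hash_feature(feat: str, n_buckets: int) -> int:
    # crc32 is stable across processes, unlike builtin hash()
    return zlib.crc32(feat.encode("utf-8")) % n_buckets


class FeaturizedScorer:
    """Linear emission model over hashed lexical features.

    Features per token: bias, token identity (cased and lowered), prefix
    and suffix up to 3 characters, digit flag, and the identities of the
    tokens at relative offsets -2..+2.
    """

    def __init__(self, n_tags: int, n_buckets: int = 1 << 18):
        self.n_buckets = n_buckets
        self.weights = np.zeros((n_buckets, n_tags))
        self._cache: dict[tuple[str, ...], list[np.ndarray]] = {}

    def features(self, tokens: Sequence[str]) -> list[np.ndarray]:
        key = tuple(tokens)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        out = []
        n = len(tokens)
        for i in range(n):
            w = tokens[i]
            feats = [
                "b",
                f"w={w}",
                f"wl={w.lower()}",
                f"p3={w[:3]}",
                f"s3={w[-3:]}",
                f"d={w.isdigit()}",
            ]
            for off in (-2, -1, 1, 2):
                j = i + off
                ctx = tokens[j] if 0 <= j < n else "<pad>"
                feats.append(f"w{off:+d}={ctx}")
            out.append(
                np.array(
                    sorted({_hash_feature(f, self.n_buckets) for f in feats}),
                    dtype=np.int64,
                )
            )
        if len(self._cache) < 200_000:
            self._cache[key] = out
        return out

    def scores(self, tokens: Sequence[str]) -> np.ndarray:
        feats = self.features(tokens)
        out = np.empty((len(tokens), self.weights.shape[1]))
        for i, idx in enumerate(feats):
            out[i] = self.weights[idx].sum(axis=0)
        return out


@dataclass
class CRFModel:
    """Linear-chain CRF parameters plus the emission scorer contract."""

    transition: np.ndarray
    start_scores: np.ndarray
    end_scores: np.ndarray
    emission_scorer: EmissionScorer
    schema: TagSchema = field(default_factory=TagSchema)
    hard_mask: bool = False

    def effective_transition(self) -> np.ndarray:
        if not self.hard_mask:
            return self.transition
        t = self.transition.copy()
        t[self.schema.invalid_transition_mask()] = NEG_INF
        return t

    def effective_start(self) -> np.ndarray:
        if not self.hard_mask:
            return self.start_scores
        s = self.start_scores.copy()
        for j, tag in enumerate(self.schema.tags):
            if tag.startswith("I-"):
                s[j] = NEG_INF
        return s


def _check_emissions(emissions: np.ndarray, n_tags: int) -> np.ndarray:
    emissions = np.asarray(emissions, dtype=float)
    if emissions.ndim != 2 or emissions.shape[1] != n_tags:
        raise ValueError(f"emissions must be (L, {n_tags}), got {emissions.shape}")
    if emissions.shape[0] < 1:
        raise ValueError("sequence length must be >= 1")
    if not np.all(np.isfinite(emissions)):
        raise ValueError("emissions must be finite")
    return emissions


def path_score(emissions: np.ndarray, model: CRFModel, path: Sequence[int]) -> float:
    """Unnormalized log-score of one tag path."""
    n_tags = model.schema.n_tags
    emissions = _check_emissions(emissions, n_tags)
    path = list(path)
    if len(path) != emissions.shape[0]:
        raise ValueError("path length must equal sequence length")
    if any(not 0 <= y < n_tags for y in path):
        raise ValueError("tag index out of range")
    trans = model.effective_transition()
    score = model.effective_start()[path[0]] + emissions[0, path[0]]
    for t in range(1, len(path)):
        score += trans[path[t - 1], path[t]] + emissions[t, path[t]]
    score += model.end_scores[path[-1]]
    return float(score)


def _forward(emissions: np.ndarray, model: CRFModel) -> np.ndarray:
    trans = model.effective_transition()
    alpha = np.empty_like(emissions)
    alpha[0] = model.effective_start() + emissions[0]
    for t in range(1, emissions.shape[0]):
        alpha[t] = logsumexp(alpha[t - 1][:, None] + trans, axis=0) + emissions[t]
    return alpha


def forward_logZ(emissions: np.ndarray, model: CRFModel) -> float:
    """Log-partition function via the numerically stable forward recursion."""
    emissions = _check_emissions(emissions, model.schema.n_tags)
    alpha = _forward(emissions, model)
    return float(logsumexp(alpha[-1] + model.end_scores))


def viterbi(emissions: np.ndarray, model: CRFModel) -> tuple[list[int], float]:
    """Highest-scoring tag path; ties broken toward the lowest tag index."""
    emissions = _check_emissions(emissions, model.schema.n_tags)
    trans = model.effective_transition()
    L = emissions.shape[0]
    delta = model.effective_start() + emissions[0]
    back = np.zeros((L, emissions.shape[1]), dtype=np.int64)
    for t in range(1, L):
        cand = delta[:, None] + trans
        back[t] = np.argmax(cand, axis=0)  # first max -> lowest index on ties
        delta = cand[back[t], np.arange(cand.shape[1])] + emissions[t]
    delta = delta + model.end_scores
    last = int(np.argmax(delta))
    path = [last]
    for t in range(L - 1, 0, -1):
        path.append(int(back[t, path[-1]]))
    path.reverse()
    return path, float(delta[last])


def _backward(emissions: np.ndarray, model: CRFModel) -> np.ndarray:
    trans = model.effective_transition()
    L = emissions.shape[0]
    beta = np.empty_like(emissions)
    beta[L - 1] = model.end_scores
    for t in range(L - 2, -1, -1):
        beta[t] = logsumexp(trans + (emissions[t + 1] + beta[t + 1])[None, :], axis=1)
    return beta


class CRFTagger(BaseEstimator):
    """Sequence labeler: featurized linear emissions + exact CRF layer.

    scikit-learn-style estimator over token sequences: ``X`` is a list of
    token-string lists, ``y`` a parallel list of BIO tag lists.  Training
    maximizes the conditional log-likelihood by adagrad ascent; epochs that
    worsen the training loss are rolled back with a halved step size, so
    the loss over accepted epochs is non-increasing.  Early stopping uses
    token accuracy on a held-out slice of the sequences.

    Parameters
    ----------
    schema : TagSchema
    n_buckets : size of the hashed feature table.
    learning_rate : adagrad base step.
    max_epochs : upper bound on passes over the (deduplicated) sequences.
    patience : epochs without held-out improvement before stopping.
    holdout : fraction of unique sequences held out for early stopping.
    hard_mask : forbid invalid BIO transitions with -inf potentials.
    seed : controls shuffling and the holdout split; default 20190401.
    """

    def __init__(
        self,
        schema: TagSchema | None = None,
        n_buckets: int = 1 << 18,
        learning_rate: float = 0.5,
        max_epochs: int = 8,
        patience: int = 2,
        holdout: float = 0.1,
        hard_mask: bool = False,
        seed: int = 20190401,
    ):
        self.schema = schema
        self.n_buckets = n_buckets
        self.learning_rate = learning_rate
        self.max_epochs = max_epochs
        self.patience = patience
        self.holdout = holdout
        self.hard_mask = hard_mask
        self.seed = seed

    # -- internal -----------------------------------------------------------

    def _nll(self, seqs, counts) -> float:
        total = n = 0.0
        for (tokens, tag_idx), c in zip(seqs, counts):
            em = self.model_.emission_scorer.scores(tokens)
            ll = path_score(em, self.model_, tag_idx) - forward_logZ(em, self.model_)
            total -= c * ll
            n += c * len(tokens)
        return total / max(n, 1.0)

    # -- estimator API ------------------------------------------------------

    def fit(self, X: Sequence[Sequence[str]], y: Sequence[Sequence[str]]):
        if len(X) != len(y):
            raise ValueError("X and y must be parallel sequence lists")
        if len(X) == 0:
            raise ValueError("empty training corpus")
        schema = self.schema or TagSchema()
        n_tags = schema.n_tags
        scorer = FeaturizedScorer(n_tags, self.n_buckets)
        self.model_ = CRFModel(
            transition=np.zeros((n_tags, n_tags)),
            start_scores=np.zeros(n_tags),
            end_scores=np.zeros(n_tags),
            emission_scorer=scorer,
            schema=schema,
            hard_mask=self.hard_mask,
        )
        if not any(any(t != "O" for t in tags) for tags in y):
            import warnings

            warnings.warn("training corpus contains zero entity spans")

        # deduplicate identical (tokens, tags) sequences; train on weighted
        # unique sequences — templated clinical text repeats heavily.
        dedup: dict[tuple, float] = {}
        for tokens, tags in zip(X, y):
            if len(tokens) != len(tags):
                raise ValueError("token/tag length mismatch")
            if not tokens:
                continue
            key = (tuple(tokens), tuple(schema.index(t) for t in tags))
            dedup[key] = dedup.get(key, 0.0) + 1.0
        seqs = list(dedup.keys())
        counts = np.array([dedup[k] for k in seqs])

        rng = np.random.default_rng(self.seed)
        order = rng.permutation(len(seqs))
        n_dev = int(round(self.holdout * len(seqs)))
        if self.holdout > 0 and len(seqs) > 4:
            n_dev = max(n_dev, 1)
        n_dev = min(n_dev, len(seqs) - 1)
        dev_idx = order[:n_dev]
        train_idx = order[n_dev:]
        if self.max_epochs <= 0:
            self.n_epochs_ = 0
            self.train_loss_path_: list[float] = []
            return self

        gW_acc = np.full((self.n_buckets, n_tags), 1e-8)
        tr_acc = np.full((n_tags, n_tags), 1e-8)
        st_acc = np.full(n_tags, 1e-8)
        en_acc = np.full(n_tags, 1e-8)
        lr = self.learning_rate

        def dev_accuracy() -> float:
            if len(dev_idx) == 0:
                return -self._nll([seqs[i] for i in train_idx], counts[train_idx])
            good = tot = 0.0
            for i in dev_idx:
                tokens, tag_idx = seqs[i]
                em = scorer.scores(tokens)
                pred, _ = viterbi(em, self.model_)
                good += counts[i] * sum(p == g for p, g in zip(pred, tag_idx))
                tot += counts[i] * len(tokens)
            return good / max(tot, 1.0)

        best_acc = -np.inf
        best_state = None
        prev_loss = np.inf
        stall = 0
        self.train_loss_path_ = []
        for epoch in range(self.max_epochs):
            snapshot = (
                scorer.weights.copy(),
                self.model_.transition.copy(),
                self.model_.start_scores.copy(),
                self.model_.end_scores.copy(),
            )
            for i in rng.permutation(train_idx):
                tokens, tag_idx = seqs[i]
                g_tr = np.zeros((n_tags, n_tags))
                g_em_rows: dict[int, np.ndarray] = {}

                model = self.model_
                em = scorer.scores(tokens)
                alpha = _forward(em, model)
                beta = _backward(em, model)
                logZ = logsumexp(alpha[-1] + model.end_scores)
                marg = np.exp(alpha + beta - logZ)
                L = em.shape[0]
                g_em = -marg
                g_em[np.arange(L), tag_idx] += 1.0
                w = counts[i]
                g_em *= w
                feats = scorer.features(tokens)
                for t in range(L):
                    for row in feats[t]:
                        acc = g_em_rows.get(row)
                        if acc is None:
                            g_em_rows[row] = g_em[t].copy()
                        else:
                            acc += g_em[t]
                g_start = -w * marg[0]
                g_start[tag_idx[0]] += w
                g_end = -w * marg[-1]
                g_end[tag_idx[-1]] += w
                if L > 1:
                    trans = model.effective_transition()
                    for t in range(L - 1):
                        pair = np.exp(
                            alpha[t][:, None]
                            + trans
                            + (em[t + 1] + beta[t + 1])[None, :]
                            - logZ
                        )
                        g_tr -= w * pair
                    for t in range(L - 1):
                        g_tr[tag_idx[t], tag_idx[t + 1]] += w

                # adagrad updates
                rows = np.fromiter(g_em_rows.keys(), dtype=np.int64)
                if rows.size:
                    grad = np.stack([g_em_rows[r] for r in rows])
                    gW_acc[rows] += grad**2
                    scorer.weights[rows] += lr * grad / np.sqrt(gW_acc[rows])
                tr_acc += g_tr**2
                self.model_.transition += lr * g_tr / np.sqrt(tr_acc)
                st_acc += g_start**2
                self.model_.start_scores += lr * g_start / np.sqrt(st_acc)
                en_acc += g_end**2
                self.model_.end_scores += lr * g_end / np.sqrt(en_acc)

            train_loss = self._nll([seqs[i] for i in train_idx], counts[train_idx])
            if train_loss > prev_loss + 1e-12:
                # reject the epoch: restore and halve the step size
                scorer.weights, tr, st, en = snapshot
                self.model_.transition = tr
                self.model_.start_scores = st
                self.model_.end_scores = en
                lr *= 0.5
                continue
            prev_loss = train_loss
            self.train_loss_path_.append(train_loss)
            acc = dev_accuracy()
            if acc > best_acc + 1e-9:
                best_acc = acc
                best_state = (
                    scorer.weights.copy(),
                    self.model_.transition.copy(),
                    self.model_.start_scores.copy(),
                    self.model_.end_scores.copy(),
                )
                stall = 0
            else:
                stall += 1
                if stall >= self.patience:
                    break
        if best_state is not None:
            scorer.weights, tr, st, en = best_state
            self.model_.transition = tr
            self.model_.start_scores = st
            self.model_.end_scores = en
        self.n_epochs_ = len(self.train_loss_path_)
        return self

    def predict(self, X: Sequence[Sequence[str]]) -> list[list[str]]:
        tags = self.model_.schema.tags
        memo: dict[tuple[str, ...], list[str]] = {}
        out = []
        for tokens in X:
            if not tokens:
                out.append([])
                continue
            key = tuple(tokens)
            hit = memo.get(key)
            if hit is None:
                em = self.model_.emission_scorer.scores(tokens)
                path, _ = viterbi(em, self.model_)
                hit = [tags[i] for i in path]
                memo[key] = hit
            out.append(list(hit))
        return out


def train_crf(
    sequences: Sequence[tuple[Sequence[str], Sequence[str]]],
    schema: TagSchema | None = None,
    **params,
) -> CRFTagger:
    """Fit a :class:`CRFTagger` on (tokens, BIO tags) pairs."""
    X = [list(t) for t, _ in sequences]
    y = [list(g) for _, g in sequences]
    return CRFTagger(schema=schema, **params).fit(X, y)


def predict_entities(record, tagger: CRFTagger, dialect: str = "whitespace") -> list[EntitySpan]:
    """Tokenize each section, decode with the CRF, map spans back to
    section character coordinates.  ``record`` needs a ``sections`` mapping."""
    spans: list[EntitySpan] = []
    for section, text in record.sections.items():
        tokens = tokenize(text, dialect)
        if not tokens:
            continue
        tags = tagger.predict([[t.text for t in tokens]])[0]
        spans.extend(
            bio_decode(tags, tokens, section=section, text=text,
                       schema=tagger.model_.schema)
        )
    return spans


def span_prf(
    gold: Sequence[Sequence[EntitySpan]],
    pred: Sequence[Sequence[EntitySpan]],
    categories: Sequence[str] = ENTITY_CATEGORIES,
) -> dict[str, tuple[float, float, float]]:
    """Exact-match span precision/recall/F1, per category plus macro.

    A predicted span counts as a true positive iff its (section, offsets,
    category) all match a gold span of the same record.  Macro values are
    unweighted means over the categories present in the gold standard.
    """
    if len(gold) != len(pred):
        raise ValueError("gold and pred must cover the same records")
    tp = {c: 0 for c in categories}
    fp = {c: 0 for c in categories}
    fn = {c: 0 for c in categories}
    gold_cats = set()
    for g_spans, p_spans in zip(gold, pred):
        g_keys = {s.key() for s in g_spans}
        p_keys = {s.key() for s in p_spans}
        for s in g_spans:
            gold_cats.add(s.category)
        for key in p_keys:
            (tp if key in g_keys else fp)[key[3]] += 1
        for key in g_keys - p_keys:
            fn[key[3]] += 1
    out: dict[str, tuple[float, float, float]] = {}
    macro = []
    for c in categories:
        p = tp[c] / (tp[c] + fp[c]) if tp[c] + fp[c] else 0.0
        r = tp[c] / (tp[c] + fn[c]) if tp[c] + fn[c] else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        out[c] = (p, r, f)
        if c in gold_cats:
            macro.append((p, r, f))
    if macro:
        arr = np.array(macro)
        out["macro"] = tuple(arr.mean(axis=0))
    else:
        out["macro"] = (0.0, 0.0, 0.0)
    return out
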