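"""Concept normalization and deep phenotyping.

Recognized mentions are standardized in two steps:

1. **Concept mapping** — the mention surface is normalized (case folding,
   full-width to half-width, punctuation stripping) and looked up in a
   terminology lexicon that collapses synonymous surface forms onto one
   canonical concept id per entity category.
2. **Attribute attachment** — trigger terms in the surrounding text attach
   phenotypic attributes (assertion/negation, severity, temporality, ...)
   to the nearest phenotype-bearing span within a token window, never
   across a sentence boundary.

Two feature representations are derived from the resulting phenotypes:

* coarse — binary concept presence;
* fine — assertion-aware concept x attribute-value indicators.  A negated
  concept sets its ``negated`` indicator and *not* its bare presence
  indicator, so "denies hemoptysis" and "hemoptysis" are different
  evidence.
"""

from __future__ import annotations

import unicodedata
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .ner import EntitySpan, Token

__all__ = [
    "DEFAULT_ATTRIBUTE_SCHEMA",
    "TermEntry",
    "Lexicon",
    "AttributeRule",
    "FinePhenotype",
    "normalize_surface",
    "map_to_concept",
    "attach_attributes",
    "CoarseVectorizer",
    "FineVectorizer",
    "coarse_features",
    "fine_features",
]

#: The ten configurable attribute slots of the deep-phenotyping schema and
#: their default value sets.  Only slots with rules/triggers in play are
#: ever populated; ``assertion`` defaults to "present" when unspecified.
DEFAULT_ATTRIBUTE_SCHEMA: dict[str, tuple[str, ...]] = {
    "assertion": ("present", "negated"),
    "severity": ("mild", "moderate", "severe"),
    "temporality": ("acute", "chronic"),
    "duration": ("short", "long"),
    "laterality": ("left", "right", "bilateral"),
    "body_site": ("upper_lobe", "lower_lobe", "pleura"),
    "trend": ("improving", "worsening"),
    "frequency": ("intermittent", "persistent"),
    "trigger": ("exertional", "nocturnal"),
    "quantifier": ("scant", "copious"),
}

_STRIP_CHARS = " \t\r\n.,;:!?()[]{}\"'、，。；：！？（）【】"


def normalize_surface(text: str) -> str:
    """Canonical surface form: NFKC (maps full-width to half-width), case
    folding, surrounding punctuation stripped, internal whitespace collapsed.

    Applied to a fixpoint, hence idempotent by construction.
    """
    prev = None
    out = text
    for _ in range(4):
        if out == prev:
            break
        prev = out
        out = unicodedata.normalize("NFKC", out).casefold()
        out = out.strip(_STRIP_CHARS)
        out = " ".join(out.split())
    return out


@dataclass(frozen=True)
class TermEntry:
    surface: str
    category: str
    concept_id: str
    preferred_name: str


class Lexicon:
    """Terminology table mapping (normalized surface, category) -> concept.

    Synonymous surfaces listed under one concept id resolve identically.
    Duplicate (surface, category) rows and concepts with conflicting
    preferred names are rejected at load time.
    """

    def __init__(self, entries: Iterable[TermEntry]):
        self._by_key: dict[tuple[str, str], TermEntry] = {}
        self._preferred: dict[str, str] = {}
        self.unmapped_count = 0
        for e in entries:
            key = (normalize_surface(e.surface), e.category)
            if key in self._by_key:
                raise ValueError(
                    f"duplicate lexicon row for surface {key[0]!r} in category {key[1]!r}"
                )
            prev = self._preferred.get(e.concept_id)
            if prev is not None and prev != e.preferred_name:
                raise ValueError(
                    f"concept {e.concept_id!r} has conflicting preferred names"
                )
            self._preferred[e.concept_id] = e.preferred_name
            self._by_key[key] = e

    def __len__(self) -> int:
        return len(self._by_key)

    @property
    def concept_ids(self) -> list[str]:
        return sorted(self._preferred)

    def preferred_name(self, concept_id: str) -> str:
        return self._preferred[concept_id]

    def lookup(self, surface: str, category: str) -> str | None:
        e = self._by_key.get((normalize_surface(surface), category))
        return e.concept_id if e else None

    # TSV: surface TAB category TAB concept_id TAB preferred_name, header row
    @classmethod
    def from_tsv(cls, path: str | Path) -> "Lexicon":
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        if not lines or lines[0].split("\t")[:2] != ["surface", "category"]:
            raise ValueError("lexicon TSV must start with a header row")
        entries = []
        for line in lines[1:]:
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise ValueError(f"malformed lexicon row: {line!r}")
            entries.append(TermEntry(*parts))
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        rows = ["surface\tcategory\tconcept_id\tpreferred_name"]
        for (surface, category), e in sorted(self._by_key.items()):
            rows.append(f"{surface}\t{category}\t{e.concept_id}\t{e.preferred_name}")
        Path(path).write_text("\n".join(rows) + "\n", encoding="utf-8")


def map_to_concept(span: EntitySpan, lexicon: Lexicon) -> str | None:
    """Exact lexicon lookup of the normalized surface within the span's
    category; unmapped surfaces return None and are counted on the lexicon."""
    concept = lexicon.lookup(span.surface, span.category)
    if concept is None:
        lexicon.unmapped_count += 1
    return concept


@dataclass(frozen=True)
class AttributeRule:
    """Trigger-based attachment rule for one attribute value.

    A trigger occurrence assigns ``value`` to the ``attribute_name`` slot of
    the nearest phenotype-bearing span in ``direction`` within
    ``scope_window`` tokens, without crossing a sentence boundary.
    """

    attribute_name: str
    value: str
    trigger_surfaces: tuple[str, ...]
    direction: str = "pre"  # pre | post | both
    scope_window: int = 3

    def __post_init__(self) -> None:
        if self.scope_window < 1:
            raise ValueError("scope_window must be >= 1")
        if not self.trigger_surfaces:
            raise ValueError("trigger surfaces must be non-empty")
        if self.direction not in ("pre", "post", "both"):
            raise ValueError(f"bad direction {self.direction!r}")


@dataclass
class FinePhenotype:
    """Canonical concept plus attribute map; the unit of fine-grained
    representation.  Unlisted attributes are unspecified; assertion defaults
    to present."""

    concept_id: str
    attributes: dict[str, str] = field(default_factory=dict)
    source_span: EntitySpan | None = None

    @property
    def assertion(self) -> str:
        return self.attributes.get("assertion", "present")


_SENTENCE_ENDERS = {".", "。", "!", "?", "！", "？"}


def _sentence_ids(tokens: Sequence[Token]) -> list[int]:
    ids = []
    sid = 0
    for t in tokens:
        ids.append(sid)
        if t.text in _SENTENCE_ENDERS:
            sid += 1
    return ids


def attach_attributes(
    spans: Sequence[EntitySpan],
    rules: Sequence[AttributeRule],
    tokens: Sequence[Token],
    concept_for_span: Mapping[int, str] | None = None,
) -> list[FinePhenotype]:
    """Attach attribute values to phenotype spans via trigger rules.

    For every trigger occurrence the value goes to the nearest span (token
    distance) in the rule's direction within ``scope_window`` tokens and the
    same sentence.  A span keeps at most one value per attribute: the
    nearest trigger wins, ties go to the preceding trigger.  Triggers with
    no attachable span are dropped; use :func:`attach_attributes_counted`
    to also get the dropped-trigger count.  ``concept_for_span`` maps the
    index of each span (in offset-sorted order) to a concept id; without it
    the normalized surface stands in for the concept.
    """
    phenos, _ = attach_attributes_counted(spans, rules, tokens, concept_for_span)
    return phenos


def attach_attributes_counted(
    spans: Sequence[EntitySpan],
    rules: Sequence[AttributeRule],
    tokens: Sequence[Token],
    concept_for_span: Mapping[int, str] | None = None,
) -> tuple[list[FinePhenotype], int]:
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    sent = _sentence_ids(tokens)
    tok_norm = [normalize_surface(t.text) for t in tokens]

    # token index range covered by each span
    span_tok: list[tuple[int, int]] = []
    for s in ordered:
        covered = [k for k, t in enumerate(tokens) if t.start >= s.start and t.end <= s.end]
        if not covered:  # span not aligned to tokens: treat nearest overlap
            covered = [
                k for k, t in enumerate(tokens) if t.end > s.start and t.start < s.end
            ]
        span_tok.append((min(covered), max(covered)) if covered else (-1, -1))

    def _match_trigger(k: int, target: str) -> int | None:
        """Try to match ``target`` (normalized, whitespace-free) against the
        concatenation of token surfaces starting at token ``k``; return the
        index of the last matched token.  Works for both word tokens and
        single-character tokens."""
        if not tok_norm[k] or not target.startswith(tok_norm[k]):
            return None
        acc = ""
        for j in range(k, min(k + 8, len(tokens))):
            acc += tok_norm[j]
            if len(acc) >= len(target):
                return j if acc == target else None
        return None

    # best (distance, trigger position) per (span index, attribute)
    best: dict[tuple[int, str], tuple[int, int, str]] = {}
    dropped = 0
    for rule in rules:
        targets = [
            normalize_surface(trig).replace(" ", "") for trig in rule.trigger_surfaces
        ]
        for k in range(len(tokens)):
            matched = None
            for target in targets:
                j = _match_trigger(k, target)
                if j is not None:
                    matched = (k, j)
                    break
            if matched is None:
                continue
            t_first, t_last = matched
            cand = None  # (distance, span index)
            for si, (a, b) in enumerate(span_tok):
                if a < 0:
                    continue
                if rule.direction in ("pre", "both") and a > t_last:
                    dist = a - t_last
                    if dist <= rule.scope_window and sent[a] == sent[t_last]:
                        if cand is None or dist < cand[0]:
                            cand = (dist, si)
                if rule.direction in ("post", "both") and b < t_first:
                    dist = t_first - b
                    if dist <= rule.scope_window and sent[b] == sent[t_first]:
                        if cand is None or dist < cand[0]:
                            cand = (dist, si)
            if cand is None:
                dropped += 1
                continue
            dist, si = cand
            key = (si, rule.attribute_name)
            prev = best.get(key)
            # nearest trigger wins; ties -> the earlier (preceding) trigger
            if prev is None or (dist, t_first) < (prev[0], prev[1]):
                best[key] = (dist, t_first, rule.value)

    phenos: list[FinePhenotype] = []
    for si, s in enumerate(ordered):
        concept = (
            concept_for_span[si]
            if concept_for_span is not None
            else normalize_surface(s.surface)
        )
        attrs = {
            attr: val
            for (sj, attr), (_, _, val) in best.items()
            if sj == si
        }
        phenos.append(FinePhenotype(concept_id=concept, attributes=attrs, source_span=s))
    return phenos, dropped


class CoarseVectorizer(BaseEstimator, TransformerMixin):
    """Binary concept-presence features over a fixed concept vocabulary."""

    def __init__(self, concepts: Sequence[str] | None = None):
        self.concepts = concepts

    def fit(self, X: Sequence[Sequence[FinePhenotype]], y=None):
        if self.concepts is not None:
            vocab = list(self.concepts)
        else:
            vocab = sorted({p.concept_id for row in X for p in row})
        self.vocabulary_ = {c: i for i, c in enumerate(vocab)}
        self.unknown_count_ = 0
        return self

    def get_feature_names_out(self) -> list[str]:
        return list(self.vocabulary_)

    def transform(self, X: Sequence[Sequence[FinePhenotype]]) -> np.ndarray:
        out = np.zeros((len(X), len(self.vocabulary_)))
        for i, row in enumerate(X):
            for p in row:
                j = self.vocabulary_.get(p.concept_id)
                if j is None:
                    self.unknown_count_ += 1
                    continue
                out[i, j] = 1.0
        return out


class FineVectorizer(BaseEstimator, TransformerMixin):
    """Assertion-aware concept x attribute-value indicator features.

    Layout: a concept-presence block (set only for non-negated mentions)
    followed, per concept, by one indicator per (attribute, value) pair of
    the schema.  Dimension is ``C + C * sum_a |values_a|``.
    """

    def __init__(
        self,
        concepts: Sequence[str] | None = None,
        schema: Mapping[str, Sequence[str]] | None = None,
    ):
        self.concepts = concepts
        self.schema = schema

    def fit(self, X: Sequence[Sequence[FinePhenotype]], y=None):
        if self.concepts is not None:
            vocab = list(self.concepts)
        else:
            vocab = sorted({p.concept_id for row in X for p in row})
        schema = dict(self.schema) if self.schema is not None else dict(DEFAULT_ATTRIBUTE_SCHEMA)
        self.vocabulary_ = {c: i for i, c in enumerate(vocab)}
        self.schema_ = {a: tuple(v) for a, v in schema.items()}
        self.unknown_count_ = 0
        pairs = [(a, v) for a, vals in self.schema_.items() for v in vals]
        self._pair_index = {av: k for k, av in enumerate(pairs)}
        self._block = len(pairs)
        names = list(vocab)
        for c in vocab:
            names.extend(f"{c}|{a}={v}" for a, v in pairs)
        self.feature_names_ = names
        return self

    def get_feature_names_out(self) -> list[str]:
        return list(self.feature_names_)

    @property
    def n_features_(self) -> int:
        return len(self.feature_names_)

    def transform(self, X: Sequence[Sequence[FinePhenotype]]) -> np.ndarray:
        C = len(self.vocabulary_)
        out = np.zeros((len(X), C + C * self._block))
        for i, row in enumerate(X):
            for p in row:
                j = self.vocabulary_.get(p.concept_id)
                if j is None:
                    self.unknown_count_ += 1
                    continue
                if p.assertion != "negated":
                    out[i, j] = 1.0
                attrs = dict(p.attributes)
                attrs.setdefault("assertion", "present")
                for a, v in attrs.items():
                    k = self._pair_index.get((a, v))
                    if k is not None:
                        out[i, C + j * self._block + k] = 1.0
        return out


def coarse_features(
    phenotypes: Sequence[FinePhenotype], vocabulary: Sequence[str]
) -> np.ndarray:
    """One record's binary concept-presence vector."""
    vec = CoarseVectorizer(concepts=vocabulary).fit([])
    return vec.transform([list(phenotypes)])[0]


def fine_features(
    phenotypes: Sequence[FinePhenotype],
    vocabulary: Sequence[str],
    schema: Mapping[str, Sequence[str]] | None = None,
) -> np.ndarray:
    """One record's assertion-aware fine-grained vector."""
    vec = FineVectorizer(concepts=vocabulary, schema=schema).fit([])
    return vec.transform([list(phenotypes)])[0]
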