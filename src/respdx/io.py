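"""Plain-text serialization: JSON-Lines corpora and CoNLL BIO files."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

from .ner import EntitySpan, Token, bio_encode, tokenize
from .synth import AnnotatedRecord, SECTION_NAMES

__all__ = [
    "write_corpus_jsonl",
    "read_corpus_jsonl",
    "write_conll",
    "read_conll",
    "record_sequences",
]


def _span_to_obj(s: EntitySpan) -> dict:
    obj = {
        "section": s.section,
        "start": s.start,
        "end": s.end,
        "category": s.category,
        "surface": s.surface,
    }
    if s.attributes:
        obj["attributes"] = dict(s.attributes)
    return obj


def _span_from_obj(obj: dict) -> EntitySpan:
    attrs = obj.get("attributes")
    return EntitySpan(
        section=obj["section"],
        start=obj["start"],
        end=obj["end"],
        category=obj["category"],
        surface=obj["surface"],
        attributes=tuple(sorted(attrs.items())) if attrs else None,
    )


def write_corpus_jsonl(records: Sequence[AnnotatedRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            obj = {
                "record_id": r.record_id,
                "sections": r.sections,
                "gold_spans": [_span_to_obj(s) for s in r.gold_spans],
                "primary_label": r.primary_label,
                "secondary_labels": r.secondary_labels,
            }
            fh.write(json.dumps(obj, ensure_ascii=False, sort_keys=True) + "\n")


def read_corpus_jsonl(path: str | Path) -> list[AnnotatedRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.strip():
                continue
            obj = json.loads(line)
            rec = AnnotatedRecord(
                record_id=obj["record_id"],
                sections=obj["sections"],
                gold_spans=[_span_from_obj(s) for s in obj["gold_spans"]],
                primary_label=obj["primary_label"],
                secondary_labels=list(obj.get("secondary_labels", [])),
            )
            rec.validate()
            records.append(rec)
    return records


def record_sequences(
    record: AnnotatedRecord, dialect: str
) -> list[tuple[list[Token], list[str]]]:
    """Per-section (tokens, gold BIO tags) pairs for one record."""
    out = []
    for section in SECTION_NAMES:
        text = record.sections.get(section, "")
        tokens = tokenize(text, dialect)
        if not tokens:
            continue
        spans = [s for s in record.gold_spans if s.section == section]
        out.append((tokens, bio_encode(spans, tokens)))
    return out


def write_conll(
    records: Sequence[AnnotatedRecord], path: str | Path, dialect: str
) -> None:
    """Token TAB tag, one blank line between sentences (= record sections)."""
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            for tokens, tags in record_sequences(r, dialect):
                for tok, tag in zip(tokens, tags):
                    fh.write(f"{tok.text}\t{tag}\n")
                fh.write("\n")


def read_conll(path: str | Path) -> list[tuple[list[str], list[str]]]:
    sequences: list[tuple[list[str], list[str]]] = []
    toks: list[str] = []
    tags: list[str] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines() + [""]:
        if not line.strip():
            if toks:
                sequences.append((toks, tags))
                toks, tags = [], []
            continue
        tok, tag = line.split("\t")
        toks.append(tok)
        tags.append(tag)
    return sequences
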