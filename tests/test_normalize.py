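"""Surface normalization, lexicon mapping, attribute attachment, and the
coarse/fine feature encodings."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from respdx.ner import EntitySpan, tokenize
from respdx.normalize import (
    CoarseVectorizer,
    FineVectorizer,
    AttributeRule,
    FinePhenotype,
    Lexicon,
    TermEntry,
    attach_attributes,
    attach_attributes_counted,
    coarse_features,
    fine_features,
    map_to_concept,
    normalize_surface,
)


# ---------------------------------------------------------------------------
# normalize_surface
# ---------------------------------------------------------------------------


def test_normalize_surface_examples():
    assert normalize_surface("  Cough,") == "cough"
    assert normalize_surface("ＣＯＰＤ") == "copd"
    assert normalize_surface("barrel   chest") == "barrel chest"


@settings(derandomize=True, max_examples=300)
@given(st.text(max_size=30))
def test_normalize_surface_idempotent(s):
    once = normalize_surface(s)
    assert normalize_surface(once) == once


# ---------------------------------------------------------------------------
# lexicon
# ---------------------------------------------------------------------------


def _lex():
    return Lexicon([
        TermEntry("cough", "symptom", "C1", "cough"),
        TermEntry("tussis", "symptom", "C1", "cough"),
        TermEntry("fever", "symptom", "C2", "fever"),
    ])


def test_synonyms_resolve_to_one_concept():
    lex = _lex()
    a = map_to_concept(EntitySpan("s", 0, 5, "symptom", "Cough"), lex)
    b = map_to_concept(EntitySpan("s", 0, 6, "symptom", "tussis"), lex)
    assert a == b == "C1"


def test_unmapped_surface_returns_none_and_is_counted():
    lex = _lex()
    assert map_to_concept(EntitySpan("s", 0, 3, "symptom", "xyz"), lex) is None
    assert lex.unmapped_count == 1


def test_category_scoping():
    lex = _lex()
    assert map_to_concept(EntitySpan("s", 0, 5, "test", "cough"), lex) is None


def test_duplicate_rows_rejected_at_load():
    with pytest.raises(ValueError):
        Lexicon([
            TermEntry("cough", "symptom", "C1", "cough"),
            TermEntry("Cough ", "symptom", "C9", "other"),
        ])
    with pytest.raises(ValueError):
        Lexicon([
            TermEntry("a", "symptom", "C1", "name1"),
            TermEntry("b", "symptom", "C1", "name2"),
        ])


def test_mapping_invariant_under_normalization():
    lex = _lex()
    for raw in ("Cough", "  cough,", "ＣＯＵＧＨ".lower()):
        s1 = map_to_concept(EntitySpan("s", 0, 5, "symptom", raw), lex)
        s2 = map_to_concept(
            EntitySpan("s", 0, 5, "symptom", normalize_surface(raw)), lex
        )
        assert s1 == s2 == "C1"


def test_442_surfaces_collapse_to_252_concepts():
    """Lexicon fixture mirroring the 442 raw features -> 252 standardized
    concepts structure: presenting every surface once yields exactly 252
    distinct mapped ids."""
    entries = []
    k = 0
    for c in range(252):
        n_surfaces = 2 if c < 190 else 1  # 190*2 + 62*1 = 442
        for s in range(n_surfaces):
            entries.append(TermEntry(f"surf{k}", "symptom", f"C{c}", f"name{c}"))
            k += 1
    assert k == 442
    lex = Lexicon(entries)
    mapped = {
        map_to_concept(EntitySpan("s", 0, 1, "symptom", f"surf{i}"), lex)
        for i in range(442)
    }
    assert len(mapped) == 252


def test_lexicon_tsv_roundtrip(tmp_path):
    lex = _lex()
    path = tmp_path / "lex.tsv"
    lex.to_tsv(path)
    back = Lexicon.from_tsv(path)
    assert len(back) == len(lex)
    assert back.lookup("tussis", "symptom") == "C1"
    bad = tmp_path / "missing_header.tsv"
    bad.write_text("a\tb\tc\td\n")
    with pytest.raises(ValueError):
        Lexicon.from_tsv(bad)


# ---------------------------------------------------------------------------
# attribute attachment
# ---------------------------------------------------------------------------

NEG = AttributeRule("assertion", "negated", ("no",), "pre", 3)


def _span_at(text, surface, category="symptom"):
    start = text.index(surface)
    return EntitySpan("s", start, start + len(surface), category, surface)


def test_negation_trigger_attaches_forward():
    text = "no fever today ."
    toks = tokenize(text, "whitespace")
    ph = attach_attributes([_span_at(text, "fever")], [NEG], toks)
    assert ph[0].attributes == {"assertion": "negated"}


def test_trigger_beyond_window_not_attached():
    text = "no aa bb cc dd fever ."
    toks = tokenize(text, "whitespace")
    ph = attach_attributes([_span_at(text, "fever")], [NEG], toks)
    assert "assertion" not in ph[0].attributes


def test_attachment_does_not_cross_sentence_boundary():
    text = "denies everything . fever persists ."
    toks = tokenize(text, "whitespace")
    rule = AttributeRule("assertion", "negated", ("denies",), "pre", 6)
    ph = attach_attributes([_span_at(text, "fever")], [rule], toks)
    assert "assertion" not in ph[0].attributes


def test_nearest_trigger_wins_ties_go_to_preceding():
    text = "mild cough severe"
    toks = tokenize(text, "whitespace")
    rules = [
        AttributeRule("severity", "mild", ("mild",), "both", 3),
        AttributeRule("severity", "severe", ("severe",), "both", 3),
    ]
    ph = attach_attributes([_span_at(text, "cough")], rules, toks)
    # both triggers at distance 1: the preceding one ("mild") wins
    assert ph[0].attributes["severity"] == "mild"


def test_unattachable_triggers_counted():
    text = "no improvement ."
    toks = tokenize(text, "whitespace")
    _, dropped = attach_attributes_counted([], [NEG], toks)
    assert dropped == 1


def test_multi_token_trigger_and_character_tokens():
    text = "患者无咳嗽。"
    toks = tokenize(text, "character")
    rule = AttributeRule("assertion", "negated", ("无",), "pre", 4)
    span = EntitySpan("s", 3, 5, "symptom", "咳嗽")
    ph = attach_attributes([span], [rule], toks)
    assert ph[0].attributes == {"assertion": "negated"}


def _brute_force_attach(spans, rules, tokens):
    """Reference implementation: exhaustive trigger/span scan."""
    from respdx.normalize import _sentence_ids, normalize_surface as norm

    sent = _sentence_ids(tokens)
    tok_norm = [norm(t.text) for t in tokens]
    ordered = sorted(spans, key=lambda s: (s.start, s.end))
    span_tok = []
    for s in ordered:
        cov = [k for k, t in enumerate(tokens) if t.start >= s.start and t.end <= s.end]
        span_tok.append((min(cov), max(cov)))
    best = {}
    for rule in rules:
        for trig in rule.trigger_surfaces:
            target = norm(trig).replace(" ", "")
            for k in range(len(tokens)):
                acc = ""
                j = k
                ok = False
                while j < len(tokens) and len(acc) < len(target):
                    acc += tok_norm[j]
                    if acc == target:
                        ok = True
                        break
                    j += 1
                if not (ok and tok_norm[k] and target.startswith(tok_norm[k])):
                    continue
                # the trigger attaches to its single nearest span only
                nearest = None  # (dist, span index)
                for si, (a, b) in enumerate(span_tok):
                    if rule.direction in ("pre", "both") and a > j:
                        d = a - j
                        if d <= rule.scope_window and sent[a] == sent[j]:
                            if nearest is None or d < nearest[0]:
                                nearest = (d, si)
                    if rule.direction in ("post", "both") and b < k:
                        d = k - b
                        if d <= rule.scope_window and sent[b] == sent[k]:
                            if nearest is None or d < nearest[0]:
                                nearest = (d, si)
                if nearest is None:
                    continue
                d, si = nearest
                key = (si, rule.attribute_name)
                prev = best.get(key)
                if prev is None or (d, k) < prev[:2]:
                    best[key] = (d, k, rule.value)
    out = []
    for si in range(len(ordered)):
        out.append({
            attr: val for (sj, attr), (_, _, val) in best.items() if sj == si
        })
    return out


def test_attachment_matches_bruteforce_reference_on_random_layouts():
    rng = np.random.default_rng(20190401)
    rules = [
        AttributeRule("assertion", "negated", ("no", "denies"), "pre", 3),
        AttributeRule("severity", "severe", ("severe",), "both", 2),
        AttributeRule("trend", "worsening", ("worsening",), "post", 4),
    ]
    vocab = ["aa", "bb", "cc", "no", "denies", "severe", "worsening", "."]
    for _ in range(200):
        n = int(rng.integers(3, 14))
        words = [vocab[i] for i in rng.integers(0, len(vocab), size=n)]
        text = " ".join(words)
        toks = tokenize(text, "whitespace")
        spans = []
        for k, t in enumerate(toks):
            if t.text in ("aa", "bb", "cc") and rng.random() < 0.5:
                spans.append(EntitySpan("s", t.start, t.end, "symptom", t.text))
        got = attach_attributes(spans, rules, toks)
        want = _brute_force_attach(spans, rules, toks)
        assert [p.attributes for p in got] == want


# ---------------------------------------------------------------------------
# feature encodings
# ---------------------------------------------------------------------------

VOCAB = ["c1", "c2", "c3", "c4", "c5"]
TOY_SCHEMA = {"assertion": ("present", "negated"), "severity": ("mild", "severe", "x")}


def test_coarse_features_basics():
    assert np.array_equal(coarse_features([], VOCAB), np.zeros(5))
    one = coarse_features([FinePhenotype("c2")], VOCAB)
    two = coarse_features([FinePhenotype("c2"), FinePhenotype("c2")], VOCAB)
    assert np.array_equal(one, two)  # binary presence
    assert one[1] == 1.0 and one.sum() == 1.0
    assert len(one) == len(VOCAB)


def test_fine_features_dimension_closed_form():
    v = fine_features([], VOCAB, TOY_SCHEMA)
    assert len(v) == 5 + 5 * (2 + 3)


def test_fine_features_negation_aware_encoding():
    vec = FineVectorizer(concepts=VOCAB, schema=TOY_SCHEMA).fit([])
    X = vec.transform([[FinePhenotype("c1", {"assertion": "negated"})]])
    names = vec.get_feature_names_out()
    assert X[0][names.index("c1")] == 0.0  # bare presence clear
    assert X[0][names.index("c1|assertion=negated")] == 1.0
    X2 = vec.transform([[FinePhenotype("c1")]])
    assert X2[0][names.index("c1")] == 1.0
    assert X2[0][names.index("c1|assertion=present")] == 1.0


def test_fine_presence_block_equals_coarse_without_negation():
    phenos = [
        [FinePhenotype("c1", {"severity": "mild"}), FinePhenotype("c3")],
        [FinePhenotype("c5")],
        [],
    ]
    coarse = CoarseVectorizer(concepts=VOCAB).fit([]).transform(phenos)
    fine = FineVectorizer(concepts=VOCAB, schema=TOY_SCHEMA).fit([]).transform(phenos)
    assert np.array_equal(fine[:, : len(VOCAB)], coarse)


def test_unknown_concepts_ignored_and_counted():
    vec = CoarseVectorizer(concepts=VOCAB).fit([])
    X = vec.transform([[FinePhenotype("nope")]])
    assert X.sum() == 0.0 and vec.unknown_count_ == 1
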