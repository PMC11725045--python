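"""Tokenization, BIO codec, and exact CRF inference checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logsumexp

from respdx import ner
from respdx.ner import (
    CRFModel,
    CRFTagger,
    EntitySpan,
    TagSchema,
    AnnotationError,
    bio_decode,
    bio_encode,
    forward_logZ,
    path_score,
    span_prf,
    tokenize,
    viterbi,
)


# ---------------------------------------------------------------------------
# tokenize
# ---------------------------------------------------------------------------


def test_tokenize_whitespace_offsets():
    toks = tokenize("no fever", "whitespace")
    assert [(t.text, t.start, t.end) for t in toks] == [("no", 0, 2), ("fever", 3, 8)]


def test_tokenize_character_mode():
    toks = tokenize("咳嗽", "character")
    assert [(t.text, t.start, t.end) for t in toks] == [("咳", 0, 1), ("嗽", 1, 2)]


def test_tokenize_empty_and_unknown_dialect():
    assert tokenize("", "whitespace") == []
    with pytest.raises(ValueError):
        tokenize("x", "bogus")


@settings(derandomize=True, max_examples=200)
@given(st.text(max_size=40), st.sampled_from(["whitespace", "character"]))
def test_tokenize_offsets_increasing_and_content_preserving(text, dialect):
    toks = tokenize(text, dialect)
    for a, b in zip(toks, toks[1:]):
        assert a.end <= b.start
    rebuilt = "".join(text[t.start : t.end] for t in toks)
    assert rebuilt == "".join(ch for ch in text if not ch.isspace()) or dialect == "whitespace"
    if dialect == "whitespace":
        assert rebuilt == "".join(text.split())
    for t in toks:
        assert text[t.start : t.end] == t.text


# ---------------------------------------------------------------------------
# BIO codec
# ---------------------------------------------------------------------------


def _toks(text):
    return tokenize(text, "whitespace")


def test_bio_encode_basics():
    text = "has barrel chest now"
    toks = _toks(text)
    assert bio_encode([], toks) == ["O"] * 4
    span = EntitySpan("s", 4, 16, "symptom", "barrel chest")
    assert bio_encode([span], toks) == ["O", "B-symptom", "I-symptom", "O"]


def test_bio_encode_rejects_overlap_and_misalignment():
    text = "aa bb cc"
    toks = _toks(text)
    s1 = EntitySpan("s", 0, 5, "symptom", "aa bb")
    s2 = EntitySpan("s", 3, 8, "symptom", "bb cc")
    with pytest.raises(AnnotationError):
        bio_encode([s1, s2], toks)
    with pytest.raises(AnnotationError):
        bio_encode([EntitySpan("s", 1, 2, "symptom", "a")], toks)


def test_bio_decode_repairs_stray_inside_tag():
    toks = _toks("fever")
    spans = bio_decode(["I-symptom"], toks, section="s", text="fever")
    assert len(spans) == 1 and spans[0].category == "symptom"
    assert spans[0].surface == "fever"


def test_bio_decode_unknown_tag():
    with pytest.raises(ValueError):
        bio_decode(["B-nope"], _toks("x"))


def _brute_force_decode(tags):
    """Reference decoder: explicit scan collecting B-x (I-x)* runs with the
    stray-I repair rule."""
    spans = []
    i = 0
    while i < len(tags):
        t = tags[i]
        if t == "O":
            i += 1
            continue
        cat = t[2:]
        j = i + 1
        while j < len(tags) and tags[j] == f"I-{cat}":
            j += 1
        spans.append((i, j, cat))
        i = j
    return spans


@settings(derandomize=True, max_examples=100)
@given(st.data())
def test_bio_decode_matches_brute_force_reference(data):
    schema = TagSchema()
    tags = data.draw(st.lists(st.sampled_from(schema.tags), min_size=1, max_size=12))
    words = [f"w{i}" for i in range(len(tags))]
    text = " ".join(words)
    toks = _toks(text)
    got = [
        (next(k for k, t in enumerate(toks) if t.start == s.start),
         next(k for k, t in enumerate(toks) if t.end == s.end) + 1,
         s.category)
        for s in bio_decode(tags, toks, text=text)
    ]
    assert got == _brute_force_decode(tags)


@settings(derandomize=True, max_examples=50)
@given(st.data())
def test_bio_roundtrip_on_valid_span_sets(data):
    n = data.draw(st.integers(3, 12))
    toks = _toks(" ".join(f"w{i}" for i in range(n)))
    # build random non-overlapping aligned spans
    spans = []
    i = 0
    while i < n - 1:
        if data.draw(st.booleans()):
            j = min(n, i + data.draw(st.integers(1, 3)))
            cat = data.draw(st.sampled_from(ner.ENTITY_CATEGORIES))
            spans.append(
                EntitySpan("s", toks[i].start, toks[j - 1].end, cat,
                           " ".join(t.text for t in toks[i:j]))
            )
            i = j
        else:
            i += 1
    tags = bio_encode(spans, toks)
    decoded = bio_decode(tags, toks)
    assert [(s.start, s.end, s.category) for s in decoded] == [
        (s.start, s.end, s.category) for s in spans
    ]


# ---------------------------------------------------------------------------
# CRF inference
# ---------------------------------------------------------------------------


def _random_model(rng, schema):
    T = schema.n_tags
    return CRFModel(
        transition=rng.normal(size=(T, T)),
        start_scores=rng.normal(size=T),
        end_scores=rng.normal(size=T),
        emission_scorer=None,
        schema=schema,
    )


def test_path_score_zero_parameters():
    schema = TagSchema(categories=("a",))
    m = CRFModel(np.zeros((3, 3)), np.zeros(3), np.zeros(3), None, schema)
    assert path_score(np.zeros((1, 3)), m, [0]) == 0.0


def test_path_score_emission_shift_linearity():
    rng = np.random.default_rng(0)
    schema = TagSchema(categories=("a", "b"))
    m = _random_model(rng, schema)
    em = rng.normal(size=(6, schema.n_tags))
    path = list(rng.integers(0, schema.n_tags, size=6))
    c = 1.7
    s0 = path_score(em, m, path)
    s1 = path_score(em + c, m, path)
    assert s1 == pytest.approx(s0 + c * 6, abs=1e-9)


def test_path_score_direct_recomputation_and_domain_error():
    rng = np.random.default_rng(1)
    schema = TagSchema(categories=("a", "b"))
    m = _random_model(rng, schema)
    for _ in range(20):
        L = int(rng.integers(1, 6))
        em = rng.normal(size=(L, schema.n_tags))
        path = list(rng.integers(0, schema.n_tags, size=L))
        expected = m.start_scores[path[0]] + em[0, path[0]]
        for t in range(1, L):
            expected += m.transition[path[t - 1], path[t]] + em[t, path[t]]
        expected += m.end_scores[path[-1]]
        assert path_score(em, m, path) == pytest.approx(expected, abs=1e-10)
    with pytest.raises(ValueError):
        path_score(np.zeros((2, schema.n_tags)), m, [0, 99])


def test_forward_logZ_single_token_uniform():
    schema = TagSchema(categories=("a",))  # 3 tags
    m = CRFModel(np.zeros((3, 3)), np.zeros(3), np.zeros(3), None, schema)
    assert forward_logZ(np.zeros((1, 3)), m) == pytest.approx(np.log(3), abs=1e-12)


def test_forward_logZ_rejects_nonfinite():
    schema = TagSchema(categories=("a",))
    m = CRFModel(np.zeros((3, 3)), np.zeros(3), np.zeros(3), None, schema)
    with pytest.raises(ValueError):
        forward_logZ(np.array([[np.nan, 0.0, 0.0]]), m)


def test_crf_enumeration_oracle_small_instances():
    """forward_logZ and viterbi against exhaustive path enumeration."""
    rng = np.random.default_rng(20190401)
    schema = TagSchema(categories=("a", "b"))  # 5 tags
    T = schema.n_tags
    for _ in range(60):
        L = int(rng.integers(1, 5))
        em = rng.normal(size=(L, T)) * 2
        m = _random_model(rng, schema)
        scores = np.array(
            [path_score(em, m, p) for p in itertools.product(range(T), repeat=L)]
        )
        assert forward_logZ(em, m) == pytest.approx(logsumexp(scores), abs=1e-8)
        path, vs = viterbi(em, m)
        assert vs == pytest.approx(scores.max(), abs=1e-8)
        assert path_score(em, m, path) == pytest.approx(vs, abs=1e-9)
        assert forward_logZ(em, m) >= vs - 1e-9


def test_viterbi_one_hot_emissions():
    schema = TagSchema(categories=("a", "b"))
    T = schema.n_tags
    m = CRFModel(np.zeros((T, T)), np.zeros(T), np.zeros(T), None, schema)
    want = [1, 3, 0, 2]
    em = np.zeros((4, T))
    for i, y in enumerate(want):
        em[i, y] = 5.0
    path, _ = viterbi(em, m)
    assert path == want


def test_viterbi_tie_breaks_to_lowest_tag_index():
    schema = TagSchema(categories=("a", "b"))
    T = schema.n_tags
    m = CRFModel(np.zeros((T, T)), np.zeros(T), np.zeros(T), None, schema)
    path, _ = viterbi(np.zeros((3, T)), m)
    assert path == [0, 0, 0]


def test_hard_mask_never_decodes_invalid_transitions():
    rng = np.random.default_rng(3)
    schema = TagSchema()
    T = schema.n_tags
    invalid = schema.invalid_transition_mask()
    for _ in range(100):
        m = CRFModel(
            transition=rng.normal(size=(T, T)) * 3,
            start_scores=rng.normal(size=T),
            end_scores=rng.normal(size=T),
            emission_scorer=None,
            schema=schema,
            hard_mask=True,
        )
        em = rng.normal(size=(int(rng.integers(1, 8)), T)) * 3
        path, _ = viterbi(em, m)
        assert not schema.tags[path[0]].startswith("I-")
        for a, b in zip(path, path[1:]):
            assert not invalid[a, b]


# ---------------------------------------------------------------------------
# training and end-to-end tagging
# ---------------------------------------------------------------------------


def _tiny_corpus():
    sents = [
        ("reports severe cough .", [("cough", "symptom")]),
        ("labs show leukocytosis .", [("leukocytosis", "test")]),
        ("imaging shows consolidation .", [("consolidation", "image_finding")]),
        ("history of emphysema .", [("emphysema", "disease_name")]),
        ("denies fever .", [("fever", "symptom")]),
    ]
    X, y = [], []
    for text, ents in sents * 4:
        toks = _toks(text)
        spans = []
        for surf, cat in ents:
            start = text.index(surf)
            spans.append(EntitySpan("s", start, start + len(surf), cat, surf))
        X.append([t.text for t in toks])
        y.append(bio_encode(spans, toks))
    return X, y


def test_train_memorizes_small_corpus():
    X, y = _tiny_corpus()
    tagger = CRFTagger(max_epochs=8, holdout=0.0, seed=1).fit(X, y)
    pred = tagger.predict(X)
    correct = sum(p == g for pp, gg in zip(pred, y) for p, g in zip(pp, gg))
    total = sum(len(g) for g in y)
    assert correct / total == 1.0


def test_train_loss_path_non_increasing():
    X, y = _tiny_corpus()
    tagger = CRFTagger(max_epochs=6, holdout=0.0, seed=1).fit(X, y)
    losses = tagger.train_loss_path_
    assert all(b <= a + 1e-9 for a, b in zip(losses, losses[1:]))


def test_zero_epochs_returns_initialization():
    X, y = _tiny_corpus()
    tagger = CRFTagger(max_epochs=0).fit(X, y)
    assert tagger.n_epochs_ == 0
    assert np.all(tagger.model_.transition == 0.0)
    assert np.all(tagger.model_.emission_scorer.weights == 0.0)


def test_train_warns_on_spanless_corpus():
    X = [["aa", "bb"], ["cc", "dd"]]
    y = [["O", "O"], ["O", "O"]]
    with pytest.warns(UserWarning):
        CRFTagger(max_epochs=1).fit(X, y)


def test_training_deterministic_given_seed():
    X, y = _tiny_corpus()
    t1 = CRFTagger(max_epochs=3, seed=5).fit(X, y)
    t2 = CRFTagger(max_epochs=3, seed=5).fit(X, y)
    assert np.array_equal(t1.model_.transition, t2.model_.transition)
    assert np.array_equal(
        t1.model_.emission_scorer.weights, t2.model_.emission_scorer.weights
    )


def test_predict_entities_with_oracle_emissions():
    """Gold-derived tag predictions decode back to exactly the gold spans."""
    from respdx.synth import SynthConfig, build_default_profiles, sample_record
    from respdx.io import record_sequences

    rng = np.random.default_rng(4)
    profiles = build_default_profiles(0.1)
    config = SynthConfig(n_records=10, seed=4)
    record = sample_record(profiles, config, rng, "r0")

    class OracleTagger:
        def __init__(self):
            self.model_ = CRFTagger().__class__  # placeholder
            self.gold = {}
            for (toks, tags) in record_sequences(record, "whitespace"):
                self.gold[tuple(t.text for t in toks)] = tags

        def predict(self, X):
            return [self.gold[tuple(x)] for x in X]

    class _M:
        schema = TagSchema()

    tagger = OracleTagger()
    tagger.model_ = _M()
    spans = ner.predict_entities(record, tagger, "whitespace")
    assert {(s.section, s.start, s.end, s.category) for s in spans} == {
        (s.section, s.start, s.end, s.category) for s in record.gold_spans
    }
    # predictions are sorted and non-overlapping within sections
    by_sec = {}
    for s in spans:
        by_sec.setdefault(s.section, []).append(s)
    for sec_spans in by_sec.values():
        for a, b in zip(sec_spans, sec_spans[1:]):
            assert a.end <= b.start


# ---------------------------------------------------------------------------
# span_prf
# ---------------------------------------------------------------------------


def test_span_prf_perfect_prediction():
    spans = [EntitySpan("s", 0, 4, "symptom", "cough")]
    out = span_prf([spans], [spans])
    assert out["symptom"] == (1.0, 1.0, 1.0)
    assert out["macro"] == (1.0, 1.0, 1.0)


def test_span_prf_f1_identity_from_printed_precision_recall():
    # harmonic-mean identity on a representative published-style row
    p, r = 0.876, 0.886
    f1 = 2 * p * r / (p + r)
    assert round(f1, 3) == 0.881


def test_span_prf_matches_set_intersection_recomputation():
    rng = np.random.default_rng(9)
    cats = list(ner.ENTITY_CATEGORIES)
    for _ in range(30):
        def rand_spans():
            out = []
            used = set()
            for _ in range(rng.integers(0, 8)):
                a = int(rng.integers(0, 30))
                span = (a, a + 1 + int(rng.integers(0, 3)))
                if any(s < span[1] and span[0] < e for s, e in used):
                    continue
                used.add(span)
                out.append(
                    EntitySpan("s", span[0], span[1], cats[rng.integers(len(cats))], "x" * (span[1] - span[0]))
                )
            return out

        gold, pred = rand_spans(), rand_spans()
        out = span_prf([gold], [pred])
        g = {(s.start, s.end, s.category) for s in gold}
        p = {(s.start, s.end, s.category) for s in pred}
        for cat in cats:
            gc = {x for x in g if x[2] == cat}
            pc = {x for x in p if x[2] == cat}
            tp = len(gc & pc)
            exp_p = tp / len(pc) if pc else 0.0
            exp_r = tp / len(gc) if gc else 0.0
            assert out[cat][0] == pytest.approx(exp_p)
            assert out[cat][1] == pytest.approx(exp_r)


def test_span_prf_swap_symmetry():
    """Swapping gold and pred exchanges precision and recall."""
    g = [EntitySpan("s", 0, 3, "symptom", "abc"), EntitySpan("s", 5, 8, "test", "def")]
    p = [EntitySpan("s", 0, 3, "symptom", "abc"), EntitySpan("s", 9, 12, "test", "ghi")]
    a = span_prf([g], [p])
    b = span_prf([p], [g])
    for cat in ("symptom", "test"):
        assert a[cat][0] == pytest.approx(b[cat][1])
        assert a[cat][1] == pytest.approx(b[cat][0])
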