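"""Span/label matching, micro-averaged scoring, confusion matrices, IAA."""

import random

import pytest

from rxneval.brat import Corpus, EntityAnnotation, parse_snippet
from rxneval.schema import NEG_LABEL
from rxneval.scoring import (
    LabelLevel,
    MatchCriterion,
    SpanMode,
    cohens_kappa,
    confusion_matrix,
    map_label,
    match_entities,
    pairwise_f1,
    score_events,
    score_ner,
    spans_match,
)

EXACT = MatchCriterion(SpanMode.EXACT, LabelLevel.FINE)
RELAXED = MatchCriterion(SpanMode.RELAXED, LabelLevel.FINE)


def ann(label, start, end, ann_id="T1", fragments=None):
    frags = fragments if fragments is not None else ((start, end),)
    return EntityAnnotation(id=ann_id, label=label, fragments=tuple(frags), surface="")


# ---------------------------------------------------------------------------
# span matching


@pytest.mark.parametrize(
    "a, b, mode, expected",
    [
        ((10, 20), (10, 20), SpanMode.EXACT, True),
        ((10, 20), (15, 30), SpanMode.EXACT, False),
        ((10, 20), (15, 30), SpanMode.RELAXED, True),
        ((10, 20), (20, 25), SpanMode.RELAXED, False),  # half-open adjacency
        ((10, 20), (19, 21), SpanMode.RELAXED, True),
    ],
)
def test_spans_match(a, b, mode, expected):
    assert spans_match(ann("TIME", *a), ann("TIME", *b), mode) is expected


def test_exact_requires_identical_fragment_lists():
    a = ann("WORKUP", 0, 0, fragments=((0, 6), (13, 17)))
    b = ann("WORKUP", 0, 0, fragments=((0, 6),))
    assert not spans_match(a, b, SpanMode.EXACT)
    assert spans_match(a, b, SpanMode.RELAXED)


def test_map_label_highlevel_collapses_categories(schema):
    high = LabelLevel.HIGHLEVEL
    assert map_label("STARTING_MATERIAL", high, schema) == map_label(
        "REAGENT_CATALYST", high, schema
    ) == "COMPOUND"
    assert map_label("TIME", LabelLevel.FINE, schema) == "TIME"
    assert map_label("YIELD_PERCENT", high, schema) == map_label(
        "YIELD_OTHER", high, schema
    )
    assert map_label("TIME", high, schema) != map_label("YIELD_PERCENT", high, schema)
    # trigger labels map to themselves at both levels
    assert map_label("WORKUP", high, schema) == "WORKUP"


# ---------------------------------------------------------------------------
# entity matching


def test_identical_lists_score_perfectly(schema):
    gold = [ann("TIME", 5, 9, "T1"), ann("SOLVENT", 12, 20, "T2")]
    _, rep = match_entities(gold, list(gold), EXACT, schema)
    assert (rep.precision, rep.recall, rep.f1) == (1.0, 1.0, 1.0)


def test_offset_slip_counts_only_under_relaxed(schema):
    gold = [ann("TIME", 5, 9)]
    pred = [ann("TIME", 6, 9)]
    _, exact = match_entities(gold, pred, EXACT, schema)
    assert (exact.tp, exact.fp, exact.fn) == (0, 1, 1)
    _, relaxed = match_entities(gold, pred, RELAXED, schema)
    assert (relaxed.tp, relaxed.fp, relaxed.fn) == (1, 0, 0)


def _brute_force_max_tp(gold, pred, crit, schema):
    """Exhaustive maximum one-to-one matching over all candidate pairings."""
    from rxneval.scoring import labels_match

    edges = [
        [
            pi
            for pi, p in enumerate(pred)
            if labels_match(g.label, p.label, crit.label_level, schema)
            and spans_match(g, p, crit.span_mode)
        ]
        for g in gold
    ]

    def rec(gi, used):
        if gi == len(gold):
            return 0
        best = rec(gi + 1, used)
        for pi in edges[gi]:
            if pi not in used:
                best = max(best, 1 + rec(gi + 1, used | {pi}))
        return best

    return rec(0, frozenset())


def _random_instance(rng, n_labels=3, max_len=40):
    labels = ["STARTING_MATERIAL", "REAGENT_CATALYST", "TIME"][:n_labels]
    out = []
    for i in range(rng.randint(0, 6)):
        start = rng.randrange(max_len - 2)
        end = rng.randint(start + 1, min(max_len, start + 8))
        frags = [(start, end)]
        if rng.random() < 0.15 and end + 3 < max_len:
            frags.append((end + 2, end + 3))
        out.append(ann(rng.choice(labels), 0, 0, f"T{i}", fragments=frags))
    return out


@pytest.mark.parametrize("crit", [EXACT, RELAXED,
                                  MatchCriterion(SpanMode.RELAXED, LabelLevel.HIGHLEVEL)])
def test_pairing_equals_exhaustive_maximum_matching(schema, crit):
    rng = random.Random(42)
    for _ in range(300):
        gold = _random_instance(rng)
        pred = _random_instance(rng)
        _, rep = match_entities(gold, pred, crit, schema)
        assert rep.tp == _brute_force_max_tp(gold, pred, crit, schema)
        assert rep.tp + rep.fn == len(gold)
        assert rep.tp + rep.fp == len(pred)


def test_chain_of_partial_overlaps_is_matched_maximally(schema):
    """A greedy-by-overlap pass would pair only one of these; maximum is two."""
    gold = [ann("TIME", 0, 5, "G1"), ann("TIME", 5, 20, "G2")]
    pred = [ann("TIME", 3, 15, "P1"), ann("TIME", 15, 30, "P2")]
    _, rep = match_entities(gold, pred, RELAXED, schema)
    assert rep.tp == 2


# ---------------------------------------------------------------------------
# corpus-level scoring


def _corpus_of(schema, *pairs):
    corpus = Corpus()
    for i, (text, ann_content) in enumerate(pairs):
        corpus.add(parse_snippet(text, ann_content, schema, key=f"s{i}"))
    return corpus


def test_score_ner_self_is_perfect(small_corpus, schema):
    for crit in (EXACT, RELAXED):
        rep = score_ner(small_corpus, small_corpus, crit, schema)
        assert rep.f1 == 1.0


def test_score_ner_empty_predictions(schema, small_corpus):
    rep = score_ner(small_corpus, Corpus(), EXACT, schema)
    assert rep.recall == 0.0 and rep.precision == 0.0
    assert rep.fn == sum(len(s.annotations) for s in small_corpus)


def test_score_ner_rejects_unknown_prediction_keys(schema, small_corpus):
    stray = Corpus()
    stray.add(parse_snippet("x y", "", schema, key="not-in-gold"))
    with pytest.raises(KeyError):
        score_ner(small_corpus, stray, EXACT, schema)


def test_score_events_self_and_role_strictness(schema):
    text = "The product was washed with methanol overnight."
    gold_ann = (
        "T1\tWORKUP 16 22\twashed\n"
        "T2\tOTHER_COMPOUND 28 36\tmethanol\n"
        "R1\tArg1 Arg1:T1 Arg2:T2\n"
    )
    gold = _corpus_of(schema, (text, gold_ann))
    assert score_events(gold, gold, EXACT, schema).f1 == 1.0

    # same trigger/argument spans, wrong role: one fp and one fn
    pred_ann = gold_ann.replace("R1\tArg1", "R1\tArgM")
    pred = _corpus_of(schema, (text, pred_ann))
    rep = score_events(gold, pred, EXACT, schema)
    assert (rep.tp, rep.fp, rep.fn) == (0, 1, 1)


def test_event_trigger_span_slip_matches_only_relaxed(schema):
    text = "The product was washed with methanol overnight."
    gold = _corpus_of(
        schema,
        (
            text,
            "T1\tWORKUP 16 22\twashed\nT2\tOTHER_COMPOUND 28 36\tmethanol\n"
            "R1\tArg1 Arg1:T1 Arg2:T2\n",
        ),
    )
    pred = _corpus_of(
        schema,
        (
            text,
            "T1\tWORKUP 12 22\twas washed\nT2\tOTHER_COMPOUND 28 36\tmethanol\n"
            "R1\tArg1 Arg1:T1 Arg2:T2\n",
        ),
    )
    assert score_events(gold, pred, EXACT, schema).tp == 0
    assert score_events(gold, pred, RELAXED, schema).tp == 1


def test_duplicate_relations_are_deduplicated(schema):
    text = "The product was washed with methanol overnight."
    gold = _corpus_of(
        schema,
        (
            text,
            "T1\tWORKUP 16 22\twashed\nT2\tOTHER_COMPOUND 28 36\tmethanol\n"
            "R1\tArg1 Arg1:T1 Arg2:T2\n",
        ),
    )
    pred = _corpus_of(
        schema,
        (
            text,
            "T1\tWORKUP 16 22\twashed\nT2\tOTHER_COMPOUND 28 36\tmethanol\n"
            "R1\tArg1 Arg1:T1 Arg2:T2\nR2\tArg1 Arg1:T1 Arg2:T2\n",
        ),
    )
    rep = score_events(gold, pred, EXACT, schema)
    assert (rep.tp, rep.fp, rep.fn) == (1, 0, 0)


# ---------------------------------------------------------------------------
# confusion matrix


def test_confusion_identity_is_diagonal(schema, small_corpus):
    cm = confusion_matrix(small_corpus, small_corpus, schema)
    assert cm.off_diagonal() == 0
    assert all(g == p for (g, p) in cm.counts)


def test_confusion_single_label_error(schema):
    text = "hydroxyacetic acid was added"
    gold = _corpus_of(schema, (text, "T1\tSTARTING_MATERIAL 0 18\thydroxyacetic acid\n"))
    pred = _corpus_of(schema, (text, "T1\tREAGENT_CATALYST 0 18\thydroxyacetic acid\n"))
    cm = confusion_matrix(gold, pred, schema)
    assert cm.counts[("STARTING_MATERIAL", "REAGENT_CATALYST")] == 1
    assert cm.off_diagonal() == 1


def test_confusion_neg_row_and_column(schema):
    text = "water was added then filtered"
    gold = _corpus_of(
        schema,
        (text, "T1\tOTHER_COMPOUND 0 5\twater\nT2\tWORKUP 21 29\tfiltered\n"),
    )
    pred = _corpus_of(schema, (text, "T1\tWORKUP 10 15\tadded\n"))
    cm = confusion_matrix(gold, pred, schema)
    assert cm.counts[("OTHER_COMPOUND", NEG_LABEL)] == 1
    assert cm.counts[("WORKUP", NEG_LABEL)] == 1
    assert cm.counts[(NEG_LABEL, "WORKUP")] == 1
    # gold conservation: non-NEG rows sum to the gold annotation count
    df = cm.to_dataframe()
    assert df.drop(index=NEG_LABEL).to_numpy().sum() == 2


# ---------------------------------------------------------------------------
# inter-annotator agreement


def test_pairwise_f1_identity_symmetry_disjoint(schema):
    text = "water was added then filtered"
    a = _corpus_of(schema, (text, "T1\tOTHER_COMPOUND 0 5\twater\n"))
    b = _corpus_of(schema, (text, "T1\tWORKUP 21 29\tfiltered\n"))
    assert pairwise_f1(a, a, EXACT, schema) == 1.0
    assert pairwise_f1(a, b, EXACT, schema) == pairwise_f1(b, a, EXACT, schema) == 0.0


def test_kappa_identical_annotations(schema, small_corpus):
    assert cohens_kappa(small_corpus, small_corpus, schema).kappa == 1.0


def test_kappa_hand_worked_example(schema):
    """4 union units, A=(X,X,Y,NONE), B=(X,Y,Y,Y).

    Marginals: A = (X 1/2, Y 1/4, NONE 1/4), B = (X 1/4, Y 3/4, NONE 0),
    so p_o = 1/2, p_e = 1/2*1/4 + 1/4*3/4 = 5/16, and
    kappa = (1/2 - 5/16)/(1 - 5/16) = 3/11 (cross-checked against an
    independent kappa routine in the next test). X/Y realized as
    TIME/SOLVENT spans; the unit where A abstains is a span only B
    annotated.
    """
    text = "aa bb cc dd ee ff gg hh"
    ann_a = (
        "T1\tTIME 0 2\taa\n"
        "T2\tTIME 3 5\tbb\n"
        "T3\tSOLVENT 6 8\tcc\n"
    )
    ann_b = (
        "T1\tTIME 0 2\taa\n"
        "T2\tSOLVENT 3 5\tbb\n"
        "T3\tSOLVENT 6 8\tcc\n"
        "T4\tSOLVENT 9 11\tdd\n"
    )
    a = _corpus_of(schema, (text, ann_a))
    b = _corpus_of(schema, (text, ann_b))
    rep = cohens_kappa(a, b, schema)
    assert rep.n_units == 4
    assert rep.observed_agreement == pytest.approx(0.5)
    assert rep.expected_agreement == pytest.approx(5 / 16)
    assert rep.kappa == pytest.approx(3 / 11)
    from sklearn.metrics import cohen_kappa_score

    assert rep.kappa == pytest.approx(
        cohen_kappa_score(["X", "X", "Y", "NONE"], ["X", "Y", "Y", "Y"])
    )


def test_kappa_agrees_with_sklearn(schema):
    """Cross-check the kappa computation against an independent routine."""
    from sklearn.metrics import cohen_kappa_score

    rng = random.Random(7)
    words = ["w%02d" % i for i in range(40)]
    text = " ".join(words)
    spans = [(i * 4, i * 4 + 3) for i in range(40)]
    labels = ["TIME", "SOLVENT", "WORKUP", None]

    def annotator(seed):
        r = random.Random(seed)
        lines = []
        assigned = []
        for i, (s, e) in enumerate(spans):
            lab = r.choice(labels)
            assigned.append(lab)
            if lab:
                lines.append(f"T{i}\t{lab} {s} {e}\t{words[i]}")
        return "\n".join(lines) + "\n", assigned

    ann_a, lab_a = annotator(1)
    ann_b, lab_b = annotator(2)
    a = _corpus_of(schema, (text, ann_a))
    b = _corpus_of(schema, (text, ann_b))
    rep = cohens_kappa(a, b, schema)
    # restrict the reference computation to union-annotated units
    units = [i for i in range(40) if lab_a[i] or lab_b[i]]
    ref = cohen_kappa_score(
        [lab_a[i] or "NONE" for i in units], [lab_b[i] or "NONE" for i in units]
    )
    assert rep.kappa == pytest.approx(ref)


def test_kappa_near_zero_for_independent_annotators(schema):
    """Independent draws from identical marginals give kappa ~ 0."""
    n = 10_000
    text = "x" * (4 * n)
    labels = ["TIME", "SOLVENT", "WORKUP"]
    weights = [0.5, 0.3, 0.2]

    def annotator(seed):
        r = random.Random(seed)
        lines = []
        for i in range(n):
            s = 4 * i
            lines.append(f"T{i}\t{r.choices(labels, weights)[0]} {s} {s + 2}\txx")
        return "\n".join(lines) + "\n"

    a = _corpus_of(schema, (text, annotator(11)))
    b = _corpus_of(schema, (text, annotator(12)))
    rep = cohens_kappa(a, b, schema)
    assert abs(rep.kappa) < 0.03
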