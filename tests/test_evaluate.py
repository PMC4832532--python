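"""Evaluation: brat I/O, relaxed matching criteria, scoring, baseline,
ablation harness."""

import pytest

from sortanaph.evaluate import (
    BratParseError,
    GoldEntity,
    GoldRelation,
    PredictedPair,
    ablate,
    baseline_resolve,
    expand_links,
    format_brat,
    match_pair,
    parse_brat,
    read_brat,
    score,
    write_brat,
)
from sortanaph.link import resolve


class TestBratIO:
    def test_round_trip_byte_identical(self, corpus, tmp_path):
        for name, ex in corpus.docs.items():
            txt, ann = tmp_path / f"{name}.txt", tmp_path / f"{name}.ann"
            write_brat(ex.document.text, ex.entities, ex.relations, txt, ann)
            text, entities, relations = read_brat(txt, ann)
            assert text == ex.document.text
            assert format_brat(entities, relations) == ann.read_text()
            assert [e.type for e in entities] == [e.type for e in ex.entities]

    def test_span_generic_type_parses(self):
        text = "An adult male bullmastiff dog was treated."
        ann = "T1\tSPAN 0 29\tAn adult male bullmastiff dog\n"
        entities, _ = parse_brat(text, ann)
        assert entities[0].type == "SPAN"
        assert entities[0].surface == "An adult male bullmastiff dog"

    def test_offset_surface_mismatch_names_entity(self):
        with pytest.raises(BratParseError, match="T1"):
            parse_brat("abc def", "T1\tSortal 0 3\tdef\n")

    def test_malformed_line_rejected(self):
        with pytest.raises(BratParseError):
            parse_brat("abc", "T1\tSortal zero three\tabc\n")

    def test_relation_with_unknown_entity_rejected(self):
        with pytest.raises(BratParseError, match="T9"):
            parse_brat("abc", "T1\tSortal 0 3\tabc\nR1\tCoref Arg1:T1 Arg2:T9\n")


def _gold(text, a_span, a_type, b_span, b_type):
    anaphor = GoldEntity("T1", a_type, a_span, text[a_span[0]:a_span[1]])
    antecedent = GoldEntity("T2", b_type, b_span, text[b_span[0]:b_span[1]])
    return GoldRelation("R1", "Coref", anaphor, antecedent)


class TestMatchPair:
    def test_criterion_2_span_subsumption(self, corpus):
        """An unmapped gold SPAN antecedent subsumes the predicted mention."""
        ex = corpus["ex03"]
        pairs = baseline_resolve(ex.document)
        assert len(pairs) == 1
        assert match_pair(pairs[0], ex.relations[0], corpus.kb) == 2

    def test_criterion_3_concept_equivalence(self, corpus):
        """Coordinate antecedent in another sentence matches gold mentions
        at the concept level only."""
        ex = corpus["ex04"]
        doc = ex.document
        links = resolve(doc, corpus.kb)
        both_pairs = [
            p for p in expand_links(links)
            if doc.surface(p.anaphor_span) == "both drugs"
        ]
        gold_both = [r for r in ex.relations if r.anaphor.surface == "both drugs"]
        crits = sorted(
            match_pair(p, g, corpus.kb)
            for p in both_pairs
            for g in gold_both
            if match_pair(p, g, corpus.kb) is not None
        )
        assert crits == [3, 3]

    def test_criterion_1_requires_type_match(self, kb):
        # gold antecedent surface is unmapped, so only the approximate
        # (offset + type) criterion can apply
        text = "zzzzzzzzzz helped the patient"
        pred = PredictedPair((17, 28), ("C_patients",), (0, 10), "C_cetirizine")
        ok = _gold(text, (17, 28), "Sortal", (0, 10), "Pharmacologic Substance")
        assert match_pair(pred, ok, kb) == 1
        wrong_type = _gold(text, (17, 28), "Sortal", (0, 10), "Mammal")
        assert match_pair(pred, wrong_type, kb) is None

    def test_disjoint_everything_no_match(self, kb):
        text = "alpha beta gamma delta"
        pred = PredictedPair((0, 5), ("C_dog",), (6, 10), "C_dog")
        gold = _gold(text, (11, 16), "Sortal", (17, 22), "Pharmacologic Substance")
        assert match_pair(pred, gold, kb) is None


class TestScore:
    def test_perfect_prediction(self, corpus):
        ex = corpus["ex01"]
        report = score(resolve(ex.document, corpus.kb), ex.relations, corpus.kb)
        assert (report.precision, report.recall, report.f1) == (1.0, 1.0, 1.0)

    def test_hand_computed_counts(self, kb):
        text = "cetirizine and formoterol helped the patients there"
        gold = [
            _gold(text, (33, 45), "Sortal", (0, 10), "Pharmacologic Substance"),
            _gold(text, (33, 45), "Sortal", (15, 25), "Pharmacologic Substance"),
            _gold(text, (33, 45), "Sortal", (46, 51), "Pharmacologic Substance"),
        ]
        pairs = [
            PredictedPair((33, 45), ("C_patients",), (0, 10), "C_cetirizine"),
            PredictedPair((33, 45), ("C_patients",), (26, 32), "C_dog"),
        ]
        report = score(pairs, gold, kb)
        assert (report.tp, report.fp, report.fn) == (1, 1, 2)
        assert report.precision == 0.5
        assert report.recall == pytest.approx(1 / 3)
        assert report.f1 == pytest.approx(0.4)

    def test_empty_predictions_degenerate_denominator(self, kb):
        gold = [_gold("ab cd", (0, 2), "Sortal", (3, 5), "Mammal")]
        report = score([], gold, kb)
        assert (report.precision, report.recall, report.f1) == (0.0, 0.0, 0.0)

    def test_self_comparison_is_perfect(self, corpus):
        """Agreement-metric property: a set of annotations scored against
        itself gives F1 = 1 (and the metric is symmetric)."""
        from sortanaph.knowledge import lookup_surface

        for ex in corpus.docs.values():
            if not ex.relations:
                continue
            pairs = []
            for r in ex.relations:
                hits = lookup_surface(corpus.kb, r.antecedent.surface)
                pairs.append(
                    PredictedPair(r.anaphor.span, (), r.antecedent.span,
                                  hits[0][0] if hits else None)
                )
            report = score(pairs, ex.relations, corpus.kb)
            assert report.f1 == 1.0

    def test_gold_pair_consumed_once(self, kb):
        text = "cetirizine helped the patient"
        gold = [_gold(text, (17, 28), "Sortal", (0, 10), "Pharmacologic Substance")]
        pair = PredictedPair((17, 28), (), (0, 10), "C_cetirizine")
        report = score([pair, pair], gold, kb)
        assert (report.tp, report.fp, report.fn) == (1, 1, 0)


try:
    from hypothesis import given, settings, strategies as st

    _span = st.tuples(st.integers(0, 40), st.integers(1, 10)).map(
        lambda t: (t[0], t[0] + t[1])
    )

    @settings(max_examples=60, derandomize=True, deadline=None)
    @given(
        preds=st.lists(st.tuples(_span, _span), max_size=6),
        golds=st.lists(st.tuples(_span, _span), max_size=6),
    )
    def test_score_count_invariants(preds, golds):
        """tp <= min(|predicted|, |gold|); metrics bounded in [0, 1]."""
        from sortanaph.fixtures import build_fixture_kb

        kb = build_fixture_kb()
        text = "x" * 64
        pairs = [PredictedPair(a, (), b, None) for a, b in preds]
        relations = [
            _gold(text, a, "Sortal", b, "SPAN") for a, b in golds
        ]
        report = score(pairs, relations, kb)
        assert report.tp <= min(len(pairs), len(relations))
        assert report.tp + report.fp == len(pairs)
        assert report.tp + report.fn == len(relations)
        for v in (report.precision, report.recall, report.f1):
            assert 0.0 <= v <= 1.0
except ImportError:  # pragma: no cover - hypothesis is an optional test dep
    pass


class TestBaseline:
    def test_head_and_number_match(self, corpus):
        ex = corpus["ex03"]
        pairs = baseline_resolve(ex.document)
        doc = ex.document
        assert [(doc.surface(p.anaphor_span), doc.surface(p.antecedent_span))
                for p in pairs] == [("the dog", "An adult male bullmastiff dog")]

    def test_misses_set_membership_link(self, corpus):
        """No preceding NP is headed by plural 'drug', so the baseline
        produces no pair for 'these drugs'."""
        doc = corpus["ex01"].document
        pairs = baseline_resolve(doc)
        assert all(
            doc.surface(p.anaphor_span) != "these drugs" for p in pairs
        )

    def test_no_trigger_nps_empty(self, corpus):
        assert baseline_resolve(corpus["ex02"].document) == []

    def test_pairs_respect_head_lemma_equality(self, corpus):
        """Independent scan: every baseline pair joins NPs with equal head
        lemmas."""
        for ex in corpus.docs.values():
            doc = ex.document
            lemma_of = {}
            for si, np_ in doc.mentions():
                lemma_of[np_.span] = doc.sentences[si].head_token(np_).lemma.lower()
            for p in baseline_resolve(doc):
                assert lemma_of[p.anaphor_span] == lemma_of[p.antecedent_span]

    def test_baseline_far_below_full_system(self, corpus):
        kb = corpus.kb
        items = corpus.corpus_items()
        base = sum(
            (score(baseline_resolve(doc), gold, kb).tp for doc, gold in items)
        )
        full = sum((score(resolve(doc, kb), gold, kb).tp for doc, gold in items))
        assert base < full


class TestAblate:
    def test_full_system_row_matches_no_removal(self, corpus):
        table = ablate(corpus.corpus_items(), corpus.kb, toggles=["number"])
        assert table.loc["(none)", "tp"] == 12

    def test_unknown_toggle_rejected(self, corpus):
        with pytest.raises(ValueError, match="bogus"):
            ablate(corpus.corpus_items(), corpus.kb, toggles=["bogus"])

    def test_removing_filters_never_decreases_predictions(self, corpus):
        from sortanaph.link import ResolverConfig

        kb = corpus.kb
        for ex in corpus.docs.values():
            full = len(expand_links(resolve(ex.document, kb)))
            nofilter = len(
                expand_links(
                    resolve(ex.document, kb,
                            ResolverConfig.without("anaphoricity_filter"))
                )
            )
            assert nofilter >= full
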