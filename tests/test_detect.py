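"""Anaphor detection: trigger scan and the five anaphoricity filters."""

import pytest

from sortanaph.builder import DocumentBuilder
from sortanaph.detect import (
    DetectConfig,
    apply_anaphoricity_filters,
    detect_anaphors,
    find_trigger_nps,
)

TRIGGERS = {"the", "this", "that", "these", "those", "both", "each",
            "either", "neither", "such"}


def _np_by_surface(doc, surface):
    for si, np_ in doc.mentions():
        if doc.surface(np_.span) == surface:
            return doc.sentences[si], np_
    raise AssertionError(f"no NP {surface!r}")


class TestTriggerScan:
    def test_example_corpus_includes_these_drugs(self, corpus):
        doc = corpus["ex01"].document
        trigs = find_trigger_nps(doc)
        surfaces = {
            doc.surface(doc.sentences[t.sentence_index]
                        .noun_phrases[t.np_index].span)
            for t in trigs
        }
        assert "these drugs" in surfaces

    def test_no_determiners_yields_empty(self, kb):
        b = DocumentBuilder("d", kb)
        s = b.sentence()
        s.np("Amantadine")
        s.word("helps")
        s.punct(".")
        assert find_trigger_nps(b.build()) == []

    def test_count_matches_token_scan(self, corpus):
        """Trigger count equals a brute-force scan for trigger determiners
        heading NPs."""
        for ex in corpus.docs.values():
            doc = ex.document
            expected = sum(
                1
                for si, np_ in doc.mentions()
                if np_.determiner_index is not None
                and doc.sentences[si].tokens[np_.determiner_index].text.lower()
                in TRIGGERS
            )
            assert len(find_trigger_nps(doc)) == expected

    def test_such_is_a_trigger(self, kb):
        b = DocumentBuilder("d", kb)
        s = b.sentence()
        s.np("such", "drugs", det=0)
        s.punct(".")
        trigs = find_trigger_nps(b.build())
        assert [t.trigger for t in trigs] == ["such"]


class TestFilters:
    def test_appositive_first_element_filtered(self, corpus):
        doc = corpus["ex02"].document
        sent, np_ = _np_by_surface(doc, "The antiviral agent")
        decision = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
        assert decision.fired_filters == {"appositive"}
        assert not decision.kept

    def test_rigid_designator_modifier(self, corpus):
        doc = corpus["ex08"].document
        sent, np_ = _np_by_surface(doc, "these long-term PAH therapies")
        decision = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
        assert decision.fired_filters == {"rigid_designator"}

    def test_of_pp_filtered(self, corpus):
        doc = corpus["ex01"].document
        sent, np_ = _np_by_surface(doc, "the long-term use")
        decision = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
        assert "of_pp" in decision.fired_filters

    def test_cataphora_word_following(self, kb):
        b = DocumentBuilder("d", kb)
        s = b.sentence()
        np_ = s.np("the", "following", "signs", det=0, head=2, head_cuis=["C_pah"])
        s.punct(".")
        doc = b.build()
        decision = apply_anaphoricity_filters(np_, doc.sentences[0], doc, kb)
        assert "cataphora" in decision.fired_filters

    def test_number_clash_both_singular_head(self, kb):
        b = DocumentBuilder("d", kb)
        s = b.sentence()
        np_ = s.np("Both", "short-term", "dynamic", "psychotherapy", det=0,
                   head=3, head_cuis=["C_treatment"], number="singular")
        s.punct(".")
        doc = b.build()
        decision = apply_anaphoricity_filters(np_, doc.sentences[0], doc, kb)
        assert "number_clash" in decision.fired_filters

    def test_definite_article_imposes_no_number(self, corpus):
        # "the" is number-neutral: plural head under "the" is fine
        doc = corpus["ex07"].document
        sent, np_ = _np_by_surface(doc, "The genes")
        decision = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
        assert decision.kept

    def test_unmapped_head_filtered(self, corpus):
        doc = corpus["ex03"].document
        sent, np_ = _np_by_surface(doc, "this time")
        decision = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
        assert decision.fired_filters == {"unmapped_head"}

    def test_kept_iff_no_filter_fired(self, corpus):
        for ex in corpus.docs.values():
            doc = ex.document
            for trig in find_trigger_nps(doc):
                sent = doc.sentences[trig.sentence_index]
                np_ = sent.noun_phrases[trig.np_index]
                d = apply_anaphoricity_filters(np_, sent, doc, corpus.kb)
                assert d.kept == (not d.fired_filters)


class TestDetectAnaphors:
    def test_pah_example_single_anaphor(self, corpus):
        doc = corpus["ex01"].document
        anaphors = detect_anaphors(doc, corpus.kb)
        assert [doc.surface(a.np.span) for a in anaphors] == ["these drugs"]

    def test_missed_appositive_lets_np_through(self, corpus):
        # upstream analysis lacks the appositive: a precision error upstream
        doc = corpus["ex09"].document
        anaphors = detect_anaphors(doc, corpus.kb)
        assert "the first phosphodiesterase inhibitor" in [
            doc.surface(a.np.span) for a in anaphors
        ]

    def test_proper_names_only_yields_empty(self, kb):
        b = DocumentBuilder("d", kb)
        s = b.sentence()
        s.np("Amantadine")
        s.word("resembles")
        s.np("Cetirizine")
        s.punct(".")
        assert detect_anaphors(b.build(), kb) == []

    def test_subset_of_trigger_nps(self, corpus):
        for ex in corpus.docs.values():
            doc = ex.document
            trigger_spans = {
                doc.sentences[t.sentence_index].noun_phrases[t.np_index].span
                for t in find_trigger_nps(doc)
            }
            for a in detect_anaphors(doc, corpus.kb):
                assert a.np.span in trigger_spans

    def test_filters_only_shrink_anaphor_set(self, corpus):
        """Enabling any single filter never adds anaphors (monotonicity)."""
        none_on = DetectConfig(appositive=False, rigid_designator=False,
                               of_pp=False, cataphora=False,
                               number_clash=False, unmapped_head=False)
        for ex in corpus.docs.values():
            doc = ex.document
            base = {a.np.span for a in detect_anaphors(doc, corpus.kb, none_on)}
            for name in ("appositive", "rigid_designator", "of_pp",
                         "cataphora", "number_clash", "unmapped_head"):
                cfg = DetectConfig(**{**none_on.__dict__, name: True})
                subset = {a.np.span for a in detect_anaphors(doc, corpus.kb, cfg)}
                assert subset <= base

    def test_detected_anaphors_have_head_concepts(self, corpus):
        for ex in corpus.docs.values():
            for a in detect_anaphors(ex.document, corpus.kb):
                assert a.head_concepts
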