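"""Antecedent linking: semantic consonance, number agreement, salience
selection, set-membership expansion."""

from types import SimpleNamespace

import numpy as np
import pytest

from sortanaph.builder import DocumentBuilder
from sortanaph.detect import detect_anaphors
from sortanaph.link import (
    Candidate,
    PROV_INTER,
    PROV_INTRA,
    PROV_SINGLE,
    ResolverConfig,
    number_agrees,
    resolve,
    select_antecedent,
    semantically_consonant,
)


def _anaphor(doc, kb, surface):
    for a in detect_anaphors(doc, kb):
        if doc.surface(a.np.span) == surface:
            return a
    raise AssertionError(f"anaphor {surface!r} not detected")


def _candidate(doc, surface):
    for si, np_ in doc.mentions():
        if doc.surface(np_.span) == surface:
            return Candidate(np_, si, np_.start, False)
    raise AssertionError(f"candidate {surface!r} not found")


def _two_sentence_doc(kb, anaphor_words, candidate_spec):
    """One candidate NP in sentence 0, one anaphor NP in sentence 1."""
    b = DocumentBuilder("d", kb)
    s = b.sentence()
    candidate_spec(s)
    s.punct(".")
    s = b.sentence()
    s.np(*anaphor_words, det=0)
    s.punct(".")
    return b.build()


class TestSemanticConsonance:
    def test_taxonomy_route(self, kb):
        doc = _two_sentence_doc(kb, ("the", "drug"), lambda s: s.np("cetirizine"))
        a = _anaphor(doc, kb, "the drug")
        assert semantically_consonant(kb, a, _candidate(doc, "cetirizine"), doc)

    def test_headword_route(self, kb):
        doc = _two_sentence_doc(
            kb, ("the", "illness"),
            lambda s: s.np("Immune", "reconstitution", "inflammatory",
                           "syndrome", head=3,
                           full_cuis=["C_iris"], head_cuis=["C_iris"]),
        )
        a = _anaphor(doc, kb, "the illness")
        cand = _candidate(doc, "Immune reconstitution inflammatory syndrome")
        assert semantically_consonant(kb, a, cand, doc)

    def test_shared_headword_route(self, kb):
        doc = _two_sentence_doc(
            kb, ("the", "reaction"),
            lambda s: s.np("anaphylactoid", "reaction"),
        )
        a = _anaphor(doc, kb, "the reaction")
        cand = _candidate(doc, "anaphylactoid reaction")
        assert cand.mention.head_concepts == ["C_anaphylactoid_reaction"]
        assert semantically_consonant(kb, a, cand, doc)

    def test_meronymy_blocks_taxonomy(self, kb):
        doc = _two_sentence_doc(
            kb, ("the", "heart"),
            lambda s: s.np("right", "ventricle", head_cuis=["C_right_ventricle"]),
        )
        a = _anaphor(doc, kb, "the heart")
        assert not semantically_consonant(
            kb, a, _candidate(doc, "right ventricle"), doc
        )

    def test_no_route_no_consonance(self, corpus):
        # chemotherapy regimen vs adjuvant chemotherapy: no taxonomy link,
        # different headwords
        doc = corpus["ex13"].document
        a = _anaphor(doc, corpus.kb, "The chemotherapy regimen")
        cand = _candidate(doc, "adjuvant chemotherapy")
        assert not semantically_consonant(corpus.kb, a, cand, doc)

    def test_concept_group_excluded(self, corpus):
        # "this study" maps into the catch-all Concept group
        doc = corpus["ex16"].document
        a = _anaphor(doc, corpus.kb, "this study")
        for surface in ("ion channel modulators", "pregabalin"):
            assert not semantically_consonant(
                corpus.kb, a, _candidate(doc, surface), doc
            )

    def test_coordinate_requires_every_conjunct(self, corpus):
        # the s1 gene coordination is consonant; a coordination containing
        # a non-consonant member would not be
        doc = corpus["ex07"].document
        kb = corpus.kb
        a = _anaphor(doc, kb, "The genes")
        sent = doc.sentences[1]
        coord = sent.coordinations[0]
        good = Candidate(coord, 1, coord.start, True)
        assert semantically_consonant(kb, a, good, doc)
        from sortanaph.docmodel import CoordinateNP

        bcl2 = next(
            i for i, np_ in enumerate(sent.noun_phrases)
            if np_.head_concepts == ["C_bcl2"]
        )
        wide = CoordinateNP(
            conjunct_indices=[bcl2] + coord.conjunct_indices,
            span=(sent.noun_phrases[bcl2].span[0], coord.span[1]),
        )
        assert not semantically_consonant(
            kb, a, Candidate(wide, 1, wide.start, True), doc
        )


class TestNumberAgreement:
    def test_singular_anaphor_plural_candidate(self, corpus):
        doc = corpus["ex14"].document
        a = _anaphor(doc, corpus.kb, "the drug")
        assert not number_agrees(a, _candidate(doc, "neuroleptics"), doc)

    def test_coordinate_counts_as_plural(self, corpus):
        doc = corpus["ex04"].document
        a = _anaphor(doc, corpus.kb, "both drugs")
        coord = doc.sentences[0].coordinations[0]
        assert number_agrees(a, Candidate(coord, 0, coord.start, True), doc)

    def test_unknown_number_treated_as_singular(self, corpus):
        doc = corpus["ex15"].document
        a = _anaphor(doc, corpus.kb, "This pathogen")
        cand = _candidate(doc, "a rare Nocardia species")
        sent = doc.sentences[cand.sentence_index]
        assert sent.head_token(cand.mention).number == "unknown"
        assert number_agrees(a, cand, doc)


def _stub_candidate(sentence_index, start):
    mention = SimpleNamespace(span=(start, start + 3), start=start)
    return Candidate(mention, sentence_index, start, False)


def _brute_force_select(cands, anaphor_sentence):
    if not cands:
        return None
    if len(cands) == 1:
        return cands[0]
    intra = [c for c in cands if c.sentence_index == anaphor_sentence]
    if intra:
        return max(intra, key=lambda c: c.start)
    best_sentence = max(c.sentence_index for c in cands)
    return min(
        (c for c in cands if c.sentence_index == best_sentence),
        key=lambda c: c.start,
    )


class TestSelectAntecedent:
    def test_empty_and_singleton(self):
        anaphor = SimpleNamespace(sentence_index=3)
        assert select_antecedent([], anaphor) is None
        c = _stub_candidate(1, 10)
        assert select_antecedent([c], anaphor) == (c, PROV_SINGLE)

    def test_leftmost_in_closest_preceding_sentence(self, corpus):
        doc = corpus["ex15"].document
        links = resolve(doc, corpus.kb)
        (link,) = links
        assert doc.surface(link.antecedent_mentions[0].span) == (
            "a rare Nocardia species"
        )
        assert link.provenance == PROV_INTER

    def test_intra_sentential_closest(self, corpus):
        doc = corpus["ex09"].document
        (link,) = resolve(doc, corpus.kb)
        assert doc.surface(link.antecedent_mentions[0].span) == "Revatio"
        assert link.provenance == PROV_INTRA

    def test_agrees_with_rule_enumeration_oracle(self):
        """1000 seeded random candidate configurations against a
        brute-force implementation of the two salience rules."""
        rng = np.random.default_rng(12345)
        anaphor = SimpleNamespace(sentence_index=5)
        for _ in range(1000):
            n = int(rng.integers(0, 8))
            starts = rng.choice(np.arange(0, 500, 5), size=n, replace=False)
            cands = [
                _stub_candidate(int(rng.integers(0, 6)), int(s))
                for s in starts
            ]
            expected = _brute_force_select(cands, 5)
            got = select_antecedent(cands, anaphor)
            if expected is None:
                assert got is None
            else:
                assert got[0] is expected


class TestResolve:
    def test_set_membership_expansion_pah(self, corpus):
        doc = corpus["ex01"].document
        (link,) = resolve(doc, corpus.kb)
        assert doc.surface(link.anaphor.np.span) == "these drugs"
        assert [doc.surface(m.span) for m in link.antecedent_mentions] == [
            "prostacyclin analogues",
            "endothelin receptor antagonists",
            "phosphodiesterase type 5 inhibitors",
        ]
        assert link.antecedent_concepts == [
            "C_prostacyclin_analogues", "C_era", "C_pde5i",
        ]

    def test_coordinate_antecedent_concept_equivalent(self, corpus):
        doc = corpus["ex04"].document
        links = resolve(doc, corpus.kb)
        both = next(
            l for l in links if doc.surface(l.anaphor.np.span) == "both drugs"
        )
        assert sorted(both.antecedent_concepts) == ["C_formoterol", "C_tiotropium"]
        assert len(both.antecedent_mentions) == 2

    def test_unresolved_without_compatible_candidate(self, corpus):
        # universal-anaphor termination: no link emitted
        for name, surface in (("ex13", "The chemotherapy regimen"),
                              ("ex14", "the drug")):
            doc = corpus[name].document
            spans = {l.anaphor.np.span for l in resolve(doc, corpus.kb)}
            a = _anaphor(doc, corpus.kb, surface)
            assert a.np.span not in spans

    def test_antecedents_precede_anaphor(self, corpus):
        for ex in corpus.docs.values():
            for link in resolve(ex.document, corpus.kb):
                for m in link.antecedent_mentions:
                    assert m.start < link.anaphor.np.start

    def test_pairwise_count_equals_conjunct_count(self, corpus):
        doc = corpus["ex16"].document
        (link,) = resolve(doc, corpus.kb)
        coord = doc.sentences[0].coordinations[0]
        assert len(link.antecedent_mentions) == len(coord.conjunct_indices) == 3

    def test_idempotent_and_deterministic(self, corpus):
        doc = corpus["ex07"].document
        first = resolve(doc, corpus.kb)
        second = resolve(doc, corpus.kb)
        assert [
            (l.anaphor.np.span, [m.span for m in l.antecedent_mentions],
             l.provenance)
            for l in first
        ] == [
            (l.anaphor.np.span, [m.span for m in l.antecedent_mentions],
             l.provenance)
            for l in second
        ]

    def test_both_max_two_rejects_wide_coordination(self, corpus):
        doc = corpus["ex11"].document
        default_links = resolve(doc, corpus.kb)
        assert len(default_links) == 1
        assert len(default_links[0].antecedent_mentions) == 3
        strict = resolve(doc, corpus.kb, ResolverConfig(both_max_two=True))
        assert strict == []

    def test_taxonomy_ablation_kills_taxonomy_links(self, corpus):
        # shared-headword-licensed link survives, taxonomy-only link dies
        doc = corpus["ex05"].document
        assert len(resolve(doc, corpus.kb)) == 1
        cfg = ResolverConfig.without("taxonomy")
        assert resolve(doc, corpus.kb, cfg) == []
        doc14 = corpus["ex14"].document
        links = resolve(doc14, corpus.kb, cfg)
        # "these disorders" still resolves via its shared-headword candidate
        assert any(
            doc14.surface(l.anaphor.np.span) == "these disorders" for l in links
        )
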