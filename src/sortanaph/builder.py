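"""Programmatic construction of analyzed documents and gold annotations.

Fixture documents and synthetic corpora are built token-by-token with
explicit linguistic structure (heads, determiners, appositives,
coordinations, concept mappings), which keeps the resolver's input
independent of the bundled heuristic analyzer.  Tokens are laid out with a
single space between all tokens, so character offsets are exact by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .docmodel import (
    CoordinateNP,
    Document,
    NounPhrase,
    Sentence,
    Token,
    validate_document,
)
from .evaluate import GoldEntity, GoldRelation
from .knowledge import (
    KnowledgeBase,
    PLURAL,
    SINGULAR,
    UNKNOWN,
    lookup_surface,
    singularize,
)


def _default_number(word: str, kb: Optional[KnowledgeBase]) -> str:
    low = word.lower()
    if kb is not None:
        entries = lookup_surface(kb, low)
        if entries:
            return entries[0][1]
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return PLURAL
    return SINGULAR


class SentenceBuilder:
    def __init__(self, doc: "DocumentBuilder", index: int):
        self._doc = doc
        self.sentence = Sentence(index=index, span=(doc._cursor, doc._cursor))

    # -- tokens ------------------------------------------------------------

    def _push(self, text: str, lemma: str, pos: str, number: str) -> int:
        start = self._doc._cursor
        tok = Token(text=text, lemma=lemma, pos=pos, number=number,
                    span=(start, start + len(text)))
        self._doc._cursor = tok.span[1] + 1
        self._doc._pieces.append(text)
        self.sentence.tokens.append(tok)
        self.sentence.span = (self.sentence.span[0], tok.span[1])
        return len(self.sentence.tokens) - 1

    def word(self, text: str, *, lemma: Optional[str] = None, pos: str = "X",
             number: str = UNKNOWN) -> int:
        """A plain (non-NP) token; pass ``pos='VERB'`` and a lemma for
        indicator verbs."""
        return self._push(text, lemma if lemma is not None else text.lower(),
                          pos, number)

    def punct(self, text: str = ",") -> int:
        return self._push(text, text, "PUNCT", UNKNOWN)

    # -- noun phrases ------------------------------------------------------

    def np(
        self,
        *words: str,
        det: Optional[int] = None,
        head: Optional[int] = None,
        head_cuis: Optional[Sequence[str]] = None,
        full_cuis: Optional[Sequence[str]] = None,
        number: Optional[str] = None,
        lemmas: Optional[dict[int, str]] = None,
        flags: Optional[dict[int, bool]] = None,
        of_pp: bool = False,
    ) -> NounPhrase:
        """Add a noun phrase from ``words``.

        ``det``/``head`` index into ``words`` (head defaults to the last
        word).  Concept mappings default to a lexicon lookup: the phrase
        without its determiner first, falling back to the head word;
        modifier concept flags default to a lexicon hit on the bare
        modifier.  All of these can be overridden explicitly.
        """
        if not words:
            raise ValueError("empty noun phrase")
        head = len(words) - 1 if head is None else head
        lemmas = lemmas or {}
        flags = flags or {}
        kb = self._doc.kb
        base = len(self.sentence.tokens)
        indices = []
        for i, w in enumerate(words):
            if i == det:
                pos = "ADJ" if w.lower() == "such" else "DET"
                lemma, num = w.lower(), UNKNOWN
            elif i == head:
                pos = "NOUN"
                lemma = lemmas.get(i, singularize(w))
                num = number if number is not None else _default_number(w, kb)
            else:
                pos = "NUM" if w[0].isdigit() else "NOUN"
                lemma, num = lemmas.get(i, singularize(w)), UNKNOWN
            indices.append(self._push(w, lemma, pos, num))
        content = [words[i] for i in range(len(words)) if i != det]
        phrase = " ".join(content)
        if full_cuis is None:
            full_cuis = [c for c, _ in lookup_surface(kb, phrase)] if kb else []
        if head_cuis is None:
            head_cuis = list(full_cuis) or (
                [c for c, _ in lookup_surface(kb, words[head])] if kb else []
            )
        modifier_indices = [
            base + i for i in range(len(words)) if i not in (det, head)
        ]
        modifier_flags = []
        for mi in modifier_indices:
            i = mi - base
            if i in flags:
                modifier_flags.append(flags[i])
            else:
                w = words[i]
                modifier_flags.append(
                    bool(kb and not w[0].isdigit() and lookup_surface(kb, w))
                )
        np = NounPhrase(
            span=(self.sentence.tokens[base].span[0],
                  self.sentence.tokens[base + len(words) - 1].span[1]),
            token_indices=indices,
            head_index=base + head,
            determiner_index=None if det is None else base + det,
            modifier_indices=modifier_indices,
            modifier_concept_flags=modifier_flags,
            head_concepts=list(head_cuis),
            full_concepts=list(full_cuis),
            followed_by_of_pp=of_pp,
        )
        self.sentence.noun_phrases.append(np)
        return np

    def coord(self, *nps: NounPhrase) -> CoordinateNP:
        idx = [self.sentence.noun_phrases.index(np) for np in nps]
        coordinate = CoordinateNP(
            conjunct_indices=idx,
            span=(nps[0].span[0], nps[-1].span[1]),
        )
        self.sentence.coordinations.append(coordinate)
        return coordinate

    def appos(self, first: NounPhrase, second: NounPhrase) -> None:
        self.sentence.appositive_pairs.append(
            (self.sentence.noun_phrases.index(first),
             self.sentence.noun_phrases.index(second))
        )


class DocumentBuilder:
    """Accumulates sentences, gold entities and gold Coref relations."""

    def __init__(self, doc_id: str, kb: Optional[KnowledgeBase] = None):
        self.doc_id = doc_id
        self.kb = kb
        self._cursor = 0
        self._pieces: list[str] = []
        self._sentences: list[Sentence] = []
        self.entities: list[GoldEntity] = []
        self.relations: list[GoldRelation] = []

    def sentence(self) -> SentenceBuilder:
        sb = SentenceBuilder(self, len(self._sentences))
        self._sentences.append(sb.sentence)
        return sb

    # -- gold annotation ---------------------------------------------------

    def entity(self, mention: NounPhrase | tuple[int, int], etype: str,
               surface: Optional[str] = None) -> GoldEntity:
        span = mention.span if isinstance(mention, NounPhrase) else mention
        if surface is None:
            surface = " ".join(self._surface_tokens(span))
        ent = GoldEntity(id=f"T{len(self.entities) + 1}", type=etype,
                         span=span, surface=surface)
        self.entities.append(ent)
        return ent

    def coref(self, anaphor: GoldEntity, antecedent: GoldEntity) -> GoldRelation:
        rel = GoldRelation(id=f"R{len(self.relations) + 1}", type="Coref",
                           anaphor=anaphor, antecedent=antecedent)
        self.relations.append(rel)
        return rel

    def _surface_tokens(self, span: tuple[int, int]) -> list[str]:
        out = []
        for sent in self._sentences:
            for tok in sent.tokens:
                if tok.span[0] >= span[0] and tok.span[1] <= span[1]:
                    out.append(tok.text)
        return out

    def build(self) -> Document:
        doc = Document(doc_id=self.doc_id, text=" ".join(self._pieces),
                       sentences=self._sentences)
        validate_document(doc)
        for ent in self.entities:
            assert doc.surface(ent.span) == ent.surface, (
                f"gold entity {ent.id} surface mismatch"
            )
        return doc
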