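"""Document data model and I/O.

The resolution core consumes documents exclusively through this model:
sentences, tokens (with lemma, coarse POS and grammatical number), noun
phrase chunks with heads/determiners/modifiers, appositive pairs,
coordinate noun phrases, and concept mappings.  Gold-quality linguistic
analyses can be injected via the standoff JSON dialect
(:func:`read_standoff`); :func:`analyze_text` is a bundled heuristic
analyzer for raw text, a convenience rather than the contract.

All character offsets are 0-based, half-open, matching brat standoff
semantics.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from .knowledge import (
    KnowledgeBase,
    NUMBERS,
    PLURAL,
    SINGULAR,
    UNKNOWN,
    lookup_surface,
    normalize_surface,
    singularize,
)

Span = tuple[int, int]


class SchemaError(ValueError):
    """Raised when a standoff document violates the model invariants."""


def spans_overlap(a: Span, b: Span) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def span_subsumed(inner: Span, outer: Span) -> bool:
    return outer[0] <= inner[0] and inner[1] <= outer[1]


@dataclass
class Token:
    text: str
    lemma: str
    pos: str  # coarse tag: NOUN, VERB, DET, ADJ, ADP, CONJ, PUNCT, NUM, X
    number: str  # singular | plural | unknown
    span: Span

    def __post_init__(self) -> None:
        if self.number not in NUMBERS:
            raise SchemaError(f"token {self.text!r}: bad number {self.number!r}")
        if self.span[0] >= self.span[1]:
            raise SchemaError(f"token {self.text!r}: empty span {self.span}")


@dataclass
class NounPhrase:
    """A base noun-phrase chunk.

    ``head_concepts`` holds the concept(s) the phrase maps to through its
    head: when the whole phrase normalizes to a concept that mapping is
    attached at the head (as concept-mapping engines do), otherwise the
    head word's own mapping is used.  ``full_concepts`` records the
    phrase-level mapping separately.
    """

    span: Span
    token_indices: list[int]
    head_index: int
    determiner_index: Optional[int] = None
    modifier_indices: list[int] = field(default_factory=list)
    modifier_concept_flags: list[bool] = field(default_factory=list)
    head_concepts: list[str] = field(default_factory=list)
    full_concepts: list[str] = field(default_factory=list)
    followed_by_of_pp: bool = False

    @property
    def start(self) -> int:
        return self.span[0]


@dataclass
class CoordinateNP:
    """A coordinate noun phrase: ordered conjunct NPs plus covering span.

    Treated as plural for number agreement regardless of conjunct numbers.
    """

    conjunct_indices: list[int]  # indices into the sentence's noun_phrases
    span: Span

    @property
    def start(self) -> int:
        return self.span[0]


@dataclass
class Sentence:
    index: int
    span: Span
    tokens: list[Token] = field(default_factory=list)
    noun_phrases: list[NounPhrase] = field(default_factory=list)
    appositive_pairs: list[tuple[int, int]] = field(default_factory=list)
    coordinations: list[CoordinateNP] = field(default_factory=list)

    def head_token(self, np: NounPhrase) -> Token:
        return self.tokens[np.head_index]

    def np_tokens(self, np: NounPhrase) -> list[Token]:
        return [self.tokens[i] for i in np.token_indices]

    def determiner_token(self, np: NounPhrase) -> Optional[Token]:
        if np.determiner_index is None:
            return None
        return self.tokens[np.determiner_index]


@dataclass
class Document:
    doc_id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)

    def surface(self, span: Span) -> str:
        return self.text[span[0] : span[1]]

    def mentions(self) -> Iterator[tuple[int, NounPhrase]]:
        """All (sentence_index, noun phrase) pairs in textual order."""
        for sent in self.sentences:
            for np in sent.noun_phrases:
                yield sent.index, np


def validate_document(doc: Document) -> None:
    n = len(doc.text)
    prev_end = -1
    for i, sent in enumerate(doc.sentences):
        if sent.index != i:
            raise SchemaError(f"sentence {i}: index mismatch ({sent.index})")
        s, e = sent.span
        if not (0 <= s < e <= n):
            raise SchemaError(f"sentence {i}: span {sent.span} outside document")
        if s < prev_end:
            raise SchemaError(f"sentence {i}: span {sent.span} overlaps previous")
        prev_end = e
        tprev = s
        for tok in sent.tokens:
            if tok.span[0] < tprev or tok.span[1] > e:
                raise SchemaError(
                    f"sentence {i}: token span {tok.span} out of order or bounds"
                )
            tprev = tok.span[1]
        for np in sent.noun_phrases:
            if np.head_index not in np.token_indices:
                raise SchemaError(f"sentence {i}: head_index not in token_indices")
            if len(np.modifier_indices) != len(np.modifier_concept_flags):
                raise SchemaError(
                    f"sentence {i}: modifier flags do not align with modifiers"
                )
            if np.determiner_index is not None and np.determiner_index > np.head_index:
                raise SchemaError(f"sentence {i}: determiner after head")
        for a, b in sent.appositive_pairs:
            if not (0 <= a < len(sent.noun_phrases) and 0 <= b < len(sent.noun_phrases)):
                raise SchemaError(f"sentence {i}: appositive pair ({a},{b}) out of range")
            if a == b:
                raise SchemaError(f"sentence {i}: degenerate appositive pair")
        for coord in sent.coordinations:
            if len(coord.conjunct_indices) < 2:
                raise SchemaError(f"sentence {i}: coordination with <2 conjuncts")
            starts = [sent.noun_phrases[j].start for j in coord.conjunct_indices]
            if starts != sorted(starts):
                raise SchemaError(f"sentence {i}: conjuncts not in textual order")
            for j in coord.conjunct_indices:
                if not 0 <= j < len(sent.noun_phrases):
                    raise SchemaError(f"sentence {i}: conjunct index {j} out of range")


# -- standoff JSON I/O -----------------------------------------------------


def document_to_dict(doc: Document) -> dict:
    return {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "sentences": [
            {
                "span": list(s.span),
                "tokens": [
                    {
                        "text": t.text,
                        "lemma": t.lemma,
                        "pos": t.pos,
                        "number": t.number,
                        "span": list(t.span),
                    }
                    for t in s.tokens
                ],
                "noun_phrases": [
                    {
                        "span": list(np.span),
                        "token_indices": np.token_indices,
                        "head_index": np.head_index,
                        "determiner_index": np.determiner_index,
                        "modifier_indices": np.modifier_indices,
                        "modifier_concept_flags": np.modifier_concept_flags,
                        "head_concepts": np.head_concepts,
                        "full_concepts": np.full_concepts,
                        "followed_by_of_pp": np.followed_by_of_pp,
                    }
                    for np in s.noun_phrases
                ],
                "appositive_pairs": [list(p) for p in s.appositive_pairs],
                "coordinations": [
                    {"conjunct_indices": c.conjunct_indices, "span": list(c.span)}
                    for c in s.coordinations
                ],
            }
            for s in doc.sentences
        ],
    }


def document_from_dict(data: dict) -> Document:
    try:
        doc = Document(doc_id=data["doc_id"], text=data["text"])
        for i, sd in enumerate(data["sentences"]):
            sent = Sentence(index=i, span=tuple(sd["span"]))
            for td in sd["tokens"]:
                sent.tokens.append(
                    Token(
                        text=td["text"],
                        lemma=td["lemma"],
                        pos=td["pos"],
                        number=td["number"],
                        span=tuple(td["span"]),
                    )
                )
            for npd in sd["noun_phrases"]:
                sent.noun_phrases.append(
                    NounPhrase(
                        span=tuple(npd["span"]),
                        token_indices=list(npd["token_indices"]),
                        head_index=npd["head_index"],
                        determiner_index=npd.get("determiner_index"),
                        modifier_indices=list(npd.get("modifier_indices", [])),
                        modifier_concept_flags=list(
                            npd.get("modifier_concept_flags", [])
                        ),
                        head_concepts=list(npd.get("head_concepts", [])),
                        full_concepts=list(npd.get("full_concepts", [])),
                        followed_by_of_pp=bool(npd.get("followed_by_of_pp", False)),
                    )
                )
            for pair in sd.get("appositive_pairs", []):
                sent.appositive_pairs.append((pair[0], pair[1]))
            for cd in sd.get("coordinations", []):
                sent.coordinations.append(
                    CoordinateNP(
                        conjunct_indices=list(cd["conjunct_indices"]),
                        span=tuple(cd["span"]),
                    )
                )
            doc.sentences.append(sent)
    except (KeyError, TypeError, IndexError) as exc:
        raise SchemaError(f"malformed standoff document: {exc}") from None
    validate_document(doc)
    return doc


def read_standoff(path) -> Document:
    with open(path, encoding="utf-8") as fh:
        return document_from_dict(json.load(fh))


def write_standoff(doc: Document, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(document_to_dict(doc), fh, indent=1)
        fh.write("\n")


# -- heuristic analyzer ----------------------------------------------------

DETERMINERS = frozenset(
    {"the", "a", "an", "this", "that", "these", "those", "both", "each",
     "either", "neither"}
)
_PREPOSITIONS = frozenset(
    {"of", "in", "on", "for", "with", "to", "from", "by", "at", "as",
     "between", "after", "before", "during", "among", "within", "without"}
)
_CONJUNCTIONS = frozenset({"and", "or"})
# Small closed verb list; unknown words default to NOUN so the chunker
# degrades to coarse chunks rather than missing phrases.
_VERBS = frozenset(
    {"is", "are", "was", "were", "be", "been", "being", "has", "have", "had",
     "can", "could", "may", "might", "will", "would", "shall", "should",
     "do", "does", "did", "used", "use", "show", "shows", "showed", "shown",
     "treat", "treats", "treated", "manage", "manages", "managed",
     "prevent", "prevents", "prevented", "support", "supports", "supported",
     "express", "expressed", "caused", "cause", "causes", "include",
     "includes", "included", "remain", "remains", "led", "lead", "leads",
     "found", "require", "requires", "required", "provide", "provides",
     "provided"}
)

_TOKEN_RE = re.compile(r"[A-Za-z0-9][A-Za-z0-9'\-\.]*[A-Za-z0-9]|[A-Za-z0-9]|[^\sA-Za-z0-9]")
_SENT_SPLIT = re.compile(r"(?<=[.!?])\s+(?=[A-Z(])")


def _coarse_pos(text: str) -> str:
    low = text.lower()
    if not any(ch.isalnum() for ch in text):
        return "PUNCT"
    if low in DETERMINERS:
        return "DET"
    if low == "such":
        return "ADJ"
    if low in _PREPOSITIONS:
        return "ADP"
    if low in _CONJUNCTIONS:
        return "CONJ"
    if low in _VERBS:
        return "VERB"
    if low[0].isdigit():
        return "NUM"
    return "NOUN"


def _token_number(text: str, kb: Optional[KnowledgeBase]) -> str:
    low = text.lower()
    if kb is not None:
        entries = lookup_surface(kb, low)
        if entries:
            return entries[0][1]
    if low in _INVARIANT_UNKNOWN:
        return UNKNOWN
    if low.endswith("s") and not low.endswith(("ss", "us", "is")) and len(low) > 3:
        return PLURAL
    return SINGULAR


_INVARIANT_UNKNOWN = frozenset({"species", "series"})


def analyze_text(text: str, kb: Optional[KnowledgeBase] = None,
                 doc_id: str = "doc") -> Document:
    """Deterministic heuristic analysis of raw text.

    Sentence split on sentence-final punctuation followed by a capital;
    NP chunks are maximal determiner/adjective/noun runs with the rightmost
    noun as head; an ``NP , NP`` sequence whose second member is
    concept-mapped becomes an appositive pair; comma/and/or series of NPs
    become coordinations; concept mapping goes through the KB lexicon
    (longest match: whole phrase without its determiner first, then the
    head word).
    """
    doc = Document(doc_id=doc_id, text=text)
    offset = 0
    pieces = _SENT_SPLIT.split(text) if text.strip() else []
    for si, piece in enumerate(pieces):
        start = text.index(piece, offset)
        end = start + len(piece)
        offset = end
        sent = Sentence(index=si, span=(start, len(piece.rstrip()) + start))
        for m in _TOKEN_RE.finditer(piece):
            ttext = m.group(0)
            sent.tokens.append(
                Token(
                    text=ttext,
                    lemma=singularize(ttext) if _coarse_pos(ttext) == "NOUN" else ttext.lower(),
                    pos=_coarse_pos(ttext),
                    number=_token_number(ttext, kb) if _coarse_pos(ttext) == "NOUN" else UNKNOWN,
                    span=(start + m.start(), start + m.end()),
                )
            )
        _chunk_sentence(sent, kb)
        doc.sentences.append(sent)
    validate_document(doc)
    return doc


def _map_np(sent: Sentence, np: NounPhrase, kb: Optional[KnowledgeBase]) -> None:
    if kb is None:
        return
    content = [sent.tokens[i] for i in np.token_indices if i != np.determiner_index]
    phrase = " ".join(t.text for t in content)
    np.full_concepts = [cui for cui, _ in lookup_surface(kb, phrase)]
    if np.full_concepts:
        np.head_concepts = list(np.full_concepts)
    else:
        head = sent.tokens[np.head_index]
        np.head_concepts = [cui for cui, _ in lookup_surface(kb, head.text)]
    for k, mi in enumerate(np.modifier_indices):
        tok = sent.tokens[mi]
        np.modifier_concept_flags[k] = bool(lookup_surface(kb, tok.text)) if kb else False


def _chunk_sentence(sent: Sentence, kb: Optional[KnowledgeBase]) -> None:
    toks = sent.tokens
    i = 0
    while i < len(toks):
        pos = toks[i].pos
        if pos == "DET" or (pos == "ADJ" and toks[i].text.lower() == "such"):
            j = i + 1
            last_noun = None
            while j < len(toks) and toks[j].pos in ("NOUN", "ADJ", "NUM"):
                if toks[j].pos == "NOUN":
                    last_noun = j
                j += 1
            if last_noun is None:
                i += 1
                continue
            _emit_np(sent, list(range(i, last_noun + 1)), det=i, head=last_noun, kb=kb)
            i = last_noun + 1
        elif pos in ("NOUN", "NUM"):
            j = i
            last_noun = None
            while j < len(toks) and toks[j].pos in ("NOUN", "ADJ", "NUM"):
                if toks[j].pos == "NOUN":
                    last_noun = j
                j += 1
            if last_noun is None:
                i = j
                continue
            _emit_np(sent, list(range(i, last_noun + 1)), det=None, head=last_noun, kb=kb)
            i = last_noun + 1
        else:
            i += 1
    _mark_of_pp(sent)
    _find_appositives_and_coordinations(sent, kb)


def _emit_np(sent: Sentence, indices: list[int], det: Optional[int],
             head: int, kb: Optional[KnowledgeBase]) -> None:
    toks = sent.tokens
    np = NounPhrase(
        span=(toks[indices[0]].span[0], toks[indices[-1]].span[1]),
        token_indices=indices,
        head_index=head,
        determiner_index=det,
        modifier_indices=[i for i in indices if i != head and i != det],
    )
    np.modifier_concept_flags = [False] * len(np.modifier_indices)
    _map_np(sent, np, kb)
    sent.noun_phrases.append(np)


def _mark_of_pp(sent: Sentence) -> None:
    for np in sent.noun_phrases:
        nxt = np.token_indices[-1] + 1
        if nxt < len(sent.tokens) and sent.tokens[nxt].text.lower() == "of":
            np.followed_by_of_pp = True


def _find_appositives_and_coordinations(sent: Sentence,
                                        kb: Optional[KnowledgeBase]) -> None:
    nps = sent.noun_phrases
    toks = sent.tokens

    def gap_tokens(a: NounPhrase, b: NounPhrase) -> list[Token]:
        return [t for t in toks if a.span[1] <= t.span[0] and t.span[1] <= b.span[0]]

    # coordination: NP (, NP)* (,)? (and|or) NP
    i = 0
    while i < len(nps):
        chain = [i]
        j = i
        saw_conj = False
        while j + 1 < len(nps):
            gap = gap_tokens(nps[j], nps[j + 1])
            texts = [t.text.lower() for t in gap]
            if texts == [","] or texts in ([",", "and"], [",", "or"], ["and"], ["or"]):
                if any(t in _CONJUNCTIONS for t in texts):
                    saw_conj = True
                chain.append(j + 1)
                j += 1
                if saw_conj:
                    break
            else:
                break
        if saw_conj and len(chain) >= 2:
            sent.coordinations.append(
                CoordinateNP(
                    conjunct_indices=chain,
                    span=(nps[chain[0]].span[0], nps[chain[-1]].span[1]),
                )
            )
            i = chain[-1] + 1
        else:
            i += 1

    coordinated = {j for c in sent.coordinations for j in c.conjunct_indices}
    # appositive: NP , NP with the second NP concept-mapped
    for i in range(len(nps) - 1):
        if i in coordinated or i + 1 in coordinated:
            continue
        gap = gap_tokens(nps[i], nps[i + 1])
        if [t.text for t in gap] == [","] and (
            nps[i + 1].head_concepts or nps[i + 1].full_concepts
        ):
            sent.appositive_pairs.append((i, i + 1))


# -- discourse accumulation ------------------------------------------------


@dataclass(frozen=True)
class DiscourseMention:
    """An antecedent-candidate mention in the accumulated discourse."""

    sentence_index: int
    mention: object  # NounPhrase | CoordinateNP
    is_coordinate: bool

    @property
    def start(self) -> int:
        return self.mention.start

    @property
    def span(self) -> Span:
        return self.mention.span


def accumulate_discourse(document: Document, upto_sentence: int,
                         before_offset: Optional[int] = None) -> list[DiscourseMention]:
    """Collect every NP and coordinate NP available as antecedent candidate.

    Mentions come from all sentences up to and including ``upto_sentence``;
    when ``before_offset`` is given (the anaphor's start), only mentions
    beginning strictly before it are returned.  Textual order is preserved.
    """
    if not 0 <= upto_sentence < len(document.sentences):
        raise IndexError(f"sentence index {upto_sentence} out of range")
    out: list[DiscourseMention] = []
    for sent in document.sentences[: upto_sentence + 1]:
        for np in sent.noun_phrases:
            out.append(DiscourseMention(sent.index, np, False))
        for coord in sent.coordinations:
            out.append(DiscourseMention(sent.index, coord, True))
    if before_offset is not None:
        out = [m for m in out if m.start < before_offset]
    out.sort(key=lambda m: (m.start, not m.is_coordinate))
    return out
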