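"""Phase 1: sortal-anaphor detection.

A noun phrase is a *candidate* sortal anaphor when it carries one of the
trigger words: the definite article (*the*), a demonstrative determiner
(*this, that, these, those*), a distributive determiner (*both, each,
either, neither*) or the demonstrative adjective *such*.  Candidates then
pass through five morpho-syntactic anaphoricity filters; survivors become
:class:`SortalAnaphor` objects handed to the linking phase.

Filters (any firing rejects the phrase):

1. ``appositive`` -- the NP is the first element of an appositive
   construction ("the gene, BRCA1").
2. ``rigid_designator`` -- a modifier maps to a concept separately from the
   head ("the Src family"); ``of_pp`` -- the NP is followed by an
   of-prepositional phrase ("the symptoms of lupus erythematosus").
3. ``cataphora`` -- the NP contains the word "following".
4. ``number_clash`` -- determiner number conflicts with head number
   ("both ... psychotherapy").
5. ``unmapped_head`` -- the head carries no concept mapping, leaving no
   semantic information for linking.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .docmodel import Document, NounPhrase, Sentence
from .knowledge import KnowledgeBase, PLURAL, SINGULAR, UNKNOWN

TRIGGER_CLASSES = {
    "the": "definite",
    "this": "demonstrative",
    "that": "demonstrative",
    "these": "demonstrative",
    "those": "demonstrative",
    "both": "distributive",
    "each": "distributive",
    "either": "distributive",
    "neither": "distributive",
    "such": "such",
}

#: Grammatical number imposed by each trigger; None = no constraint.
DETERMINER_NUMBER: dict[str, Optional[str]] = {
    "the": None,
    "such": None,
    "this": SINGULAR,
    "that": SINGULAR,
    "each": SINGULAR,
    "either": SINGULAR,
    "neither": SINGULAR,
    "these": PLURAL,
    "those": PLURAL,
    "both": PLURAL,
}

ALL_FILTERS = frozenset(
    {"appositive", "rigid_designator", "of_pp", "cataphora", "number_clash",
     "unmapped_head"}
)


@dataclass
class DetectConfig:
    """Per-filter toggles; the ablation harness switches them off in bulk."""

    appositive: bool = True
    rigid_designator: bool = True
    of_pp: bool = True
    cataphora: bool = True
    number_clash: bool = True
    unmapped_head: bool = True

    def enabled(self) -> set[str]:
        return {f for f in ALL_FILTERS if getattr(self, f)}


@dataclass(frozen=True)
class TriggerNP:
    sentence_index: int
    np_index: int
    trigger: str  # definite | demonstrative | distributive | such
    trigger_word: str


@dataclass
class FilterDecision:
    np: NounPhrase
    kept: bool
    fired_filters: set[str] = field(default_factory=set)


@dataclass
class SortalAnaphor:
    """An anaphoric NP that survived filtering; head_concepts is non-empty."""

    np: NounPhrase
    sentence_index: int
    np_index: int
    trigger: str
    trigger_word: str
    head_concepts: list[str]


def trigger_of(sentence: Sentence, np: NounPhrase) -> Optional[tuple[str, str]]:
    det = sentence.determiner_token(np)
    if det is None:
        return None
    word = det.text.lower()
    cls = TRIGGER_CLASSES.get(word)
    return (cls, word) if cls else None


def find_trigger_nps(document: Document) -> list[TriggerNP]:
    """All NPs whose determiner/adjective is a sortal trigger, textual order."""
    out = []
    for sent in document.sentences:
        for k, np in enumerate(sent.noun_phrases):
            hit = trigger_of(sent, np)
            if hit:
                out.append(TriggerNP(sent.index, k, hit[0], hit[1]))
    return out


def head_number(sentence: Sentence, np: NounPhrase) -> str:
    """Head number with the unknown-defaults-to-singular convention."""
    num = sentence.head_token(np).number
    return SINGULAR if num == UNKNOWN else num


def apply_anaphoricity_filters(
    np: NounPhrase,
    sentence: Sentence,
    document: Document,
    kb: Optional[KnowledgeBase] = None,
    config: Optional[DetectConfig] = None,
) -> FilterDecision:
    config = config or DetectConfig()
    enabled = config.enabled()
    fired: set[str] = set()
    np_index = sentence.noun_phrases.index(np)

    if "appositive" in enabled and any(
        a == np_index for a, _ in sentence.appositive_pairs
    ):
        fired.add("appositive")

    if "rigid_designator" in enabled and any(np.modifier_concept_flags):
        fired.add("rigid_designator")
    if "of_pp" in enabled and np.followed_by_of_pp:
        fired.add("of_pp")

    if "cataphora" in enabled and any(
        t.text.lower() == "following" for t in sentence.np_tokens(np)
    ):
        fired.add("cataphora")

    if "number_clash" in enabled:
        det = sentence.determiner_token(np)
        if det is not None:
            det_num = DETERMINER_NUMBER.get(det.text.lower())
            if det_num is not None and det_num != head_number(sentence, np):
                fired.add("number_clash")

    if "unmapped_head" in enabled and not np.head_concepts:
        fired.add("unmapped_head")

    return FilterDecision(np=np, kept=not fired, fired_filters=fired)


def detect_anaphors(
    document: Document,
    kb: Optional[KnowledgeBase] = None,
    config: Optional[DetectConfig] = None,
) -> list[SortalAnaphor]:
    """Trigger scan followed by the anaphoricity filters; deterministic order."""
    anaphors = []
    for trig in find_trigger_nps(document):
        sent = document.sentences[trig.sentence_index]
        np = sent.noun_phrases[trig.np_index]
        decision = apply_anaphoricity_filters(np, sent, document, kb, config)
        if decision.kept:
            anaphors.append(
                SortalAnaphor(
                    np=np,
                    sentence_index=trig.sentence_index,
                    np_index=trig.np_index,
                    trigger=trig.trigger,
                    trigger_word=trig.trigger_word,
                    head_concepts=list(np.head_concepts),
                )
            )
    return anaphors
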