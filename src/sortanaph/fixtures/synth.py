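"""Seeded synthetic corpora with planted anaphora links.

The generator emulates the *structural* conditions the resolver faces --
discourse distance, set-membership coordinations, the three consonance
routes, and non-consonant distractor mentions -- rather than natural
prose: candidate noun phrases carry explicit knowledge-base entries, and
every planted link is recoverable by construction (the intended antecedent
is the only consonant, number-agreeing candidate for its anaphor, hence
trivially the salience winner).  Word families are unique per link so
planted links never interfere with one another.

Default condition values follow the annotated-corpus statistics reported
for this task: ~2.95 anaphoric mentions per citation, ~29 % of anaphors
indicating set membership, 85 % inter-sentential relations, and
set-membership member counts between 2 and 9 with mean 2.66.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ..builder import DocumentBuilder
from ..docmodel import Document, Span
from ..evaluate import GoldEntity, GoldRelation
from ..knowledge import Concept, KnowledgeBase, PLURAL, SINGULAR

#: Member counts of set-membership relations and their observed frequency
#: (mean 2.66 members per set-membership anaphor).
MEMBER_COUNT_DISTRIBUTION: dict[int, int] = {
    2: 166, 3: 66, 4: 29, 5: 6, 6: 3, 7: 3, 8: 1, 9: 1,
}

MECHANISMS = ("taxonomy", "headword", "shared_headword")

#: (semantic group, generic headword) combinations available for
#: headword-route links; one per group per document to keep planted links
#: independent.
_HEADWORD_SLOTS = [
    ("Disorder", "condition"),
    ("Therapeutic Modality", "medication"),
]

_FILLER = ["observation", "report", "analysis", "result", "context",
           "summary", "finding", "note"]


class SynthSpecError(ValueError):
    pass


@dataclass
class SynthSpec:
    n_documents: int = 20
    sentences_per_doc: int = 8
    #: expected anaphors per document (Poisson)
    anaphora_density: float = 2.95
    #: fraction of planted links that are set-membership (coordinate) links
    set_membership_fraction: float = 0.29
    #: fractions of links resolvable only via taxonomy / headword /
    #: shared-headword; any remainder falls back to the taxonomy route
    constraint_mix: tuple[float, float, float] = (0.7, 0.2, 0.1)
    #: fraction of links whose antecedent lies in an earlier sentence
    inter_sentential_fraction: float = 0.85
    #: expected non-consonant distractor NPs per sentence (Poisson)
    distractor_rate: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        fracs = (self.set_membership_fraction, self.inter_sentential_fraction,
                 *self.constraint_mix)
        if any(not 0.0 <= f <= 1.0 for f in fracs):
            raise SynthSpecError("fractions must lie in [0, 1]")
        if sum(self.constraint_mix) > 1.0 + 1e-9:
            raise SynthSpecError("constraint_mix must sum to at most 1")
        if self.n_documents < 1 or self.sentences_per_doc < 2:
            raise SynthSpecError("need at least 1 document of 2 sentences")
        if self.anaphora_density < 0 or self.distractor_rate < 0:
            raise SynthSpecError("rates must be non-negative")


@dataclass(frozen=True)
class PlantedLink:
    doc_index: int
    mechanism: str
    set_membership: bool
    inter_sentential: bool
    n_antecedents: int
    anaphor_span: Span
    antecedent_spans: tuple[Span, ...]


@dataclass
class SyntheticCorpus:
    kb: KnowledgeBase
    documents: list[Document]
    gold: list[tuple[list[GoldEntity], list[GoldRelation]]]
    planted: list[PlantedLink]

    def corpus_items(self):
        return [
            (doc, relations)
            for doc, (_, relations) in zip(self.documents, self.gold)
        ]


def _add_concept(kb: KnowledgeBase, cui: str, name: str, stype: str,
                 group: str) -> str:
    kb.add_concept(Concept(cui=cui, preferred_name=name,
                           semantic_types=frozenset({stype}),
                           semantic_group=group))
    return cui


def _base_kb() -> KnowledgeBase:
    kb = KnowledgeBase()
    kb.set_group_headwords(
        "Disorder", {"condition", "ailment", "abnormality", "problem"}
    )
    kb.set_group_headwords(
        "Therapeutic Modality", {"medication", "intervention", "agent"}
    )
    # anaphor-head concepts for the headword route; a neutral group keeps
    # them out of every group-headword list
    for word in ("condition", "medication"):
        cui = _add_concept(kb, f"C_{word}", word.capitalize(),
                           "Generic Term", "Physiology")
        kb.add_lexicon_entry(word, cui, SINGULAR)
    return kb


def _sample_member_count(rng: np.random.Generator) -> int:
    counts = np.array(sorted(MEMBER_COUNT_DISTRIBUTION))
    weights = np.array(
        [MEMBER_COUNT_DISTRIBUTION[c] for c in counts], dtype=float
    )
    return int(rng.choice(counts, p=weights / weights.sum()))


@dataclass
class _Plan:
    """One planted link before realization."""

    mechanism: str
    set_membership: bool
    n_antecedents: int
    anaphor_sentence: int
    antecedent_sentence: int
    headword_slot: Optional[tuple[str, str]] = None
    anaphor_np: object = None
    antecedent_nps: list = field(default_factory=list)


def generate(spec: SynthSpec) -> SyntheticCorpus:
    """Build a seeded corpus; identical specs yield identical corpora."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    kb = _base_kb()
    documents: list[Document] = []
    gold: list[tuple[list[GoldEntity], list[GoldRelation]]] = []
    planted: list[PlantedLink] = []

    for d in range(spec.n_documents):
        n_links = int(rng.poisson(spec.anaphora_density))
        free_slots = list(_HEADWORD_SLOTS)
        plans: list[_Plan] = []
        for k in range(n_links):
            u = rng.random()
            t, h, s = spec.constraint_mix
            if u < t:
                mech = "taxonomy"
            elif u < t + h:
                mech = "headword"
            elif u < t + h + s:
                mech = "shared_headword"
            else:
                mech = "taxonomy"
            slot = None
            if mech == "headword":
                if free_slots:
                    slot = free_slots.pop(0)
                else:
                    mech = "taxonomy"  # per-document headword slots exhausted
            set_mem = rng.random() < spec.set_membership_fraction
            n_ant = _sample_member_count(rng) if set_mem else 1
            s_a = int(rng.integers(1, spec.sentences_per_doc))
            if rng.random() < spec.inter_sentential_fraction:
                s_b = int(rng.integers(0, s_a))
            else:
                s_b = s_a
            plans.append(
                _Plan(mechanism=mech, set_membership=set_mem,
                      n_antecedents=n_ant, anaphor_sentence=s_a,
                      antecedent_sentence=s_b, headword_slot=slot)
            )

        b = DocumentBuilder(f"synth{d:04d}", kb)
        for si in range(spec.sentences_per_doc):
            sb = b.sentence()
            sb.word(_FILLER[si % len(_FILLER)])
            sb.word("regarding")
            for k, plan in enumerate(plans):
                if plan.antecedent_sentence == si:
                    _realize_antecedent(kb, sb, plan, d, k)
                if plan.anaphor_sentence == si:
                    _realize_anaphor(kb, sb, plan, d, k)
            for j in range(int(rng.poisson(spec.distractor_rate))):
                word = f"dx{d}s{si}n{j}"
                cui = _add_concept(kb, f"C_{word}", word, "Synthetic Object",
                                   "Objects")
                kb.add_lexicon_entry(word, cui, SINGULAR)
                sb.np(word, head_cuis=[cui])
            sb.punct(".")
        doc = b.build()
        documents.append(doc)

        entities: list[GoldEntity] = []
        relations: list[GoldRelation] = []
        for plan in plans:
            sortal = b.entity(plan.anaphor_np, "Sortal")
            entities.append(sortal)
            spans = []
            for ant in plan.antecedent_nps:
                stype = next(iter(kb.semantic_types(ant.head_concepts[0])))
                ent = b.entity(ant, stype)
                entities.append(ent)
                relations.append(b.coref(sortal, ent))
                spans.append(ant.span)
            planted.append(
                PlantedLink(
                    doc_index=d,
                    mechanism=plan.mechanism,
                    set_membership=plan.set_membership,
                    inter_sentential=(
                        plan.antecedent_sentence != plan.anaphor_sentence
                    ),
                    n_antecedents=plan.n_antecedents,
                    anaphor_span=plan.anaphor_np.span,
                    antecedent_spans=tuple(spans),
                )
            )
        for ent in entities:
            assert doc.surface(ent.span) == ent.surface
        gold.append((entities, relations))

    kb.validate()
    return SyntheticCorpus(kb=kb, documents=documents, gold=gold,
                           planted=planted)


def _realize_antecedent(kb: KnowledgeBase, sb, plan: _Plan, d: int, k: int) -> None:
    tag = f"{d}x{k}"
    nps = []
    for j in range(plan.n_antecedents):
        suffix = chr(ord("a") + j) if plan.set_membership else ""
        if plan.mechanism == "taxonomy":
            word = f"mem{tag}{suffix}"
            cui = _add_concept(kb, f"C_{word}", word, "Synthetic Chemical",
                               "Chemicals & Drugs")
            kb.add_edge(_anaphor_cui(kb, plan, tag), cui)
            np_ = sb.np(word, head_cuis=[cui], number=SINGULAR)
        elif plan.mechanism == "headword":
            group, _ = plan.headword_slot
            word = f"dis{tag}{suffix}"
            stype = "Synthetic Disorder" if group == "Disorder" else "Synthetic Therapy"
            cui = _add_concept(kb, f"C_{word}", word, stype, group)
            np_ = sb.np(word, head_cuis=[cui], number=SINGULAR)
        else:  # shared headword: longer phrase, same head lemma, new concept
            word = f"shw{tag}"
            cui = _add_concept(kb, f"C_long_{word}{suffix}",
                               f"specific {word} {suffix}",
                               "Synthetic Phenomenon", "Phenomena")
            np_ = sb.np(f"sub{suffix or 'x'}", word, head=1, head_cuis=[cui],
                        number=SINGULAR)
        kb.add_lexicon_entry(sb.sentence.tokens[np_.head_index].text, cui,
                             SINGULAR)
        nps.append(np_)
        if j < plan.n_antecedents - 1:
            sb.punct(",")
            if j == plan.n_antecedents - 2:
                sb.word("and", pos="CONJ")
    if plan.set_membership:
        sb.coord(*nps)
    plan.antecedent_nps = nps


def _anaphor_cui(kb: KnowledgeBase, plan: _Plan, tag: str) -> str:
    """Concept of the anaphor head, creating it on first use."""
    if plan.mechanism == "taxonomy":
        cui = f"C_cat{tag}"
        if cui not in kb.concepts:
            _add_concept(kb, cui, f"cat{tag}", "Synthetic Chemical",
                         "Chemicals & Drugs")
            kb.add_lexicon_entry(f"cat{tag}", cui, SINGULAR)
        return cui
    if plan.mechanism == "headword":
        _, headword = plan.headword_slot
        return f"C_{headword}"
    cui = f"C_shw{tag}"
    if cui not in kb.concepts:
        _add_concept(kb, cui, f"shw{tag}", "Synthetic Phenomenon", "Phenomena")
        kb.add_lexicon_entry(f"shw{tag}", cui, SINGULAR)
    return cui


def _realize_anaphor(kb: KnowledgeBase, sb, plan: _Plan, d: int, k: int) -> None:
    tag = f"{d}x{k}"
    cui = _anaphor_cui(kb, plan, tag)
    if plan.mechanism == "taxonomy":
        head = f"cat{tag}"
    elif plan.mechanism == "headword":
        head = plan.headword_slot[1]
    else:
        head = f"shw{tag}"
    if plan.set_membership:
        plan.anaphor_np = sb.np(
            "these", head + "s", det=0, head_cuis=[cui], number=PLURAL,
            lemmas={1: head},
        )
    else:
        plan.anaphor_np = sb.np("the", head, det=0, head_cuis=[cui],
                                number=SINGULAR)
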