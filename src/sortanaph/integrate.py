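"""Integration of anaphora links with relation (predication) generation.

A predication is a subject-predicate-object triple over knowledge-base
concepts.  The bundled indicator-rule engine is deliberately minimal: it
covers restrictive appositives (ISA) and a handful of lexical indicators
(TREATS, PREVENTS, PART_OF) with semantic-group constraints on the
arguments, which is enough to exercise argument substitution; it is in no
way a full relation-extraction system.

:func:`substitute_arguments` is the operation of interest: whenever a
predication's subject or object mention is a resolved sortal anaphor, the
argument is replaced by the antecedent concept(s), multiplying the
predication for set-membership links.  Links whose anaphor serves as no
predication argument simply remain unused.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from .docmodel import CoordinateNP, Document, NounPhrase, Sentence, Span
from .knowledge import KnowledgeBase
from .link import AnaphoraLink


@dataclass(frozen=True)
class Predication:
    subject_cui: str
    predicate: str
    object_cui: str
    subject_span: Span
    object_span: Span
    indicator_span: Span

    def triple(self) -> tuple[str, str, str]:
        return (self.subject_cui, self.predicate, self.object_cui)


@dataclass(frozen=True)
class IndicatorRule:
    """Maps a lexical or syntactic indicator to a predicate.

    ``trigger`` is a token lemma, or the construction tag ``"appositive"``.
    For appositives the specific member (second NP) is the subject and the
    generic member the object (amantadine ISA antiviral agent).  For
    lexical indicators the subject is the nearest preceding argument whose
    semantic group is allowed, the object the nearest following one.
    """

    trigger: str
    predicate: str
    subject_groups: Optional[frozenset[str]] = None
    object_groups: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if not self.trigger:
            raise ValueError("indicator rule with empty trigger")


_THERAPY_GROUPS = frozenset({"Chemicals & Drugs", "Procedures", "Therapeutic Modality"})


def default_rules() -> list[IndicatorRule]:
    return [
        IndicatorRule("appositive", "ISA"),
        IndicatorRule("manage", "TREATS", _THERAPY_GROUPS, frozenset({"Disorder"})),
        IndicatorRule("treat", "TREATS", _THERAPY_GROUPS, frozenset({"Disorder"})),
        IndicatorRule("treatment", "TREATS", _THERAPY_GROUPS, frozenset({"Disorder"})),
        IndicatorRule("prevent", "PREVENTS", _THERAPY_GROUPS, frozenset({"Disorder"})),
        IndicatorRule("express", "PART_OF", frozenset({"Genes"}),
                      frozenset({"Anatomy"})),
    ]


def _np_concept(np: NounPhrase) -> Optional[str]:
    if np.head_concepts:
        return np.head_concepts[0]
    if np.full_concepts:
        return np.full_concepts[0]
    return None


@dataclass(frozen=True)
class _ArgUnit:
    """An argument position: a lone NP or a whole coordination."""

    start: int
    end: int
    nps: tuple[NounPhrase, ...]


def _argument_units(sentence: Sentence) -> list[_ArgUnit]:
    coordinated: set[int] = set()
    units = []
    for coord in sentence.coordinations:
        nps = tuple(sentence.noun_phrases[j] for j in coord.conjunct_indices)
        units.append(_ArgUnit(coord.span[0], coord.span[1], nps))
        coordinated.update(coord.conjunct_indices)
    for j, np in enumerate(sentence.noun_phrases):
        if j not in coordinated:
            units.append(_ArgUnit(np.span[0], np.span[1], (np,)))
    units.sort(key=lambda u: u.start)
    return units


def _group_ok(kb: KnowledgeBase, cui: str, groups: Optional[frozenset[str]]) -> bool:
    return groups is None or kb.semantic_group(cui) in groups


def _match_unit(
    kb: KnowledgeBase, unit: _ArgUnit, groups: Optional[frozenset[str]]
) -> list[tuple[NounPhrase, str]]:
    """Concept-bearing NPs of the unit, kept only if every member passes the
    group constraint (a half-matching coordination is not an argument)."""
    out = []
    for np in unit.nps:
        cui = _np_concept(np)
        if cui is None or not _group_ok(kb, cui, groups):
            return []
        out.append((np, cui))
    return out


def generate_predications(
    document: Document,
    kb: KnowledgeBase,
    rules: Optional[Iterable[IndicatorRule]] = None,
) -> list[Predication]:
    """One predication per (indicator, subject NP, object NP), with
    coordinate arguments distributed over their conjuncts; deterministic
    order (sentence, indicator position)."""
    rules = list(default_rules() if rules is None else rules)
    lexical = {r.trigger: r for r in rules if r.trigger != "appositive"}
    appositive_rules = [r for r in rules if r.trigger == "appositive"]
    out: list[Predication] = []

    for sent in document.sentences:
        for rule in appositive_rules:
            for i, j in sent.appositive_pairs:
                generic, specific = sent.noun_phrases[i], sent.noun_phrases[j]
                s_cui, o_cui = _np_concept(specific), _np_concept(generic)
                if s_cui is None or o_cui is None:
                    continue
                out.append(
                    Predication(
                        subject_cui=s_cui,
                        predicate=rule.predicate,
                        object_cui=o_cui,
                        subject_span=specific.span,
                        object_span=generic.span,
                        indicator_span=(generic.span[0], specific.span[1]),
                    )
                )
        units = _argument_units(sent)
        for tok in sent.tokens:
            rule = lexical.get(tok.lemma.lower())
            if rule is None:
                continue
            before = [u for u in units if u.end <= tok.span[0]]
            after = [u for u in units if u.start >= tok.span[1]]
            subject = next(
                (
                    m
                    for u in reversed(before)
                    if (m := _match_unit(kb, u, rule.subject_groups))
                ),
                None,
            )
            obj = next(
                (m for u in after if (m := _match_unit(kb, u, rule.object_groups))),
                None,
            )
            if not subject or not obj:
                continue
            for s_np, s_cui in subject:
                for o_np, o_cui in obj:
                    out.append(
                        Predication(
                            subject_cui=s_cui,
                            predicate=rule.predicate,
                            object_cui=o_cui,
                            subject_span=s_np.span,
                            object_span=o_np.span,
                            indicator_span=tok.span,
                        )
                    )
    return out


def substitute_arguments(
    predications: Iterable[Predication], links: Iterable[AnaphoraLink]
) -> list[Predication]:
    """Replace anaphoric arguments by their antecedent concept(s).

    Anaphor-argument matching is by exact span equality of the noun phrase
    (both sides come from the same document analysis).  A predication whose
    subject or object is a resolved anaphor is emitted once per antecedent
    concept; untouched predications pass through unchanged.  Duplicates on
    (subject, predicate, object) are removed, keeping first occurrence.
    """
    by_span: dict[Span, AnaphoraLink] = {}
    for link in links:
        by_span.setdefault(link.anaphor.np.span, link)

    out: list[Predication] = []
    for pred in predications:
        subs: list[tuple[str, Span]] = [(pred.subject_cui, pred.subject_span)]
        link = by_span.get(pred.subject_span)
        if link is not None:
            subs = [
                (cui, m.span)
                for m, cui in zip(link.antecedent_mentions, link.antecedent_concepts)
                if cui is not None
            ] or subs
        objs: list[tuple[str, Span]] = [(pred.object_cui, pred.object_span)]
        link = by_span.get(pred.object_span)
        if link is not None:
            objs = [
                (cui, m.span)
                for m, cui in zip(link.antecedent_mentions, link.antecedent_concepts)
                if cui is not None
            ] or objs
        for s_cui, s_span in subs:
            for o_cui, o_span in objs:
                out.append(
                    Predication(
                        subject_cui=s_cui,
                        predicate=pred.predicate,
                        object_cui=o_cui,
                        subject_span=s_span,
                        object_span=o_span,
                        indicator_span=pred.indicator_span,
                    )
                )
    seen: set[tuple[str, str, str]] = set()
    deduped = []
    for pred in out:
        if pred.triple() not in seen:
            seen.add(pred.triple())
            deduped.append(pred)
    return deduped
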