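"""Phase 2: anaphor-antecedent linking.

For each detected sortal anaphor the resolver enumerates every noun phrase
and coordinate noun phrase in the preceding discourse, keeps the candidates
that are *semantically consonant* and *number-agreeing* with the anaphor,
and then either terminates (no compatible candidate: likely a universal
anaphor such as "this study"; exactly one: take it) or picks the most
salient candidate:

* same-sentence candidates win, the one closest to the anaphor first;
* otherwise the leftmost compatible candidate of the closest preceding
  sentence that has any.

Semantic consonance is hypernymy in a broad sense.  With A the anaphor's
head concept and B the candidate's concept, A is consonant with B when any
of these hold (and neither concept is in the catch-all ``Concept`` group):

* **Taxonomy** -- A is a proper taxonomy ancestor of B, and the pair is not
  meronymic (anatomy above the cell level);
* **Headword** -- B's semantic group lists A's headword among its generic
  headwords (``condition`` vs. a specific disorder);
* **Shared headword** -- same headword, different concepts, and B's phrase
  is strictly longer than A's ("the reaction" vs. "anaphylactoid
  reaction").

A coordinate candidate is consonant only if *every* conjunct is; a winning
coordinate yields a set-membership link with one antecedent per conjunct.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .detect import DetectConfig, SortalAnaphor, detect_anaphors, head_number
from .docmodel import (
    CoordinateNP,
    DiscourseMention,
    Document,
    NounPhrase,
    Sentence,
    accumulate_discourse,
)
from .knowledge import KnowledgeBase, PLURAL, SINGULAR, UNKNOWN, is_ancestor, is_meronymic_pair

PROV_SINGLE = "single_candidate"
PROV_INTRA = "intra_sentential_closest"
PROV_INTER = "inter_sentential_leftmost"


@dataclass
class ResolverConfig:
    """Constraint and filter toggles for the full system and its ablations."""

    filters: DetectConfig = field(default_factory=DetectConfig)
    taxonomy: bool = True
    headword: bool = True
    shared_headword: bool = True
    number: bool = True
    set_membership: bool = True
    #: Optional stipulation that a "both"-anaphor takes exactly two
    #: antecedents; off by default.
    both_max_two: bool = False

    @classmethod
    def without(cls, component: str) -> "ResolverConfig":
        """Config with one named component removed (ablation harness)."""
        cfg = cls()
        if component == "anaphoricity_filter":
            # morpho-syntactic filters off; the unmapped-head condition stays,
            # since linking is impossible without a head concept
            cfg.filters = DetectConfig(
                appositive=False, rigid_designator=False, of_pp=False,
                cataphora=False, number_clash=False,
            )
        elif component in ("taxonomy", "headword", "shared_headword", "number",
                           "set_membership"):
            setattr(cfg, component, False)
        else:
            raise ValueError(f"unknown ablation component {component!r}")
        return cfg


@dataclass(frozen=True)
class Candidate:
    mention: object  # NounPhrase | CoordinateNP
    sentence_index: int
    start: int
    is_coordinate: bool


@dataclass
class AnaphoraLink:
    """One anaphor linked to one or more antecedent mentions.

    Multiple antecedent mentions encode set-membership anaphora (the chosen
    candidate was a coordinate NP); pairwise expansion is left to the
    scorer.
    """

    anaphor: SortalAnaphor
    antecedent_mentions: list[NounPhrase]
    antecedent_sentences: list[int]
    antecedent_concepts: list[Optional[str]]
    provenance: str


def _np_concepts(np: NounPhrase) -> list[str]:
    return np.head_concepts if np.head_concepts else np.full_concepts


def _np_headword(sentence: Sentence, np: NounPhrase) -> str:
    return sentence.head_token(np).lemma.lower()


def _np_token_count(np: NounPhrase) -> int:
    """Phrase length for the shared-headword test, determiner excluded."""
    return len([i for i in np.token_indices if i != np.determiner_index])


def _pair_consonant(
    kb: KnowledgeBase,
    a_cui: str,
    a_headword: str,
    a_tokens: int,
    b_np: NounPhrase,
    b_sentence: Sentence,
    config: ResolverConfig,
) -> Optional[str]:
    """Return the candidate cui that makes the pair consonant, else None."""
    if kb.semantic_group(a_cui) == "Concept":
        return None
    for b_cui in _np_concepts(b_np):
        if kb.semantic_group(b_cui) == "Concept":
            continue
        if config.taxonomy and is_ancestor(kb, a_cui, b_cui) and not is_meronymic_pair(
            kb, a_cui, b_cui
        ):
            return b_cui
        if config.headword and a_headword in kb.group_headwords.get(
            kb.semantic_group(b_cui), ()
        ):
            return b_cui
        if (
            config.shared_headword
            and a_headword == _np_headword(b_sentence, b_np)
            and a_cui != b_cui
            and _np_token_count(b_np) > a_tokens
        ):
            return b_cui
    return None


def semantically_consonant(
    kb: KnowledgeBase,
    anaphor: SortalAnaphor,
    candidate: Candidate,
    document: Document,
    config: Optional[ResolverConfig] = None,
) -> bool:
    """Semantic-consonance test between an anaphor and one candidate.

    When the anaphor head maps to several concepts, consonance over any of
    them is accepted.  A coordinate candidate must have every conjunct
    consonant.
    """
    config = config or ResolverConfig()
    sent = document.sentences[anaphor.sentence_index]
    a_headword = _np_headword(sent, anaphor.np)
    a_tokens = _np_token_count(anaphor.np)
    cand_sent = document.sentences[candidate.sentence_index]

    def np_ok(np: NounPhrase) -> bool:
        return any(
            _pair_consonant(kb, a_cui, a_headword, a_tokens, np, cand_sent, config)
            for a_cui in anaphor.head_concepts
        )

    if candidate.is_coordinate:
        conjuncts = [
            cand_sent.noun_phrases[j] for j in candidate.mention.conjunct_indices
        ]
        return all(_np_concepts(c) and np_ok(c) for c in conjuncts)
    if not _np_concepts(candidate.mention):
        return False
    return np_ok(candidate.mention)


def number_agrees(
    anaphor: SortalAnaphor, candidate: Candidate, document: Document
) -> bool:
    """Number agreement; coordinate candidates count as plural, unknown as
    singular."""
    a_num = head_number(document.sentences[anaphor.sentence_index], anaphor.np)
    if candidate.is_coordinate:
        c_num = PLURAL
    else:
        c_num = head_number(
            document.sentences[candidate.sentence_index], candidate.mention
        )
    return a_num == c_num


def select_antecedent(
    compatible: list[Candidate], anaphor: SortalAnaphor
) -> Optional[tuple[Candidate, str]]:
    """Salience-based choice among compatible candidates.

    Empty -> None (resolution terminates; likely a universal anaphor).
    Singleton -> that candidate.  Otherwise same-sentence candidates win
    (greatest start offset = closest to the anaphor); failing that, the
    leftmost candidate of the closest preceding sentence with any.  Equal
    start offsets (a coordination and its first conjunct) are broken in
    favor of the coordinate, then the wider mention.
    """
    if not compatible:
        return None
    if len(compatible) == 1:
        return compatible[0], PROV_SINGLE

    def width(c: Candidate) -> int:
        return c.mention.span[1] - c.mention.span[0]

    intra = [c for c in compatible if c.sentence_index == anaphor.sentence_index]
    if intra:
        best = max(intra, key=lambda c: (c.start, c.is_coordinate, width(c)))
        return best, PROV_INTRA
    best_sentence = max(c.sentence_index for c in compatible)
    in_sent = [c for c in compatible if c.sentence_index == best_sentence]
    best = min(in_sent, key=lambda c: (c.start, not c.is_coordinate, -width(c)))
    return best, PROV_INTER


def _chosen_concept(
    kb: KnowledgeBase,
    anaphor: SortalAnaphor,
    np: NounPhrase,
    sentence: Sentence,
    document: Document,
    config: ResolverConfig,
) -> Optional[str]:
    """The candidate concept that satisfied consonance (first match),
    falling back to the mention's first concept."""
    a_sent = document.sentences[anaphor.sentence_index]
    a_headword = _np_headword(a_sent, anaphor.np)
    a_tokens = _np_token_count(anaphor.np)
    for a_cui in anaphor.head_concepts:
        hit = _pair_consonant(kb, a_cui, a_headword, a_tokens, np, sentence, config)
        if hit:
            return hit
    concepts = _np_concepts(np)
    return concepts[0] if concepts else None


def resolve(
    document: Document,
    kb: KnowledgeBase,
    config: Optional[ResolverConfig] = None,
) -> list[AnaphoraLink]:
    """Full resolution: detect anaphors, link each to its antecedent(s).

    Deterministic: anaphors are processed in textual order and candidate
    selection has no ties by construction.  Unresolved anaphors produce no
    link.
    """
    config = config or ResolverConfig()
    links: list[AnaphoraLink] = []
    for anaphor in detect_anaphors(document, kb, config.filters):
        if not anaphor.head_concepts:
            continue
        candidates = [
            Candidate(m.mention, m.sentence_index, m.start, m.is_coordinate)
            for m in accumulate_discourse(
                document, anaphor.sentence_index, before_offset=anaphor.np.start
            )
        ]
        if not config.set_membership:
            candidates = [c for c in candidates if not c.is_coordinate]
        if config.both_max_two and anaphor.trigger_word == "both":
            candidates = [
                c
                for c in candidates
                if not c.is_coordinate or len(c.mention.conjunct_indices) == 2
            ]
        compatible = [
            c
            for c in candidates
            if semantically_consonant(kb, anaphor, c, document, config)
            and (not config.number or number_agrees(anaphor, c, document))
        ]
        selected = select_antecedent(compatible, anaphor)
        if selected is None:
            continue
        winner, provenance = selected
        sent = document.sentences[winner.sentence_index]
        if winner.is_coordinate:
            mentions = [sent.noun_phrases[j] for j in winner.mention.conjunct_indices]
        else:
            mentions = [winner.mention]
        links.append(
            AnaphoraLink(
                anaphor=anaphor,
                antecedent_mentions=mentions,
                antecedent_sentences=[winner.sentence_index] * len(mentions),
                antecedent_concepts=[
                    _chosen_concept(kb, anaphor, m, sent, document, config)
                    for m in mentions
                ],
                provenance=provenance,
            )
        )
    return links
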