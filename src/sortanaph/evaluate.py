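"""Evaluation: brat standoff gold I/O, relaxed pairwise matching, scoring,
the head-match baseline resolver, and the ablation harness.

Coreference is represented pairwise, matching the gold annotation style:
a set-membership link with *k* antecedents expands into *k* (anaphor,
antecedent) pairs.  A predicted pair counts as a true positive against a
gold pair under the union of three relaxed criteria:

1. **approximate match** -- the character offsets of both arguments overlap
   with the gold pair's, and the semantic types of the arguments match;
2. **span subsumption** -- the predicted antecedent is subsumed by a gold
   annotation of the generic ``SPAN`` type (no type matching required);
3. **concept match** -- the predicted antecedent *concept* equals the gold
   antecedent's concept (no antecedent offset overlap required).

The same F1 computation doubles as the inter-annotator agreement metric
(score one annotation set against the other as gold).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .detect import find_trigger_nps, head_number
from .docmodel import (
    Document,
    NounPhrase,
    Span,
    span_subsumed,
    spans_overlap,
)
from .knowledge import KnowledgeBase, SINGULAR, UNKNOWN, lookup_surface
from .link import AnaphoraLink, ResolverConfig, resolve


class BratParseError(ValueError):
    pass


@dataclass(frozen=True)
class GoldEntity:
    id: str
    type: str  # "Sortal", "SPAN", or a semantic-type label
    span: Span
    surface: str


@dataclass(frozen=True)
class GoldRelation:
    id: str
    type: str
    anaphor: GoldEntity
    antecedent: GoldEntity


_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_R_LINE = re.compile(r"^(R\d+)\t(\S+) Arg1:(T\d+) Arg2:(T\d+)\s*$")


def parse_brat(text: str, ann: str) -> tuple[list[GoldEntity], list[GoldRelation]]:
    entities: dict[str, GoldEntity] = {}
    relations: list[GoldRelation] = []
    for line in ann.splitlines():
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if not m:
                raise BratParseError(f"malformed entity line: {line!r}")
            tid, etype, start, end, surface = m.groups()
            # brat types are single tokens; multi-word semantic-type labels
            # are written with underscores
            etype = etype.replace("_", " ") if etype not in ("SPAN", "Sortal") else etype
            span = (int(start), int(end))
            if text[span[0] : span[1]] != surface:
                raise BratParseError(
                    f"{tid}: surface {surface!r} does not match text slice "
                    f"{text[span[0]:span[1]]!r} at {span}"
                )
            entities[tid] = GoldEntity(tid, etype, span, surface)
        elif line.startswith("R"):
            m = _R_LINE.match(line)
            if not m:
                raise BratParseError(f"malformed relation line: {line!r}")
            rid, rtype, arg1, arg2 = m.groups()
            for t in (arg1, arg2):
                if t not in entities:
                    raise BratParseError(f"{rid}: unknown entity {t}")
            relations.append(GoldRelation(rid, rtype, entities[arg1], entities[arg2]))
        elif line.startswith("#"):
            continue
        else:
            raise BratParseError(f"unrecognized annotation line: {line!r}")
    return list(entities.values()), relations


def read_brat(txt_path, ann_path) -> tuple[str, list[GoldEntity], list[GoldRelation]]:
    with open(txt_path, encoding="utf-8") as fh:
        text = fh.read()
    with open(ann_path, encoding="utf-8") as fh:
        ann = fh.read()
    entities, relations = parse_brat(text, ann)
    return text, entities, relations


def format_brat(entities: Sequence[GoldEntity],
                relations: Sequence[GoldRelation]) -> str:
    lines = [
        f"{e.id}\t{e.type.replace(' ', '_')} {e.span[0]} {e.span[1]}\t{e.surface}"
        for e in entities
    ]
    lines += [
        f"{r.id}\t{r.type} Arg1:{r.anaphor.id} Arg2:{r.antecedent.id}"
        for r in relations
    ]
    return "\n".join(lines) + ("\n" if lines else "")


def write_brat(text: str, entities: Sequence[GoldEntity],
               relations: Sequence[GoldRelation], txt_path, ann_path) -> None:
    with open(txt_path, "w", encoding="utf-8") as fh:
        fh.write(text)
    with open(ann_path, "w", encoding="utf-8") as fh:
        fh.write(format_brat(entities, relations))


# -- pairwise expansion and matching --------------------------------------


@dataclass(frozen=True)
class PredictedPair:
    """One pairwise (anaphor, antecedent) prediction."""

    anaphor_span: Span
    anaphor_cuis: tuple[str, ...]
    antecedent_span: Span
    antecedent_cui: Optional[str]


def expand_links(links: Iterable[AnaphoraLink]) -> list[PredictedPair]:
    pairs = []
    for link in links:
        for mention, cui in zip(link.antecedent_mentions, link.antecedent_concepts):
            pairs.append(
                PredictedPair(
                    anaphor_span=link.anaphor.np.span,
                    anaphor_cuis=tuple(link.anaphor.head_concepts),
                    antecedent_span=mention.span,
                    antecedent_cui=cui,
                )
            )
    return pairs


def _types_of(kb: KnowledgeBase, cuis: Iterable[str]) -> set[str]:
    out: set[str] = set()
    for cui in cuis:
        if cui is not None and cui in kb.concepts:
            out |= kb.semantic_types(cui)
    return out


def _gold_type_matches(kb: KnowledgeBase, gold: GoldEntity,
                       pred_cuis: Iterable[str]) -> bool:
    # "Sortal" carries no semantic type: anaphor side matches by offsets
    # alone; "SPAN" is the generic unmapped type and never type-matches.
    if gold.type == "Sortal":
        return True
    if gold.type == "SPAN":
        return False
    return gold.type in _types_of(kb, pred_cuis)


def _gold_concepts(kb: KnowledgeBase, gold: GoldEntity) -> set[str]:
    return {cui for cui, _ in lookup_surface(kb, gold.surface)}


def match_pair(pred: PredictedPair, gold: GoldRelation,
               kb: KnowledgeBase) -> Optional[int]:
    """Relaxed pairwise match; returns the first criterion that fires
    (1, 2 or 3) or None.
    """
    anaphor_overlaps = spans_overlap(pred.anaphor_span, gold.anaphor.span)
    ant_cuis = [pred.antecedent_cui] if pred.antecedent_cui else []

    if (
        anaphor_overlaps
        and spans_overlap(pred.antecedent_span, gold.antecedent.span)
        and _gold_type_matches(kb, gold.anaphor, pred.anaphor_cuis)
        and _gold_type_matches(kb, gold.antecedent, ant_cuis)
    ):
        return 1
    if (
        anaphor_overlaps
        and gold.antecedent.type == "SPAN"
        and span_subsumed(pred.antecedent_span, gold.antecedent.span)
    ):
        return 2
    if (
        anaphor_overlaps
        and pred.antecedent_cui is not None
        and pred.antecedent_cui in _gold_concepts(kb, gold.antecedent)
    ):
        return 3
    return None


@dataclass
class EvalReport:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    criterion_tp: dict[int, int] = field(default_factory=lambda: {1: 0, 2: 0, 3: 0})

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 0.0

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 0.0

    @property
    def f1(self) -> float:
        p, r = self.precision, self.recall
        return 2 * p * r / (p + r) if (p + r) else 0.0

    def __iadd__(self, other: "EvalReport") -> "EvalReport":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        for k, v in other.criterion_tp.items():
            self.criterion_tp[k] = self.criterion_tp.get(k, 0) + v
        return self


def score(
    predicted: Iterable[AnaphoraLink] | Iterable[PredictedPair],
    gold_relations: Sequence[GoldRelation],
    kb: KnowledgeBase,
) -> EvalReport:
    """Greedy left-to-right one-to-one matching of predicted pairs against
    gold pairs; each gold pair is consumable once.  Deterministic."""
    items = list(predicted)
    if items and isinstance(items[0], AnaphoraLink):
        pairs = expand_links(items)
    else:
        pairs = items  # already pairwise
    report = EvalReport()
    unmatched = list(gold_relations)
    for pair in pairs:
        hit = None
        for gi, gold in enumerate(unmatched):
            crit = match_pair(pair, gold, kb)
            if crit is not None:
                hit = (gi, crit)
                break
        if hit is None:
            report.fp += 1
        else:
            gi, crit = hit
            unmatched.pop(gi)
            report.tp += 1
            report.criterion_tp[crit] = report.criterion_tp.get(crit, 0) + 1
    report.fn = len(unmatched)
    return report


# -- head-match baseline ---------------------------------------------------


def baseline_resolve(document: Document) -> list[PredictedPair]:
    """Naive baseline: every trigger NP is taken as a sortal anaphor (no
    anaphoricity filtering) and linked to the closest preceding NP whose
    head lemma and number match; no link when none exists."""
    pairs = []
    mentions = list(document.mentions())
    for trig in find_trigger_nps(document):
        sent = document.sentences[trig.sentence_index]
        np = sent.noun_phrases[trig.np_index]
        lemma = sent.head_token(np).lemma.lower()
        number = head_number(sent, np)
        preceding = [
            (si, cand)
            for si, cand in mentions
            if cand.start < np.start and cand is not np
        ]
        for si, cand in sorted(preceding, key=lambda x: -x[1].start):
            cand_sent = document.sentences[si]
            if (
                cand_sent.head_token(cand).lemma.lower() == lemma
                and head_number(cand_sent, cand) == number
            ):
                cuis = cand.head_concepts or cand.full_concepts
                pairs.append(
                    PredictedPair(
                        anaphor_span=np.span,
                        anaphor_cuis=tuple(np.head_concepts),
                        antecedent_span=cand.span,
                        antecedent_cui=cuis[0] if cuis else None,
                    )
                )
                break
    return pairs


# -- ablation harness ------------------------------------------------------

ABLATION_COMPONENTS = (
    "anaphoricity_filter",
    "taxonomy",
    "headword",
    "shared_headword",
    "number",
    "set_membership",
)

CorpusItem = tuple[Document, Sequence[GoldRelation]]


def score_corpus(
    corpus: Iterable[CorpusItem], kb: KnowledgeBase,
    config: Optional[ResolverConfig] = None,
) -> EvalReport:
    total = EvalReport()
    for document, gold in corpus:
        total += score(resolve(document, kb, config), gold, kb)
    return total


def ablate(
    corpus: Sequence[CorpusItem],
    kb: KnowledgeBase,
    toggles: Sequence[str] = ABLATION_COMPONENTS,
) -> pd.DataFrame:
    """Full system plus one row per single-component-removed configuration.

    Mirrors the classic ablation design: remove a component, re-run, and
    re-score.  Removing ``set_membership`` skips coordinate candidates
    entirely.
    """
    for t in toggles:
        if t not in ABLATION_COMPONENTS:
            raise ValueError(f"unknown ablation toggle {t!r}")
    rows = []
    configs = [("(none)", ResolverConfig())] + [
        (t, ResolverConfig.without(t)) for t in toggles
    ]
    for name, config in configs:
        rep = score_corpus(corpus, kb, config)
        rows.append(
            {
                "removed": name,
                "tp": rep.tp,
                "fp": rep.fp,
                "fn": rep.fn,
                "precision": rep.precision,
                "recall": rep.recall,
                "f1": rep.f1,
            }
        )
    return pd.DataFrame(rows).set_index("removed")
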