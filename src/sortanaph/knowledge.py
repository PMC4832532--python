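"""Pluggable biomedical knowledge base.

The resolver needs four kinds of semantic knowledge, all modeled after the
UMLS Metathesaurus / Semantic Network organization:

* **concepts** -- each with an opaque identifier (CUI), a preferred name,
  one or more semantic types (e.g. ``Pharmacologic Substance``) and exactly
  one coarse semantic group (e.g. ``Chemicals & Drugs``);
* **taxonomy** -- a directed acyclic parent->child graph over concepts,
  queried for (proper) ancestry when testing hypernymy;
* **group headwords** -- per-group lists of generic nouns (``condition``,
  ``medication``, ...) whose instances are rarely linked taxonomically to
  the generic concept in real terminologies;
* **lexicon** -- a surface-string -> concept map standing in for a full
  concept-normalization engine, with a grammatical-number feature per entry.

The KB is deliberately file-based and pluggable: a user with access to a
licensed terminology can export the slice they need into the JSON dialect
documented in :func:`load_kb`.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import networkx as nx

#: Closed enumeration of semantic groups shipped with the KB schema.
#: Coarse partition in the spirit of the UMLS semantic groups; ``Concept``
#: is included so that the broad/heterogeneous-group exclusion rule used in
#: semantic consonance is expressible.
SEMANTIC_GROUPS = frozenset(
    {
        "Activities & Behaviors",
        "Anatomy",
        "Chemicals & Drugs",
        "Concept",
        "Devices",
        "Disorder",
        "Genes",
        "Geographic Areas",
        "Living Beings",
        "Objects",
        "Occupations",
        "Organizations",
        "Phenomena",
        "Physiology",
        "Procedures",
        "Therapeutic Modality",
    }
)

SINGULAR = "singular"
PLURAL = "plural"
UNKNOWN = "unknown"
NUMBERS = frozenset({SINGULAR, PLURAL, UNKNOWN})


class KBError(ValueError):
    """Raised for malformed knowledge-base files or unknown identifiers."""


@dataclass(frozen=True)
class Concept:
    """A knowledge-base concept (node of the taxonomy)."""

    cui: str
    preferred_name: str
    semantic_types: frozenset[str]
    semantic_group: str

    def __post_init__(self) -> None:
        if not self.cui:
            raise KBError("concept with empty cui")
        if not self.semantic_types:
            raise KBError(f"concept {self.cui!r} has no semantic types")
        if self.semantic_group not in SEMANTIC_GROUPS:
            raise KBError(
                f"concept {self.cui!r} has unknown semantic group "
                f"{self.semantic_group!r}"
            )


_WS = re.compile(r"\s+")


def normalize_surface(surface: str) -> str:
    """Lowercase and whitespace-normalize a surface string for lexicon lookup."""
    return _WS.sub(" ", surface.strip().lower())


# Minimal deterministic depluralizer; enough for the noun vocabulary the
# bundled analyzer and fixtures deal with.  Invariant nouns stay as-is.
_INVARIANT = frozenset({"species", "diabetes", "series", "analysis", "fibrosis"})


def singularize(word: str) -> str:
    w = word.lower()
    if w in _INVARIANT or len(w) < 3:
        return w
    if w.endswith("ies"):
        return w[:-3] + "y"
    if w.endswith(("ches", "shes", "sses", "xes", "zes")):
        return w[:-2]
    if w.endswith("s") and not w.endswith(("ss", "us", "is")):
        return w[:-1]
    return w


@dataclass
class KnowledgeBase:
    concepts: dict[str, Concept] = field(default_factory=dict)
    taxonomy: nx.DiGraph = field(default_factory=nx.DiGraph)
    group_headwords: dict[str, set[str]] = field(default_factory=dict)
    lexicon: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    # -- construction ------------------------------------------------------

    def add_concept(self, concept: Concept) -> None:
        if concept.cui in self.concepts:
            raise KBError(f"duplicate cui {concept.cui!r}")
        self.concepts[concept.cui] = concept
        self.taxonomy.add_node(concept.cui)

    def add_edge(self, parent: str, child: str) -> None:
        for cui in (parent, child):
            if cui not in self.concepts:
                raise KBError(f"taxonomy edge references unknown cui {cui!r}")
        self.taxonomy.add_edge(parent, child)
        if not nx.is_directed_acyclic_graph(self.taxonomy):
            self.taxonomy.remove_edge(parent, child)
            raise KBError(f"edge {parent!r}->{child!r} would create a cycle")

    def add_lexicon_entry(self, surface: str, cui: str, number: str = UNKNOWN) -> None:
        if cui not in self.concepts:
            raise KBError(f"lexicon entry references unknown cui {cui!r}")
        if number not in NUMBERS:
            raise KBError(f"bad number feature {number!r}")
        entry = (cui, number)
        entries = self.lexicon.setdefault(normalize_surface(surface), [])
        if entry not in entries:
            entries.append(entry)

    def set_group_headwords(self, group: str, headwords: Iterable[str]) -> None:
        if group not in SEMANTIC_GROUPS:
            raise KBError(f"unknown semantic group {group!r}")
        self.group_headwords[group] = {h.lower() for h in headwords}

    # -- queries -----------------------------------------------------------

    def concept(self, cui: str) -> Concept:
        try:
            return self.concepts[cui]
        except KeyError:
            raise KBError(f"unknown cui {cui!r}") from None

    def semantic_group(self, cui: str) -> str:
        return self.concept(cui).semantic_group

    def semantic_types(self, cui: str) -> frozenset[str]:
        return self.concept(cui).semantic_types

    def validate(self) -> None:
        if not nx.is_directed_acyclic_graph(self.taxonomy):
            raise KBError("taxonomy contains a cycle")
        for a, b in self.taxonomy.edges:
            if a not in self.concepts or b not in self.concepts:
                raise KBError(f"dangling taxonomy edge {a!r}->{b!r}")
        for group in self.group_headwords:
            if group not in SEMANTIC_GROUPS:
                raise KBError(f"group_headwords key {group!r} is not a valid group")
        for surface, entries in self.lexicon.items():
            for cui, number in entries:
                if cui not in self.concepts:
                    raise KBError(
                        f"lexicon entry {surface!r} references unknown cui {cui!r}"
                    )
                if number not in NUMBERS:
                    raise KBError(f"lexicon entry {surface!r} has bad number {number!r}")


def is_ancestor(kb: KnowledgeBase, a: str, b: str) -> bool:
    """True iff ``a`` is a *proper* ancestor of ``b`` in the taxonomy.

    The reflexive case is false by convention: hypernymy holds between
    distinct concepts only.
    """
    kb.concept(a)
    kb.concept(b)
    if a == b:
        return False
    return nx.has_path(kb.taxonomy, a, b)


def is_meronymic_pair(kb: KnowledgeBase, a: str, b: str) -> bool:
    """Heuristic part-whole test: both concepts are anatomical structures
    above the cellular level.

    Concept hierarchies mix taxonomic and partonomic edges for anatomy, so
    an ancestry link between two super-cellular Anatomy concepts (heart /
    right ventricle) is treated as meronymy, not hypernymy.  Concepts
    carrying the ``Cell`` semantic type are exempt.
    """
    ca, cb = kb.concept(a), kb.concept(b)
    if ca.semantic_group != "Anatomy" or cb.semantic_group != "Anatomy":
        return False
    return "Cell" not in ca.semantic_types and "Cell" not in cb.semantic_types


def lookup_surface(kb: KnowledgeBase, surface: str) -> list[tuple[str, str]]:
    """Case-insensitive, whitespace-normalized lexicon lookup.

    Returns ``[(cui, number), ...]`` or an empty list for unmapped strings.
    When the exact form is absent, a singularized form of the last word is
    tried; a hit through that fallback is reported as plural (the surface
    carried the plural inflection).
    """
    key = normalize_surface(surface)
    if not key:
        return []
    if key in kb.lexicon:
        return list(kb.lexicon[key])
    words = key.split(" ")
    fallback = " ".join(words[:-1] + [singularize(words[-1])])
    if fallback != key and fallback in kb.lexicon:
        return [(cui, PLURAL) for cui, _ in kb.lexicon[fallback]]
    return []


# -- serialization ---------------------------------------------------------


def save_kb(kb: KnowledgeBase, path) -> None:
    data = {
        "concepts": {
            c.cui: {
                "preferred_name": c.preferred_name,
                "semantic_types": sorted(c.semantic_types),
                "semantic_group": c.semantic_group,
            }
            for c in kb.concepts.values()
        },
        "taxonomy": sorted([p, c] for p, c in kb.taxonomy.edges),
        "group_headwords": {
            g: sorted(ws) for g, ws in sorted(kb.group_headwords.items())
        },
        "lexicon": {
            s: [[cui, num] for cui, num in entries]
            for s, entries in sorted(kb.lexicon.items())
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")


def kb_from_dict(data: dict) -> KnowledgeBase:
    kb = KnowledgeBase()
    try:
        concepts = data["concepts"]
    except KeyError:
        raise KBError("KB file missing top-level 'concepts' key") from None
    for cui, rec in concepts.items():
        try:
            kb.add_concept(
                Concept(
                    cui=cui,
                    preferred_name=rec["preferred_name"],
                    semantic_types=frozenset(rec["semantic_types"]),
                    semantic_group=rec["semantic_group"],
                )
            )
        except (KeyError, TypeError) as exc:
            raise KBError(f"malformed concept record {cui!r}: {exc}") from None
    for i, edge in enumerate(data.get("taxonomy", [])):
        try:
            parent, child = edge
        except (TypeError, ValueError):
            raise KBError(f"malformed taxonomy edge at index {i}: {edge!r}") from None
        kb.add_edge(parent, child)
    for group, headwords in data.get("group_headwords", {}).items():
        kb.set_group_headwords(group, headwords)
    for surface, entries in data.get("lexicon", {}).items():
        for entry in entries:
            try:
                cui, number = entry
            except (TypeError, ValueError):
                raise KBError(
                    f"malformed lexicon entry for {surface!r}: {entry!r}"
                ) from None
            kb.add_lexicon_entry(surface, cui, number)
    kb.validate()
    return kb


def load_kb(path) -> KnowledgeBase:
    """Load and validate a KB from the documented JSON dialect.

    Top-level keys: ``concepts`` (cui -> {preferred_name, semantic_types,
    semantic_group}), ``taxonomy`` (list of [parent, child] cui pairs),
    ``group_headwords`` (group -> list of lowercase headwords), ``lexicon``
    (normalized surface -> list of [cui, number]).
    """
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    return kb_from_dict(data)
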