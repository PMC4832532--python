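# Methods

This note documents the resolution model, the knowledge-base abstraction,
the evaluation protocol, the synthetic data, and the design choices made
where the design was genuinely open. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Document model and analysis

The resolver consumes documents only through a typed model: sentences,
tokens (text, lemma, coarse POS, grammatical number), base NP chunks with
a head token, optional determiner, modifiers and concept mappings,
appositive pairs, and coordinate NPs. Character offsets are 0-based and
half-open throughout, matching brat standoff semantics, so gold and
predicted mentions compare directly.

This boundary is deliberate: resolution quality depends heavily on the
upstream analysis (chunking, coordination, concept normalization), and
the mature pipelines that produce such analyses are outside this
package's scope. Gold-quality analyses are injected via a standoff JSON
dialect; the bundled `analyze_text` heuristic (regex tokenizer,
determiner/adjective/noun chunking, rightmost-noun heads, comma/and/or
coordination, `NP , NP` appositives) is a deterministic convenience that
degrades to coarse chunks, not the contract. Several fixture documents
intentionally encode *defective* analyses (a missed appositive, an
over-wide or absent coordination, an unmapped acronym) because the
behaviors they document are downstream consequences of exactly those
defects. Serial coordination interrupted by other material (percentages
between conjuncts) is not recognized by the bundled analyzer; it can
still be expressed in standoff input.

Concept mappings follow the convention of concept-normalization engines:
when a whole phrase maps to a concept, that mapping is attached at the
head (`head_concepts`); otherwise the head word's own mapping is used.
`full_concepts` preserves the phrase-level mapping separately.

## Knowledge base

A `KnowledgeBase` bundles concepts (identifier, preferred name, semantic
types, one semantic group from a closed 16-group enumeration), an acyclic
parent→child taxonomy, per-group generic-headword lists, and a surface
lexicon with a number feature per entry. Ancestry is the proper
transitive closure (the reflexive case is false: hypernymy is only ever
invoked between distinct concepts). The taxonomy abstraction does not fix
which source hierarchy the edges come from; a KB author exporting from a
licensed terminology chooses the hierarchies they trust.

Meronymy is approximated structurally: a concept pair is treated as
part–whole when both concepts are in the Anatomy group and neither
carries the `Cell` semantic type — concept hierarchies for anatomy mix
taxonomic and partonomic edges above the cellular level, and a partonomic
"ancestor" (heart over right ventricle) must not license coreference.

Lexicon lookup is case-insensitive and whitespace-normalized, with a
depluralization fallback on the last word (a fallback hit is reported as
plural). Number for unknown words defaults to unknown, which all
downstream consumers treat as singular.

## Anaphor detection

Trigger words: definite *the*; demonstratives *this/that/these/those*;
distributives *both/each/either/neither*; the demonstrative adjective
*such* (matched as a pre-head modifier; "such as" exemplification is not
special-cased — those links are soft errors for the downstream consumer
anyway). Five filters then remove unlikely anaphors; each is
independently toggleable for ablation:

1. **appositive** — first element of an appositive pair ("the gene,
   BRCA1").
2. **rigid_designator / of_pp** — a modifier maps to a concept separately
   from the head ("the Src family"), or the NP is followed by an of-PP
   ("the symptoms of lupus erythematosus"). The of-PP test uses the
   analyzer/standoff flag only; no attachment disambiguation is
   attempted.
3. **cataphora** — the NP contains the word *following*.
4. **number_clash** — the determiner's number (both/these/those plural;
   this/that/each/either/neither singular) conflicts with the head's.
   *the* and *such* impose no constraint, and the filter only applies
   when a determiner is present.
5. **unmapped_head** — no concept on the head: there is nothing for the
   semantic constraints to work with. This condition is kept even when
   the "anaphoricity filter" is ablated, since linking is undefined
   without a head concept.

## Linking

Candidates are all NPs and coordinate NPs starting strictly before the
anaphor, across the whole preceding discourse (abstracts are short;
no distance cutoff is applied). Compatibility is the conjunction of
semantic consonance and number agreement.

Semantic consonance (any route suffices, and any of a multi-mapped
anaphor head's concepts may satisfy it — multi-mappings are rare and a
disjunctive reading is the permissive, recall-friendly choice):

* **Taxonomy**: `is_ancestor(A, B)` and not `is_meronymic_pair(A, B)`.
* **Headword**: A's headword (lowercased head lemma) appears in the
  generic-headword list of B's semantic group. These lists compensate
  for generic terms (*condition*, *medication*) that real terminologies
  rarely connect taxonomically to their instances.
* **Shared headword**: same headword, different concepts, and B's phrase
  is strictly longer than A's, counting non-determiner tokens ("the
  reaction" [1] vs "anaphylactoid reaction" [2]).

Neither concept may belong to the catch-all **Concept** group (tested on
the head concept's group only); that group is too broad and heterogeneous
to constrain reference, and excluding it is also what leaves universal
anaphors ("this study") unresolved. A coordinate candidate is consonant
only if *every* conjunct is — a partially consonant coordination is not
decomposed into its passing conjuncts (choosing the conservative reading;
the alternative, keeping the consonant subset, is defensible but makes
the emitted link depend on the coordination's internal structure in ways
the gold pairwise representation cannot distinguish on the bundled
fixtures).

Number agreement: coordinate candidates count as plural; unknown number
counts as singular; agreement is equality. A singular anaphor therefore
never takes a coordinate antecedent.

Selection: zero compatible candidates terminates resolution for that
anaphor; one is taken directly; among several, same-sentence candidates
win with the greatest start offset (closest), else the candidate with the
smallest start offset in the nearest preceding sentence containing any
(leftmost — an approximation of the preferred center of that sentence).
A coordination and its first conjunct share a start offset; the tie goes
to the coordinate (wider) mention, which is what lets a plural anaphor
prefer the whole series over its first conjunct.

`both_max_two` (default off) optionally restricts *both*-anaphors to
2-conjunct coordinate candidates — a stipulated guard against over-wide
coordinations that is deliberately not part of the default system.

## Integration with predication generation

The bundled indicator-rule engine exists to exercise argument
substitution, not to extract relations at large: restrictive appositives
produce ISA (specific member as subject), and a handful of lexical
indicators (*manage/treat/treatment* → TREATS, *prevent* → PREVENTS,
*express* → PART_OF) take the nearest preceding/following argument whose
semantic group satisfies the rule (e.g. TREATS wants a
chemical/procedure subject and a Disorder object). Coordinate arguments
distribute over their conjuncts.

Substitution matches anaphors to predication arguments by exact NP-span
equality (both come from the same analysis), replaces the argument with
the antecedent concept(s) — per-conjunct head concepts for set-membership
links — one predication per antecedent, and de-duplicates on
(subject, predicate, object). Links whose anaphor is no argument remain
unused.

## Evaluation

Gold is brat standoff: `Sortal`-typed anaphor mentions, antecedent
mentions typed by semantic type (written with underscores in `.ann`
files, since brat types are single tokens) or by the generic `SPAN` type
when no adequate concept mapping exists, and pairwise `Coref` relations.
Set-membership links expand to pairwise (anaphor, antecedent) pairs
before scoring.

A predicted pair matches a gold pair under the union of three relaxed
criteria: (1) both argument offsets overlap and the semantic types match
(non-empty intersection; `Sortal` carries no type and matches by offsets
alone, `SPAN` never type-matches); (2) the predicted antecedent span is
subsumed by a gold `SPAN` annotation, no type match required; (3) the
predicted antecedent concept equals the gold antecedent's concept (looked
up from its surface), with no antecedent offset requirement. Criterion 1
requires *both* arguments to overlap — the alternative (either argument)
would be more lenient but blurs the distinction criterion 2 exists to
make. The anaphor span must overlap in all three criteria.

Matching is greedy left-to-right and one-to-one (each gold pair
consumable once); the discipline is a documented deterministic choice,
since ties are not otherwise specified. Precision, recall and F1 use the
0-when-undefined convention. The same F1 doubles as the inter-annotator
agreement metric (score one annotation set with the other as gold).
Coreference-chain metrics (MUC, B³, CEAF) are out of scope: the
representation is pairwise.

The baseline resolver treats every trigger NP as an anaphor and links it
to the closest preceding NP with equal head lemma and agreeing number.
The ablation harness re-runs the full system with one component removed
at a time (anaphoricity filters 1–4, each consonance route, number
agreement, set-membership processing — removing the latter skips
coordinate candidates entirely) and tabulates the scores.

## Fixture corpus and synthetic data

The fixture corpus holds 16 hand-built documents, one per worked example,
with the analysis states and knowledge-base gaps their narratives
presuppose, plus brat gold. The fixture KB is a ~80-concept terminology
slice whose deliberate gaps (no NASH concept, no drugs→ion-channel-
modulator edge, no chemotherapy-regimen links) drive the documented
failure modes.

The synthetic generator plants anaphora links of known provenance rather
than imitating prose: every candidate NP carries an explicit KB entry,
word families are unique per link, and distractors are non-consonant by
construction, so the intended antecedent is provably the salience winner
and planted-link recall is 1.0 by design. What passing these tests shows
is that the *mechanics* (constraint routes, number, salience,
set-membership expansion, scoring) are correct under controlled
conditions; it says nothing about chunker/normalizer quality on real
text, which the fixture corpus's defective-analysis documents probe
instead. Generator defaults mirror the reference corpus statistics:
2.95 anaphors per document (Poisson), 29 % set-membership links, member
counts 2–9 drawn from the observed distribution (mean 2.66), 85 %
inter-sentential links, one distractor NP per sentence (Poisson), and a
constraint mix of 0.7/0.2/0.1 for taxonomy/headword/shared-headword (the
taxonomy route dominates real data; any residual probability falls back
to taxonomy, as do headword draws beyond the two per-document headword
slots — one per seeded group — that keep headword links from interfering
with each other). All randomness flows from a single seeded generator;
identical specs yield byte-identical corpora.

## Problem sizes and numerical choices

Property suites use 30-node random DAGs (exhaustive reachability
comparison), 1 000 random candidate configurations for the salience
oracle, and 200-document synthetic corpora for ablation directionality;
these sizes make the full suite run in a few seconds while keeping the
exhaustive checks exhaustive. There are no floating-point tolerances in
the resolver itself; scoring fractions are exact rationals of small
integers and compared with pytest's default approx only where division is
involved.

## Known limitations

* Rule coverage of the predication engine is intentionally minimal.
* The bundled analyzer's POS/lemma heuristics are crude; quality input
  should come through the standoff format.
* Salience is two rules; intra-sentential selection in particular is a
  known source of errors (the closest candidate is often an appositive
  partner of the correct one).
* Pronominal anaphora, bridging/associative coreference, and cataphora
  resolution are out of scope by design.
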