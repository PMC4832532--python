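# sortanaph

Rule-based **sortal anaphora resolution** for biomedical text, with an
emphasis on its payoff for relation extraction.

Sortal (nominal) anaphors are full noun phrases — *these drugs*, *the
disease*, *both agents* — whose head noun carries semantic-type
information constraining what they can refer back to. They are the most
frequent kind of coreference in biomedical abstracts, and leaving them
unresolved makes extracted relations generic and uninformative: from

> *There are currently 3 classes of drugs approved for the treatment of
> PAH: prostacyclin analogues, endothelin receptor antagonists, and
> phosphodiesterase type 5 inhibitors. … the current evidence supports the
> long-term use of **these drugs** for the treatment of patients with
> PAH.*

a sentence-level extractor can only produce `Drugs-TREATS-PAH`. With the
anaphor resolved to the coordinated drug classes, that one triple becomes
three informative ones (`Prostacyclin analogues-TREATS-PAH`, …).

## The method

Resolution runs in two phases over a pre-analyzed document (sentences,
tokens with lemma/number, NP chunks with heads and determiners,
appositives, coordinations, and concept mappings into a UMLS-style
knowledge base):

1. **Anaphor detection.** NPs triggered by *the; this/that/these/those;
   both/each/either/neither; such* pass five anaphoricity filters
   (appositive first-element, rigid-designator modifier / of-PP,
   cataphora, determiner–head number clash, unmapped head).
2. **Anaphor–antecedent linking.** Every NP and coordinate NP in the
   preceding discourse is a candidate. A candidate *B* is kept for anaphor
   *A* if it is **semantically consonant** — *A*'s concept is a proper
   taxonomy ancestor of *B*'s (and the pair is not anatomical meronymy),
   or *B*'s semantic group lists *A*'s headword as a generic headword, or
   the two share a headword with *B* the longer phrase — and
   **number-agreeing** (coordinations count as plural, unknown number as
   singular). No candidate ⇒ the anaphor is left unresolved (universal
   anaphors like *this study*); one candidate ⇒ link it; otherwise
   salience decides: closest same-sentence candidate, else the leftmost
   candidate of the nearest preceding sentence with any. A coordinate
   winner yields a *set-membership* link with one antecedent per conjunct.

Resolved links substitute anaphoric arguments in subject–predicate–object
predications, multiplying a predication across set-membership antecedents.
Evaluation is pairwise against brat-standoff gold under three relaxed
criteria (offset+type overlap; subsumption by a generic `SPAN` annotation;
concept-level equality), with a closest-head-match baseline and a
component-ablation harness.

## Worked example

```python
from sortanaph import build_example_corpus, resolve
from sortanaph.integrate import generate_predications, substitute_arguments

corpus = build_example_corpus()          # fixture KB + analyzed documents
kb, ex = corpus.kb, corpus["ex01"]       # the PAH abstract above
doc = ex.document

for link in resolve(doc, kb):
    print(doc.surface(link.anaphor.np.span), "->",
          [doc.surface(m.span) for m in link.antecedent_mentions])

preds = substitute_arguments(generate_predications(doc, kb), resolve(doc, kb))
for p in preds:
    print(kb.concept(p.subject_cui).preferred_name, p.predicate,
          kb.concept(p.object_cui).preferred_name)
```

prints

```
these drugs -> ['prostacyclin analogues', 'endothelin receptor antagonists', 'phosphodiesterase type 5 inhibitors']
Prostacyclin analogues TREATS Pulmonary Arterial Hypertension
Endothelin receptor antagonists TREATS Pulmonary Arterial Hypertension
Phosphodiesterase type 5 inhibitors TREATS Pulmonary Arterial Hypertension
```

i.e. the single set-membership link (3 antecedents) replaces the one
uninformative predication with three specific ones — these are the numbers
the acceptance script checks.

A command-line interface wraps the same operations:

```bash
sortanaph kb validate kb.json
sortanaph resolve --kb kb.json --in doc.json        # standoff JSON or raw text
sortanaph score --kb kb.json --gold-txt g.txt --gold-ann g.ann --doc doc.json
sortanaph ablate --synthetic 200 --seed 7
sortanaph predicate --kb kb.json --in doc.json
```

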