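"""Worked-example fixture corpus.

One fully analyzed document per worked example (motivating abstracts,
integration cases, and the documented error cases), with brat-style gold
annotations.  The analyses deliberately reproduce the *upstream* analysis
quality the narrative assumes -- e.g. a missed appositive, an erroneous or
missing coordination, an unmapped acronym -- since several documented
behaviors are downstream consequences of those analysis states.
"""

from __future__ import annotations

from dataclasses import dataclass

from ..builder import DocumentBuilder
from ..docmodel import Document
from ..evaluate import GoldEntity, GoldRelation
from ..knowledge import KnowledgeBase, UNKNOWN
from .kb import build_fixture_kb

PSU = "Pharmacologic Substance"


@dataclass
class ExampleDoc:
    name: str
    document: Document
    entities: list[GoldEntity]
    relations: list[GoldRelation]


@dataclass
class ExampleCorpus:
    kb: KnowledgeBase
    docs: dict[str, ExampleDoc]

    def corpus_items(self):
        return [(d.document, d.relations) for d in self.docs.values()]

    def __getitem__(self, name: str) -> ExampleDoc:
        return self.docs[name]


def _finish(b: DocumentBuilder, name: str) -> ExampleDoc:
    return ExampleDoc(name=name, document=b.build(),
                      entities=b.entities, relations=b.relations)


def _ex01_pah(kb: KnowledgeBase) -> ExampleDoc:
    """Abstract fragments: plural demonstrative anaphor over a coordinated
    series of drug classes; the uninformative Drugs-TREATS-PAH predication
    becomes three informative ones after substitution."""
    b = DocumentBuilder("21349396", kb)
    s = b.sentence()
    s.np("Pulmonary", "arterial", "hypertension")
    s.punct("(")
    s.np("PAH")
    s.punct(")")
    s.word("is", pos="VERB")
    s.np("a", "rare", "and", "progressive", "disease", det=0, head=4, of_pp=True)
    s.word("of")
    s.np("the", "pulmonary", "arterial", "circulation", det=0, head=3, head_cuis=[])
    s.punct(".")

    s = b.sentence()
    s.word("There")
    s.word("are", pos="VERB")
    s.word("currently")
    s.np("3", "classes", head=1, head_cuis=[], of_pp=True)
    s.word("of")
    s.word("drugs", pos="NOUN", lemma="drug")
    s.word("approved")
    s.word("for")
    s.np("the", "treatment", det=0, of_pp=True)
    s.word("of")
    s.np("PAH")
    s.punct(":")
    np_prost = s.np("prostacyclin", "analogues")
    s.punct(",")
    np_era = s.np("endothelin", "receptor", "antagonists")
    s.punct(",")
    s.word("and", pos="CONJ")
    np_pde = s.np("phosphodiesterase", "type", "5", "inhibitors", head=3)
    s.punct(".")
    s.coord(np_prost, np_era, np_pde)

    s = b.sentence()
    s.word("Although")
    s.word("definitive")
    s.word("evidence")
    s.word("will")
    s.word("require", pos="VERB")
    for w in ("randomized", "and", "properly", "controlled", "long-term", "trials"):
        s.word(w)
    s.punct(",")
    s.np("the", "current", "evidence", det=0, head=2, head_cuis=[])
    s.word("supports", pos="VERB", lemma="support")
    s.np("the", "long-term", "use", det=0, head=2, head_cuis=[], of_pp=True)
    s.word("of")
    np_these = s.np("these", "drugs", det=0)
    s.word("for")
    s.np("the", "treatment", det=0, of_pp=True)
    s.word("of")
    s.np("patients")
    s.word("with")
    s.np("PAH")
    s.punct(".")

    sortal = b.entity(np_these, "Sortal")
    for ant in (np_prost, np_era, np_pde):
        b.coref(sortal, b.entity(ant, PSU))
    return _finish(b, "ex01")


def _ex02_amantadine(kb: KnowledgeBase) -> ExampleDoc:
    """Appositive ISA plus a lexically indicated TREATS over a coordinated
    object; the appositive's generic member is correctly non-anaphoric."""
    b = DocumentBuilder("ex02", kb)
    s = b.sentence()
    np_agent = s.np("The", "antiviral", "agent", det=0)
    s.punct(",")
    np_am = s.np("amantadine")
    s.punct(",")
    for w in ("has", "been", "used", "to"):
        s.word(w)
    s.word("manage", pos="VERB", lemma="manage")
    np_pd = s.np("Parkinson", "disease")
    s.word("or", pos="CONJ")
    np_dysk = s.np("levodopa-induced", "dyskinesias")
    for w in ("for", "nearly", "5", "decades"):
        s.word(w)
    s.punct(".")
    s.appos(np_agent, np_am)
    s.coord(np_pd, np_dysk)
    return _finish(b, "ex02")


def _ex03_dog(kb: KnowledgeBase) -> ExampleDoc:
    """Gold antecedent is an unmapped full phrase annotated with the
    generic SPAN type; span subsumption is what licenses the match."""
    b = DocumentBuilder("ex03", kb)
    s = b.sentence()
    np_full = s.np("An", "adult", "male", "bullmastiff", "dog", det=0, head=4)
    s.word("was", pos="VERB")
    s.word("treated", pos="VERB", lemma="treat")
    s.word("for")
    s.np("paraparesis", head_cuis=[])
    s.word("and", pos="CONJ")
    s.np("ataxia", head_cuis=[])
    s.word("due")
    s.word("to")
    s.np("discospondylitis", head_cuis=[])
    s.word("and", pos="CONJ")
    s.np("disc", "herniation", head_cuis=[])
    s.punct(".")

    s = b.sentence()
    s.word("At")
    s.np("this", "time", det=0, head_cuis=[])
    s.punct(",")
    np_dog = s.np("the", "dog", det=0)
    s.word("had", pos="VERB")
    s.np("a", "nonhealing", "ulcer", det=0, head=2, head_cuis=[])
    s.word("between")
    s.np("the", "pads", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("the", "left", "hindfoot", det=0, head=2, head_cuis=[])
    s.punct(".")

    b.coref(b.entity(np_dog, "Sortal"), b.entity(np_full, "SPAN"))
    return _finish(b, "ex03")


def _ex04_bronchodilators(kb: KnowledgeBase) -> ExampleDoc:
    """Two set-membership anaphors over the same drug pair; the gold
    antecedents for 'both drugs' are later mentions, so only the
    concept-level criterion can credit the coordinate-NP link."""
    b = DocumentBuilder("ex04", kb)
    s = b.sentence()
    s.np("A", "radioaerosol", "technique", det=0, head=2, head_cuis=[])
    for w in ("was", "used", "to", "assess"):
        s.word(w)
    s.np("the", "effects", det=0, head_cuis=[])
    s.word("on")
    s.np("mucus", "clearance", head_cuis=[], of_pp=True)
    s.word("of")
    s.np("14", "days", "treatment", head=2, head_cuis=[])
    s.word("with")
    np_form0 = s.np("formoterol")
    s.word("or", pos="CONJ")
    np_tio0 = s.np("tiotropium")
    s.punct(",")
    for w in ("as", "well", "as"):
        s.word(w)
    s.np("single", "doses", head_cuis=[], of_pp=True)
    s.word("of")
    np_these = s.np("these", "drugs", det=0)
    s.punct(".")
    s.coord(np_form0, np_tio0)

    s = b.sentence()
    s.word("RESULTS")
    s.punct(":")
    s.np("The", "4", "h", "whole", "lung", "retention", det=0, head=5,
         head_cuis=[], of_pp=True)
    s.word("of")
    s.np("radioaerosol", head_cuis=[])
    for w in ("was", "significantly", "higher", "after"):
        s.word(w)
    s.np("14", "days", "treatment", head=2, head_cuis=[])
    s.word("with")
    np_tio1 = s.np("tiotropium")
    s.punct("(")
    s.word("P")
    s.word("=")
    s.word("0.016")
    s.punct(")")
    s.punct(",")
    for w in ("but", "not", "after"):
        s.word(w)
    s.np("14", "days", "treatment", head=2, head_cuis=[])
    s.word("with")
    np_form1 = s.np("formoterol")
    s.punct(".")

    s = b.sentence()
    s.word("However")
    s.punct(",")
    s.np("patients")
    s.word("bronchodilated", pos="VERB")
    s.word("after")
    s.np("14", "days", "treatment", head=2, head_cuis=[])
    s.word("with")
    np_both = s.np("both", "drugs", det=0)
    s.punct(",")
    s.word("so")
    s.word("that")
    s.np("the", "deposited", "radioaerosol", det=0, head=2, head_cuis=[])
    for w in ("may", "have", "had"):
        s.word(w)
    s.np("an", "increased", "distance", det=0, head=2, head_cuis=[])
    for w in ("to", "travel", "in", "order", "to", "be", "cleared", "by"):
        s.word(w)
    s.np("mucociliary", "action", head_cuis=[])
    s.punct(".")

    sortal1 = b.entity(np_these, "Sortal")
    b.coref(sortal1, b.entity(np_form0, PSU))
    b.coref(sortal1, b.entity(np_tio0, PSU))
    sortal2 = b.entity(np_both, "Sortal")
    b.coref(sortal2, b.entity(np_tio1, PSU))
    b.coref(sortal2, b.entity(np_form1, PSU))
    return _finish(b, "ex04")


def _ex05_glycoproteins(kb: KnowledgeBase) -> ExampleDoc:
    """A correctly resolved taxonomic link (proteins > acidic
    glycoproteins)."""
    b = DocumentBuilder("ex05", kb)
    s = b.sentence()
    s.np("The", "cyst", "fluids", det=0, head=2, head_cuis=[])
    for w in ("were", "shown", "to", "be"):
        s.word(w)
    s.np("a", "rich", "source", det=0, head=2, head_cuis=[])
    s.word("for")
    np_gly = s.np("acidic", "glycoproteins")
    s.punct(".")

    s = b.sentence()
    s.np("The", "study", det=0, of_pp=True)
    s.word("of")
    np_tp = s.np("these", "proteins", det=0)
    s.word("can")
    s.word("potentially")
    s.word("lead", pos="VERB")
    s.word("to")
    s.np("the", "identification", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("more", "effective", "biomarkers", head=2, head_cuis=[])
    s.word("for")
    s.np("ovarian", "cancer")
    s.punct(".")

    b.coref(b.entity(np_tp, "Sortal"),
            b.entity(np_gly, "Amino Acid, Peptide, or Protein"))
    return _finish(b, "ex05")


def _ex06_nash(kb: KnowledgeBase) -> ExampleDoc:
    """An unmapped acronym (NASH) hides the true antecedent; the resolver
    links 'the disease' to 'inflammation' instead, turning a correct but
    uninformative PREVENTS predication into an incorrect one."""
    b = DocumentBuilder("ex06", kb)
    s = b.sentence()
    np_nash = s.np("NASH", head_cuis=[])
    s.word("is", pos="VERB")
    s.np("a", "distinct", "entity", det=0, head=2, head_cuis=[])
    s.word("from")
    s.np("NAFLD", head_cuis=[])
    s.punct(",")
    for w in ("and", "is", "characterized", "by"):
        s.word(w)
    s.np("the", "presence", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("inflammation")
    s.word("with")
    s.np("hepatocytes", "damage", head_cuis=[])
    s.punct(",")
    for w in ("with", "or", "without"):
        s.word(w)
    s.np("fibrosis")
    s.punct(".")

    s = b.sentence()
    s.word("While")
    s.np("several", "therapeutic", "strategies", head=2, head_cuis=[])
    for w in ("have", "been", "proposed"):
        s.word(w)
    s.punct(",")
    s.np("the", "present", "review", det=0, head=2, head_cuis=[])
    for w in ("aims", "to", "discuss"):
        s.word(w)
    s.np("nonmedicinal", "interventions")
    for w in ("used", "to", "reduce"):
        s.word(w)
    s.np("liver", "involvement", head_cuis=[])
    s.word("or")
    s.word("to")
    s.word("prevent", pos="VERB", lemma="prevent")
    np_dis = s.np("the", "disease", det=0)
    s.word("altogether")
    s.punct(".")

    b.coref(b.entity(np_dis, "Sortal"), b.entity(np_nash, "SPAN"))
    return _finish(b, "ex06")


def _ex07_genes(kb: KnowledgeBase) -> ExampleDoc:
    """Salience picks the wrong (closer) gene coordination; a single
    set-membership link multiplies one PART_OF predication into four."""
    b = DocumentBuilder("ex07", kb)
    s = b.sentence()
    s.word("Meanwhile")
    s.punct(",")
    s.np("three", "genes", head=1)
    s.punct("(")
    np_api = s.np("API5")
    s.punct(",")
    np_aif = s.np("AIFM1")
    s.punct(",")
    s.word("and", pos="CONJ")
    np_nf = s.np("NFkappaB1")
    s.punct(")")
    s.word("showed", pos="VERB", lemma="show")
    s.np("changes", head_cuis=[], of_pp=True)
    s.word("of")
    s.np("expression", head_cuis=[])
    s.word("in")
    s.np("the", "hippocampus", det=0, of_pp=True)
    s.word("of")
    s.np("Ts65Dn", "mice", head_cuis=[])
    s.word("compared")
    s.word("with")
    s.np("normal", "mice", head_cuis=[])
    s.punct(".")
    s.coord(np_api, np_aif, np_nf)

    s = b.sentence()
    s.word("However")
    s.punct(",")
    s.np("some", "well-known", "genes", head=2)
    s.word("related")
    s.word("to")
    s.np("cell", "apoptosis", head_cuis=[])
    s.punct(",")
    s.word("such")
    s.word("as")
    s.np("the", "caspase", "family", det=0, head=2, head_cuis=[])
    s.punct(",")
    s.np("Bcl-2")
    s.punct(",")
    np_bad = s.np("Bad")
    s.punct(",")
    np_bid = s.np("Bid")
    s.punct(",")
    np_fas = s.np("Fas")
    s.punct(",")
    s.word("and", pos="CONJ")
    np_tnf = s.np("TNF")
    s.punct(",")
    s.word("did")
    s.word("not")
    s.word("show", pos="VERB", lemma="show")
    s.np("changes", head_cuis=[])
    s.word("in")
    s.np("expression", "levels", head_cuis=[])
    s.punct(".")
    s.coord(np_bad, np_bid, np_fas, np_tnf)

    s = b.sentence()
    np_genes = s.np("The", "genes", det=0)
    s.word("we")
    s.word("found", pos="VERB")
    for w in ("which", "were", "differentially"):
        s.word(w)
    s.word("expressed", pos="VERB", lemma="express")
    s.word("in")
    s.np("the", "hippocampus", det=0, of_pp=True)
    s.word("of")
    s.np("Ts65Dn", "mice", head_cuis=[])
    for w in ("may", "be", "closely", "related", "to"):
        s.word(w)
    s.np("cell", "apoptosis", head_cuis=[])
    s.punct(".")

    sortal = b.entity(np_genes, "Sortal")
    for ant in (np_api, np_aif, np_nf):
        b.coref(sortal, b.entity(ant, "Gene or Genome"))
    return _finish(b, "ex07")


def _ex08_rigid(kb: KnowledgeBase) -> ExampleDoc:
    """A legitimate anaphor lost to rigid-designator filtering: the PAH
    modifier maps to a concept on its own."""
    b = DocumentBuilder("ex08", kb)
    s = b.sentence()
    s.word("Therefore")
    s.punct(",")
    s.np("data", head_cuis=[])
    s.word("that")
    s.word("support", pos="VERB", lemma="support")
    s.np("the", "long-term", "therapeutic", "benefits", det=0, head=3,
         head_cuis=[], of_pp=True)
    s.word("of")
    s.np("these", "long-term", "PAH", "therapies", det=0, head=3)
    for w in ("are", "limited", "and", "derived", "primarily", "from"):
        s.word(w)
    s.np("uncontrolled", "observational", "studies", head=2, head_cuis=[])
    s.punct(".")
    return _finish(b, "ex08")


def _ex09_revatio(kb: KnowledgeBase) -> ExampleDoc:
    """A missed appositive lets a non-anaphoric NP through detection; the
    closest-candidate rule then links it to Revatio (precision error)."""
    b = DocumentBuilder("ex09", kb)
    s = b.sentence()
    s.np("This", "paper", det=0, head_cuis=[])
    s.word("provides", pos="VERB")
    s.np("an", "overview", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("clinically", "available", "phosphodiesterase", "inhibitors",
         head=3, head_cuis=["C_pdei"])
    s.word("and")
    s.word("discusses", pos="VERB")
    s.np("tadalafil")
    s.word("in")
    s.np("relationship", head_cuis=[])
    s.word("to")
    s.np("sildenafil")
    s.punct("(")
    s.np("Revatio")
    s.punct(")")
    s.punct(",")
    s.np("the", "first", "phosphodiesterase", "inhibitor", det=0, head=3,
         head_cuis=["C_pdei"])
    s.word("approved")
    s.word("for")
    s.np("PAH")
    s.punct(".")
    return _finish(b, "ex09")


def _ex10_coordination_miss(kb: KnowledgeBase) -> ExampleDoc:
    """The coordination is absent from the analysis (one conjunct was
    unmappable), so a plural anaphor finds no number-agreeing candidate:
    three recall errors."""
    b = DocumentBuilder("ex10", kb)
    s = b.sentence()
    s.np("Progressive", "focal", "glomerulosclerosis", head=2,
         head_cuis=["C_glomerulosclerosis"])
    s.word("in")
    s.np("the", "Imai", "rats", det=0, head=2, head_cuis=[])
    for w in ("is", "associated", "with"):
        s.word(w)
    np_ox = s.np("oxidative", "stress")
    s.punct(",")
    np_inf = s.np("inflammation")
    s.punct(",")
    s.word("and", pos="CONJ")
    np_nrf = s.np("impaired", "Nrf2", "activation", head=2, head_cuis=[])
    s.punct(".")
    # no coordination recorded: reproduces the upstream processing miss

    s = b.sentence()
    np_ab = s.np("These", "abnormalities", det=0)
    for w in ("are", "accompanied", "by"):
        s.word(w)
    s.np("activation", head_cuis=[], of_pp=True)
    s.word("of")
    s.np("NF-kB", head_cuis=[])
    s.punct(".")

    sortal = b.entity(np_ab, "Sortal")
    b.coref(sortal, b.entity(np_ox, "Pathologic Function"))
    b.coref(sortal, b.entity(np_inf, "Pathologic Function"))
    b.coref(sortal, b.entity(np_nrf, "SPAN"))
    return _finish(b, "ex10")


def _ex11_both(kb: KnowledgeBase) -> ExampleDoc:
    """An over-wide (erroneous) coordination yields three antecedents for a
    'both'-anaphor instead of the two correct ones."""
    b = DocumentBuilder("ex11", kb)
    s = b.sentence()
    s.word("After")
    s.np("fasting", "glucose", head_cuis=[])
    for w in ("was", "optimized", "by"):
        s.word(w)
    np_ig = s.np("insulin", "glargine")
    s.punct(",")
    np_nat = s.np("nateglinide")
    s.word("or", pos="CONJ")
    np_ac = s.np("acarbose")
    for w in ("was", "initiated", "and", "then", "crossed", "over", "after"):
        s.word(w)
    s.np("second", "wash", "out", "period", head=3, head_cuis=[])
    s.punct(".")
    s.coord(np_ig, np_nat, np_ac)

    s = b.sentence()
    np_both = s.np("Both", "drugs", det=0)
    s.word("improved", pos="VERB")
    s.np("glycemic", "control", head_cuis=[])
    s.punct(".")

    sortal = b.entity(np_both, "Sortal")
    b.coref(sortal, b.entity(np_nat, PSU))
    b.coref(sortal, b.entity(np_ac, PSU))
    return _finish(b, "ex11")


def _ex12_serial(kb: KnowledgeBase) -> ExampleDoc:
    """Serial coordination defeated by intervening percentages: no
    coordination in the analysis, seven recall errors."""
    b = DocumentBuilder("ex12", kb)
    s = b.sentence()
    s.np("The", "percentage", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("patients")
    s.word("discontinued", pos="VERB")
    s.np("treatment", head_cuis=[])
    s.word("within")
    s.np("12", "months", head=1, head_cuis=[])
    s.word("was", pos="VERB")
    drugs = []
    rates = ["41.4", "39.5", "36.7", "40.2", "39.6", "46.9", "40.2"]
    names = ["chlorpromazine", "sulpiride", "clozapine", "risperidone",
             "olanzapine", "quetiapine", "aripiprazole"]
    for i, (rate, name) in enumerate(zip(rates, names)):
        if i > 0:
            s.punct(",")
            if i == len(names) - 1:
                s.word("and", pos="CONJ")
        s.word(rate)
        s.punct("%")
        s.word("for")
        drugs.append(s.np(name))
    s.punct(",")
    s.np("a", "nonsignificant", "difference", det=0, head=2, head_cuis=[])
    s.punct(".")
    # no coordination recorded

    s = b.sentence()
    for w in ("There", "were", "no"):
        s.word(w)
    s.np("significant", "differences", head_cuis=[])
    s.word("among")
    np_t = s.np("these", "seven", "treatments", det=0, head=2)
    s.word("on")
    s.np("discontinuation", head_cuis=[])
    s.word("due")
    s.word("to")
    s.np("relapse", head_cuis=[])
    s.punct(".")

    sortal = b.entity(np_t, "Sortal")
    for d in drugs:
        b.coref(sortal, b.entity(d, PSU))
    return _finish(b, "ex12")


def _ex13_regimen(kb: KnowledgeBase) -> ExampleDoc:
    """Semantic-consonance miss: no taxonomy link and no shared headword
    between 'the chemotherapy regimen' and 'adjuvant chemotherapy'."""
    b = DocumentBuilder("ex13", kb)
    s = b.sentence()
    for w in ("From", "January", "1993", "to", "March", "1998"):
        s.word(w)
    s.punct(",")
    s.np("268", "patients", head=1)
    for w in ("were", "randomized", "to"):
        s.word(w)
    np_ac = s.np("adjuvant", "chemotherapy")
    s.punct("(")
    s.np("135", "patients", head=1)
    s.punct(")")
    s.word("or")
    s.np("surgery")
    s.word("alone")
    s.punct("(")
    s.np("133", "patients", head=1)
    s.punct(")")
    s.punct(".")

    s = b.sentence()
    s.word("All")
    s.np("patients")
    s.word("underwent", pos="VERB")
    s.np("gastrectomy")
    s.word("with")
    s.np("D2", "lymph", "node", "dissection", head=3, head_cuis=[])
    s.punct(".")

    s = b.sentence()
    np_reg = s.np("The", "chemotherapy", "regimen", det=0, head=2,
                  flags={1: False})
    s.word("consisted", pos="VERB")
    s.word("of")
    s.np("fluorouracil")
    s.punct(".")

    b.coref(b.entity(np_reg, "Sortal"),
            b.entity(np_ac, "Therapeutic or Preventive Procedure"))
    return _finish(b, "ex13")


def _ex14_neuroleptics(kb: KnowledgeBase) -> ExampleDoc:
    """Number disagreement blocks the taxonomically licensed link between
    'the drug' (singular) and 'neuroleptics' (plural): a recall error."""
    b = DocumentBuilder("ex14", kb)
    s = b.sentence()
    np_st = s.np("Stereotypies")
    s.word("and", pos="CONJ")
    np_od = s.np("orobuccolingual", "dyskinesias")
    s.word("are", pos="VERB")
    s.np("the", "most", "frequently", "observed", "tardive", "disorders",
         det=0, head=5, head_cuis=["C_tardive_disorders"])
    s.punct(",")
    s.word("particularly")
    s.word("in")
    s.np("the", "elderly", "population", det=0, head=2, head_cuis=[])
    s.word("exposed")
    s.word("to")
    np_neu = s.np("neuroleptics")
    s.punct(".")
    s.coord(np_st, np_od)

    s = b.sentence()
    s.np("The", "development", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    np_disord = s.np("these", "disorders", det=0)
    for w in ("is", "dependent", "on"):
        s.word(w)
    s.np("the", "potency", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    np_drug = s.np("the", "drug", det=0)
    s.punct(",")
    s.np("duration", head_cuis=[], of_pp=True)
    s.word("of")
    s.np("exposure", head_cuis=[])
    s.punct(",")
    s.word("and")
    s.np("individual", "susceptibility", head_cuis=[])
    s.punct(".")

    sortal1 = b.entity(np_disord, "Sortal")
    b.coref(sortal1, b.entity(np_st, "Mental or Behavioral Dysfunction"))
    b.coref(sortal1, b.entity(np_od, "Mental or Behavioral Dysfunction"))
    b.coref(b.entity(np_drug, "Sortal"), b.entity(np_neu, PSU))
    return _finish(b, "ex14")


def _ex15_nocardia(kb: KnowledgeBase) -> ExampleDoc:
    """Leftmost-candidate salience picks 'Nocardia species' over the more
    specific 'Nocardia beijingensis': a precision and a recall error."""
    b = DocumentBuilder("ex15", kb)
    s = b.sentence()
    s.word("We")
    s.word("report", pos="VERB")
    s.np("a", "case", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("pulmonary", "infection")
    s.word("caused")
    s.word("by")
    np_ns = s.np("a", "rare", "Nocardia", "species", det=0, head=3,
                 head_cuis=["C_nocardia"], number=UNKNOWN)
    s.punct(",")
    np_nb = s.np("Nocardia", "beijingensis")
    s.punct(",")
    s.word("in")
    s.np("a", "48-year-old", "man", det=0, head=2, head_cuis=[])
    s.word("who")
    s.word("received", pos="VERB")
    s.np("multiple", "immunosuppressive", "therapy", head=2, head_cuis=[])
    s.word("after")
    s.np("renal", "transplantation", head_cuis=[])
    s.punct(".")
    s.appos(np_ns, np_nb)

    s = b.sentence()
    np_path = s.np("This", "pathogen", det=0)
    for w in ("was", "isolated", "from"):
        s.word(w)
    s.np("a", "bronchoscopic", "protected", "specimen", "brush", det=0,
         head=4, head_cuis=[])
    s.punct(".")

    b.coref(b.entity(np_path, "Sortal"), b.entity(np_nb, "Bacterium"))
    return _finish(b, "ex15")


def _ex16_exemplification(kb: KnowledgeBase) -> ExampleDoc:
    """Exemplification: the resolver links 'these drugs' to the example
    drugs rather than the annotated class mention (soft precision errors);
    'this study' terminates unresolved (universal anaphor)."""
    b = DocumentBuilder("ex16", kb)
    s = b.sentence()
    s.word("Among")
    s.np("the", "substances", det=0, head_cuis=[])
    for w in ("which", "are", "commonly", "used", "are"):
        s.word(w)
    np_icm = s.np("ion", "channel", "modulators", head=2)
    s.punct("(")
    s.word("e.g.")
    np_pre = s.np("pregabalin")
    s.punct(",")
    np_gab = s.np("gabapentin")
    s.punct(",")
    np_car = s.np("carbamazepine")
    s.punct(")")
    s.punct(".")
    s.coord(np_pre, np_gab, np_car)

    s = b.sentence()
    s.np("The", "aim", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    s.np("this", "study", det=0)
    for w in ("was", "to", "investigate"):
        s.word(w)
    s.np("the", "use", det=0, head_cuis=[], of_pp=True)
    s.word("of")
    np_td = s.np("these", "drugs", det=0)
    s.word("in")
    s.np("clinical", "practice", head_cuis=[])
    s.word("in")
    s.np("a", "larger", "patient", "cohort", det=0, head=3, head_cuis=[])
    s.punct(".")

    b.coref(b.entity(np_td, "Sortal"), b.entity(np_icm, PSU))
    return _finish(b, "ex16")


_BUILDERS = [
    _ex01_pah, _ex02_amantadine, _ex03_dog, _ex04_bronchodilators,
    _ex05_glycoproteins, _ex06_nash, _ex07_genes, _ex08_rigid,
    _ex09_revatio, _ex10_coordination_miss, _ex11_both, _ex12_serial,
    _ex13_regimen, _ex14_neuroleptics, _ex15_nocardia, _ex16_exemplification,
]


def build_example_corpus() -> ExampleCorpus:
    """Deterministic fixture corpus: one document per worked example."""
    kb = build_fixture_kb()
    docs = {}
    for fn in _BUILDERS:
        doc = fn(kb)
        docs[doc.name] = doc
    return ExampleCorpus(kb=kb, docs=docs)
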