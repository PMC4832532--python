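"""Bundled fixture knowledge base.

A hand-built terminology slice sufficient for the worked-example corpus:
drug classes and members, disorders, procedures, genes, anatomy, and
organisms, with the taxonomy edges, group headwords and lexicon entries
the examples rely on.  Deliberate *gaps* (missing concepts such as NASH,
missing edges such as drugs -> ion channel modulators) mirror the
terminology shortfalls that drive several documented failure modes.
"""

from __future__ import annotations

from ..knowledge import Concept, KnowledgeBase, PLURAL, SINGULAR, UNKNOWN

# (cui, preferred name, semantic types, semantic group)
_CONCEPTS = [
    # chemicals & drugs
    ("C_drugs", "Drugs", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_pharm_prep", "Pharmaceutical Preparations", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_cetirizine", "Cetirizine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_prostacyclin_analogues", "Prostacyclin analogues", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_era", "Endothelin receptor antagonists", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_pde5i", "Phosphodiesterase type 5 inhibitors", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_pdei", "Phosphodiesterase Inhibitors", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_sildenafil", "Sildenafil", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_tadalafil", "Tadalafil", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_revatio", "Revatio", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_amantadine", "Amantadine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_antiviral_agents", "Antiviral Agents", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_formoterol", "Formoterol", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_tiotropium", "Tiotropium", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_neuroleptics", "Neuroleptic Agents", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_insulin_glargine", "Insulin Glargine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_nateglinide", "Nateglinide", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_acarbose", "Acarbose", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_pregabalin", "Pregabalin", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_gabapentin", "Gabapentin", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_carbamazepine", "Carbamazepine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_chlorpromazine", "Chlorpromazine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_sulpiride", "Sulpiride", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_clozapine", "Clozapine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_risperidone", "Risperidone", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_olanzapine", "Olanzapine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_quetiapine", "Quetiapine", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_aripiprazole", "Aripiprazole", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_icm", "Ion Channel Modulators", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_fluorouracil", "Fluorouracil", ["Pharmacologic Substance"], "Chemicals & Drugs"),
    ("C_proteins", "Proteins", ["Amino Acid, Peptide, or Protein"], "Chemicals & Drugs"),
    ("C_acidic_glycoproteins", "Acidic Glycoproteins", ["Amino Acid, Peptide, or Protein"], "Chemicals & Drugs"),
    # disorders
    ("C_pah", "Pulmonary Arterial Hypertension", ["Disease or Syndrome"], "Disorder"),
    ("C_disease", "Disease", ["Disease or Syndrome"], "Disorder"),
    ("C_inflammation", "Inflammation", ["Pathologic Function"], "Disorder"),
    ("C_fibrosis", "Fibrosis", ["Pathologic Function"], "Disorder"),
    ("C_iris", "Immune reconstitution inflammatory syndrome", ["Disease or Syndrome"], "Disorder"),
    ("C_illness", "Illness", ["Disease or Syndrome"], "Disorder"),
    ("C_reaction", "Reaction", ["Pathologic Function"], "Disorder"),
    ("C_anaphylactoid_reaction", "Anaphylactoid reaction", ["Pathologic Function"], "Disorder"),
    ("C_parkinson", "Parkinson Disease", ["Disease or Syndrome"], "Disorder"),
    ("C_dyskinesias", "Levodopa-induced dyskinesias", ["Disease or Syndrome"], "Disorder"),
    ("C_oxidative_stress", "Oxidative Stress", ["Pathologic Function"], "Disorder"),
    ("C_abnormality", "Abnormality", ["Anatomical Abnormality"], "Disorder"),
    ("C_glomerulosclerosis", "Focal glomerulosclerosis", ["Disease or Syndrome"], "Disorder"),
    ("C_disorder", "Disorder", ["Disease or Syndrome"], "Disorder"),
    ("C_tardive_disorders", "Tardive disorders", ["Mental or Behavioral Dysfunction"], "Disorder"),
    ("C_stereotypies", "Stereotypies", ["Mental or Behavioral Dysfunction"], "Disorder"),
    ("C_orobuccolingual_dyskinesias", "Orobuccolingual dyskinesias", ["Mental or Behavioral Dysfunction"], "Disorder"),
    ("C_ovarian_cancer", "Ovarian Carcinoma", ["Neoplastic Process"], "Disorder"),
    ("C_pulmonary_infection", "Pulmonary infection", ["Disease or Syndrome"], "Disorder"),
    # procedures / therapeutic modality
    ("C_treatment", "Treatment", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_therapy", "Therapy", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_adjuvant_chemo", "Adjuvant chemotherapy", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_chemo_regimen", "Chemotherapy Regimen", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_surgery", "Surgery", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_gastrectomy", "Gastrectomy", ["Therapeutic or Preventive Procedure"], "Procedures"),
    ("C_interventions", "Interventions", ["Therapeutic or Preventive Procedure"], "Therapeutic Modality"),
    # living beings
    ("C_patients", "Patients", ["Patient or Disabled Group"], "Living Beings"),
    ("C_dog", "Canis familiaris", ["Mammal"], "Living Beings"),
    ("C_pathogen", "Pathogenic organism", ["Organism"], "Living Beings"),
    ("C_nocardia", "Nocardia", ["Bacterium"], "Living Beings"),
    ("C_nocardia_beijingensis", "Nocardia beijingensis", ["Bacterium"], "Living Beings"),
    # genes
    ("C_genes", "Genes", ["Gene or Genome"], "Genes"),
    ("C_bad", "BAD gene", ["Gene or Genome"], "Genes"),
    ("C_bid", "BID gene", ["Gene or Genome"], "Genes"),
    ("C_fas", "FAS gene", ["Gene or Genome"], "Genes"),
    ("C_tnf", "TNF gene", ["Gene or Genome"], "Genes"),
    ("C_api5", "API5 gene", ["Gene or Genome"], "Genes"),
    ("C_aifm1", "AIFM1 gene", ["Gene or Genome"], "Genes"),
    ("C_nfkb1", "NFKB1 gene", ["Gene or Genome"], "Genes"),
    ("C_bcl2", "BCL2 gene", ["Gene or Genome"], "Genes"),
    ("C_brca1", "BRCA1 gene", ["Gene or Genome"], "Genes"),
    # anatomy
    ("C_hippocampus", "Entire hippocampus", ["Body Part, Organ, or Organ Component"], "Anatomy"),
    ("C_heart", "Heart", ["Body Part, Organ, or Organ Component"], "Anatomy"),
    ("C_right_ventricle", "Right ventricular structure", ["Body Part, Organ, or Organ Component"], "Anatomy"),
    ("C_t_lymphocyte", "T-Lymphocyte", ["Cell"], "Anatomy"),
    ("C_b_lymphocyte", "B-Lymphocyte", ["Cell"], "Anatomy"),
    # concept group (excluded from consonance by rule)
    ("C_study", "Study", ["Intellectual Product"], "Concept"),
]

_EDGES = [
    ("C_drugs", "C_pharm_prep"),
    ("C_pharm_prep", "C_cetirizine"),
    ("C_pharm_prep", "C_neuroleptics"),
    ("C_drugs", "C_prostacyclin_analogues"),
    ("C_drugs", "C_era"),
    ("C_drugs", "C_pde5i"),
    ("C_drugs", "C_pdei"),
    ("C_pdei", "C_sildenafil"),
    ("C_pdei", "C_tadalafil"),
    ("C_pdei", "C_revatio"),
    ("C_drugs", "C_antiviral_agents"),
    ("C_antiviral_agents", "C_amantadine"),
    ("C_drugs", "C_formoterol"),
    ("C_drugs", "C_tiotropium"),
    ("C_drugs", "C_insulin_glargine"),
    ("C_drugs", "C_nateglinide"),
    ("C_drugs", "C_acarbose"),
    ("C_drugs", "C_pregabalin"),
    ("C_drugs", "C_gabapentin"),
    ("C_drugs", "C_carbamazepine"),
    ("C_drugs", "C_chlorpromazine"),
    ("C_drugs", "C_sulpiride"),
    ("C_drugs", "C_clozapine"),
    ("C_drugs", "C_risperidone"),
    ("C_drugs", "C_olanzapine"),
    ("C_drugs", "C_quetiapine"),
    ("C_drugs", "C_aripiprazole"),
    # note: no edge drugs -> ion channel modulators (drives an
    # exemplification-linking failure mode)
    ("C_proteins", "C_acidic_glycoproteins"),
    ("C_disease", "C_inflammation"),
    ("C_disease", "C_pah"),
    ("C_disorder", "C_stereotypies"),
    ("C_disorder", "C_orobuccolingual_dyskinesias"),
    ("C_genes", "C_bad"),
    ("C_genes", "C_bid"),
    ("C_genes", "C_fas"),
    ("C_genes", "C_tnf"),
    ("C_genes", "C_api5"),
    ("C_genes", "C_aifm1"),
    ("C_genes", "C_nfkb1"),
    ("C_genes", "C_brca1"),
    # an ancestry edge that is meronymic, not taxonomic
    ("C_heart", "C_right_ventricle"),
    ("C_pathogen", "C_nocardia"),
    ("C_nocardia", "C_nocardia_beijingensis"),
]

_GROUP_HEADWORDS = {
    "Disorder": {"condition", "ailment", "abnormality", "problem", "illness"},
    "Therapeutic Modality": {"medication", "intervention", "agent"},
}

# surface -> (cui, number); preferred names are also entered automatically
_EXTRA_LEXICON = [
    ("drugs", "C_drugs", PLURAL),
    ("drug", "C_pharm_prep", SINGULAR),
    ("antiviral agent", "C_antiviral_agents", SINGULAR),
    ("pah", "C_pah", SINGULAR),
    ("patient", "C_patients", SINGULAR),
    ("dog", "C_dog", SINGULAR),
    ("glycoproteins", "C_acidic_glycoproteins", PLURAL),
    ("intervention", "C_interventions", SINGULAR),
    ("gene", "C_genes", SINGULAR),
    ("genes", "C_genes", PLURAL),
    ("bad", "C_bad", SINGULAR),
    ("bid", "C_bid", SINGULAR),
    ("fas", "C_fas", SINGULAR),
    ("tnf", "C_tnf", SINGULAR),
    ("api5", "C_api5", SINGULAR),
    ("aifm1", "C_aifm1", SINGULAR),
    ("nfkappab1", "C_nfkb1", SINGULAR),
    ("bcl-2", "C_bcl2", SINGULAR),
    ("brca1", "C_brca1", SINGULAR),
    ("hippocampus", "C_hippocampus", SINGULAR),
    ("therapy", "C_therapy", SINGULAR),
    ("therapies", "C_therapy", PLURAL),
    ("neuroleptics", "C_neuroleptics", PLURAL),
    ("stereotypies", "C_stereotypies", PLURAL),
    ("disorders", "C_disorder", PLURAL),
    ("regimen", "C_chemo_regimen", SINGULAR),
    ("nocardia", "C_nocardia", SINGULAR),
    ("nocardia species", "C_nocardia", UNKNOWN),
    ("pathogen", "C_pathogen", SINGULAR),
    ("heart", "C_heart", SINGULAR),
    ("right ventricle", "C_right_ventricle", SINGULAR),
    ("t-lymphocyte", "C_t_lymphocyte", SINGULAR),
    ("b-lymphocyte", "C_b_lymphocyte", SINGULAR),
    ("study", "C_study", SINGULAR),
    ("parkinson disease", "C_parkinson", SINGULAR),
    ("parkinson's disease", "C_parkinson", SINGULAR),
    ("oxidative stress", "C_oxidative_stress", SINGULAR),
    ("abnormality", "C_abnormality", SINGULAR),
    ("ovarian cancer", "C_ovarian_cancer", SINGULAR),
    ("amantadine", "C_amantadine", SINGULAR),
    ("cetirizine", "C_cetirizine", SINGULAR),
]


def build_fixture_kb() -> KnowledgeBase:
    kb = KnowledgeBase()
    for cui, name, types, group in _CONCEPTS:
        kb.add_concept(
            Concept(cui=cui, preferred_name=name,
                    semantic_types=frozenset(types), semantic_group=group)
        )
    for parent, child in _EDGES:
        kb.add_edge(parent, child)
    for group, headwords in _GROUP_HEADWORDS.items():
        kb.set_group_headwords(group, headwords)
    for cui, name, _, _ in _CONCEPTS:
        low = name.lower()
        number = PLURAL if low.endswith("s") and not low.endswith(
            ("ss", "us", "is")
        ) else SINGULAR
        kb.add_lexicon_entry(low, cui, number)
    for surface, cui, number in _EXTRA_LEXICON:
        kb.add_lexicon_entry(surface, cui, number)
    kb.validate()
    return kb
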