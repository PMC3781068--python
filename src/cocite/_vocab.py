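"""Fixed filler vocabulary for synthetic abstracts.

A small, bundled word list keeps generated corpora human-readable and
deterministic.  The word "gene" is deliberately absent: in generated text it
appears only inside planted "<SYMBOL> gene" phrases, so index expansion has
an unambiguous ground truth.
"""

FILLER_WORDS = (
    "analysis", "apoptosis", "assay", "binding", "biology", "cell", "cells",
    "chromatin", "clinical", "cohort", "complex", "control", "culture",
    "cycle", "data", "decrease", "development", "differentiation", "dna",
    "domain", "effect", "embryo", "enzyme", "evidence", "experiment",
    "expression", "factor", "function", "growth", "human", "increase",
    "induction", "inhibition", "interaction", "kinase", "level", "ligand",
    "lineage", "localization", "loss", "mechanism", "membrane", "metabolism",
    "method", "mice", "model", "molecular", "mouse", "mutation", "network",
    "novel", "nuclear", "observed", "pathway", "patient", "patients",
    "peptide", "phenotype", "phosphorylation", "population", "process",
    "profile", "promoter", "protein", "proteins", "receptor", "region",
    "regulation", "repair", "response", "result", "results", "rna", "role",
    "sample", "screen", "sequence", "signal", "signaling", "significant",
    "stem", "stress", "structure", "study", "substrate", "suggest", "system",
    "target", "tissue", "transcription", "translation", "treatment", "tumor",
    "variant", "vitro", "vivo", "wild", "type", "pathways", "binding",
    "activation", "adhesion", "migration", "proliferation", "senescence",
    "autophagy", "degradation", "ubiquitin", "mitochondria", "cytoplasm",
    "nucleus", "ribosome", "vesicle", "secretion", "transport", "channel",
    "gradient", "polarity", "division", "replication", "recombination",
)
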