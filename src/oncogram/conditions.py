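"""Controlled vocabularies for assay conditions, categories and outcomes.

The assay tests each patient's primary culture under four conditions in
monoplicate: an untreated control and three standard colorectal-cancer
regimens (5-FU with folinic acid, FOLFIRI, FOLFOX).  Clinical follow-up is
coded with the four RECIST 1.1 outcomes.
"""

from __future__ import annotations

import enum


class Treatment(enum.StrEnum):
    """Drug regimens tested ex vivo (treated wells)."""

    FU_FA = "FU_FA"
    FOLFIRI = "FOLFIRI"
    FOLFOX = "FOLFOX"


class Condition(enum.StrEnum):
    """All well conditions, including the untreated control."""

    UNTREATED = "UNTREATED"
    FU_FA = "FU_FA"
    FOLFIRI = "FOLFIRI"
    FOLFOX = "FOLFOX"


class Category(enum.StrEnum):
    """Percentile category of a response ratio within the cohort."""

    RESISTANT = "R"
    INTERMEDIATE = "I"
    SENSITIVE = "S"
    NOT_DETERMINED = "ND"


class BinaryCall(enum.StrEnum):
    """Collapsed assay call: intermediate counts as sensitive."""

    SENSITIVE = "SENSITIVE"
    RESISTANT = "RESISTANT"
    NOT_DETERMINED = "ND"


class Outcome(enum.StrEnum):
    """RECIST 1.1 evaluation outcome."""

    CR = "CR"  # complete response
    PR = "PR"  # partial response
    SD = "SD"  # stable disease
    PD = "PD"  # progressive disease


class ClinicalLabel(enum.StrEnum):
    RESPONDER = "RESPONDER"
    NON_RESPONDER = "NON_RESPONDER"


class Policy(enum.StrEnum):
    """How a multi-evaluation history collapses to one clinical label.

    ANY_PROGRESSION labels a case non-responder as soon as any attributed
    evaluation shows progressive disease (principal analysis).
    FINAL_EVALUATION uses only the last attributed evaluation
    (supplementary analysis).
    """

    ANY_PROGRESSION = "any-progression"
    FINAL_EVALUATION = "final-evaluation"


#: chemotherapy components the assay conditions are built from
CHEMO_COMPONENTS = frozenset({"5-FU", "FA", "irinotecan", "oxaliplatin"})

#: monoclonal antibodies carried as covariates, never mapped to a condition
BIOLOGICS = frozenset({"bevacizumab", "panitumumab"})

#: received component sets that map onto a tested condition
REGIMEN_MAP: dict[frozenset[str], Treatment] = {
    frozenset({"5-FU"}): Treatment.FU_FA,
    frozenset({"5-FU", "FA"}): Treatment.FU_FA,
    frozenset({"5-FU", "FA", "irinotecan"}): Treatment.FOLFIRI,
    frozenset({"5-FU", "FA", "oxaliplatin"}): Treatment.FOLFOX,
}

#: final assay concentrations, µg/mL — configuration metadata only
DRUG_CONCENTRATIONS_UG_ML = {
    "5-FU": 25.0,
    "FA": 5.0,
    "irinotecan": 100.0,
    "oxaliplatin": 150.0,
}

#: responder = CR, PR or SD; non-responder = PD
RESPONDER_OUTCOMES = frozenset({Outcome.CR, Outcome.PR, Outcome.SD})


def collapse_category(category: Category) -> BinaryCall:
    """Collapse R/I/S to the binary assay call (I and S are sensitive)."""
    if category is Category.NOT_DETERMINED:
        return BinaryCall.NOT_DETERMINED
    if category is Category.RESISTANT:
        return BinaryCall.RESISTANT
    return BinaryCall.SENSITIVE
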