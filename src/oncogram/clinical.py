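"""Clinical coding: regimens, RECIST responder labels and case building.

A *case* is one (patient, tested regimen) pair for which both an assay
call and a clinical label exist.  Received chemotherapy lines are mapped
onto the tested conditions (5-FU alone or with folinic acid both map to
the 5-FU+FA well; FOLFIRI and FOLFOX map to their wells); biologics and
radiotherapy never affect the mapping, and a biologic-only line maps to
no condition.

Evaluation k is attributed to the regimen administered in cure k.  A cure
with neither chemotherapy nor a biologic (follow-up without treatment)
inherits the previous cure's regimen; a biologic-only cure attributes its
evaluation to no regimen.
"""

from __future__ import annotations

import logging
import warnings
from collections.abc import Iterable, Sequence

import pandas as pd

from .conditions import (
    BIOLOGICS,
    CHEMO_COMPONENTS,
    REGIMEN_MAP,
    BinaryCall,
    Category,
    ClinicalLabel,
    Outcome,
    Policy,
    Treatment,
    collapse_category,
)
from .errors import InvalidInputError, UncodableCaseError, UnmappedRegimenWarning

logger = logging.getLogger(__name__)

TREATMENT_COLUMNS = [
    "patient_id",
    "cure_index",
    "components",
    "cycles",
    "biologics",
    "radiotherapy",
]
EVALUATION_COLUMNS = ["patient_id", "evaluation_index", "outcome"]
CASE_COLUMNS = ["patient_id", "regimen", "assay_binary", "clinical"]


def parse_components(value) -> frozenset[str]:
    """Parse a '+'-separated component string into a set of drug names."""
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return frozenset()
    text = str(value).strip()
    if not text:
        return frozenset()
    return frozenset(part.strip() for part in text.split("+") if part.strip())


def map_regimen(
    components: Iterable[str],
    biologics: Iterable[str] = (),
    radiotherapy: bool = False,
) -> Treatment | None:
    """Map a received line onto a tested condition, or None.

    Biologics and radiotherapy are ignored; an empty chemotherapy set
    (including biologic-only lines) maps to None.  An unrecognized
    non-empty combination raises a warning and also maps to None
    (the line is excluded from case building).
    """
    chemo = frozenset(components)
    if not chemo:
        return None
    unknown = chemo - CHEMO_COMPONENTS
    if unknown or chemo not in REGIMEN_MAP:
        warnings.warn(
            f"unmapped regimen components {sorted(chemo)}; line excluded",
            UnmappedRegimenWarning,
            stacklevel=2,
        )
        return None
    return REGIMEN_MAP[chemo]


def _check_lines(lines: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TREATMENT_COLUMNS if c not in lines.columns]
    if missing:
        raise InvalidInputError(f"treatments table missing columns {missing}")
    lines = lines.copy()
    lines["patient_id"] = lines["patient_id"].astype(str)
    lines["cure_index"] = lines["cure_index"].astype(int)
    dup = lines.duplicated(subset=["patient_id", "cure_index"])
    if dup.any():
        raise InvalidInputError("duplicate (patient, cure_index) rows")
    return lines.sort_values(["patient_id", "cure_index"])


def _cure_mappings(
    patient_lines: pd.DataFrame,
) -> tuple[dict[int, Treatment | None], dict[int, Treatment | None]]:
    """Raw and attribution mappings of each cure to a tested condition.

    The raw mapping reflects what was administered in that cure alone;
    the attribution mapping additionally lets an empty (no-treatment)
    cure inherit the previous cure's regimen so late evaluations stay
    attached to the ongoing line.
    """
    raw: dict[int, Treatment | None] = {}
    attributed: dict[int, Treatment | None] = {}
    previous: Treatment | None = None
    for row in patient_lines.itertuples(index=False):
        chemo = parse_components(row.components)
        bio = parse_components(row.biologics)
        unknown_bio = bio - BIOLOGICS
        if unknown_bio:
            logger.info(
                "patient %s cure %d: unrecognized biologics %s",
                row.patient_id,
                row.cure_index,
                sorted(unknown_bio),
            )
        mapped = map_regimen(chemo, bio)
        raw[row.cure_index] = mapped
        if not chemo and not bio:
            attributed[row.cure_index] = previous
        else:
            attributed[row.cure_index] = mapped
            previous = mapped
    return raw, attributed


def code_response(
    outcomes: Sequence[Outcome | str], policy: Policy | str
) -> ClinicalLabel:
    """Collapse the evaluations attributed to one regimen to one label."""
    policy = Policy(str(policy))
    coded = [Outcome(str(o)) for o in outcomes]
    if not coded:
        raise UncodableCaseError("no attributable evaluation for this regimen")
    if policy is Policy.ANY_PROGRESSION:
        if any(o is Outcome.PD for o in coded):
            return ClinicalLabel.NON_RESPONDER
        return ClinicalLabel.RESPONDER
    # FINAL_EVALUATION
    return (
        ClinicalLabel.NON_RESPONDER
        if coded[-1] is Outcome.PD
        else ClinicalLabel.RESPONDER
    )


def _category_lookup(categories: pd.DataFrame) -> dict[tuple[str, Treatment], Category]:
    categories = pd.DataFrame(categories)
    for col in ("patient_id", "treatment", "category"):
        if col not in categories.columns:
            raise InvalidInputError(f"categories table missing column {col!r}")
    lookup = {}
    for row in categories.itertuples(index=False):
        key = (str(row.patient_id), Treatment(str(row.treatment)))
        lookup[key] = Category(str(row.category))
    return lookup


def select_no_switch_subset(
    lines: pd.DataFrame, categories: pd.DataFrame
) -> list[str]:
    """Patients whose first two cures map to the same tested condition.

    Biologics are ignored in the comparison; patients without an actual
    second chemotherapy cure, or whose condition has no determined assay
    result, are excluded.
    """
    lines = _check_lines(lines)
    lookup = _category_lookup(categories)
    selected = []
    for patient_id, patient_lines in lines.groupby("patient_id", sort=True):
        raw, _ = _cure_mappings(patient_lines)
        first, second = raw.get(1), raw.get(2)
        if first is None or second is None or first != second:
            continue
        category = lookup.get((patient_id, first), Category.NOT_DETERMINED)
        if category is Category.NOT_DETERMINED:
            logger.info(
                "patient %s: no-switch regimen %s not determined ex vivo",
                patient_id,
                first,
            )
            continue
        selected.append(patient_id)
    return selected


def build_cases(
    lines: pd.DataFrame,
    evaluations: pd.DataFrame,
    categories: pd.DataFrame,
    policy: Policy | str = Policy.ANY_PROGRESSION,
    patients: Iterable[str] | None = None,
    no_switch_only: bool = False,
) -> pd.DataFrame:
    """Build the comparable-case table.

    One case per (patient, distinct mapped regimen actually received)
    with a determined assay category.  ``patients`` restricts the cohort;
    ``no_switch_only`` keeps, per patient, only the regimen given in both
    of the first two cures (supplementary design).

    Returns a DataFrame ``patient_id, regimen, assay_binary, clinical``.
    """
    policy = Policy(str(policy))
    lines = _check_lines(lines)
    evaluations = pd.DataFrame(evaluations)
    missing = [c for c in EVALUATION_COLUMNS if c not in evaluations.columns]
    if missing:
        raise InvalidInputError(f"evaluations table missing columns {missing}")
    evaluations = evaluations.copy()
    evaluations["patient_id"] = evaluations["patient_id"].astype(str)
    evaluations["evaluation_index"] = evaluations["evaluation_index"].astype(int)
    lookup = _category_lookup(categories)
    if patients is not None:
        keep = {str(p) for p in patients}
        lines = lines[lines["patient_id"].isin(keep)]
        evaluations = evaluations[evaluations["patient_id"].isin(keep)]

    records = []
    for patient_id, patient_lines in lines.groupby("patient_id", sort=True):
        raw, attributed = _cure_mappings(patient_lines)
        received = [t for t in dict.fromkeys(raw.values()) if t is not None]
        if no_switch_only:
            first, second = raw.get(1), raw.get(2)
            received = [first] if first is not None and first == second else []
        if not received:
            logger.info("patient %s: no mapped chemotherapy regimen", patient_id)
            continue
        patient_evals = evaluations[
            evaluations["patient_id"] == patient_id
        ].sort_values("evaluation_index")
        for regimen in received:
            category = lookup.get((patient_id, regimen), Category.NOT_DETERMINED)
            if category is Category.NOT_DETERMINED:
                logger.info(
                    "patient %s: regimen %s excluded (assay not determined)",
                    patient_id,
                    regimen,
                )
                continue
            outcomes = [
                Outcome(str(row.outcome))
                for row in patient_evals.itertuples(index=False)
                if attributed.get(row.evaluation_index) == regimen
            ]
            clinical = code_response(outcomes, policy)
            binary = collapse_category(category)
            assert binary is not BinaryCall.NOT_DETERMINED
            records.append((patient_id, str(regimen), str(binary), str(clinical)))

    return pd.DataFrame(records, columns=CASE_COLUMNS)


def count_experimental_conditions(
    categories: pd.DataFrame,
) -> tuple[int, int]:
    """(successes, planned) condition counts over the cohort.

    Four conditions are planned per patient (untreated control plus the
    three treatments); a success is any condition that was determined.
    """
    categories = pd.DataFrame(categories)
    lookup = _category_lookup(categories)
    patients = {p for p, _ in lookup}
    planned = 4 * len(patients)
    not_determined = sum(
        1 for c in lookup.values() if c is Category.NOT_DETERMINED
    )
    return planned - not_determined, planned
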