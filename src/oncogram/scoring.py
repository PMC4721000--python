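"""Well-level cell counts -> death fractions -> treated/untreated ratios.

Each patient contributes one well per condition (monoplicate design).  For
every well the dead fraction is dead / total, where *total* is the
independently labelled overall population (not live + dead, which may
undercount).  The per-drug response score is the ratio of the treated dead
fraction to the untreated dead fraction; values above 1 mean the drug
killed more cells than the spontaneous baseline.

Quality control flags wells with fewer than ``qc_min_cells`` counted cells
(default 1000); flagged wells are reported, not dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import Condition, Treatment
from .errors import (
    DegenerateBaselineError,
    InvalidInputError,
    InvalidPairingError,
)

logger = logging.getLogger(__name__)

DEFAULT_QC_MIN_CELLS = 1000

#: required columns of a wells table
WELL_COLUMNS = ["patient_id", "condition", "live", "dead", "total"]


@dataclass(frozen=True)
class WellCount:
    """Raw counts for one patient x condition well.

    ``total`` is the overall (nucleus-labelled) population across the
    randomly sampled microscope fields; ``live`` and ``dead`` are the
    viability-labelled subpopulations.
    """

    patient_id: str
    condition: Condition
    live: int
    dead: int
    total: int

    def __post_init__(self) -> None:
        if self.total < 1:
            raise InvalidInputError(
                f"{self.patient_id}/{self.condition}: total count must be >= 1"
            )
        if self.live < 0 or self.dead < 0:
            raise InvalidInputError(
                f"{self.patient_id}/{self.condition}: negative cell count"
            )
        if self.dead > self.total or self.live > self.total:
            raise InvalidInputError(
                f"{self.patient_id}/{self.condition}: live/dead exceed total"
            )
        if self.live + self.dead > self.total:
            raise InvalidInputError(
                f"{self.patient_id}/{self.condition}: "
                "live + dead exceed the overall labelled population"
            )


@dataclass(frozen=True)
class DeathFraction:
    patient_id: str
    condition: Condition
    fraction: float
    n_counted: int
    qc_pass: bool


@dataclass(frozen=True)
class ResponseRatio:
    patient_id: str
    treatment: Treatment
    ratio: float


def compute_death_fraction(
    well: WellCount, qc_min_cells: int = DEFAULT_QC_MIN_CELLS
) -> DeathFraction:
    """Dead fraction of a well, with the cell-count QC flag."""
    return DeathFraction(
        patient_id=well.patient_id,
        condition=well.condition,
        fraction=well.dead / well.total,
        n_counted=well.total,
        qc_pass=well.total >= qc_min_cells,
    )


def compute_response_ratio(
    treated: DeathFraction, untreated: DeathFraction
) -> ResponseRatio:
    """Treated dead fraction divided by the untreated dead fraction.

    The ratio is dimensionless and invariant to expressing both fractions
    as proportions or percentages.
    """
    if treated.patient_id != untreated.patient_id:
        raise InvalidPairingError(
            f"cannot pair {treated.patient_id} with {untreated.patient_id}"
        )
    if untreated.condition is not Condition.UNTREATED:
        raise InvalidPairingError(
            f"{untreated.patient_id}: baseline well is {untreated.condition},"
            " expected UNTREATED"
        )
    if untreated.fraction == 0:
        raise DegenerateBaselineError(
            f"{untreated.patient_id}: untreated death fraction is zero"
        )
    return ResponseRatio(
        patient_id=treated.patient_id,
        treatment=Treatment(str(treated.condition)),
        ratio=treated.fraction / untreated.fraction,
    )


def _validate_wells_frame(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise InvalidInputError(f"wells table missing columns {missing}")
    wells = wells.copy()
    wells["patient_id"] = wells["patient_id"].astype(str)
    wells["condition"] = wells["condition"].map(lambda c: Condition(str(c)))
    dup = wells.duplicated(subset=["patient_id", "condition"], keep=False)
    if dup.any():
        pairs = wells.loc[dup, ["patient_id", "condition"]].drop_duplicates()
        raise InvalidInputError(
            "monoplicate design violated; duplicate wells for "
            + ", ".join(f"{p}/{c}" for p, c in pairs.itertuples(index=False))
        )
    return wells


def score_wells(
    wells: pd.DataFrame, qc_min_cells: int = DEFAULT_QC_MIN_CELLS
) -> pd.DataFrame:
    """Score a wells table into per-patient per-treatment response ratios.

    Parameters
    ----------
    wells
        Table with columns ``patient_id, condition, live, dead, total``,
        one row per well.  Exactly one well per (patient, condition) is
        required; duplicates raise (monoplicates are never averaged).
    qc_min_cells
        Minimum counted cells for the QC flag.

    Returns
    -------
    DataFrame with columns ``patient_id, treatment, ratio, qc_pass``.
    One row per patient per tested treatment; a missing treated well or a
    zero untreated baseline yields ``ratio = NaN`` (not determined), which
    downstream categorization propagates as N/D.
    """
    wells = _validate_wells_frame(wells)

    fractions: dict[tuple[str, Condition], DeathFraction] = {}
    for row in wells.itertuples(index=False):
        wc = WellCount(
            patient_id=row.patient_id,
            condition=row.condition,
            live=int(row.live),
            dead=int(row.dead),
            total=int(row.total),
        )
        fractions[(wc.patient_id, wc.condition)] = compute_death_fraction(
            wc, qc_min_cells
        )

    records = []
    for patient_id in wells["patient_id"].unique():
        untreated = fractions.get((patient_id, Condition.UNTREATED))
        if untreated is None:
            raise InvalidInputError(f"{patient_id}: no untreated control well")
        for treatment in Treatment:
            treated = fractions.get((patient_id, Condition(str(treatment))))
            if treated is None:
                logger.info(
                    "patient %s: condition %s not determined (missing well)",
                    patient_id,
                    treatment,
                )
                records.append((patient_id, str(treatment), np.nan, False))
                continue
            qc_pass = treated.qc_pass and untreated.qc_pass
            if not qc_pass:
                logger.info(
                    "patient %s: condition %s below QC cell count",
                    patient_id,
                    treatment,
                )
            try:
                rr = compute_response_ratio(treated, untreated)
            except DegenerateBaselineError:
                logger.info(
                    "patient %s: zero untreated mortality, %s excluded",
                    patient_id,
                    treatment,
                )
                records.append((patient_id, str(treatment), np.nan, qc_pass))
                continue
            records.append((patient_id, str(treatment), rr.ratio, qc_pass))

    return pd.DataFrame(
        records, columns=["patient_id", "treatment", "ratio", "qc_pass"]
    )
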