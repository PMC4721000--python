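"""Concordance statistics for the 2x2 assay-vs-outcome table.

Rows are the clinical labels (responder / non-responder), columns the
binary assay calls (sensitive / resistant).  Sensitivity is the fraction
of responders called sensitive ex vivo, specificity the fraction of
non-responders called resistant; both carry exact Clopper–Pearson
binomial intervals.  Chance-corrected agreement uses Cohen's kappa,

    kappa = (po - pe) / (1 - pe),

with po the observed agreement and pe the product-margin chance
agreement; its confidence interval uses the non-null large-sample
variance of Fleiss, Cohen and Everitt for unweighted kappa (a simpler
po-based variance is available but does not match the exact interval
widths the FCE formula gives).  Verbal interpretation follows the
Landis–Koch bands, with a magnitude-scale variant ("very weak" ...
"very strong") emitted alongside.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .conditions import BinaryCall, ClinicalLabel
from .errors import InvalidInputError

KAPPA_SE_METHODS = ("fleiss-cohen-everitt", "simple")

LANDIS_KOCH_BANDS = (
    (0.0, "poor"),
    (0.20, "slight"),
    (0.40, "fair"),
    (0.60, "moderate"),
    (0.80, "substantial"),
    (1.0, "almost perfect"),
)

MAGNITUDE_BANDS = (
    (0.20, "very weak"),
    (0.40, "weak"),
    (0.60, "moderate"),
    (0.80, "strong"),
    (1.0, "very strong"),
)


def interpret_kappa(kappa: float) -> str:
    """Landis–Koch verbal band for a kappa value."""
    if kappa <= 0:
        return "poor"
    for upper, label in LANDIS_KOCH_BANDS[1:]:
        if kappa <= upper:
            return label
    return "almost perfect"


def interpret_kappa_magnitude(kappa: float) -> str:
    """Magnitude-scale variant used in some reports ("very weak"...)."""
    for upper, label in MAGNITUDE_BANDS:
        if kappa < upper:
            return label
    return "very strong"


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 table of clinical labels (rows) against assay calls (columns).

    tp: responder called sensitive; fn: responder called resistant;
    fp: non-responder called sensitive; tn: non-responder called resistant.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise InvalidInputError("contingency cells must be non-negative")
        if self.n < 1:
            raise InvalidInputError("contingency table is empty")

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def responders(self) -> int:
        return self.tp + self.fn

    @property
    def non_responders(self) -> int:
        return self.fp + self.tn

    @property
    def called_sensitive(self) -> int:
        return self.tp + self.fp

    @property
    def called_resistant(self) -> int:
        return self.fn + self.tn

    @classmethod
    def from_cases(cls, cases: pd.DataFrame) -> "ContingencyTable":
        """Tabulate a cases table (columns assay_binary, clinical)."""
        cases = pd.DataFrame(cases)
        for col in ("assay_binary", "clinical"):
            if col not in cases.columns:
                raise InvalidInputError(f"cases table missing column {col!r}")
        resp = cases["clinical"].astype(str) == str(ClinicalLabel.RESPONDER)
        sens = cases["assay_binary"].astype(str) == str(BinaryCall.SENSITIVE)
        return cls(
            tp=int((resp & sens).sum()),
            fn=int((resp & ~sens).sum()),
            fp=int((~resp & sens).sum()),
            tn=int((~resp & ~sens).sum()),
        )


@dataclass(frozen=True)
class ProportionEstimate:
    """A binomial proportion with its exact Clopper–Pearson interval."""

    k: int
    n: int
    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n": self.n,
            "estimate": self.estimate,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "level": self.level,
        }


@dataclass(frozen=True)
class KappaEstimate:
    po: float
    pe: float
    kappa: float
    se: float
    ci_low: float       # clipped to [-1, 1] for reporting
    ci_high: float
    ci_low_raw: float   # unclipped kappa +/- z*se
    ci_high_raw: float
    level: float
    se_method: str
    interpretation: str
    interpretation_magnitude: str

    def to_dict(self) -> dict:
        return {
            "po": self.po,
            "pe": self.pe,
            "kappa": self.kappa,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "ci_low_raw": self.ci_low_raw,
            "ci_high_raw": self.ci_high_raw,
            "level": self.level,
            "se_method": self.se_method,
            "interpretation": self.interpretation,
            "interpretation_magnitude": self.interpretation_magnitude,
        }


def clopper_pearson(k: int, n: int, level: float = 0.95) -> ProportionEstimate:
    """Exact binomial interval by inversion of the beta quantiles."""
    if not 0 < level < 1:
        raise InvalidInputError(f"confidence level {level} outside (0, 1)")
    if n < 1 or not 0 <= k <= n:
        raise InvalidInputError(f"invalid successes/trials {k}/{n}")
    low, high = proportion_confint(k, n, alpha=1 - level, method="beta")
    # statsmodels returns NaN at the boundary cases; the exact limits there
    # are 0 and 1 by construction
    low = 0.0 if k == 0 else float(low)
    high = 1.0 if k == n else float(high)
    return ProportionEstimate(
        k=int(k), n=int(n), estimate=k / n, ci_low=low, ci_high=high, level=level
    )


def sensitivity_specificity(
    table: ContingencyTable, level: float = 0.95
) -> tuple[ProportionEstimate | None, ProportionEstimate | None]:
    """(sensitivity, specificity) with exact intervals.

    A zero margin makes the corresponding estimate undefined; it is
    returned as None, never as 0.
    """
    sensitivity = (
        clopper_pearson(table.tp, table.responders, level)
        if table.responders >= 1
        else None
    )
    specificity = (
        clopper_pearson(table.tn, table.non_responders, level)
        if table.non_responders >= 1
        else None
    )
    return sensitivity, specificity


def overall_agreement(
    table: ContingencyTable, level: float = 0.95
) -> ProportionEstimate:
    """Raw agreement (tp + tn) / n with its exact interval."""
    return clopper_pearson(table.tp + table.tn, table.n, level)


def _fce_variance(table: ContingencyTable, po: float, pe: float, kappa: float) -> float:
    """Fleiss–Cohen–Everitt non-null large-sample variance of kappa.

    Cell proportions are arranged so the diagonal holds the agreement
    cells (responder&sensitive, non-responder&resistant).
    """
    n = table.n
    p = [
        [table.tp / n, table.fn / n],
        [table.fp / n, table.tn / n],
    ]
    row = [p[0][0] + p[0][1], p[1][0] + p[1][1]]
    col = [p[0][0] + p[1][0], p[0][1] + p[1][1]]
    a = sum(
        p[i][i] * (1.0 - (row[i] + col[i]) * (1.0 - kappa)) ** 2
        for i in range(2)
    )
    b = (1.0 - kappa) ** 2 * sum(
        p[i][j] * (col[i] + row[j]) ** 2
        for i in range(2)
        for j in range(2)
        if i != j
    )
    c = (kappa - pe * (1.0 - kappa)) ** 2
    return (a + b - c) / (n * (1.0 - pe) ** 2)


def cohens_kappa(
    table: ContingencyTable,
    level: float = 0.95,
    se_method: str = "fleiss-cohen-everitt",
) -> KappaEstimate:
    """Unweighted Cohen's kappa with an asymptotic confidence interval."""
    if se_method not in KAPPA_SE_METHODS:
        raise InvalidInputError(f"unknown kappa SE method {se_method!r}")
    if not 0 < level < 1:
        raise InvalidInputError(f"confidence level {level} outside (0, 1)")
    n = table.n
    po = (table.tp + table.tn) / n
    pe = (
        table.responders * table.called_sensitive
        + table.non_responders * table.called_resistant
    ) / n**2
    if pe >= 1.0:
        raise InvalidInputError(
            "chance agreement is 1 (degenerate identical margins); "
            "kappa undefined"
        )
    kappa = (po - pe) / (1.0 - pe)
    if se_method == "fleiss-cohen-everitt":
        var = _fce_variance(table, po, pe, kappa)
    else:
        var = po * (1.0 - po) / (n * (1.0 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    z = float(norm.ppf(0.5 + level / 2.0))
    low_raw, high_raw = kappa - z * se, kappa + z * se
    return KappaEstimate(
        po=po,
        pe=pe,
        kappa=kappa,
        se=se,
        ci_low=max(low_raw, -1.0),
        ci_high=min(high_raw, 1.0),
        ci_low_raw=low_raw,
        ci_high_raw=high_raw,
        level=level,
        se_method=se_method,
        interpretation=interpret_kappa(kappa),
        interpretation_magnitude=interpret_kappa_magnitude(kappa),
    )


@dataclass(frozen=True)
class ConcordanceResult:
    """Full 2x2 concordance analysis of a cases table."""

    table: ContingencyTable
    sensitivity: ProportionEstimate | None
    specificity: ProportionEstimate | None
    agreement: ProportionEstimate
    kappa: KappaEstimate
    level: float = 0.95
    notes: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        def prop(p: ProportionEstimate | None, reason: str):
            if p is None:
                return {"value": None, "reason": reason}
            return p.to_dict()

        return {
            "table": {
                "tp": self.table.tp,
                "fn": self.table.fn,
                "fp": self.table.fp,
                "tn": self.table.tn,
                "n": self.table.n,
            },
            "sensitivity": prop(self.sensitivity, "no responders"),
            "specificity": prop(self.specificity, "no non-responders"),
            "agreement": self.agreement.to_dict(),
            "kappa": self.kappa.to_dict(),
            "level": self.level,
            "notes": list(self.notes),
        }


def concordance(
    cases_or_table: pd.DataFrame | ContingencyTable,
    level: float = 0.95,
    kappa_se: str = "fleiss-cohen-everitt",
) -> ConcordanceResult:
    """Run the full concordance analysis on cases or a prebuilt table."""
    if isinstance(cases_or_table, ContingencyTable):
        table = cases_or_table
    else:
        table = ContingencyTable.from_cases(cases_or_table)
    sens, spec = sensitivity_specificity(table, level)
    notes = []
    if sens is None:
        notes.append("sensitivity undefined: zero responder margin")
    if spec is None:
        notes.append("specificity undefined: zero non-responder margin")
    return ConcordanceResult(
        table=table,
        sensitivity=sens,
        specificity=spec,
        agreement=overall_agreement(table, level),
        kappa=cohens_kappa(table, level, kappa_se),
        level=level,
        notes=tuple(notes),
    )
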