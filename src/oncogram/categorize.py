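"""Method-of-percentiles categorization of response ratios.

Within each treatment, the cohort's 25th and 75th percentiles split the
ratios into resistant (below the 25th), intermediate (between, boundary
ties included) and sensitive (above the 75th).  The binary assay call
gathers intermediate with sensitive, so only ratios strictly below the
25th percentile read out as resistant.

Thresholds default to linear interpolation between order statistics (the
"type 7" convention shared by numpy and spreadsheets); published
threshold pairs can be injected verbatim as overrides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .conditions import BinaryCall, Category, Treatment, collapse_category
from .errors import InsufficientCohortError, InvalidInputError

MIN_COHORT_RATIOS = 3

#: numpy percentile methods accepted as the interpolation convention
PERCENTILE_METHODS = (
    "linear",
    "lower",
    "higher",
    "nearest",
    "midpoint",
)


@dataclass(frozen=True)
class PercentileThresholds:
    treatment: Treatment
    q25: float
    q75: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.q25 > self.q75:
            raise InvalidInputError(
                f"{self.treatment}: q25 {self.q25} exceeds q75 {self.q75}"
            )


def compute_thresholds(
    ratios,
    treatment: Treatment | str,
    method: str = "linear",
) -> PercentileThresholds:
    """25th/75th percentile thresholds from a cohort of finite ratios."""
    if method not in PERCENTILE_METHODS:
        raise InvalidInputError(f"unknown percentile method {method!r}")
    values = np.asarray(ratios, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < MIN_COHORT_RATIOS:
        raise InsufficientCohortError(
            f"{treatment}: need >= {MIN_COHORT_RATIOS} finite ratios, "
            f"got {values.size}"
        )
    q25, q75 = np.percentile(values, [25, 75], method=method)
    return PercentileThresholds(
        treatment=Treatment(str(treatment)),
        q25=float(q25),
        q75=float(q75),
        n_samples=int(values.size),
    )


def categorize_value(
    ratio: float, thresholds: PercentileThresholds
) -> Category:
    """Assign R/I/S; ties with either threshold fall to intermediate."""
    if ratio is None or not np.isfinite(ratio):
        return Category.NOT_DETERMINED
    if ratio > thresholds.q75:
        return Category.SENSITIVE
    if ratio < thresholds.q25:
        return Category.RESISTANT
    return Category.INTERMEDIATE


class PercentileCategorizer(BaseEstimator):
    """Cohort-relative ratio categorizer with a scikit-learn interface.

    ``fit`` learns per-treatment (or pooled) percentile thresholds from a
    cohort of response ratios; ``predict`` maps ratios to R/I/S categories
    against the fitted thresholds, so new patients can be categorized
    relative to a reference cohort.

    Parameters
    ----------
    percentile_method : str, default "linear"
        Interpolation convention passed to :func:`numpy.percentile`.
    pooled : bool, default False
        Pool ratios across treatments into a single threshold pair
        instead of the per-treatment pairs the study design uses.
    thresholds_override : DataFrame, optional
        Columns ``treatment, q25, q75``: explicit threshold pairs (e.g. a
        published table) that replace the fitted values.

    Attributes
    ----------
    thresholds_ : dict[Treatment, PercentileThresholds]
        Fitted (or overridden) thresholds per treatment.
    """

    def __init__(
        self,
        percentile_method: str = "linear",
        pooled: bool = False,
        thresholds_override: pd.DataFrame | None = None,
    ) -> None:
        self.percentile_method = percentile_method
        self.pooled = pooled
        self.thresholds_override = thresholds_override

    @staticmethod
    def _check_frame(X) -> pd.DataFrame:
        X = pd.DataFrame(X)
        for col in ("patient_id", "treatment", "ratio"):
            if col not in X.columns:
                raise InvalidInputError(f"ratios table missing column {col!r}")
        X = X.copy()
        X["treatment"] = X["treatment"].map(lambda t: Treatment(str(t)))
        X["ratio"] = pd.to_numeric(X["ratio"], errors="coerce")
        return X

    def fit(self, X, y=None) -> "PercentileCategorizer":
        """Learn thresholds from a ratios table.

        ``X`` is a DataFrame with columns ``patient_id, treatment, ratio``;
        ``y`` is ignored (unsupervised, cohort-relative).
        """
        X = self._check_frame(X)
        if self.thresholds_override is not None:
            ov = pd.DataFrame(self.thresholds_override)
            self.thresholds_ = {
                Treatment(str(r.treatment)): PercentileThresholds(
                    Treatment(str(r.treatment)),
                    float(r.q25),
                    float(r.q75),
                    n_samples=0,
                )
                for r in ov.itertuples(index=False)
            }
            return self
        if self.pooled:
            pooled = compute_thresholds(
                X["ratio"], Treatment.FU_FA, self.percentile_method
            )
            self.thresholds_ = {
                t: PercentileThresholds(t, pooled.q25, pooled.q75, pooled.n_samples)
                for t in Treatment
            }
            return self
        self.thresholds_ = {}
        for treatment, group in X.groupby("treatment", observed=True):
            self.thresholds_[Treatment(str(treatment))] = compute_thresholds(
                group["ratio"], treatment, self.percentile_method
            )
        return self

    def predict(self, X) -> pd.DataFrame:
        """Categorize ratios against the fitted thresholds.

        Returns a DataFrame ``patient_id, treatment, ratio, category,
        binary``; ratios whose treatment has no fitted thresholds or that
        are missing propagate as N/D.
        """
        if not hasattr(self, "thresholds_"):
            raise InvalidInputError("categorizer is not fitted")
        X = self._check_frame(X)
        records = []
        for row in X.itertuples(index=False):
            thresholds = self.thresholds_.get(row.treatment)
            if thresholds is None:
                category = Category.NOT_DETERMINED
            else:
                category = categorize_value(row.ratio, thresholds)
            records.append(
                (
                    row.patient_id,
                    str(row.treatment),
                    row.ratio,
                    str(category),
                    str(collapse_category(category)),
                )
            )
        return pd.DataFrame(
            records,
            columns=["patient_id", "treatment", "ratio", "category", "binary"],
        )

    def fit_predict(self, X, y=None) -> pd.DataFrame:
        """Fit thresholds on the cohort and categorize it in one pass."""
        return self.fit(X, y).predict(X)


def categorize_cohort(
    ratios: pd.DataFrame,
    thresholds: pd.DataFrame | None = None,
    method: str = "linear",
    pooled: bool = False,
) -> pd.DataFrame:
    """Functional wrapper: categorize a ratios table against itself.

    With ``thresholds`` given (columns ``treatment, q25, q75``), those
    values are used verbatim instead of being recomputed from the cohort.
    """
    est = PercentileCategorizer(
        percentile_method=method, pooled=pooled, thresholds_override=thresholds
    )
    return est.fit_predict(ratios)


def binary_from_category(category: Category | str) -> BinaryCall:
    return collapse_category(Category(str(category)))
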