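"""The bundled 19-patient study fixture.

The package ships the published cohort tables as plain CSV: the
treatment histories and per-evaluation RECIST outcomes, the per-patient
per-treatment assay categories with a ``received`` flag (the source
table marks received treatments typographically, which cannot survive
CSV), the per-treatment ratio summaries and percentile thresholds, and
per-patient flags for the 13-patient no-switch supplementary subset.
Two category rows (patients 08 and 09) are typographically ambiguous in
the source and carry an ``underline_ambiguous`` flag; the adopted
reading is the one consistent with the published contingency counts.

Loading validates checksums and structural invariants (19 patients,
exactly two not-determined conditions, all on patient 06, 13
supplementary patients) and raises ``FixtureIntegrityError`` otherwise.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources

import pandas as pd

from .conditions import Category, Outcome, Treatment
from .errors import FixtureIntegrityError

N_PATIENTS = 19
N_SUPPLEMENTARY = 13
CONDITIONS_PER_PATIENT = 4  # untreated control + three treatments

#: sha256 of the bundled CSVs; guards silent corruption
FIXTURE_CHECKSUMS = {
    "treatments.csv": "a16d1be9c6082e3ba4bc81d71405e7567609c2470a8d16f6777b887fff892c20",
    "evaluations.csv": "019023f02690490e98a5059e477a58dcb0a64507efb63cf3caff99cc87f89c15",
    "categories.csv": "934784d775183a9ad412a9171a2dc1a1a0a4c8fdc77792c60ad9aa6b14e7b13f",
    "patients.csv": "eb5dff4fb85912d56a85d9be5bbecbab5645d324a6af43a70fff07740e1fd17d",
    "thresholds.csv": "52156c0f0ab6e78c93b1b7c4246de2723d4029a1fc131e927aaa68fa43ff2f16",
}


@dataclass(frozen=True)
class StudyFixture:
    treatments: pd.DataFrame
    evaluations: pd.DataFrame
    categories: pd.DataFrame
    patients: pd.DataFrame
    thresholds: pd.DataFrame

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.patients["patient_id"].astype(str))

    @property
    def supplementary_patient_ids(self) -> list[str]:
        mask = self.patients["supplementary"].astype(int) == 1
        return sorted(self.patients.loc[mask, "patient_id"].astype(str))


def _read(name: str, verify: bool = True) -> pd.DataFrame:
    ref = resources.files("oncogram.data") / name
    raw = ref.read_bytes()
    if verify:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != FIXTURE_CHECKSUMS[name]:
            raise FixtureIntegrityError(
                f"fixture file {name} is corrupted "
                f"(sha256 {digest}, expected {FIXTURE_CHECKSUMS[name]})"
            )
    from io import BytesIO

    df = pd.read_csv(BytesIO(raw), dtype={"patient_id": str})
    return df


def load_fixture(verify: bool = True) -> StudyFixture:
    """Load and validate the bundled study fixture."""
    fixture = StudyFixture(
        treatments=_read("treatments.csv", verify),
        evaluations=_read("evaluations.csv", verify),
        categories=_read("categories.csv", verify),
        patients=_read("patients.csv", verify),
        thresholds=_read("thresholds.csv", verify),
    )
    _validate(fixture)
    return fixture


def _validate(fx: StudyFixture) -> None:
    ids = set(fx.patients["patient_id"].astype(str))
    if len(ids) != N_PATIENTS:
        raise FixtureIntegrityError(
            f"expected {N_PATIENTS} patients, found {len(ids)}"
        )
    for name, frame in [
        ("treatments", fx.treatments),
        ("evaluations", fx.evaluations),
        ("categories", fx.categories),
    ]:
        extra = set(frame["patient_id"].astype(str)) - ids
        if extra or set(frame["patient_id"].astype(str)) != ids:
            raise FixtureIntegrityError(
                f"{name} table patient ids inconsistent with patients table"
            )

    try:
        fx.evaluations["outcome"].map(lambda o: Outcome(str(o)))
        fx.categories["treatment"].map(lambda t: Treatment(str(t)))
        categories = fx.categories["category"].map(lambda c: Category(str(c)))
    except ValueError as exc:
        raise FixtureIntegrityError(f"invalid coded value: {exc}") from exc

    per_patient = fx.categories.groupby("patient_id").size()
    if not (per_patient == len(list(Treatment))).all():
        raise FixtureIntegrityError("each patient needs one row per treatment")

    nd = fx.categories.loc[
        categories == Category.NOT_DETERMINED, "patient_id"
    ].astype(str)
    if len(nd) != 2 or set(nd) != {"06"}:
        raise FixtureIntegrityError(
            "expected exactly 2 not-determined conditions, both on patient 06"
        )

    n_suppl = int(fx.patients["supplementary"].astype(int).sum())
    if n_suppl != N_SUPPLEMENTARY:
        raise FixtureIntegrityError(
            f"expected {N_SUPPLEMENTARY} supplementary patients, got {n_suppl}"
        )

    thr = fx.thresholds
    if set(thr["treatment"]) != {str(t) for t in Treatment}:
        raise FixtureIntegrityError("thresholds must cover all treatments")
    if not ((thr["q25"] <= thr["median"]) & (thr["median"] <= thr["q75"])).all():
        raise FixtureIntegrityError("threshold quartiles must bracket medians")
    if not (
        (thr["minimum"] <= thr["q25"]) & (thr["q75"] <= thr["maximum"])
    ).all():
        raise FixtureIntegrityError("threshold quartiles outside min/max range")
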