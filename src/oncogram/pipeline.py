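"""End-to-end reproduction of the study's principal and supplementary
concordance analyses from the bundled fixture.

The principal analysis builds all comparable cases under the
any-progression response policy; the supplementary analysis restricts to
the 13 no-treatment-switch patients, one case each, under the
final-evaluation policy.  The report carries every quantity at full
precision alongside presentation-rounded values (1 decimal for
percentages, 4 for kappa).
"""

from __future__ import annotations

from .clinical import (
    build_cases,
    count_experimental_conditions,
    select_no_switch_subset,
)
from .conditions import Policy
from .errors import ReproductionMismatchError
from .fixture import StudyFixture, load_fixture
from .stats import ConcordanceResult, concordance


def _rounded(result: ConcordanceResult) -> dict:
    def pct(p):
        if p is None:
            return None
        return {
            "percent": round(p.estimate * 100, 1),
            "ci_percent": [round(p.ci_low * 100, 2), round(p.ci_high * 100, 2)],
            "fraction": f"{p.k}/{p.n}",
        }

    return {
        "sensitivity": pct(result.sensitivity),
        "specificity": pct(result.specificity),
        "agreement": pct(result.agreement),
        "kappa": round(result.kappa.kappa, 4),
        "kappa_ci": [
            round(result.kappa.ci_low, 4),
            round(result.kappa.ci_high, 4),
        ],
    }


def _check_against_received_flags(fixture: StudyFixture, cases) -> None:
    """The case set derived from the treatment histories must equal the
    (patient, treatment) pairs the source table marks as received with a
    determined category."""
    flagged = fixture.categories.query("received == 1 and category != 'ND'")
    expected = {
        (str(r.patient_id), str(r.treatment))
        for r in flagged.itertuples(index=False)
    }
    built = {
        (str(r.patient_id), str(r.regimen)) for r in cases.itertuples(index=False)
    }
    if built != expected:
        raise ReproductionMismatchError(
            "case set does not match the received-treatment markers: "
            f"extra={sorted(built - expected)}, missing={sorted(expected - built)}"
        )


def reproduce_paper(
    level: float = 0.95, kappa_se: str = "fleiss-cohen-everitt"
) -> dict:
    """Recompute the published analyses from the fixture.

    Returns a nested dict with structural counts (cases, patients
    compared, experimental-condition successes) and the full principal
    and supplementary concordance results.
    """
    fixture = load_fixture()

    principal_cases = build_cases(
        fixture.treatments,
        fixture.evaluations,
        fixture.categories,
        policy=Policy.ANY_PROGRESSION,
    )
    _check_against_received_flags(fixture, principal_cases)
    principal = concordance(principal_cases, level=level, kappa_se=kappa_se)

    subset = select_no_switch_subset(fixture.treatments, fixture.categories)
    if sorted(subset) != fixture.supplementary_patient_ids:
        raise ReproductionMismatchError(
            "no-switch subset does not match the flagged supplementary "
            f"patients: computed {sorted(subset)}"
        )
    supplementary_cases = build_cases(
        fixture.treatments,
        fixture.evaluations,
        fixture.categories,
        policy=Policy.FINAL_EVALUATION,
        patients=subset,
        no_switch_only=True,
    )
    supplementary = concordance(
        supplementary_cases, level=level, kappa_se=kappa_se
    )

    successes, planned = count_experimental_conditions(fixture.categories)
    return {
        "structural": {
            "n_patients": len(fixture.patient_ids),
            "n_cases": int(len(principal_cases)),
            "n_patients_compared": int(principal_cases["patient_id"].nunique()),
            "conditions_successful": successes,
            "conditions_planned": planned,
            "success_rate_percent": round(100.0 * successes / planned, 1),
            "n_supplementary_patients": len(subset),
            "n_supplementary_cases": int(len(supplementary_cases)),
        },
        "principal": {
            "policy": str(Policy.ANY_PROGRESSION),
            "full": principal.to_dict(),
            "rounded": _rounded(principal),
        },
        "supplementary": {
            "policy": str(Policy.FINAL_EVALUATION),
            "patients": sorted(subset),
            "full": supplementary.to_dict(),
            "rounded": _rounded(supplementary),
        },
    }


def _analysis_block(name: str, block: dict) -> list[str]:
    full = block["full"]
    rounded = block["rounded"]
    t = full["table"]
    lines = [
        f"## {name} analysis (policy: {block['policy']})",
        "",
        "|                | assay sensitive | assay resistant |",
        "|----------------|-----------------|-----------------|",
        f"| responder      | {t['tp']:>15} | {t['fn']:>15} |",
        f"| non-responder  | {t['fp']:>15} | {t['tn']:>15} |",
        "",
    ]
    for metric in ("sensitivity", "specificity", "agreement"):
        r = rounded[metric]
        if r is None:
            lines.append(f"- {metric}: undefined (zero margin)")
            continue
        lo, hi = r["ci_percent"]
        lines.append(
            f"- {metric}: {r['percent']} % ({r['fraction']}), "
            f"95 % CI ({lo}; {hi})"
        )
    kap = full["kappa"]
    lines.append(
        f"- kappa: {rounded['kappa']} "
        f"[95 % CI ({rounded['kappa_ci'][0]}; {rounded['kappa_ci'][1]})], "
        f"{kap['interpretation']} (Landis–Koch) / "
        f"{kap['interpretation_magnitude']} (magnitude scale)"
    )
    lines.append("")
    return lines


def report_markdown(report: dict) -> str:
    """Human-readable report mirroring the published contingency table."""
    s = report["structural"]
    lines = [
        "# Ex vivo chemosensitivity vs clinical outcome",
        "",
        f"- patients: {s['n_patients']}",
        f"- experimental conditions: {s['conditions_successful']}/"
        f"{s['conditions_planned']} successful "
        f"({s['success_rate_percent']} %)",
        f"- comparable cases: {s['n_cases']} from "
        f"{s['n_patients_compared']} patients",
        f"- no-switch supplementary subset: {s['n_supplementary_patients']} "
        f"patients, {s['n_supplementary_cases']} cases",
        "",
    ]
    lines += _analysis_block("Principal", report["principal"])
    lines += _analysis_block("Supplementary", report["supplementary"])
    return "\n".join(lines)
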