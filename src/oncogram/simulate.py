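"""Synthetic cohorts with the study's statistical structure.

The generator emulates, per patient: spontaneous (untreated) mortality
drawn from a scaled-Beta law whose median matches the observed 18.1 %
and whose 19-draw range brackets 8.2-30.9 %; per-drug death ratios drawn
from log-normal laws whose medians match the per-treatment cohort
medians; occasional missing treated conditions; treatment histories
(first-line shares, cycle counts, switches, concomitant bevacizumab);
and clinical outcomes linked to a latent per-(patient, regimen) assay
truth with configurable true sensitivity and specificity.

The clinical link is drawn responder-first: each case's responder label
is Bernoulli(responder_rate); the latent assay truth is then sensitive
with probability ``true_assay_sensitivity`` for responders and resistant
with probability ``true_assay_specificity`` for non-responders, so the
downstream pipeline estimates of sensitivity/specificity are unbiased
for the configured values.  The truth is tied to the ratios by rank:
within each treatment the cohort's ratio draws are reassigned so that
truly-resistant cases hold the lowest ranks and truly-sensitive cases
the highest, with unconstrained (non-case) patients filling the middle.
The drawn values are permuted, not redrawn, and the resistant cases'
quantiles are additionally compressed into the lower half of the
below-quartile region: the median and upper distribution are exactly
preserved, the empirical 25th percentile is unchanged, and a guard
margin separates every constrained case from the quartile boundary so
cohort-relative categorization reproduces the latent truth despite
cell-counting noise.

A single root seed feeds named substreams per patient and stage;
enlarging the cohort never perturbs earlier patients' raw draws,
though the cohort-relative rank assignment (intrinsic to a
percentile-based truth) does depend on the whole cohort.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .conditions import Condition, Outcome, Treatment
from .errors import ConfigError

_TREATMENTS = list(Treatment)
_STAGE = {
    "baseline": 1,
    "regimen": 2,
    "clinical": 3,
    "ratio": 4,
    "wells": 5,
    "missing": 6,
    "evals": 7,
}

#: quartile share of resistant calls under the method of percentiles
RESISTANT_QUANTILE = 0.25

MAX_DEATH_FRACTION = 0.95


def _default_drug_effect() -> dict[str, dict[str, float]]:
    # medians are the cohort medians; sigma calibrated so that the
    # expected min/max of 19 log-normal draws (~ +/-1.8 sigma) bracket
    # the observed per-treatment ranges
    return {
        "FU_FA": {"median": 1.343, "sigma": 0.24, "minimum": 0.895, "maximum": 2.102},
        "FOLFIRI": {"median": 1.633, "sigma": 0.36, "minimum": 0.788, "maximum": 2.883},
        "FOLFOX": {"median": 1.787, "sigma": 0.32, "minimum": 1.147, "maximum": 3.613},
    }


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults encode the pilot-study structure: 19 patients, 1000-3000
    cells counted per well, untreated mortality Beta(9.6, 42.2) (median
    0.181), per-drug ratio medians 1.343/1.633/1.787, 2 of 76 conditions
    missing, responder share 13/22, assay truth linked to outcome with
    the study's estimated sensitivity/specificity, first-line regimen
    shares 6/2/11 of 19 and a 4/18 switch rate.
    """

    n_patients: int = 19
    cells_counted_range: tuple[int, int] = (1000, 3000)
    baseline_mortality: tuple[float, float] = (9.6, 42.2)  # Beta(a, b)
    drug_effect: dict[str, dict[str, float]] = field(
        default_factory=_default_drug_effect
    )
    missing_condition_rate: float = 2 / 76
    true_assay_sensitivity: float = 0.846
    true_assay_specificity: float = 0.333
    responder_rate: float = 13 / 22
    first_line_probs: dict[str, float] = field(
        default_factory=lambda: {"FU_FA": 6 / 19, "FOLFIRI": 2 / 19, "FOLFOX": 11 / 19}
    )
    n_cures_probs: dict[int, float] = field(
        default_factory=lambda: {2: 0.3, 3: 0.7}
    )
    switch_probability: float = 4 / 18
    biologic_rate: float = 8 / 19
    counting_noise: bool = True

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ConfigError("n_patients must be >= 1")
        lo, hi = self.cells_counted_range
        if not 1 <= lo <= hi:
            raise ConfigError("cells_counted_range must satisfy 1 <= lo <= hi")
        a, b = self.baseline_mortality
        if a <= 0 or b <= 0:
            raise ConfigError("baseline Beta parameters must be positive")
        for name, prob in [
            ("missing_condition_rate", self.missing_condition_rate),
            ("true_assay_sensitivity", self.true_assay_sensitivity),
            ("true_assay_specificity", self.true_assay_specificity),
            ("responder_rate", self.responder_rate),
            ("switch_probability", self.switch_probability),
            ("biologic_rate", self.biologic_rate),
        ]:
            if not 0.0 <= prob <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1], got {prob}")
        for t in _TREATMENTS:
            spec = self.drug_effect.get(str(t))
            if spec is None:
                raise ConfigError(f"drug_effect missing treatment {t}")
            if spec["median"] <= 0 or spec["sigma"] <= 0:
                raise ConfigError(f"{t}: median and sigma must be positive")
            lo_r = spec.get("minimum", 0.0)
            hi_r = spec.get("maximum", math.inf)
            if not lo_r <= spec["median"] <= hi_r:
                raise ConfigError(
                    f"{t}: median {spec['median']} outside "
                    f"[{lo_r}, {hi_r}] — impossible calibration"
                )
        if abs(sum(self.first_line_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("first_line_probs must sum to 1")
        if abs(sum(self.n_cures_probs.values()) - 1.0) > 1e-9:
            raise ConfigError("n_cures_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if "cells_counted_range" in raw:
            raw["cells_counted_range"] = tuple(raw["cells_counted_range"])
        if "baseline_mortality" in raw:
            raw["baseline_mortality"] = tuple(raw["baseline_mortality"])
        if "n_cures_probs" in raw:
            raw["n_cures_probs"] = {
                int(k): float(v) for k, v in raw["n_cures_probs"].items()
            }
        return cls(**raw)


@dataclass
class SyntheticCohort:
    """Generated tables plus the latent truth for recovery tests."""

    wells: pd.DataFrame
    lines: pd.DataFrame
    evaluations: pd.DataFrame
    truth: pd.DataFrame

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.wells.to_csv(out / "wells.csv", index=False)
        self.lines.to_csv(out / "treatments.csv", index=False)
        self.evaluations.to_csv(out / "evaluations.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)


def _rng(seed: int, stage: str, *ids: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), _STAGE[stage], *map(int, ids)])


def _lognorm_ppf(u: float, median: float, sigma: float) -> float:
    return float(math.exp(math.log(median) + sigma * norm.ppf(u)))


_REGIMEN_COMPONENTS = {
    Treatment.FU_FA: "5-FU+FA",
    Treatment.FOLFIRI: "5-FU+FA+irinotecan",
    Treatment.FOLFOX: "5-FU+FA+oxaliplatin",
}


def simulate_cohort(config: SimulationConfig, seed: int) -> SyntheticCohort:
    """Draw a complete synthetic cohort, reproducible from the seed."""
    config.validate()
    a, b = config.baseline_mortality
    lo_cells, hi_cells = config.cells_counted_range
    first_names = list(config.first_line_probs)
    first_p = np.array([config.first_line_probs[k] for k in first_names])
    cures_n = list(config.n_cures_probs)
    cures_p = np.array([config.n_cures_probs[k] for k in cures_n])

    wells_rows, line_rows, eval_rows, truth_rows = [], [], [], []

    # pass 1: per-patient draws (baseline, history, clinical link,
    # raw ratio quantiles, missing-condition flags)
    patients: list[dict] = []
    for i in range(config.n_patients):
        pid = f"SIM{i + 1:04d}"
        f0 = float(_rng(seed, "baseline", i).beta(a, b))

        rng_reg = _rng(seed, "regimen", i)
        first = Treatment(first_names[rng_reg.choice(len(first_names), p=first_p)])
        n_cures = int(cures_n[rng_reg.choice(len(cures_n), p=cures_p)])
        history = [first] * n_cures
        if n_cures >= 2 and rng_reg.random() < config.switch_probability:
            others = [t for t in _TREATMENTS if t is not first]
            second = others[rng_reg.integers(len(others))]
            history = [first] + [second] * (n_cures - 1)
        biologic = "bevacizumab" if rng_reg.random() < config.biologic_rate else ""
        for k, regimen in enumerate(history, start=1):
            line_rows.append(
                (
                    pid,
                    k,
                    _REGIMEN_COMPONENTS[regimen],
                    int(rng_reg.integers(2, 9)),
                    biologic,
                    0,
                )
            )
        received = list(dict.fromkeys(history))

        # clinical link: responder first, latent assay truth second
        responder: dict[Treatment, bool] = {}
        truth_sensitive: dict[Treatment, bool] = {}
        for t in received:
            rng_cl = _rng(seed, "clinical", i, _TREATMENTS.index(t))
            resp = bool(rng_cl.random() < config.responder_rate)
            p_sensitive = (
                config.true_assay_sensitivity
                if resp
                else 1.0 - config.true_assay_specificity
            )
            responder[t] = resp
            truth_sensitive[t] = bool(rng_cl.random() < p_sensitive)

        u_draw = {}
        dropped = {}
        for t_idx, t in enumerate(_TREATMENTS):
            u_draw[t] = float(_rng(seed, "ratio", i, t_idx).uniform())
            dropped[t] = bool(
                _rng(seed, "missing", i, t_idx).random()
                < config.missing_condition_rate
            )
        patients.append(
            {
                "pid": pid,
                "f0": f0,
                "history": history,
                "received": received,
                "responder": responder,
                "truth_sensitive": truth_sensitive,
                "u": u_draw,
                "dropped": dropped,
            }
        )

    # pass 2: tie latent truth to the ratios by rank within each
    # treatment.  The drawn quantiles are permuted, not redrawn:
    # truly-resistant cases take the lowest ranks, truly-sensitive the
    # highest, unconstrained patients the middle (each group keeps its
    # own draw order).  The middle and upper marginal distribution is
    # exactly preserved while the empirical 25th percentile lands among
    # the unconstrained, far from any constrained case.
    ratios: list[dict[Treatment, float]] = [{} for _ in patients]
    truth_label: list[dict[Treatment, str]] = [{} for _ in patients]
    for t in _TREATMENTS:
        spec = config.drug_effect[str(t)]
        us = np.array([p["u"][t] for p in patients])
        sorted_values = np.sort(us)

        def group(p: dict) -> int:
            sens = p["truth_sensitive"].get(t)
            if sens is None:
                return 1  # unconstrained, middle ranks
            return 2 if sens else 0

        order = sorted(
            range(len(patients)), key=lambda j: (group(patients[j]), us[j])
        )
        # guard margin: compress the resistant cases' quantiles into the
        # lower half of the below-quartile region, so cell-counting noise
        # cannot push a truly-resistant case across the cohort's 25th
        # percentile.  Values at and above the boundary order statistic
        # are untouched, so the empirical quartile itself is unchanged.
        n_cohort = len(patients)
        boundary = int(np.floor(RESISTANT_QUANTILE * (n_cohort - 1)))
        u_boundary = float(sorted_values[boundary])
        k_resistant = sum(1 for j in order if group(patients[j]) == 0)
        for rank, j in enumerate(order):
            u = float(sorted_values[rank])
            if rank < k_resistant:
                u = 0.5 * u_boundary * (rank + 1) / (k_resistant + 1)
            ratios[j][t] = _lognorm_ppf(u, spec["median"], spec["sigma"])
        q25 = float(np.percentile([r[t] for r in ratios], 25))
        for j, p in enumerate(patients):
            sens = p["truth_sensitive"].get(t)
            if sens is None:
                sens = ratios[j][t] >= q25
            truth_label[j][t] = "S" if sens else "R"

    # pass 3: emit wells, truth and evaluations
    for j, p in enumerate(patients):
        pid = p["pid"]
        rng_w = _rng(seed, "wells", patients.index(p))

        def draw_well(fraction: float, condition: Condition) -> None:
            total = int(rng_w.integers(lo_cells, hi_cells + 1))
            fraction = min(max(fraction, 0.0), MAX_DEATH_FRACTION)
            if config.counting_noise:
                dead = int(rng_w.binomial(total, fraction))
            else:
                dead = int(round(fraction * total))
            wells_rows.append((pid, str(condition), total - dead, dead, total))

        draw_well(p["f0"], Condition.UNTREATED)
        for t in _TREATMENTS:
            if not p["dropped"][t]:
                draw_well(ratios[j][t] * p["f0"], Condition(str(t)))
            truth_rows.append(
                (
                    pid,
                    str(t),
                    truth_label[j][t],
                    t in p["received"],
                    p["responder"].get(t),
                )
            )

        # evaluations: one per cure; PD appears only as the final
        # evaluation of a non-responder's regimen run
        rng_e = _rng(seed, "evals", j)
        runs: list[tuple[Treatment, int]] = []
        for regimen in p["history"]:
            if runs and runs[-1][0] is regimen:
                runs[-1] = (regimen, runs[-1][1] + 1)
            else:
                runs.append((regimen, 1))
        k = 0
        for regimen, length in runs:
            resp = p["responder"][regimen]
            for idx in range(length):
                k += 1
                final = idx == length - 1
                if not resp:
                    outcome = Outcome.PD if final else Outcome.SD
                elif final:
                    outcome = [Outcome.SD, Outcome.PR, Outcome.CR][
                        rng_e.choice(3, p=[0.60, 0.25, 0.15])
                    ]
                else:
                    outcome = Outcome.SD
                eval_rows.append((pid, k, str(outcome)))

    return SyntheticCohort(
        wells=pd.DataFrame(
            wells_rows, columns=["patient_id", "condition", "live", "dead", "total"]
        ),
        lines=pd.DataFrame(
            line_rows,
            columns=[
                "patient_id",
                "cure_index",
                "components",
                "cycles",
                "biologics",
                "radiotherapy",
            ],
        ),
        evaluations=pd.DataFrame(
            eval_rows, columns=["patient_id", "evaluation_index", "outcome"]
        ),
        truth=pd.DataFrame(
            truth_rows,
            columns=["patient_id", "treatment", "truth", "is_case", "responder"],
        ),
    )


def population_kappa(config: SimulationConfig) -> float:
    """Kappa implied by the configured responder rate and truth link."""
    r = config.responder_rate
    se = config.true_assay_sensitivity
    sp = config.true_assay_specificity
    po = r * se + (1 - r) * sp
    col_s = r * se + (1 - r) * (1 - sp)
    pe = r * col_s + (1 - r) * (1 - col_s)
    return (po - pe) / (1 - pe)


def run_pipeline_on_cohort(cohort: SyntheticCohort, level: float = 0.95):
    """Score, categorize, build cases and analyse one synthetic cohort."""
    from .categorize import categorize_cohort
    from .clinical import build_cases
    from .scoring import score_wells
    from .stats import concordance

    ratios = score_wells(cohort.wells)
    categories = categorize_cohort(ratios)
    cases = build_cases(cohort.lines, cohort.evaluations, categories)
    return concordance(cases, level=level)


def recovery_experiment(
    config: SimulationConfig,
    n_replicates: int,
    seed: int,
    level: float = 0.95,
) -> dict:
    """Monte-Carlo bias/RMSE and CI coverage of the pipeline estimators.

    Each replicate simulates a cohort from a child seed, runs the full
    pipeline (scoring, percentile categorization, case building,
    concordance) and records the sensitivity, specificity and kappa
    estimates with their intervals.  Returns per-metric summaries (truth,
    Monte-Carlo mean, bias, RMSE, MC standard error, CI coverage) and the
    power of the kappa interval to exclude 0.
    """
    if n_replicates < 1:
        raise ConfigError("n_replicates must be >= 1")
    truths = {
        "sensitivity": config.true_assay_sensitivity,
        "specificity": config.true_assay_specificity,
        "kappa": population_kappa(config),
    }
    estimates: dict[str, list[float]] = {m: [] for m in truths}
    covered: dict[str, list[bool]] = {m: [] for m in truths}
    kappa_excludes_zero: list[bool] = []

    for rep in range(n_replicates):
        child = int(
            np.random.SeedSequence([int(seed), rep]).generate_state(1)[0]
            & 0x7FFFFFFF
        )
        cohort = simulate_cohort(config, seed=child)
        result = run_pipeline_on_cohort(cohort, level=level)
        for metric, est in [
            ("sensitivity", result.sensitivity),
            ("specificity", result.specificity),
        ]:
            if est is None:
                continue
            estimates[metric].append(est.estimate)
            covered[metric].append(
                est.ci_low <= truths[metric] <= est.ci_high
            )
        kap = result.kappa
        estimates["kappa"].append(kap.kappa)
        covered["kappa"].append(kap.ci_low <= truths["kappa"] <= kap.ci_high)
        kappa_excludes_zero.append(kap.ci_low > 0.0)

    summary: dict = {"n_replicates": n_replicates, "metrics": {}}
    for metric, truth in truths.items():
        values = np.asarray(estimates[metric], dtype=float)
        if values.size == 0:
            summary["metrics"][metric] = {"truth": truth, "n": 0}
            continue
        bias = float(values.mean() - truth)
        summary["metrics"][metric] = {
            "truth": truth,
            "n": int(values.size),
            "mean": float(values.mean()),
            "bias": bias,
            "rmse": float(np.sqrt(np.mean((values - truth) ** 2))),
            "mc_se": float(values.std(ddof=1) / np.sqrt(values.size))
            if values.size > 1
            else float("nan"),
            "ci_coverage": float(np.mean(covered[metric])),
        }
    summary["power_kappa_gt_zero"] = float(np.mean(kappa_excludes_zero))
    return summary
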