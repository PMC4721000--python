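"""Regimen mapping, responder coding and case building."""

import pandas as pd
import pytest

from oncogram import (
    ClinicalLabel,
    Policy,
    Treatment,
    build_cases,
    code_response,
    count_experimental_conditions,
    map_regimen,
    select_no_switch_subset,
)
from oncogram.errors import UncodableCaseError, UnmappedRegimenWarning
from oncogram.stats import ContingencyTable


class TestMapRegimen:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ({"5-FU"}, Treatment.FU_FA),
            ({"5-FU", "FA"}, Treatment.FU_FA),
            ({"5-FU", "FA", "irinotecan"}, Treatment.FOLFIRI),
            ({"5-FU", "FA", "oxaliplatin"}, Treatment.FOLFOX),
            (set(), None),
        ],
    )
    def test_component_mapping(self, components, expected):
        assert map_regimen(components) is expected

    def test_biologics_and_radiotherapy_ignored(self):
        assert (
            map_regimen(
                {"5-FU", "FA", "oxaliplatin"},
                biologics={"bevacizumab"},
                radiotherapy=True,
            )
            is Treatment.FOLFOX
        )

    def test_biologic_only_line_maps_to_none(self):
        assert map_regimen(set(), biologics={"panitumumab"}) is None

    def test_unrecognized_combination_warns(self):
        with pytest.warns(UnmappedRegimenWarning):
            assert map_regimen({"5-FU", "cisplatin"}) is None
        with pytest.warns(UnmappedRegimenWarning):
            assert map_regimen({"irinotecan"}) is None


class TestCodeResponse:
    def test_any_progression_policy(self):
        assert (
            code_response(["PD", "SD", "SD"], Policy.ANY_PROGRESSION)
            is ClinicalLabel.NON_RESPONDER
        )

    def test_final_evaluation_policy(self):
        assert (
            code_response(["PD", "SD", "SD"], Policy.FINAL_EVALUATION)
            is ClinicalLabel.RESPONDER
        )

    @pytest.mark.parametrize("policy", list(Policy))
    def test_complete_response(self, policy):
        assert code_response(["CR"], policy) is ClinicalLabel.RESPONDER

    @pytest.mark.parametrize("policy", list(Policy))
    def test_empty_history_uncodable(self, policy):
        with pytest.raises(UncodableCaseError):
            code_response([], policy)


def single_patient_inputs():
    lines = pd.DataFrame(
        [["P1", 1, "5-FU+FA+oxaliplatin", 4, "", 0]],
        columns=[
            "patient_id",
            "cure_index",
            "components",
            "cycles",
            "biologics",
            "radiotherapy",
        ],
    )
    evals = pd.DataFrame(
        [["P1", 1, "SD"]],
        columns=["patient_id", "evaluation_index", "outcome"],
    )
    cats = pd.DataFrame(
        [["P1", "FOLFOX", "S"], ["P1", "FU_FA", "I"], ["P1", "FOLFIRI", "I"]],
        columns=["patient_id", "treatment", "category"],
    )
    return lines, evals, cats


class TestBuildCases:
    def test_single_patient_single_case(self):
        cases = build_cases(*single_patient_inputs())
        assert len(cases) == 1
        row = cases.iloc[0]
        assert (row.regimen, row.assay_binary, row.clinical) == (
            "FOLFOX",
            "SENSITIVE",
            "RESPONDER",
        )

    def test_not_determined_regimen_yields_no_case(self):
        lines, evals, cats = single_patient_inputs()
        cats.loc[cats.treatment == "FOLFOX", "category"] = "ND"
        assert len(build_cases(lines, evals, cats)) == 0

    def test_policy_changes_labels_not_membership(self, fixture):
        kwargs = dict(
            lines=fixture.treatments,
            evaluations=fixture.evaluations,
            categories=fixture.categories,
        )
        a = build_cases(policy=Policy.ANY_PROGRESSION, **kwargs)
        b = build_cases(policy=Policy.FINAL_EVALUATION, **kwargs)
        key = ["patient_id", "regimen"]
        assert a[key].equals(b[key])
        assert a["assay_binary"].equals(b["assay_binary"])

    def test_fixture_principal_cases(self, fixture):
        cases = build_cases(
            fixture.treatments,
            fixture.evaluations,
            fixture.categories,
            policy=Policy.ANY_PROGRESSION,
        )
        assert len(cases) == 22
        assert cases["patient_id"].nunique() == 18
        table = ContingencyTable.from_cases(cases)
        assert (table.tp, table.fn, table.fp, table.tn) == (11, 2, 6, 3)

    def test_fixture_supplementary_cases(self, fixture):
        subset = select_no_switch_subset(fixture.treatments, fixture.categories)
        cases = build_cases(
            fixture.treatments,
            fixture.evaluations,
            fixture.categories,
            policy=Policy.FINAL_EVALUATION,
            patients=subset,
            no_switch_only=True,
        )
        assert len(cases) == 13
        table = ContingencyTable.from_cases(cases)
        assert (table.tp, table.fn, table.fp, table.tn) == (7, 3, 1, 2)


class TestNoSwitchSubset:
    def test_fixture_subset_matches_flags(self, fixture):
        subset = select_no_switch_subset(fixture.treatments, fixture.categories)
        assert sorted(subset) == fixture.supplementary_patient_ids
        assert len(subset) == 13

    def test_switch_excluded(self):
        lines = pd.DataFrame(
            [
                ["P1", 1, "5-FU+FA+oxaliplatin", 4, "", 0],
                ["P1", 2, "5-FU+FA+irinotecan", 4, "", 0],
            ],
            columns=[
                "patient_id",
                "cure_index",
                "components",
                "cycles",
                "biologics",
                "radiotherapy",
            ],
        )
        cats = single_patient_inputs()[2]
        assert select_no_switch_subset(lines, cats) == []

    def test_same_regimen_with_biologic_included(self):
        lines = pd.DataFrame(
            [
                ["P1", 1, "5-FU+FA+oxaliplatin", 6, "bevacizumab", 0],
                ["P1", 2, "5-FU+FA+oxaliplatin", 4, "bevacizumab", 0],
            ],
            columns=[
                "patient_id",
                "cure_index",
                "components",
                "cycles",
                "biologics",
                "radiotherapy",
            ],
        )
        cats = single_patient_inputs()[2]
        assert select_no_switch_subset(lines, cats) == ["P1"]

    def test_no_second_cure_excluded(self):
        lines, _, cats = single_patient_inputs()
        assert select_no_switch_subset(lines, cats) == []


class TestConditionCounts:
    def test_fixture_success_rate(self, fixture):
        successes, planned = count_experimental_conditions(fixture.categories)
        assert (successes, planned) == (74, 76)

    def test_complete_patient(self):
        cats = single_patient_inputs()[2]
        assert count_experimental_conditions(cats) == (4, 4)

    def test_no_missing_conditions_scale(self):
        frames = []
        for i in range(5):
            c = single_patient_inputs()[2]
            c["patient_id"] = f"P{i}"
            frames.append(c)
        assert count_experimental_conditions(pd.concat(frames)) == (20, 20)
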