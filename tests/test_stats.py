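"""Exact binomial intervals, sensitivity/specificity and Cohen's kappa."""

import itertools

import numpy as np
import pytest
import statsmodels.stats.inter_rater as smir

from oncogram import (
    ContingencyTable,
    clopper_pearson,
    cohens_kappa,
    concordance,
    overall_agreement,
    sensitivity_specificity,
)
from oncogram.errors import InvalidInputError
from oncogram.stats import interpret_kappa, interpret_kappa_magnitude


class TestClopperPearson:
    @pytest.mark.parametrize(
        "k,n,low,high",
        [
            (11, 13, 0.5455, 0.9808),
            (7, 10, 0.3475, 0.9333),
            (3, 9, 0.0749, 0.7007),
            (2, 3, 0.0943, 0.9916),
        ],
    )
    def test_published_intervals(self, k, n, low, high):
        est = clopper_pearson(k, n)
        assert est.ci_low == pytest.approx(low, abs=5e-5)
        assert est.ci_high == pytest.approx(high, abs=5e-5)

    def test_boundaries_exact(self):
        assert clopper_pearson(0, 10).ci_low == 0.0
        assert clopper_pearson(10, 10).ci_high == 1.0

    @pytest.mark.parametrize("k,n,level", [(-1, 10, 0.95), (11, 10, 0.95), (5, 0, 0.95), (5, 10, 1.5)])
    def test_invalid_inputs(self, k, n, level):
        with pytest.raises(InvalidInputError):
            clopper_pearson(k, n, level)

    def test_interval_brackets_estimate(self):
        for k, n in [(0, 5), (3, 7), (22, 22), (1, 100)]:
            est = clopper_pearson(k, n)
            assert est.ci_low <= est.estimate <= est.ci_high


class TestSensitivitySpecificity:
    def test_principal_table(self):
        sens, spec = sensitivity_specificity(ContingencyTable(11, 2, 6, 3))
        assert sens.estimate == pytest.approx(11 / 13)
        assert spec.estimate == pytest.approx(3 / 9)

    def test_supplementary_table(self):
        sens, spec = sensitivity_specificity(ContingencyTable(7, 3, 1, 2))
        assert sens.estimate == pytest.approx(0.700, abs=5e-4)
        assert spec.estimate == pytest.approx(0.667, abs=5e-4)

    def test_perfect_assay(self):
        sens, spec = sensitivity_specificity(ContingencyTable(5, 0, 0, 7))
        assert (sens.estimate, spec.estimate) == (1.0, 1.0)

    def test_zero_margin_undefined_not_zero(self):
        sens, spec = sensitivity_specificity(ContingencyTable(0, 0, 6, 3))
        assert sens is None and spec is not None


class TestAgreement:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((11, 2, 6, 3), 14 / 22),
            ((7, 3, 1, 2), 9 / 13),
            ((4, 0, 0, 6), 1.0),
        ],
    )
    def test_values(self, table, expected):
        assert overall_agreement(ContingencyTable(*table)).estimate == pytest.approx(
            expected
        )


class TestKappa:
    def test_principal_estimate(self):
        kap = cohens_kappa(ContingencyTable(11, 2, 6, 3))
        assert kap.kappa == pytest.approx(0.193, abs=5e-4)
        assert kap.ci_low == pytest.approx(-0.196, abs=1e-3)
        assert kap.ci_high == pytest.approx(0.582, abs=1e-3)

    def test_supplementary_estimate(self):
        kap = cohens_kappa(ContingencyTable(7, 3, 1, 2))
        assert kap.kappa == pytest.approx(0.2973, abs=5e-5)
        assert kap.ci_low == pytest.approx(-0.2184, abs=5e-5)
        assert kap.ci_high == pytest.approx(0.8130, abs=5e-5)

    def test_perfect_agreement(self):
        kap = cohens_kappa(ContingencyTable(6, 0, 0, 4))
        assert kap.kappa == pytest.approx(1.0)

    def test_zero_when_independent(self):
        # po equals pe when calls are independent of outcome
        kap = cohens_kappa(ContingencyTable(2, 2, 2, 2))
        assert kap.kappa == pytest.approx(0.0, abs=1e-12)

    def test_label_swap_invariance(self):
        a = cohens_kappa(ContingencyTable(11, 2, 6, 3))
        b = cohens_kappa(ContingencyTable(3, 6, 2, 11))
        assert a.kappa == pytest.approx(b.kappa)
        assert a.se == pytest.approx(b.se)

    def test_degenerate_margins_undefined(self):
        with pytest.raises(InvalidInputError):
            cohens_kappa(ContingencyTable(5, 0, 0, 0))

    def test_reported_ci_clipped_raw_retained(self):
        kap = cohens_kappa(ContingencyTable(9, 1, 1, 9))
        assert -1.0 <= kap.ci_low <= kap.ci_high <= 1.0
        assert kap.ci_low_raw <= kap.ci_low and kap.ci_high <= kap.ci_high_raw

    def test_simple_se_differs_from_default(self):
        table = ContingencyTable(11, 2, 6, 3)
        fce = cohens_kappa(table, se_method="fleiss-cohen-everitt")
        simple = cohens_kappa(table, se_method="simple")
        assert fce.kappa == simple.kappa
        assert fce.se != pytest.approx(simple.se)

    def test_matches_statsmodels(self):
        for cells in [(11, 2, 6, 3), (7, 3, 1, 2), (5, 5, 4, 6), (1, 2, 3, 4)]:
            tp, fn, fp, tn = cells
            ours = cohens_kappa(ContingencyTable(*cells))
            ref = smir.cohens_kappa(np.array([[tp, fn], [fp, tn]]))
            assert ours.kappa == pytest.approx(ref.kappa)
            assert ours.se == pytest.approx(np.sqrt(ref.var_kappa))
            assert ours.ci_low_raw == pytest.approx(ref.kappa_low)
            assert ours.ci_high_raw == pytest.approx(ref.kappa_upp)

    def test_brute_force_case_enumeration_small_tables(self):
        """po/pe/kappa from the closed form equal counting agreements
        over the enumerated cases (all 2x2 tables up to n = 12)."""
        for n in range(2, 13):
            for tp, fn, fp in itertools.combinations_with_replacement(range(n + 1), 3):
                tn = n - tp - fn - fp
                if tn < 0:
                    continue
                clinical = np.array([1] * (tp + fn) + [0] * (fp + tn))
                assay = np.array([1] * tp + [0] * fn + [1] * fp + [0] * tn)
                po = float(np.mean(clinical == assay))
                pe = float(np.mean(clinical[:, None] == assay[None, :]))
                if pe >= 1.0:
                    continue
                kap = cohens_kappa(ContingencyTable(tp, fn, fp, tn))
                assert kap.po == pytest.approx(po)
                assert kap.pe == pytest.approx(pe)
                assert kap.kappa == pytest.approx((po - pe) / (1 - pe))


class TestInterpretation:
    @pytest.mark.parametrize(
        "kappa,band,magnitude",
        [
            (-0.1, "poor", "very weak"),
            (0.193, "slight", "very weak"),
            (0.2973, "fair", "weak"),
            (0.5, "moderate", "moderate"),
            (0.7, "substantial", "strong"),
            (0.95, "almost perfect", "very strong"),
        ],
    )
    def test_bands(self, kappa, band, magnitude):
        assert interpret_kappa(kappa) == band
        assert interpret_kappa_magnitude(kappa) == magnitude


class TestConcordance:
    def test_full_result_serializes(self):
        result = concordance(ContingencyTable(11, 2, 6, 3))
        payload = result.to_dict()
        assert payload["table"]["n"] == 22
        assert payload["sensitivity"]["k"] == 11
        assert payload["kappa"]["interpretation"] == "slight"
        assert payload["kappa"]["interpretation_magnitude"] == "very weak"

    def test_zero_margin_serializes_with_reason(self):
        result = concordance(ContingencyTable(0, 0, 6, 3))
        payload = result.to_dict()
        assert payload["sensitivity"] == {"value": None, "reason": "no responders"}
        assert "sensitivity undefined: zero responder margin" in payload["notes"]
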