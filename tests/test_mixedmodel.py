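"""REML fit, moments oracle, variance proportions and fixed-effect tests."""

import math

import numpy as np
import pandas as pd
import pytest

from folliclepower import (
    DataError,
    FitError,
    HierarchyParams,
    ModelSpec,
    ParameterError,
    VarianceComponents,
    estimate_components_moments,
    fit_mixed_model,
    generate_density_table,
    variance_proportion_ses,
    variance_proportions,
)
from folliclepower import test_fixed_effect as fixed_effect_pvalue


class TestMomentsOracle:
    def test_hand_computed_toy(self, toy_nested, intercept_only_spec):
        vc = estimate_components_moments(toy_nested, intercept_only_spec)
        assert vc.sigma2_section == pytest.approx(2.0)
        assert vc.sigma2_fragment == pytest.approx(7.0)
        assert not vc.truncated

    def test_all_equal_gives_zero_components(self, intercept_only_spec):
        tab = pd.DataFrame(
            {
                "ewe_id": "e",
                "ovary_id": "o",
                "fragment_id": list("AABB"),
                "section_index": [0, 1, 0, 1],
                "y": 4.0,
            }
        )
        vc = estimate_components_moments(tab, intercept_only_spec)
        assert (vc.sigma2_fragment, vc.sigma2_section) == (0.0, 0.0)

    def test_truncation_flagged_when_between_ms_small(self, intercept_only_spec):
        # equal fragment means but positive within-variance
        tab = pd.DataFrame(
            {
                "ewe_id": "e",
                "ovary_id": "o",
                "fragment_id": list("AABB"),
                "section_index": [0, 1, 0, 1],
                "y": [1.0, 3.0, 3.0, 1.0],
            }
        )
        vc = estimate_components_moments(tab, intercept_only_spec)
        assert vc.sigma2_fragment == 0.0
        assert vc.truncated

    def test_unbalanced_table_redirected(self, toy_nested, intercept_only_spec):
        with pytest.raises(DataError, match="fit_mixed_model"):
            estimate_components_moments(toy_nested.iloc[:3], intercept_only_spec)


class TestReml:
    def test_agrees_with_moments_on_balanced_toy(self, toy_nested, intercept_only_spec):
        fit = fit_mixed_model(toy_nested, intercept_only_spec)
        assert fit.vc.sigma2_fragment == pytest.approx(7.0, rel=1e-6)
        assert fit.vc.sigma2_section == pytest.approx(2.0, rel=1e-6)
        assert fit.converged

    def test_degenerate_constant_response(self, intercept_only_spec):
        tab = pd.DataFrame(
            {
                "ewe_id": "e",
                "ovary_id": "o",
                "fragment_id": list("AAABBB"),
                "section_index": [0, 1, 2] * 2,
                "group": ["control"] * 3 + ["treated"] * 3,
                "y": 2.0,
            }
        )
        spec = ModelSpec(fixed_factors=("group",), nesting={"fragment_id": ("group",)})
        fit = fit_mixed_model(tab, spec)
        assert fit.vc.sigma2_fragment == 0.0 and fit.vc.sigma2_section == 0.0
        assert fit.params["group[treated]"] == 0.0
        assert fixed_effect_pvalue(fit, "group") == pytest.approx(1.0)

    def test_needs_replication(self, toy_nested, intercept_only_spec):
        with pytest.raises(DataError):
            fit_mixed_model(toy_nested.iloc[:2], intercept_only_spec)

    def test_relabelling_invariance(self, intercept_only_spec, rng):
        params = HierarchyParams(
            n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=8,
            sections_per_fragment=6, seed=31,
        )
        tab = generate_density_table(params)
        fit = fit_mixed_model(tab, intercept_only_spec)
        relabel = {f"frag{i+1}": f"zz{9-i}" for i in range(8)}
        tab2 = tab.assign(fragment_id=tab["fragment_id"].map(relabel))
        fit2 = fit_mixed_model(tab2, intercept_only_spec)
        assert fit2.vc.sigma2_fragment == pytest.approx(fit.vc.sigma2_fragment, rel=1e-6)
        assert fit2.vc.sigma2_section == pytest.approx(fit.vc.sigma2_section, rel=1e-6)

    def test_shift_invariance(self, intercept_only_spec):
        params = HierarchyParams(
            n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=8,
            sections_per_fragment=6, seed=13,
        )
        tab = generate_density_table(params)
        fit = fit_mixed_model(tab, intercept_only_spec)
        fit2 = fit_mixed_model(tab.assign(y=tab["y"] + 5.0), intercept_only_spec)
        assert fit2.vc.sigma2_fragment == pytest.approx(fit.vc.sigma2_fragment, rel=1e-6)
        assert fit2.vc.sigma2_section == pytest.approx(fit.vc.sigma2_section, rel=1e-6)
        assert fit2.params["Intercept"] == pytest.approx(fit.params["Intercept"] + 5.0)

    def test_parameter_recovery_short(self):
        # small-scale version of the recovery study (full run in acceptance)
        s2f_hat, s2s_hat = [], []
        for r in range(60):
            params = HierarchyParams(
                n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=20,
                sections_per_fragment=40, seed=5000 + r,
            )
            fit = fit_mixed_model(generate_density_table(params), ModelSpec(fixed_factors=()))
            s2f_hat.append(fit.vc.sigma2_fragment)
            s2s_hat.append(fit.vc.sigma2_section)
        assert abs(np.mean(s2s_hat) - 0.993) / 0.993 < 0.05
        assert abs(np.mean(s2f_hat) - 0.116) / 0.116 < 0.15

    def test_estimator_consistency_across_sizes(self):
        # RMSE of the fragment component shrinks as the design grows
        rmses = []
        for F, S in ((4, 4), (12, 12), (36, 36)):
            errs = []
            for r in range(30):
                params = HierarchyParams(
                    n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=F,
                    sections_per_fragment=S, seed=77_000 + 100 * F + r,
                )
                fit = fit_mixed_model(
                    generate_density_table(params), ModelSpec(fixed_factors=())
                )
                errs.append((fit.vc.sigma2_fragment - 0.116) ** 2)
            rmses.append(math.sqrt(float(np.mean(errs))))
        assert rmses[0] > rmses[1] > rmses[2]


class TestVarianceProportions:
    @pytest.mark.parametrize(
        "components,expected",
        [
            ((0.116, 0.993), (10.46, 89.54)),
            ((1.0, 1.0), (50.0, 50.0)),
            ((0.0, 1.0), (0.0, 100.0)),
        ],
    )
    def test_examples(self, components, expected):
        pf, ps = variance_proportions(components)
        assert round(pf, 2) == expected[0]
        assert round(ps, 2) == expected[1]
        assert pf + ps == pytest.approx(100.0)

    def test_undefined_when_both_zero(self):
        with pytest.raises(ParameterError):
            variance_proportions((0.0, 0.0))

    def test_delta_method_ses(self):
        vc = VarianceComponents(0.116, 0.993, se_fragment=0.037, se_section=0.023)
        se_f, se_s = variance_proportion_ses(vc)
        # gradient (100/T²)·(s2s, -s2f) with T = 1.109
        assert se_f == pytest.approx(3.0, abs=0.05)
        assert se_f == se_s  # p_s = 100 - p_f shares the standard error


@pytest.fixture(scope="module")
def ewe_effect_fit():
    params = HierarchyParams(
        n_ewes=2, ovaries_per_ewe=2, fragments_per_ovary=10,
        sections_per_fragment=40, ewe_offsets=(0.0, 3.0), seed=5,
    )
    tab = generate_density_table(params)
    return fit_mixed_model(tab, ModelSpec(fixed_factors=("ewe_id", "ovary_id")))


class TestFixedEffects:
    def test_large_ewe_offset_detected(self, ewe_effect_fit):
        # 3 log10 units is ~3 section SDs: decisive evidence expected
        assert fixed_effect_pvalue(ewe_effect_fit, "ewe_id") < 1e-4

    def test_null_ovary_effect_not_flagged(self, ewe_effect_fit):
        assert fixed_effect_pvalue(ewe_effect_fit, "ovary_id") > 1e-4

    def test_unknown_factor_rejected(self, ewe_effect_fit):
        with pytest.raises(ParameterError):
            fixed_effect_pvalue(ewe_effect_fit, "breed")

    def test_single_level_factor_rejected(self):
        params = HierarchyParams(
            n_ewes=1, ovaries_per_ewe=1, fragments_per_ovary=4,
            sections_per_fragment=4, seed=9,
        )
        tab = generate_density_table(params)
        with pytest.raises(FitError):
            fit_mixed_model(tab, ModelSpec(fixed_factors=("ewe_id",)))

    def test_type_i_error_of_ewe_test(self):
        # under the null the containment F test rejects ~alpha of the time
        hits = 0
        reps = 150
        for r in range(reps):
            params = HierarchyParams(
                n_ewes=2, ovaries_per_ewe=1, fragments_per_ovary=6,
                sections_per_fragment=5, seed=31_000 + r,
            )
            tab = generate_density_table(params)
            fit = fit_mixed_model(tab, ModelSpec(fixed_factors=("ewe_id",)))
            hits += fixed_effect_pvalue(fit, "ewe_id") < 0.05
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * math.sqrt(0.05 * 0.95 / reps)
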