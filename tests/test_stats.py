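"""Statistical layer: agreement regression, group contrasts, ordinal tests."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st
from scipy import stats as sps

from _oracles import kw_h_oracle, kw_permutation_pvalue
from tarsalct import (
    compare_groups_longitudinal,
    compare_groups_terminal,
    cumulative_dose,
    fit_agreement_regression,
    ordinal_group_test,
    simulate_cohort,
)
from tarsalct.cohort import CohortDesign, default_cohort_design
from tarsalct.errors import DesignError, RangeError, SingularFitError
from tarsalct.stats import dunn_z, kruskal_wallis_h


def long_table(rows):
    return pd.DataFrame(rows, columns=["animal_id", "group", "day", "measure", "value"])


def score_table(by_group, measure="histo_bone_destruction"):
    rows = []
    for g, scores in by_group.items():
        for i, s in enumerate(scores):
            rows.append((f"{g}{i}", g, 21, measure, float(s)))
    return long_table(rows)


class TestAgreementRegression:
    def test_identity_line(self):
        pairs = [(x, x) for x in (1.0, 2.0, 3.0, 4.0)]
        fit = fit_agreement_regression(pairs)
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_linregress_on_noisy_data(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(1, 4, 21)
        y = 0.7 * x + 0.4 + rng.normal(0, 0.05, 21)
        fit = fit_agreement_regression(np.column_stack([x, y]))
        ref = sps.linregress(x, y)
        assert fit.slope == pytest.approx(ref.slope, abs=1e-12)
        assert fit.intercept == pytest.approx(ref.intercept, abs=1e-12)
        assert fit.r_squared == pytest.approx(ref.rvalue**2, abs=1e-12)

    def test_too_few_pairs(self):
        with pytest.raises(DesignError):
            fit_agreement_regression([(1.0, 1.0), (2.0, 2.0)])

    def test_constant_predictor_is_singular(self):
        with pytest.raises(SingularFitError):
            fit_agreement_regression([(2.0, 1.0), (2.0, 2.0), (2.0, 3.0)])


def zero_noise_design(means_by_group, measure="stv_mm3"):
    flat = lambda v: (v, v, v, v)
    return CohortDesign(
        group_sizes={g: 6 for g in means_by_group},
        means={measure: {g: flat(v) for g, v in means_by_group.items()}},
        total_sd={measure: {g: flat(0.0) for g in means_by_group}},
        animal_sd={measure: 0.0},
    )


class TestLongitudinal:
    @pytest.mark.parametrize("method", ["two_way_anova", "mixed_effects"])
    def test_forced_separation_at_zero_variance(self, method):
        # day-21 STV endpoints with zero residual and zero animal SD
        design = zero_noise_design({"untreated": 19.5, "prednisolone": 10.7})
        table = simulate_cohort(design, seed=0)
        results = compare_groups_longitudinal(table, "stv_mm3", method=method)
        day21 = next(r for r in results if r.contrast.endswith("day 21"))
        assert day21.p_value < 1e-6
        assert day21.group_stats["untreated"][0] == pytest.approx(19.5, abs=1e-12)
        assert day21.group_stats["prednisolone"][0] == pytest.approx(10.7, abs=1e-12)

    def test_single_group_is_design_error(self):
        design = zero_noise_design({"untreated": 19.5})
        table = simulate_cohort(design, seed=0)
        with pytest.raises(DesignError):
            compare_groups_longitudinal(table, "stv_mm3")

    def test_empty_cell_is_design_error_naming_cell(self):
        table = simulate_cohort(default_cohort_design(), seed=0)
        sel = (table.group == "prednisolone") & (table.day == 14)
        with pytest.raises(DesignError, match="prednisolone.*14"):
            compare_groups_longitudinal(table[~sel], "bv_mm3")

    def test_methods_agree_when_animal_variance_is_zero(self):
        # balanced design, no animal-level variance: the fixed-effect cell
        # means (hence contrasts) must coincide between OLS and REML
        design = default_cohort_design()
        design = CohortDesign(
            group_sizes=design.group_sizes,
            means=design.means,
            total_sd=design.total_sd,
            animal_sd={m: 0.0 for m in design.animal_sd},
            histo_probs={},
        )
        table = simulate_cohort(design, seed=3)
        anova = compare_groups_longitudinal(table, "bv_mm3", method="two_way_anova")
        mixed = compare_groups_longitudinal(table, "bv_mm3", method="mixed_effects")
        a = {r.contrast: r for r in anova if "vs" in r.contrast}
        b = {r.contrast: r for r in mixed if "vs" in r.contrast}
        assert set(a) == set(b)
        for c in a:
            est_a = a[c].group_stats[c.split(" vs ")[0]][0] - list(a[c].group_stats.values())[1][0]
            est_b = b[c].group_stats[c.split(" vs ")[0]][0] - list(b[c].group_stats.values())[1][0]
            assert est_a == pytest.approx(est_b, abs=1e-9)

    def test_caliper_defaults_to_change_from_baseline(self):
        design = zero_noise_design(
            {"untreated": 2.6, "prednisolone": 2.6}, measure="caliper_mm"
        )
        table = simulate_cohort(design, seed=0)
        results = compare_groups_longitudinal(table, "caliper_mm", method="two_way_anova")
        day21 = next(r for r in results if r.contrast.endswith("day 21"))
        # identical trajectories: change-from-baseline means are exactly 0
        assert day21.group_stats["untreated"][0] == pytest.approx(0.0, abs=1e-12)

    def test_all_pvalues_in_unit_interval(self):
        table = simulate_cohort(default_cohort_design(), seed=9)
        for measure in ("bv_mm3", "stv_mm3", "caliper_mm"):
            for r in compare_groups_longitudinal(table, measure):
                assert 0.0 <= r.p_value <= 1.0
                if r.p_adjusted is not None:
                    assert 0.0 <= r.p_adjusted <= 1.0


class TestTerminalAnova:
    def test_identical_groups_give_f0_p1(self):
        table = long_table(
            [(f"a{i}", g, 21, "ex_vivo_bv_mm3", 2.0) for g in ("untreated", "prednisolone") for i in range(3)]
        )
        res = compare_groups_terminal(table)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_forced_separation_with_tiny_jitter(self):
        rows = []
        for i in range(3):
            rows.append((f"u{i}", "untreated", 21, "ex_vivo_bv_mm3", 1.4 + i * 1e-6))
            rows.append((f"p{i}", "prednisolone", 21, "ex_vivo_bv_mm3", 2.9 + i * 1e-6))
        res = compare_groups_terminal(long_table(rows))
        assert res.p_value < 1e-6

    def test_f_statistic_matches_hand_computation(self):
        # groups {1,2,3} and {4,5,6}: SSB = 13.5, SSW = 4, F = 13.5 / 1 = 13.5
        rows = [(f"u{i}", "untreated", 21, "ex_vivo_bv_mm3", float(v)) for i, v in enumerate([1, 2, 3])]
        rows += [(f"p{i}", "prednisolone", 21, "ex_vivo_bv_mm3", float(v)) for i, v in enumerate([4, 5, 6])]
        res = compare_groups_terminal(long_table(rows))
        assert res.statistic == pytest.approx(13.5, abs=1e-12)
        assert res.p_value == pytest.approx(float(sps.f.sf(13.5, 1, 4)), abs=1e-12)

    def test_undersized_group_is_design_error(self):
        rows = [("u0", "untreated", 21, "ex_vivo_bv_mm3", 1.0)]
        rows += [(f"p{i}", "prednisolone", 21, "ex_vivo_bv_mm3", 2.0) for i in range(3)]
        with pytest.raises(DesignError):
            compare_groups_terminal(long_table(rows))


class TestOrdinal:
    def test_all_scores_equal_gives_h0_p1(self):
        table = score_table({"naive": [2] * 4, "untreated": [2] * 4})
        omni = ordinal_group_test(table, "histo_bone_destruction")[0]
        assert omni.statistic == 0.0
        assert omni.p_value == 1.0

    def test_h_matches_exhaustive_permutation_oracle(self):
        groups = [[0, 0, 0], [4, 4, 4], [2, 2, 2]]
        h, _ = kruskal_wallis_h([np.asarray(g, float) for g in groups])
        assert h == pytest.approx(kw_h_oracle(groups), abs=1e-12)
        assert h == pytest.approx(8.0, abs=1e-12)
        p_perm, total = kw_permutation_pvalue(groups)
        assert total == 1680
        assert p_perm < 0.05  # fully separated groups are extreme

    def test_dunn_flags_untreated_vs_naive(self):
        table = score_table(
            {"untreated": [3, 3, 4, 4, 3, 4], "naive": [0, 0, 0, 0, 0, 0]}
        )
        results = ordinal_group_test(table, "histo_bone_destruction")
        dunn = next(r for r in results if r.test_name == "dunn")
        assert dunn.p_adjusted < 0.05
        # direction confirmed by the exact permutation null of H
        p_perm, _ = kw_permutation_pvalue(
            [[3, 3, 4, 4, 3, 4], [0, 0, 0], [0, 0, 0]]
        )
        assert p_perm < 0.05

    def test_off_scale_scores_rejected(self):
        table = score_table({"naive": [0, 1], "untreated": [3, 7]})
        with pytest.raises(RangeError):
            ordinal_group_test(table, "histo_bone_destruction")

    @given(
        scores=st.lists(
            st.lists(st.integers(0, 4), min_size=3, max_size=6), min_size=2, max_size=3
        )
    )
    def test_h_invariant_under_monotone_transform(self, scores):
        samples = [np.asarray(s, dtype=float) for s in scores]
        h1, _ = kruskal_wallis_h(samples)
        h2, _ = kruskal_wallis_h([3.0 * s**3 + 2.0 for s in samples])
        assert h1 == pytest.approx(h2, abs=1e-9)

    def test_dunn_z_hand_worked_example(self):
        # naive {0 x6} vs untreated {3,3,4,4,3,4}: mean ranks 3.5 and 9.5,
        # tie term 258, sigma2 = 13 - 258/132, z = 6 / sqrt(2 sigma2 / 6)
        samples = {
            "naive": np.zeros(6),
            "untreated": np.array([3.0, 3, 4, 4, 3, 4]),
        }
        sigma2 = 13.0 - 258.0 / 132.0
        expected = 6.0 / np.sqrt(sigma2 * (2.0 / 6.0))
        assert dunn_z(samples, "untreated", "naive") == pytest.approx(expected, abs=1e-12)


class TestDose:
    def test_four_sessions_at_1100(self):
        assert cumulative_dose(4, 1100.0) == 4400.0

    @pytest.mark.parametrize("n,d,expected", [(0, 1100.0, 0.0), (3, 1100.0, 3300.0)])
    def test_arithmetic(self, n, d, expected):
        assert cumulative_dose(n, d) == expected

    def test_negative_inputs_rejected(self):
        with pytest.raises(RangeError):
            cumulative_dose(-1, 1100.0)
        with pytest.raises(RangeError):
            cumulative_dose(4, -5.0)
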