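import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cubkit.codon_stats import CompositionSummary, composition_summary
from cubkit.selection_forces import (
    cai_group_comparison,
    detect_outliers,
    neutrality_fit,
    pr2_coordinates,
    selection_contribution,
    spearman_matrix,
)
from cubkit.sequence_io import CodingSequence


def comp_with_thirds(a3, c3, u3, g3):
    """Composition summary with chosen synonymous third-position percents."""
    return CompositionSummary(
        a_pct=25, c_pct=25, u_pct=25, g_pct=25, gc_pct=50,
        a3s_pct=a3, c3s_pct=c3, u3s_pct=u3, g3s_pct=g3,
        gc1_pct=50, gc2_pct=50, gc3_pct=c3 + g3, gc12_pct=50,
        gc3s=(c3 + g3) / 100,
    )


class TestPR2:
    def test_balanced_thirds_give_center(self):
        p = pr2_coordinates(comp_with_thirds(25, 25, 25, 25))
        assert (p.at_bias, p.gc_bias) == (0.5, 0.5)

    def test_at_bias_arithmetic(self):
        p = pr2_coordinates(comp_with_thirds(30, 30, 10, 30))
        assert p.at_bias == pytest.approx(0.75)

    def test_zero_denominator_flagged_not_silently_zero(self):
        p = pr2_coordinates(comp_with_thirds(50, 0, 50, 0))
        assert not p.gc_defined
        assert math.isnan(p.gc_bias)
        assert p.at_defined

    def test_scale_invariance_on_real_sequence(self):
        seq = CodingSequence("x", "GGAGGCAAATTTGGGTAC")
        p1 = pr2_coordinates(composition_summary(seq))
        p10 = pr2_coordinates(
            composition_summary(CodingSequence("x10", seq.seq * 10))
        )
        assert p1.at_bias == pytest.approx(p10.at_bias)
        assert p1.gc_bias == pytest.approx(p10.gc_bias)


class TestDetectOutliers:
    def test_identical_values_keep_all(self):
        kept, removed = detect_outliers([0.5] * 20, [0.4] * 20)
        assert len(kept) == 20 and removed.size == 0

    def test_single_extreme_point_removed(self):
        rng = np.random.default_rng(1)
        gc3 = list(0.5 + 0.01 * rng.standard_normal(99)) + [0.99]
        gc12 = list(0.45 + 0.01 * rng.standard_normal(99)) + [0.45]
        kept, removed = detect_outliers(gc3, gc12)
        assert 99 in removed  # the planted extreme point is caught
        assert len(kept) >= 90  # near-normal bulk mostly survives the fences

    def test_method_none_is_identity(self):
        kept, removed = detect_outliers([0.1, 0.9], [0.1, 0.9], method="none")
        assert len(kept) == 2 and removed.size == 0

    def test_too_few_points_warns_and_keeps_all(self):
        with pytest.warns(UserWarning, match="fewer than 8"):
            kept, removed = detect_outliers([1, 2, 3], [1, 2, 3])
        assert removed.size == 0

    def test_sd3_method_runs(self):
        kept, _ = detect_outliers(np.linspace(0, 1, 30), np.linspace(0, 1, 30), "sd3")
        assert len(kept) == 30


class TestNeutralityFit:
    def test_diagonal_points_mean_pure_mutation_pressure(self):
        x = np.linspace(0.3, 0.7, 20)
        fit = neutrality_fit(x, x, outlier_method="none")
        assert fit.slope == pytest.approx(1.0)
        assert fit.mutation_pct == pytest.approx(100.0)

    def test_horizontal_points_mean_pure_selection(self):
        x = np.linspace(0.3, 0.7, 20)
        fit = neutrality_fit(np.full_like(x, 0.45), x, outlier_method="none")
        assert fit.slope == pytest.approx(0.0)
        assert fit.selection_pct == pytest.approx(100.0)

    def test_recovers_generating_slope(self):
        rng = np.random.default_rng(11)
        gc3 = rng.uniform(0.2, 0.8, 500)
        gc12 = 0.2 + 0.3 * gc3 + rng.normal(0, 0.005, 500)
        fit = neutrality_fit(gc12, gc3)
        assert fit.slope == pytest.approx(0.3, abs=0.05)

    def test_constant_gc3_raises(self):
        with pytest.raises(ValueError, match="constant"):
            neutrality_fit([0.4, 0.5, 0.6], [0.5, 0.5, 0.5], outlier_method="none")

    def test_recovery_within_three_standard_errors_over_replicates(self):
        misses = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            gc3 = rng.uniform(0.2, 0.8, 200)
            gc12 = 0.1 + 0.4 * gc3 + rng.normal(0, 0.01, 200)
            res = stats.linregress(gc3, gc12)
            fit = neutrality_fit(gc12, gc3, outlier_method="none")
            if abs(fit.slope - 0.4) > 3 * res.stderr:
                misses += 1
        assert misses == 0


class TestSelectionContribution:
    @pytest.mark.parametrize(
        "slope,selection",
        [(-0.243, 75.7), (0.0, 100.0), (1.0, 0.0), (-1.5, 0.0), (0.5, 50.0)],
    )
    def test_values(self, slope, selection):
        sel, mut = selection_contribution(slope)
        assert sel == pytest.approx(selection)
        assert sel + mut == 100.0

    def test_sums_to_100_for_any_slope(self):
        for slope in np.linspace(-3, 3, 61):
            sel, mut = selection_contribution(float(slope))
            assert sel + mut == 100.0

    def test_non_finite_slope_rejected(self):
        with pytest.raises(ValueError):
            selection_contribution(float("nan"))


def make_metrics(n=30, seed=0):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {c: rng.normal(size=n) for c in
         ["A3s%", "C3s%", "U3s%", "G3s%", "GC3%", "ENC",
          "A%", "C%", "U%", "G%", "GC%", "Gravy", "Aroma"]}
    )
    return df


class TestSpearmanMatrix:
    def test_shape_and_layout(self):
        m = spearman_matrix(make_metrics())
        assert m.rho.shape == (6, 7)
        assert list(m.rho.index) == ["A3s%", "C3s%", "U3s%", "G3s%", "GC3%", "ENC"]

    def test_perfect_correlations(self):
        df = make_metrics()
        df["A%"] = df["A3s%"]
        df["C%"] = -df["C3s%"]
        m = spearman_matrix(df)
        assert m.rho.loc["A3s%", "A%"] == pytest.approx(1.0)
        assert m.rho.loc["C3s%", "C%"] == pytest.approx(-1.0)
        assert m.stars.loc["A3s%", "A%"] == "**"

    def test_matches_rank_difference_formula(self):
        # untied ranks: rho = 1 - 6*sum(d^2)/(n(n^2-1))
        df = make_metrics(n=6, seed=3)
        m = spearman_matrix(df)
        x = df["GC3%"].rank().to_numpy()
        y = df["GC%"].rank().to_numpy()
        d2 = ((x - y) ** 2).sum()
        expected = 1 - 6 * d2 / (6 * 35)
        assert m.rho.loc["GC3%", "GC%"] == pytest.approx(expected, abs=1e-8)

    def test_constant_column_flagged_nan(self):
        df = make_metrics()
        df["Gravy"] = 1.23
        m = spearman_matrix(df)
        assert m.rho["Gravy"].isna().all()
        assert (m.stars["Gravy"] == "").all()

    def test_too_few_rows_raises(self):
        with pytest.raises(ValueError, match=">= 5"):
            spearman_matrix(make_metrics(n=4))

    def test_monotone_transform_invariance(self):
        df = make_metrics(seed=9)
        m1 = spearman_matrix(df)
        df2 = df.copy()
        df2["GC%"] = np.exp(df2["GC%"])  # strictly monotone
        df2["ENC"] = df2["ENC"] ** 3
        m2 = spearman_matrix(df2)
        pd.testing.assert_frame_equal(m1.rho, m2.rho)


class TestCAIGroupComparison:
    def test_identical_groups_share_a_letter(self):
        res = cai_group_comparison({"a": [1, 2, 3, 4], "b": [1, 2, 3, 4]})
        assert res.pairwise["p"].iloc[0] > 0.9
        assert res.letters["a"] == res.letters["b"]

    def test_disjoint_groups_hit_exact_minimal_p(self):
        res = cai_group_comparison(
            {"lo": [1, 2, 3, 4, 5], "hi": [101, 102, 103, 104, 105]}
        )
        # exact two-sided Mann-Whitney floor for n=m=5: 2 / C(10,5)
        assert res.pairwise["p"].iloc[0] == pytest.approx(2 / 252)
        assert res.letters["lo"] != res.letters["hi"]

    def test_shifted_group_gets_distinct_letter(self):
        rng = np.random.default_rng(4)
        groups = {
            "g1": rng.normal(0, 1, 10),
            "g2": rng.normal(0, 1, 10),
            "g3": rng.normal(50, 1, 10),
        }
        res = cai_group_comparison(groups)
        assert res.letters["g3"] not in (res.letters["g1"], res.letters["g2"])
        assert set(res.letters["g1"]) & set(res.letters["g2"])

    def test_degenerate_group_sizes_raise(self):
        with pytest.raises(ValueError):
            cai_group_comparison({"a": [1, 2], "b": [1, 2, 3]})
        with pytest.raises(ValueError):
            cai_group_comparison({"a": [1, 2, 3]})

    def test_bh_adjustment_column_present(self):
        res = cai_group_comparison(
            {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}, adjust=True
        )
        assert "p_adj" in res.pairwise.columns
        assert (res.pairwise["p_adj"] >= res.pairwise["p"] - 1e-12).all()
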