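"""Volume conversion, Grubbs screening, ANOVA/Tukey, and the uncertainty budget."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dropvol.synthetic import HierarchicalDiameterSpec, generate_hierarchical_diameters
from dropvol.volume_stats import (
    anova_oneway,
    diameter_from_volume,
    droplet_volume,
    grubbs_critical,
    grubbs_screen,
    relative_sd,
    summarize_well,
    tukey_pairwise,
    uncertainty_budget,
    uncertainty_budget_from_ms,
)


class TestDropletVolume:
    @pytest.mark.parametrize(
        "d,expected,tol",
        [
            (0.0, 0.0, 1e-15),
            (110.89, 0.7139631, 1e-6),  # (pi/6) * 110.89^3 / 1e6
            (124.07046, 1.0, 1e-3),  # inverse cube root of 6e6/pi
        ],
    )
    def test_closed_forms(self, d, expected, tol):
        assert droplet_volume(d) == pytest.approx(expected, abs=tol)

    def test_negative_diameter_rejected(self):
        with pytest.raises(ValueError):
            droplet_volume(-1.0)

    @given(st.floats(min_value=1.0, max_value=500.0))
    @settings(deadline=None, max_examples=50)
    def test_cubic_scaling_and_inverse(self, d):
        assert droplet_volume(2 * d) == pytest.approx(8 * droplet_volume(d), rel=1e-12)
        assert diameter_from_volume(droplet_volume(d)) == pytest.approx(d, rel=1e-12)


class TestSummarizeWell:
    def test_single_droplet_flagged_with_zero_sd(self):
        s = summarize_well([111.0], well="W1")
        assert s.single_droplet
        assert s.sd_volume_nl == 0.0
        assert s.mean_volume_nl == pytest.approx(droplet_volume(111.0))

    def test_mean_of_volumes_exceeds_volume_of_mean(self):
        # Jensen: the cube is convex, so mean(V(d)) > V(mean(d)) for non-constant d
        s = summarize_well([110.0, 112.0])
        assert s.mean_volume_nl > droplet_volume(111.0)
        assert s.mean_volume_nl == pytest.approx(
            (droplet_volume(110.0) + droplet_volume(112.0)) / 2, rel=1e-12
        )

    def test_constant_input_zero_sd(self):
        s = summarize_well([111.0] * 200)
        assert s.sd_volume_nl == 0.0
        assert s.n_droplets == 200

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            summarize_well([])

    @given(
        st.lists(st.floats(min_value=50.0, max_value=200.0), min_size=2, max_size=30).filter(
            lambda x: np.std(x) > 1e-9
        )
    )
    @settings(deadline=None, max_examples=50)
    def test_jensen_strict_for_dispersed_diameters(self, diams):
        s = summarize_well(diams)
        assert s.mean_volume_nl > droplet_volume(float(np.mean(diams)))


class TestGrubbs:
    def test_flags_published_example(self):
        # G = 1.7727 > critical 1.7150 at n=5, alpha=0.05 (two-sided)
        res = grubbs_screen([0.70, 0.71, 0.72, 0.73, 0.90], alpha=0.05)
        assert res.outlier_labels == [4]
        _, value, g, g_crit = res.outliers[0]
        assert value == 0.90
        assert g == pytest.approx(1.7727, abs=1e-3)
        assert g_crit == pytest.approx(1.7150, abs=1e-3)

    def test_identical_values_no_outliers(self):
        res = grubbs_screen([0.71, 0.71, 0.71])
        assert res.outliers == []

    def test_needs_three_values(self):
        with pytest.raises(ValueError):
            grubbs_screen([1.0, 2.0])

    def test_idempotent_after_convergence(self):
        rng = np.random.default_rng(2)
        x = np.concatenate([rng.normal(0.715, 0.01, 17), [0.9]])
        first = grubbs_screen(x)
        assert len(first.outliers) >= 1
        again = grubbs_screen(first.kept_values)
        assert again.outliers == []

    def test_planted_outlier_well_flagged_in_study_layout(self):
        # 18 well means (6 wells x 3 days) with one planted high well, as in
        # the generator-comparison screens that flagged 1-2 wells per set-up
        df = generate_hierarchical_diameters(HierarchicalDiameterSpec(), seed=21)
        means = df.groupby("well")["diameter_um"].mean()
        vols = droplet_volume(means.to_numpy())
        vols[means.index.get_loc("D1W3")] += 0.12  # ~10 sigma shift
        res = grubbs_screen(vols, labels=list(means.index))
        assert res.outlier_labels == ["D1W3"]

    def test_critical_value_against_reference_table(self):
        # published two-sided 5% points: n=10 -> 2.290, n=20 -> 2.709
        assert grubbs_critical(10, 0.05) == pytest.approx(2.290, abs=2e-3)
        assert grubbs_critical(20, 0.05) == pytest.approx(2.709, abs=2e-3)


class TestAnova:
    def test_hand_computed_example(self):
        res = anova_oneway([[1, 2, 3], [2, 3, 4]])
        assert res.ms_between == pytest.approx(1.5)
        assert res.ms_within == pytest.approx(1.0)
        assert res.f_statistic == pytest.approx(1.5)

    def test_identical_groups_no_between_signal(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert res.ms_between == 0.0
        assert res.f_statistic == 0.0

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = [rng.normal(m, 1.0, n) for m, n in [(0, 8), (0.5, 11), (1.0, 6)]]
        res = anova_oneway(groups)
        ref = stats.f_oneway(*groups)
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_group_needs_two_values(self):
        with pytest.raises(ValueError):
            anova_oneway([[1.0], [2.0, 3.0]])

    def test_variance_component_recovery(self):
        # 6 wells x 3 days x 200 droplets with between-day SD 0.02 nL and
        # within SD 0.04 nL at the volume scale: the ANOVA on volumes grouped
        # by day recovers the within-group variance within 15%
        sd_within_d = 0.04 / 0.019316  # volume SD -> diameter SD at 110.94 um
        sd_day_d = 0.02 / 0.019316
        spec = HierarchicalDiameterSpec(
            within_well_sd_um=sd_within_d,
            between_well_sd_um=0.0,
            between_day_sd_um=sd_day_d,
            droplets_per_well=200,
        )
        df = generate_hierarchical_diameters(spec, seed=13)
        vols = droplet_volume(df.diameter_um.to_numpy())
        groups = {d: vols[(df.day == d).to_numpy()] for d in (1, 2, 3)}
        res = anova_oneway(groups)
        assert res.ms_within == pytest.approx(0.04**2, rel=0.15)
        n = 1200
        sigma_day_sq = (res.ms_between - res.ms_within) / n
        assert sigma_day_sq == pytest.approx(0.02**2, rel=1.0)  # 2 df estimate


class TestTukey:
    def test_identical_groups_not_significant(self):
        t = tukey_pairwise({"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]})
        assert not t.significant.any()

    def test_generator_shift_detected(self):
        # two same-mean groups and one shifted by +0.024 nL with study-like
        # SDs: the same-mean pair is not significant, the shifted pairs are
        rng = np.random.default_rng(17)
        dg8_nib = rng.normal(0.715, 0.012, 18)
        dg8_inrim = rng.normal(0.715, 0.010, 18)
        dg32 = rng.normal(0.739, 0.013, 18)
        t = tukey_pairwise({"dg8_nib": dg8_nib, "dg8_inrim": dg8_inrim, "dg32": dg32})
        row = lambda a, b: t[(t.group1 == a) & (t.group2 == b)].iloc[0]
        assert not row("dg8_nib", "dg8_inrim").significant
        assert row("dg8_nib", "dg32").significant
        assert row("dg8_inrim", "dg32").significant

    def test_extreme_group_significant_against_both(self):
        t = tukey_pairwise([[1.0, 1.1, 0.9], [1.05, 0.95, 1.0], [5.0, 5.1, 4.9]])
        sig_pairs = t[t.significant]
        assert len(sig_pairs) == 2
        assert all(2 in (r.group1, r.group2) for r in sig_pairs.itertuples())


class TestUncertaintyBudget:
    def test_worked_example_branch_ip1(self):
        b = uncertainty_budget_from_ms(9e-4, 2.5e-3, n=6, N=3, k=2.1)
        assert b.branch == "ip1"
        assert b.u_r == pytest.approx(0.012247, abs=1e-6)
        assert b.u_ip == pytest.approx(0.009428, abs=1e-6)
        assert b.u_c == pytest.approx(0.015456, abs=1e-6)
        assert b.U == pytest.approx(0.032458, abs=1e-6)

    def test_branch_ip2_when_between_not_larger(self):
        b = uncertainty_budget_from_ms(9e-4, 5e-4, n=6, N=3)
        assert b.branch == "ip2"
        assert b.u_ip == pytest.approx(0.004273, abs=1e-6)

    def test_equal_mean_squares_take_ip2(self):
        b = uncertainty_budget_from_ms(9e-4, 9e-4, n=6, N=3)
        assert b.branch == "ip2"
        assert b.u_ip > 0

    def test_combined_dominates_repeatability(self):
        for msb in (1e-4, 9e-4, 5e-3):
            b = uncertainty_budget_from_ms(9e-4, msb, n=6, N=3)
            assert b.u_c >= b.u_r
            assert b.U == pytest.approx(b.k * b.u_c, rel=1e-15)

    def test_invalid_design_rejected(self):
        with pytest.raises(ValueError):
            uncertainty_budget_from_ms(1e-3, 1e-3, n=1, N=3)
        with pytest.raises(ValueError):
            uncertainty_budget_from_ms(1e-3, 1e-3, n=6, N=1)

    def test_identical_group_means_drive_budget_to_ip2(self):
        rng = np.random.default_rng(23)
        base = rng.normal(0.715, 0.01, 6)
        groups = {d: base.copy() for d in (1, 2, 3)}  # no between-group effect
        b = uncertainty_budget(groups)
        assert b.branch == "ip2"
        assert b.u_ip < b.u_r

    def test_unbalanced_groups_use_harmonic_mean_n(self):
        groups = {1: [1.0, 2.0, 3.0, 4.0], 2: [2.0, 3.0], 3: [1.5, 2.5, 3.5]}
        b = uncertainty_budget(groups)
        sizes = np.array([4, 2, 3], dtype=float)
        assert b.n == pytest.approx(3 / (1 / sizes).sum())


class TestRelativeSD:
    def test_constant_values_zero(self):
        assert relative_sd([10.0, 10.0, 10.0]) == 0.0

    def test_hand_computed(self):
        assert relative_sd([9.5, 10.5]) == pytest.approx(7.0711, abs=1e-3)

    def test_recovery_at_study_scale(self):
        # 18 inter-well volumes generated at 5.5% RSD: a single draw of the
        # sample RSD has SD ~0.9 points, so check the mean over 50 replicates
        rng = np.random.default_rng(29)
        rsds = [relative_sd(rng.normal(0.715, 0.055 * 0.715, 18)) for _ in range(50)]
        assert np.mean(rsds) == pytest.approx(5.5, abs=1.0)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            relative_sd([-1.0, 1.0])
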