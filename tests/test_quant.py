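"""Poisson quantification, QC, rescaling, bias and GM% arithmetic."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dropvol import quant
from dropvol.quant import (
    ReactionResult,
    SaturationError,
    bias_percent,
    concentration_from_counts,
    gm_percent,
    gm_percent_from_counts,
    qc_filter,
    rescale_concentration,
    rsd_repeatability,
    rsd_reproducibility,
    volume_induced_bias,
)


class TestConcentration:
    def test_no_positives_gives_zero(self):
        assert concentration_from_counts(0, 20000, 0.85) == 0.0

    def test_hand_computed_example(self):
        # -ln(0.75) / 8.5e-4 = 338.45 copies/uL
        assert concentration_from_counts(5000, 20000, 0.85, 1.0) == pytest.approx(338.45, abs=0.01)

    def test_inverts_published_group_mean(self):
        # the positive fraction implied by 115,351 copies/uL at Vd=0.85, D=100
        tc = concentration_from_counts(
            round(0.62487 * 15000), 15000, 0.85, 100.0
        )
        assert tc == pytest.approx(115_351, rel=1e-3)

    def test_saturation_and_domain_errors(self):
        with pytest.raises(SaturationError):
            concentration_from_counts(100, 100, 0.85)
        with pytest.raises(ValueError):
            concentration_from_counts(101, 100, 0.85)
        with pytest.raises(ValueError):
            concentration_from_counts(5, 100, 0.0)

    @given(st.integers(min_value=1, max_value=14998))
    @settings(deadline=None, max_examples=100)
    def test_strictly_increasing_in_positives(self, p):
        lo = concentration_from_counts(p, 15000, 0.85)
        hi = concentration_from_counts(p + 1, 15000, 0.85)
        assert hi > lo

    def test_linear_poisson_limit_at_low_occupancy(self):
        # -ln(1-f) = f + f^2/2 + ...: at low positive fraction f the relative
        # deviation from the linear estimate is f/2 (~1% at f = 0.02)
        for p in (30, 150, 300):
            r, vd = 15000, 0.85
            f = p / r
            poisson = concentration_from_counts(p, r, vd)
            linear = f / (vd * 1e-3)
            assert (poisson - linear) / linear == pytest.approx(f / 2, rel=0.05)


class TestRescaling:
    @pytest.mark.parametrize(
        "tc,v_old,v_new,expected",
        [
            (115_351, 0.85, 0.715, 137_131),
            (114_131, 0.85, 0.739, 131_274),
            (119_230, 0.85, 0.715, 141_742),
            (117_369, 0.85, 0.739, 134_998),
        ],
    )
    def test_published_volume_corrections(self, tc, v_old, v_new, expected):
        assert round(rescale_concentration(tc, v_old, v_new)) == expected

    def test_identity_and_invariant(self):
        assert rescale_concentration(123.4, 0.85, 0.85) == 123.4
        tc2 = rescale_concentration(123.4, 0.85, 0.7)
        assert tc2 * 0.7 == pytest.approx(123.4 * 0.85, rel=1e-15)

    def test_rejects_nonpositive_volume(self):
        with pytest.raises(ValueError):
            rescale_concentration(1.0, 0.85, 0.0)

    @given(
        st.floats(min_value=1.0, max_value=1e6),
        st.floats(min_value=0.1, max_value=2.0),
        st.floats(min_value=0.1, max_value=2.0),
    )
    @settings(deadline=None, max_examples=100)
    def test_tc_times_vd_invariant(self, tc, v_old, v_new):
        assert rescale_concentration(tc, v_old, v_new) * v_new == pytest.approx(
            tc * v_old, rel=1e-12
        )


class TestQC:
    def test_strict_threshold(self):
        rxns = [
            ReactionResult("low", "t", 10, 9_999),
            ReactionResult("edge", "t", 10, 10_000),
            ReactionResult("high", "t", 10, 12_000),
        ]
        accepted, log = qc_filter(rxns)
        assert [r.well for r in accepted] == ["edge", "high"]
        assert log[0][0] == "low"
        assert rxns[0].qc_status.startswith("fail")

    def test_empty_input(self):
        assert qc_filter([]) == ([], [])

    def test_reaction_invariants(self):
        with pytest.raises(ValueError):
            ReactionResult("w", "t", 10, 5)
        with pytest.raises(ValueError):
            ReactionResult("w", "t", 1, 10, vd_nl=0.0)
        with pytest.raises(ValueError):
            ReactionResult("w", "t", 1, 10, dilution=0.5)


class TestBiasAndGM:
    @pytest.mark.parametrize(
        "value,ref,expected",
        [
            (115_351, 114_131, 1.07),
            (119_230, 117_369, 1.59),
            (137_131, 131_274, 4.46),
            (141_742, 134_998, 5.00),
            (100.0, 100.0, 0.0),
        ],
    )
    def test_generator_bias_cells(self, value, ref, expected):
        assert round(bias_percent(value, ref), 2) == expected

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            bias_percent(1.0, 0.0)

    @pytest.mark.parametrize(
        "fixed,measured,expected",
        [(0.85, 0.715, 15.9), (0.85, 0.739, 13.1), (0.85, 0.85, 0.0)],
    )
    def test_volume_induced_bias(self, fixed, measured, expected):
        assert round(volume_induced_bias(fixed, measured), 1) == expected

    def test_gm_percent_published_ratio(self):
        assert gm_percent(114_131, 117_369) == pytest.approx(97.24, abs=0.005)
        assert gm_percent(115_351, 119_230) == pytest.approx(96.75, abs=0.005)
        assert gm_percent(5.0, 5.0) == 100.0

    def test_gm_percent_volume_invariance_through_rescaling(self):
        gm, endo = 115_351.0, 119_230.0
        base = gm_percent(gm, endo)
        for v_new in (0.715, 0.739, 1.234):
            scaled = gm_percent(
                rescale_concentration(gm, 0.85, v_new),
                rescale_concentration(endo, 0.85, v_new),
            )
            assert scaled == pytest.approx(base, rel=1e-12)

    def test_gm_from_counts_is_volume_free_and_matches_ratio(self):
        p_gm, p_endo, r = 8900, 9100, 15000
        gm_counts = gm_percent_from_counts(p_gm, p_endo, r)
        # same value as the concentration ratio at any volume
        for vd in (0.85, 0.715):
            a = concentration_from_counts(p_gm, r, vd, 100.0)
            b = concentration_from_counts(p_endo, r, vd, 100.0)
            assert gm_counts == pytest.approx(gm_percent(a, b), rel=1e-12)

    def test_gm_saturation_rejected(self):
        with pytest.raises(SaturationError):
            gm_percent_from_counts(100, 50, 100)


class TestRSD:
    def test_constant_replicates_zero(self):
        assert rsd_repeatability([5.0, 5.0, 5.0]) == 0.0

    def test_two_value_hand_computation(self):
        assert rsd_repeatability([100.0, 110.0]) == pytest.approx(6.7344, abs=1e-3)

    def test_recovery_at_study_rsd(self):
        rng = np.random.default_rng(31)
        reps = rng.normal(115_351, 0.057 * 115_351, 18)
        assert rsd_repeatability(reps) == pytest.approx(5.7, abs=2.0)

    def test_reproducibility_pooled_hand_computation(self):
        # pooled values 100,110,120,130: sample SD 12.910, mean 115 -> 11.23%
        assert rsd_reproducibility([100.0, 110.0], [120.0, 130.0]) == pytest.approx(
            11.226, abs=0.01
        )
        assert rsd_reproducibility([7.0, 7.0], [7.0, 7.0]) == 0.0

    def test_reproducibility_band_for_two_generator_study(self):
        # two 18-replicate groups mimicking the published means at ~5.7% RSDr:
        # the pooled RSD_R lands in the 5-7% band
        rng = np.random.default_rng(37)
        dg8 = rng.normal(115_351, 0.057 * 115_351, 18)
        dg32 = rng.normal(114_131, 0.057 * 114_131, 18)
        assert 5.0 <= rsd_reproducibility(dg8, dg32) <= 7.0

    def test_performance_limit_flags(self):
        rng = np.random.default_rng(41)
        reps = {
            ("A", "t"): rng.normal(100, 5, 18),
            ("B", "t"): rng.normal(99, 5, 18),
        }
        report = quant.build_comparison(reps, generators=("A", "B"), fixed_vd_nl=0.85)
        assert report.within_performance_limits()
        assert report.rsd_r[("A", "t")] <= quant.RSDR_LIMIT
        assert report.rsd_repro[("fixed", "t")] <= quant.RSDR_REPRO_LIMIT


class TestMonteCarloRoundTrip:
    def test_estimates_unbiased_over_seeds(self):
        from dropvol.synthetic import PartitionCountSpec, generate_partition_counts

        true = 115_351.0
        means = []
        for seed in range(100):
            rxns = generate_partition_counts(
                PartitionCountSpec(concentration=true, seed=seed, replicates=6)
            )
            means.append(np.mean([r.concentration() for r in rxns]))
        means = np.asarray(means)
        se = means.std(ddof=1) / math.sqrt(means.size)
        assert abs(means.mean() - true) < 3 * se
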