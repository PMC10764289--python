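"""Concentrations, dissociation constants, exclusion and aggregation."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytofccs.affinity import (
    FccsMeasurement,
    aggregate_kd,
    analyze_trace,
    apply_exclusion,
    bin_kd,
    channel_concentration,
    complex_concentration,
    dissociation_constant,
    relative_affinity,
)
from cytofccs.synthetic import SimulationBox, equilibrium_mixture, simulate_fccs_trace


def meas(c_green, c_red, c_cc=1.0, kd=100.0, **kw):
    return FccsMeasurement(
        n1=1.0, n2=1.0, ncc=1.0, c_green=c_green, c_red=c_red, c_cc=c_cc, kd=kd, **kw
    )


class TestChannelConcentration:
    def test_independent_arithmetic(self):
        # 1 molecule in 0.65 fl is 2.5547 nM
        assert channel_concentration(1.0, 0.65) == pytest.approx(2.5547, abs=1e-4)

    def test_linear_in_molecule_number(self):
        assert channel_concentration(8.0, 0.3) == pytest.approx(
            2 * channel_concentration(4.0, 0.3)
        )

    def test_vanishes_for_large_volume(self):
        assert channel_concentration(5.0, 1e12) < 1e-11

    def test_non_positive_volume_rejected(self):
        with pytest.raises(ValueError):
            channel_concentration(1.0, 0.0)


class TestComplexConcentration:
    def test_full_codiffusion_limit(self):
        # N1 = N2 = N_cc = N means every molecule is bound: C = N/(V_cc N_A)
        assert complex_concentration(7.0, 7.0, 7.0, 0.65) == pytest.approx(
            channel_concentration(7.0, 0.65)
        )

    def test_independent_arithmetic(self):
        # N1*N2/Ncc = 2 molecules in 0.65 fl
        assert complex_concentration(4.0, 5.0, 10.0, 0.65) == pytest.approx(5.109, abs=1e-3)

    def test_vanishing_cross_amplitude(self):
        assert complex_concentration(4.0, 5.0, 1e12, 0.65) < 1e-9

    def test_non_positive_ncc_rejected(self):
        with pytest.raises(ValueError):
            complex_concentration(4.0, 5.0, 0.0, 0.65)


class TestDissociationConstant:
    def test_direct_formula(self):
        assert dissociation_constant(300.0, 400.0, 100.0) == pytest.approx(600.0)

    def test_complete_binding_gives_zero(self):
        assert dissociation_constant(50.0, 50.0, 50.0) == 0.0

    def test_round_trip_with_equilibrium_mixture(self):
        """dissociation_constant ∘ equilibrium_mixture is the identity on K_d."""
        mix = equilibrium_mixture(300.0, 400.0, 600.0)
        kd = dissociation_constant(mix.total_green, mix.total_red, mix.complex)
        assert kd == pytest.approx(600.0, rel=1e-9)

    @given(
        tg=st.floats(10.0, 2000.0),
        tr=st.floats(10.0, 2000.0),
        kd=st.floats(1.0, 5000.0),
    )
    def test_round_trip_property(self, tg, tr, kd):
        mix = equilibrium_mixture(tg, tr, kd)
        assert dissociation_constant(tg, tr, mix.complex) == pytest.approx(kd, rel=1e-6)

    def test_symmetric_under_channel_swap(self):
        assert dissociation_constant(220.0, 510.0, 90.0) == pytest.approx(
            dissociation_constant(510.0, 220.0, 90.0)
        )

    def test_overshooting_complex_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            kd = dissociation_constant(100.0, 200.0, 150.0)
        assert kd == 0.0  # clipped to the green channel concentration

    def test_zero_complex_rejected(self):
        with pytest.raises(ValueError):
            dissociation_constant(100.0, 100.0, 0.0)


class TestExclusionRule:
    def test_one_channel_over_threshold_excludes(self):
        retained, excluded = apply_exclusion([meas(2500.0, 100.0)])
        assert not retained
        assert excluded[0].excluded
        assert "green" in excluded[0].exclusion_reason

    def test_boundary_values_retained(self):
        retained, excluded = apply_exclusion([meas(1999.0, 1999.0), meas(2000.0, 100.0)])
        assert len(retained) == 2
        assert not excluded

    def test_empty_input(self):
        assert apply_exclusion([]) == ([], [])

    def test_both_rule_requires_both_channels(self):
        m = meas(2500.0, 100.0)
        retained, excluded = apply_exclusion([m], rule="both")
        assert retained and not excluded
        retained, excluded = apply_exclusion([meas(2500.0, 2500.0)], rule="both")
        assert excluded and not retained

    def test_custom_threshold(self):
        retained, excluded = apply_exclusion([meas(150.0, 10.0)], threshold=100.0)
        assert excluded


class TestAggregation:
    def test_mean_and_sd(self):
        summary = aggregate_kd([meas(1, 1, kd=k) for k in (400.0, 440.0, 480.0)])
        assert summary.mean == pytest.approx(440.0)
        assert summary.sd == pytest.approx(40.0)
        assert summary.n == 3

    def test_single_value_has_undefined_sd(self):
        summary = aggregate_kd([meas(1, 1, kd=300.0)])
        assert math.isnan(summary.sd)

    def test_lower_bounds_never_averaged(self):
        ms = [
            meas(1, 1, kd=400.0),
            meas(1, 1, kd=9301.0, kd_is_lower_bound=True),
            meas(1, 1, kd=440.0),
        ]
        summary = aggregate_kd(ms)
        assert summary.mean == pytest.approx(420.0)
        assert summary.lower_bounds == (9301.0,)

    def test_only_bounds_rejected(self):
        with pytest.raises(ValueError):
            aggregate_kd([meas(1, 1, kd=5000.0, kd_is_lower_bound=True)])


class TestRelativeAffinity:
    def test_anchor_definitions(self):
        assert relative_affinity(229.0, 9301.0, 229.0) == pytest.approx(100.0)
        assert relative_affinity(9301.0, 9301.0, 229.0) == pytest.approx(0.0)

    def test_linear_in_inverse_kd(self):
        neg, pos = 1000.0, 100.0
        midpoint_affinity = 0.5 * (1 / neg + 1 / pos)
        assert relative_affinity(1 / midpoint_affinity, neg, pos) == pytest.approx(50.0)

    def test_zero_kd_saturates_with_warning(self):
        with pytest.warns(UserWarning):
            assert relative_affinity(0.0, 1000.0, 100.0) == 100.0

    def test_identical_anchors_rejected(self):
        with pytest.raises(ValueError):
            relative_affinity(50.0, 200.0, 200.0)


class TestKdBinning:
    def test_single_occupied_bin_is_hundred_percent(self):
        counts, pct = bin_kd([meas(1, 1, kd=k) for k in (150.0, 180.0)], [0, 200, 400])
        assert counts.tolist() == [2, 0]
        assert pct[0] == pytest.approx(100.0)

    def test_percentages_sum_to_hundred(self):
        values = [meas(1, 1, kd=float(k)) for k in range(50, 1950, 100)]
        _, pct = bin_kd(values, [0, 500, 1000, 2000])
        assert pct.sum() == pytest.approx(100.0, abs=1e-9)

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            bin_kd([meas(1, 1)], [0, 500, 300])

    def test_lower_bounds_not_binned(self):
        ms = [meas(1, 1, kd=100.0), meas(1, 1, kd=5000.0, kd_is_lower_bound=True)]
        counts, _ = bin_kd(ms, [0, 10000])
        assert counts.tolist() == [1]


class TestMeasurementInvariants:
    def test_complex_cannot_exceed_channel_concentration(self):
        with pytest.raises(ValueError):
            meas(100.0, 100.0, c_cc=150.0)


class TestEndToEndRecovery:
    """The pipeline's core property: simulate → correlate → fit → equations
    recovers the true K_d with bounded bias across the affinity range."""

    # The weak-binding case sits near the cross-correlation detection
    # limit, so it gets longer recordings for the amplitude noise floor to
    # fall below the true cross-amplitude in most repeats.
    @pytest.mark.parametrize(
        "kd_true, totals, duration",
        [(100.0, 300.0, 2.2), (500.0, 300.0, 2.2), (2000.0, 500.0, 7.0)],
    )
    def test_kd_recovery_bias_below_25_percent(
        self, kd_true, totals, duration, exact_calibration, optics
    ):
        green, red = optics
        mix = equilibrium_mixture(totals, totals, kd_true)
        kds = []
        for seed in range(20):
            box = SimulationBox(
                side_length=2.2, bin_width=250.0, duration=duration, seed=1000 + seed
            )
            trace = simulate_fccs_trace(mix, green, red, box)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = analyze_trace(trace, exact_calibration)
            if not m.kd_is_lower_bound:
                kds.append(m.kd)
        assert len(kds) >= 10
        median = float(np.median(kds))
        assert abs(median - kd_true) < 0.25 * kd_true

    def test_relabelling_channels_leaves_kd_invariant(
        self, exact_calibration, optics
    ):
        """Swapping the channel labels of the data and the calibration
        together changes nothing about the K_d estimate."""
        from cytofccs.calibration import CalibrationResult, DetectionVolume
        from cytofccs.correlate import PhotonTrace

        green, red = optics
        box = SimulationBox(side_length=2.2, bin_width=250.0, duration=2.0, seed=55)
        trace = simulate_fccs_trace(
            equilibrium_mixture(200.0, 400.0, 300.0), green, red, box
        )
        swapped_trace = PhotonTrace(
            counts_green=trace.counts_red,
            counts_red=trace.counts_green,
            bin_width=trace.bin_width,
            duration=trace.duration,
        )
        swapped_cal = CalibrationResult(
            green=DetectionVolume(waist=red.waist, axial=red.axial, channel="green"),
            red=DetectionVolume(waist=green.waist, axial=green.axial, channel="red"),
            v_cc=exact_calibration.v_cc,
            dye_diffusion=exact_calibration.dye_diffusion,
        )
        m = analyze_trace(trace, exact_calibration)
        m_swapped = analyze_trace(swapped_trace, swapped_cal)
        assert m_swapped.kd == pytest.approx(m.kd, rel=1e-9)
        assert m_swapped.c_green == pytest.approx(m.c_red, rel=1e-9)
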