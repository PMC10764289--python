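"""TCSPC decay fitting, FRET efficiency and Förster distance."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytofccs.flim import (
    DecayFitError,
    TcspcDecay,
    donor_acceptor_distance,
    fit_decay,
    fret_efficiency,
    roi_fret_analysis,
)
from cytofccs.synthetic import simulate_tcspc


class TestDecayFitting:
    def test_mono_exponential_recovery_within_two_percent(self):
        """Fitted lifetime within 2% of 2.41 ns at 1e5 photons."""
        taus = []
        for seed in range(3):
            decay = simulate_tcspc([(1.0, 2.41)], 100_000, irf_sigma=0.1, seed=seed)
            fit = fit_decay(decay, 1)
            taus.append(fit.tau_amp)
        assert np.mean(taus) == pytest.approx(2.41, rel=0.02)

    def test_noiseless_curve_recovered_precisely(self):
        """A binned model curve (no photon noise) is fitted to 1e-4 relative."""
        from cytofccs.flim import _expected_counts

        edges = np.arange(0.0, 25.0, 0.05)
        lam = _expected_counts(edges, np.array([2e5]), np.array([2.2]), 0.1, 0.0)
        decay = TcspcDecay(bin_edges=edges, counts=lam, irf_sigma=0.1)
        fit = fit_decay(decay, 1, fit_shift=False)
        assert fit.components[0][1] == pytest.approx(2.2, rel=1e-4)

    def test_bi_exponential_recovery(self):
        """50/50 mixture of 1 ns and 4 ns recovered within 10% per lifetime."""
        decay = simulate_tcspc(
            [(0.5, 1.0), (0.5, 4.0)], 300_000, irf_sigma=0.05, seed=11
        )
        fit = fit_decay(decay, 2)
        (a_slow, tau_slow), (a_fast, tau_fast) = fit.components
        assert tau_slow == pytest.approx(4.0, rel=0.10)
        assert tau_fast == pytest.approx(1.0, rel=0.10)
        assert tau_slow > tau_fast  # ordered by lifetime descending
        assert a_slow / (a_slow + a_fast) == pytest.approx(0.5, abs=0.1)

    def test_low_photon_count_flagged_not_dropped(self):
        decay = simulate_tcspc([(1.0, 2.5)], 400, seed=5)
        fit = fit_decay(decay, 1)
        assert fit.low_signal

    def test_empty_decay_rejected(self):
        decay = simulate_tcspc([(1.0, 2.5)], 0, seed=5)
        with pytest.raises(DecayFitError):
            fit_decay(decay, 1)

    def test_fixed_unquenched_lifetime_component(self):
        """Two-component fit with the unquenched lifetime held fixed."""
        decay = simulate_tcspc([(1.0, 2.0)], 100_000, seed=6)
        fit = fit_decay(decay, 2, fixed_lifetimes=[2.5])
        assert any(t == 2.5 for _, t in fit.components)
        assert fit.tau_amp == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("tau", [1.0, 2.5, 4.0])
    def test_lifetime_estimator_bias_below_two_percent(self, tau):
        """Bias sweep across the nanosecond range at 1e5 photons."""
        fits = [
            fit_decay(simulate_tcspc([(1.0, tau)], 100_000, seed=40 + s), 1)
            for s in range(3)
        ]
        assert np.mean([f.tau_amp for f in fits]) == pytest.approx(tau, rel=0.02)

    def test_intensity_weighted_lifetime_exceeds_amplitude_weighted(self):
        decay = simulate_tcspc([(0.5, 1.0), (0.5, 4.0)], 200_000, seed=12)
        fit = fit_decay(decay, 2)
        assert fit.tau_intensity > fit.tau_amp


class TestFretEfficiency:
    def test_equal_lifetimes_give_zero(self):
        assert fret_efficiency(2.5, 2.5) == 0.0

    def test_forced_arithmetic(self):
        assert fret_efficiency(2.25, 2.50) == pytest.approx(0.10)

    def test_quenched_longer_than_donor_clips_to_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert fret_efficiency(2.6, 2.5) == 0.0

    def test_invalid_lifetimes_rejected(self):
        with pytest.raises(ValueError):
            fret_efficiency(2.0, 0.0)

    @given(
        tau_da=st.floats(0.1, 4.9),
        tau_d=st.floats(5.0, 10.0),
    )
    def test_strictly_decreasing_in_quenched_lifetime(self, tau_da, tau_d):
        e1 = fret_efficiency(tau_da, tau_d)
        e2 = fret_efficiency(tau_da + 0.05, tau_d)
        assert e2 < e1


class TestForsterDistance:
    def test_half_efficiency_returns_forster_radius(self):
        assert donor_acceptor_distance(0.5) == pytest.approx(52.4)

    def test_independent_arithmetic(self):
        # r = 52.4 * 9^(1/6) at E = 0.10
        assert donor_acceptor_distance(0.10) == pytest.approx(75.57, abs=0.01)

    def test_extremes_are_not_detectable(self):
        assert math.isnan(donor_acceptor_distance(0.0))
        assert math.isnan(donor_acceptor_distance(1.0))

    def test_distance_vanishes_as_efficiency_approaches_one(self):
        assert donor_acceptor_distance(0.999999) < 6.0

    @given(e=st.floats(0.01, 0.98))
    def test_strictly_decreasing_in_efficiency(self, e):
        assert donor_acceptor_distance(e + 0.01) < donor_acceptor_distance(e)

    @given(e=st.floats(0.01, 0.99))
    def test_sub_ten_nanometre_classification(self, e):
        """r < 100 Å exactly when E exceeds the inverse-relation threshold."""
        r = donor_acceptor_distance(e)
        threshold = 1.0 / (1.0 + (100.0 / 52.4) ** 6)
        assert (r < 100.0) == (e > threshold)


class TestRoiFretAnalysis:
    def test_identical_populations_give_near_zero_efficiency(self):
        donors = [simulate_tcspc([(1.0, 2.5)], 50_000, seed=i) for i in range(3)]
        samples = [simulate_tcspc([(1.0, 2.5)], 50_000, seed=10 + i) for i in range(3)]
        results = roi_fret_analysis(donors, samples)
        assert abs(np.mean([r.efficiency for r in results])) < 0.02

    def test_quenched_population_recovered_within_three_se(self):
        e_true = 0.15
        donors = [simulate_tcspc([(1.0, 2.6)], 80_000, seed=20 + i) for i in range(4)]
        samples = [
            simulate_tcspc([(1.0, 2.6 * (1 - e_true))], 80_000, seed=30 + i)
            for i in range(6)
        ]
        results = roi_fret_analysis(donors, samples)
        effs = [r.efficiency for r in results]
        se = np.std(effs, ddof=1) / math.sqrt(len(effs))
        assert abs(np.mean(effs) - e_true) < 3 * se + 0.005

    def test_missing_donor_set_rejected(self):
        samples = [simulate_tcspc([(1.0, 2.0)], 10_000, seed=1)]
        with pytest.raises(ValueError):
            roi_fret_analysis([], samples)
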