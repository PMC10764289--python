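"""FCS model evaluation and curve fitting."""

import numpy as np
import pytest

from cytofccs.correlate import CorrelationCurve, multi_tau_correlate
from cytofccs.models import (
    FitError,
    fit_curve,
    pure_diffusion_model,
    triplet_diffusion_model,
)

from conftest import make_single_species_trace


class TestModelEvaluation:
    def test_amplitude_identity_at_zero_lag(self):
        assert triplet_diffusion_model(0.0, 4.0, 100.0, 0.0, 1.0, 5.0) == pytest.approx(0.25)

    def test_decorrelation_limit(self):
        assert triplet_diffusion_model(1e12, 2.0, 100.0, 0.1, 5.0, 5.0) < 1e-6

    def test_independent_arithmetic_value(self):
        # N=2, tau_D=100, T=0, S=5 at tau=100: 0.5 * 0.5 * 1.04^(-1/2)
        g = triplet_diffusion_model(100.0, 2.0, 100.0, 0.0, 1.0, 5.0)
        assert g == pytest.approx(0.24514, abs=1e-5)

    def test_pure_diffusion_equals_triplet_with_zero_fraction(self):
        tau = np.geomspace(0.1, 1e5, 50)
        np.testing.assert_allclose(
            pure_diffusion_model(tau, 3.0, 250.0, 4.0),
            triplet_diffusion_model(tau, 3.0, 250.0, 0.0, 7.0, 4.0),
        )

    def test_axial_term_vanishes_for_large_structure_parameter(self):
        g = pure_diffusion_model(100.0, 1.0, 100.0, 1e8)
        assert g == pytest.approx(0.5, rel=1e-6)

    def test_monotone_decreasing_without_triplet(self):
        tau = np.geomspace(0.1, 1e6, 200)
        g = pure_diffusion_model(tau, 2.0, 300.0, 5.0)
        assert (np.diff(g) < 0).all()

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            triplet_diffusion_model(1.0, -1.0, 100.0, 0.0, 1.0, 5.0)
        with pytest.raises(ValueError):
            triplet_diffusion_model(1.0, 1.0, 100.0, 1.0, 1.0, 5.0)  # T = 1 singular


def model_curve(n=5.0, tau_d=200.0, t_frac=0.12, tau_tr=4.0, s=4.0, noise=0.0, seed=0):
    lags = np.geomspace(1.0, 5e4, 80)
    g = triplet_diffusion_model(lags, n, tau_d, t_frac, tau_tr, s)
    if noise:
        g = g + np.random.default_rng(seed).normal(0.0, noise, size=g.size)
    return CorrelationCurve(lags=lags, g=g, sigma=None, kind="auto_green")


class TestCurveFitting:
    def test_noiseless_self_consistency(self):
        """Parameters of a noiseless model curve are recovered to 1e-6."""
        curve = model_curve()
        fit = fit_curve(curve, "triplet_diffusion", fixed={"structure_parameter": 4.0})
        assert fit.n_molecules == pytest.approx(5.0, rel=1e-6)
        assert fit.tau_d == pytest.approx(200.0, rel=1e-6)
        assert fit.triplet_fraction == pytest.approx(0.12, rel=1e-4)
        assert fit.triplet_tau == pytest.approx(4.0, rel=1e-4)

    def test_pure_diffusion_noiseless_recovery(self):
        lags = np.geomspace(1.0, 5e4, 60)
        g = pure_diffusion_model(lags, 8.0, 500.0, 6.0)
        curve = CorrelationCurve(lags=lags, g=g, sigma=None, kind="cross")
        fit = fit_curve(curve, "pure_diffusion")
        assert fit.n_molecules == pytest.approx(8.0, rel=1e-6)
        assert fit.tau_d == pytest.approx(500.0, rel=1e-5)

    def test_too_few_lags_rejected(self):
        curve = CorrelationCurve(
            lags=np.array([1.0, 2.0, 4.0]),
            g=np.array([0.5, 0.4, 0.3]),
            sigma=None,
            kind="auto_green",
        )
        with pytest.raises(FitError):
            fit_curve(curve, "triplet_diffusion")

    def test_fixed_parameters_are_honoured(self):
        curve = model_curve()
        fit = fit_curve(
            curve,
            "triplet_diffusion",
            fixed={"structure_parameter": 4.0, "triplet_tau": 4.0},
        )
        assert fit.structure_parameter == 4.0
        assert fit.triplet_tau == 4.0

    def test_fixing_structure_parameter_barely_moves_tau_d(self):
        """On well-behaved data, τ_D changes < 5% between fixed and free S."""
        curve = model_curve(noise=2e-3, seed=4)
        free = fit_curve(curve, "triplet_diffusion")
        fixed = fit_curve(curve, "triplet_diffusion", fixed={"structure_parameter": 4.0})
        assert fixed.tau_d == pytest.approx(free.tau_d, rel=0.05)

    def test_triplet_term_improves_chi2_on_blinking_data(self):
        """χ² decreases (or ties) when the triplet term is available."""
        trace, _, _ = make_single_species_trace(
            concentration_nm=8.0,
            diffusion=50.0,
            duration=0.6,
            bin_width=2.0,
            seed=77,
            triplet_fraction=0.3,
            triplet_tau=8.0,
        )
        curve = multi_tau_correlate(trace, "auto_green")
        with_triplet = fit_curve(
            curve, "triplet_diffusion", fixed={"structure_parameter": 3.0}
        )
        without = fit_curve(curve, "pure_diffusion", fixed={"structure_parameter": 3.0})
        assert with_triplet.chi2 <= without.chi2 * (1 + 1e-9)
        assert with_triplet.triplet_fraction > 0.1

    def test_diffusion_time_recovered_from_simulation(self, optics):
        """Fitted τ_D within 15% of ω²/(4D) for a simulated single species."""
        green, _ = optics
        diffusion = 50.0
        expected = green.waist**2 / (4.0 * diffusion * 1e-6)  # µs
        tau_ds = []
        for seed in range(4):
            trace, _, _ = make_single_species_trace(
                concentration_nm=10.0, diffusion=diffusion, duration=0.6, seed=400 + seed
            )
            curve = multi_tau_correlate(trace, "auto_green")
            fit = fit_curve(curve, "triplet_diffusion", fixed={"structure_parameter": 3.0})
            tau_ds.append(fit.tau_d)
        assert np.mean(tau_ds) == pytest.approx(expected, rel=0.15)

    def test_fitted_n_matches_concentration(self, optics):
        """Median fitted N within 10% of C·V_ef·N_A across ≥10 seeds."""
        from cytofccs.units import MOLECULES_PER_NM_FL

        green, _ = optics
        conc = 10.0
        expected = conc * green.v_eff * MOLECULES_PER_NM_FL
        ns = []
        for seed in range(10):
            trace, _, _ = make_single_species_trace(
                concentration_nm=conc, duration=0.6, seed=500 + seed
            )
            curve = multi_tau_correlate(trace, "auto_green")
            fit = fit_curve(curve, "triplet_diffusion", fixed={"structure_parameter": 3.0})
            ns.append(fit.n_molecules)
        assert float(np.median(ns)) == pytest.approx(expected, rel=0.10)
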