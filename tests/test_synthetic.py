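"""Synthetic-data generator: equilibria, traces, decays, cell grids."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cytofccs.synthetic import (
    CellRecord,
    ConfigurationError,
    SimulationBox,
    default_optics,
    equilibrium_mixture,
    expected_count_rate,
    generate_cell_grid,
    simulate_fccs_trace,
    simulate_tcspc,
    spawn_seed,
    telegraph_dark_fraction,
)

from conftest import make_single_species_trace


class TestEquilibriumMixture:
    @pytest.mark.parametrize(
        "total_green, total_red, kd, expected_complex",
        [
            (300.0, 400.0, 600.0, 100.0),  # back-substitution: 200*300/100 = 600
            (200.0, 500.0, 0.0, 200.0),  # infinite-affinity limit: min of totals
            (300.0, 400.0, math.inf, 0.0),  # no-binding limit
            (0.0, 400.0, 50.0, 0.0),
        ],
    )
    def test_complex_concentration(self, total_green, total_red, kd, expected_complex):
        mix = equilibrium_mixture(total_green, total_red, kd)
        assert mix.complex == pytest.approx(expected_complex, abs=1e-9)
        assert mix.free_green + mix.complex == pytest.approx(total_green, abs=1e-9)
        assert mix.free_red + mix.complex == pytest.approx(total_red, abs=1e-9)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            equilibrium_mixture(-1.0, 100.0, 50.0)
        with pytest.raises(ValueError):
            equilibrium_mixture(100.0, 100.0, -5.0)

    @given(
        total_green=st.floats(1.0, 5000.0),
        total_red=st.floats(1.0, 5000.0),
        kd=st.floats(1e-2, 1e5),
    )
    def test_mass_action_residual(self, total_green, total_red, kd):
        """(G_t-C)(R_t-C)/C reproduces K_d to relative 1e-6."""
        mix = equilibrium_mixture(total_green, total_red, kd)
        assert mix.complex > 0
        residual = mix.free_green * mix.free_red / mix.complex
        assert residual == pytest.approx(kd, rel=1e-6)


class TestFccsTraceSimulation:
    def test_all_zero_concentrations_give_empty_channels(self, optics):
        green, red = optics
        mix = equilibrium_mixture(0.0, 0.0, math.inf)
        box = SimulationBox(side_length=2.2, bin_width=100.0, duration=0.01, seed=0)
        trace = simulate_fccs_trace(mix, green, red, box)
        assert not trace.counts_green.any()
        assert not trace.counts_red.any()

    def test_identical_seed_gives_bit_identical_traces(self):
        t1, _, _ = make_single_species_trace(duration=0.05, seed=11)
        t2, _, _ = make_single_species_trace(duration=0.05, seed=11)
        assert np.array_equal(t1.counts_green, t2.counts_green)
        assert np.array_equal(t1.counts_red, t2.counts_red)
        t3, _, _ = make_single_species_trace(duration=0.05, seed=12)
        assert not np.array_equal(t1.counts_green, t3.counts_green)

    def test_box_smaller_than_ten_waists_rejected(self, optics):
        green, red = optics
        mix = equilibrium_mixture(10.0, 10.0, 100.0)
        box = SimulationBox(side_length=1.0, bin_width=100.0, duration=0.01, seed=0)
        with pytest.raises(ConfigurationError):
            simulate_fccs_trace(mix, green, red, box)

    def test_mean_count_rate_matches_analytic_expectation(self, optics):
        """Rates agree with C·N_A·ε·∫W (box-truncated) within 3 s.e. of seeds."""
        green, red = optics
        rates = []
        expected = None
        for seed in range(10):
            trace, mix, box = make_single_species_trace(
                concentration_nm=20.0,
                diffusion=50.0,
                duration=0.3,
                bin_width=4.0,
                seed=100 + seed,
                triplet_fraction=0.15,
            )
            rates.append(trace.mean_rates_hz()[0])
            expected = expected_count_rate(mix, green, red, box)[0]
        mean = np.mean(rates)
        se = np.std(rates, ddof=1) / math.sqrt(len(rates))
        assert abs(mean - expected) < 3 * se

    def test_triplet_occupancy_converges_to_stationary_fraction(self):
        """Telegraph dark-state occupancy within 1% over a 10-s realisation."""
        frac = telegraph_dark_fraction(0.15, 5.0, 1.0, 10_000_000, 42)
        assert frac == pytest.approx(0.15, abs=0.01)

    def test_duration_must_be_whole_bins(self):
        with pytest.raises(ValueError):
            SimulationBox(side_length=2.2, bin_width=300.0, duration=0.001, seed=0)


class TestSeedFanOut:
    def test_streams_are_distinct_and_reproducible(self):
        assert spawn_seed(1, 2, 3) == spawn_seed(1, 2, 3)
        seeds = {spawn_seed(1, i) for i in range(100)}
        assert len(seeds) == 100
        assert all(0 <= s < 2**31 for s in seeds)


class TestTcspcSimulation:
    def test_single_component_mean_arrival(self):
        """Sample mean arrival time ≈ τ within 3 s.e. (exponential mean)."""
        d = simulate_tcspc([(1.0, 2.5)], 50_000, irf_sigma=0.0, seed=1)
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        mean = float((d.counts * centers).sum() / d.counts.sum())
        se = 2.5 / math.sqrt(50_000)
        assert abs(mean - 2.5) < 3 * se + 0.025  # half a bin of discretisation

    def test_two_component_fractions(self):
        """A 50/50 1 ns / 4 ns mixture yields ~half the photons per component."""
        d = simulate_tcspc([(0.5, 1.0), (0.5, 4.0)], 100_000, irf_sigma=0.0, seed=2)
        centers = 0.5 * (d.bin_edges[:-1] + d.bin_edges[1:])
        mean = float((d.counts * centers).sum() / d.counts.sum())
        assert mean == pytest.approx(0.5 * 1.0 + 0.5 * 4.0, rel=0.03)

    def test_zero_photons_yields_flagged_empty_histogram(self):
        d = simulate_tcspc([(1.0, 2.0)], 0, seed=3)
        assert d.is_empty
        assert not d.counts.any()

    def test_invalid_components_rejected(self):
        with pytest.raises(ValueError):
            simulate_tcspc([(0.7, 2.0)], 100, seed=0)  # fractions must sum to 1
        with pytest.raises(ValueError):
            simulate_tcspc([(1.0, -1.0)], 100, seed=0)


class TestCellGrid:
    def test_extreme_activities(self):
        grid_on = generate_cell_grid(7, 7, [(3, 3)], {d: 1.0 for d in range(1, 9)}, seed=1)
        grid_off = generate_cell_grid(7, 7, [(3, 3)], {d: 0.0 for d in range(1, 9)}, seed=1)
        on_ratios = [
            c.nuclear_intensity / c.cytoplasmic_intensity
            for c in grid_on.cells
            if not c.is_clone
        ]
        off_ratios = [
            c.nuclear_intensity / c.cytoplasmic_intensity
            for c in grid_off.cells
            if not c.is_clone
        ]
        assert max(on_ratios) < 1.0
        assert min(off_ratios) > 1.0

    def test_row_distance_is_graph_distance(self):
        grid = generate_cell_grid(5, 5, [(0, 0)], {}, seed=0)
        dist = {}
        idx = 0
        for r in range(5):
            for c in range(5):
                dist[(r, c)] = grid.cells[idx].row_distance
                idx += 1
        assert dist[(0, 0)] == 0
        assert dist[(4, 4)] == 8  # Manhattan distance on 4-neighbour adjacency
        assert dist[(2, 1)] == 3

    def test_step_profile_recovered_within_binomial_ci(self):
        """Per-row active fractions match the generating probabilities."""
        profile = {1: 0.8, 2: 0.8, 3: 0.8, 4: 0.8, 5: 0.8, 6: 0.1, 7: 0.1}
        grid = generate_cell_grid(41, 41, [(20, 20)], profile, seed=5)
        tested = 0
        for d, p in profile.items():
            cells = [c for c in grid.cells if c.row_distance == d]
            active = [
                c for c in cells if c.nuclear_intensity / c.cytoplasmic_intensity < 1.0
            ]
            n = len(cells)
            if n < 15:  # innermost rings are too small for a CI check
                continue
            tested += 1
            frac = len(active) / n
            half_width = 1.96 * math.sqrt(p * (1 - p) / n)
            assert abs(frac - p) <= half_width + 1e-9
        assert tested >= 4

    def test_clone_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_cell_grid(4, 4, [(5, 0)], {}, seed=0)

    def test_cell_record_invariants(self):
        with pytest.raises(ValueError):
            CellRecord(row_distance=0, is_clone=False, nuclear_intensity=1, cytoplasmic_intensity=1)
        with pytest.raises(ValueError):
            CellRecord(row_distance=2, is_clone=False, nuclear_intensity=-1, cytoplasmic_intensity=1)
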