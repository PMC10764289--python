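"""Synthetic ground-truth data for every stage of the pipeline.

Generates (a) mass-action equilibrium binding mixtures of a green-labelled
and a red-labelled species plus their complex, (b) two-colour photon-count
traces of those mixtures diffusing through two overlapping Gaussian confocal
volumes (Brownian dynamics with triplet blinking and Poisson photon noise),
(c) TCSPC decay histograms as exponential mixtures convolved with a Gaussian
instrument response, and (d) labelled cell grids for reporter-based
paracrine signalling profiles. Every generator is deterministic given its
seed; a master seed fans out to independent per-purpose streams via a
counter-based scheme (`spawn_seed`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from ._kernels import propagate_chunk, telegraph_dark_fraction
from .calibration import DetectionVolume
from .correlate import PhotonTrace
from .flim import TcspcDecay
from .units import MOLECULES_PER_NM_FL

__all__ = [
    "SpeciesMix",
    "SimulationBox",
    "CellGrid",
    "CellRecord",
    "ConfigurationError",
    "spawn_seed",
    "equilibrium_mixture",
    "simulate_fccs_trace",
    "simulate_tcspc",
    "generate_cell_grid",
    "default_optics",
    "telegraph_dark_fraction",
]


class ConfigurationError(ValueError):
    """Simulation configuration is physically or numerically inconsistent."""


def spawn_seed(master_seed: int, *stream: int) -> int:
    """Derive an independent 31-bit child seed from a master seed.

    Counter-based fan-out: `(master, k1, k2, ...)` streams are mutually
    independent, so each module or repeat can be re-run in isolation.
    """
    ss = np.random.SeedSequence((int(master_seed), *map(int, stream)))
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


# ---------------------------------------------------------------------------
# Equilibrium binding mixtures

#: Default per-species diffusion coefficients, µm²/s. Values typical of
#: membrane-tethered ligand/receptor proteins; the bound complex diffuses
#: more slowly than either free partner.
DEFAULT_DIFFUSION = {"free_green": 0.8, "free_red": 0.8, "complex": 0.5}

#: Default peak molecular brightness per fluorophore, counts/molecule/s.
DEFAULT_BRIGHTNESS = {"green": 30_000.0, "red": 30_000.0}


@dataclass(frozen=True)
class SpeciesMix:
    """A two-colour binding mixture at mass-action equilibrium.

    Concentrations in nM. The complex carries one green and one red
    fluorophore and emits the summed brightness of both. ``triplet_fraction``
    and ``triplet_tau`` (µs) describe fluorophore dark-state blinking and
    apply to every fluorophore.
    """

    total_green: float
    total_red: float
    kd_true: float  # nM, may be math.inf
    free_green: float
    free_red: float
    complex: float
    diffusion: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIFFUSION))
    brightness: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_BRIGHTNESS))
    triplet_fraction: float = 0.15
    triplet_tau: float = 5.0  # µs

    def __post_init__(self) -> None:
        for name in ("total_green", "total_red", "free_green", "free_red", "complex"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet_fraction must be in [0, 1)")
        if self.triplet_fraction > 0 and self.triplet_tau <= 0:
            raise ValueError("triplet_tau must be positive when blinking is on")
        if abs(self.free_green + self.complex - self.total_green) > 1e-9:
            raise ValueError("green mass balance violated")
        if abs(self.free_red + self.complex - self.total_red) > 1e-9:
            raise ValueError("red mass balance violated")
        if self.complex > 0 and math.isfinite(self.kd_true):
            kd_check = self.free_green * self.free_red / self.complex
            if self.kd_true > 0 and abs(kd_check - self.kd_true) > 1e-6 * self.kd_true:
                raise ValueError("species not at mass-action equilibrium")

    def with_diffusion(self, **coefficients: float) -> "SpeciesMix":
        return replace(self, diffusion={**self.diffusion, **coefficients})


def equilibrium_mixture(
    total_green: float,
    total_red: float,
    kd_true: float,
    **kwargs,
) -> SpeciesMix:
    """Solve the mass-action equilibrium for given totals and true K_d.

    The complex concentration is the physical root of

        C² − (G_t + R_t + K_d)·C + G_t·R_t = 0,

    i.e. C = ((G_t+R_t+K_d) − sqrt((G_t+R_t+K_d)² − 4·G_t·R_t)) / 2.
    K_d = 0 gives the infinite-affinity limit C = min(G_t, R_t); K_d = inf
    gives C = 0 (no binding).
    """
    if total_green < 0 or total_red < 0:
        raise ValueError("total concentrations must be non-negative")
    if kd_true < 0:
        raise ValueError("kd_true must be non-negative (or infinite)")
    if math.isinf(kd_true) or total_green == 0 or total_red == 0:
        c = 0.0
    elif kd_true == 0:
        c = min(total_green, total_red)
    else:
        s = total_green + total_red + kd_true
        disc = s * s - 4.0 * total_green * total_red
        c = (s - math.sqrt(max(disc, 0.0))) / 2.0
        c = min(c, total_green, total_red)
    return SpeciesMix(
        total_green=total_green,
        total_red=total_red,
        kd_true=kd_true,
        free_green=total_green - c,
        free_red=total_red - c,
        complex=c,
        **kwargs,
    )


# ---------------------------------------------------------------------------
# Brownian-dynamics photon traces


@dataclass(frozen=True)
class SimulationBox:
    """Periodic cubic simulation box and time discretisation.

    ``side_length`` in µm (must be at least 10x the largest beam waist so
    the box approximates an open reservoir), ``bin_width`` in µs,
    ``duration`` in s (default the standard 10-s recording), ``seed`` for
    all randomness of one trace.
    """

    side_length: float  # µm
    bin_width: float  # µs
    duration: float = 10.0  # s
    seed: int = 0

    def __post_init__(self) -> None:
        if self.side_length <= 0 or self.bin_width <= 0 or self.duration <= 0:
            raise ValueError("box dimensions must be positive")
        n = self.duration * 1e6 / self.bin_width
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration must be a whole number of bins")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration * 1e6 / self.bin_width))

    @property
    def volume_fl(self) -> float:
        return self.side_length**3


def default_optics() -> tuple[DetectionVolume, DetectionVolume]:
    """Ground-truth detection volumes used by the generator by default.

    A high-NA confocal geometry with a tight pinhole: green ω = 0.20 µm,
    red ω = 0.22 µm, structure parameter 3 on both channels. The modest
    axial extent keeps the detection profile well inside the periodic
    simulation box, so the infinite-space correlation models apply.
    """
    return (
        DetectionVolume(waist=0.20, axial=0.60, channel="green"),
        DetectionVolume(waist=0.22, axial=0.66, channel="red"),
    )


def default_box(
    green_vol: DetectionVolume,
    red_vol: DetectionVolume,
    *,
    bin_width: float,
    duration: float = 10.0,
    seed: int = 0,
    side_factor: float = 10.0,
) -> SimulationBox:
    """A box sized to ``side_factor`` times the largest beam waist."""
    side = side_factor * max(green_vol.waist, red_vol.waist)
    return SimulationBox(side_length=side, bin_width=bin_width, duration=duration, seed=seed)


def _substeps(box: SimulationBox, diffusion: float, min_waist: float) -> int:
    """Sub-steps per bin so that one step's r.m.s. displacement <= ω/10."""
    if diffusion <= 0:
        return 1
    max_dt_us = min_waist**2 / (200.0 * diffusion * 1e-6)
    return max(1, int(math.ceil(box.bin_width / max_dt_us)))


#: Steps simulated per kernel call; fixed so random draws are reproducible.
_CHUNK_STEPS = 8192


def _simulate_species(
    rng: np.random.Generator,
    lam_g: np.ndarray,
    lam_r: np.ndarray,
    n_particles: int,
    diffusion: float,
    eps_g: float,
    eps_r: float,
    mix: SpeciesMix,
    green_vol: DetectionVolume,
    red_vol: DetectionVolume,
    box: SimulationBox,
    substeps: int,
) -> None:
    """Drive the jitted propagator for one species over the whole recording.

    Standard-normal steps and telegraph uniforms are drawn in bulk per chunk
    from ``rng`` (fixed chunk layout, hence deterministic) and handed to the
    kernel together with the particle state, which persists across chunks.
    """
    n_bins = box.n_bins
    dt_us = box.bin_width / substeps
    dt_s = dt_us * 1e-6
    step_sd = math.sqrt(2.0 * diffusion * dt_s)
    side = box.side_length

    xs = rng.uniform(-side / 2, side / 2, n_particles)
    ys = rng.uniform(-side / 2, side / 2, n_particles)
    zs = rng.uniform(-side / 2, side / 2, n_particles)

    blink = mix.triplet_fraction > 0.0
    if blink:
        relax = 1.0 - math.exp(-dt_us / mix.triplet_tau)
        p_bd = mix.triplet_fraction * relax
        p_db = (1.0 - mix.triplet_fraction) * relax
        bright_g = (rng.random(n_particles) >= mix.triplet_fraction).astype(np.uint8)
        bright_r = (rng.random(n_particles) >= mix.triplet_fraction).astype(np.uint8)
    else:
        p_bd = p_db = 0.0
        bright_g = np.ones(n_particles, np.uint8)
        bright_r = np.ones(n_particles, np.uint8)

    empty = np.empty((0, 0), dtype=np.float32)
    chunk_bins = max(1, _CHUNK_STEPS // substeps)
    total_steps = n_bins * substeps
    first_bin = 0
    while first_bin < n_bins:
        bins_here = min(chunk_bins, n_bins - first_bin)
        steps_here = bins_here * substeps
        normals = rng.standard_normal((steps_here, n_particles, 3), dtype=np.float32)
        u_g = (
            rng.random((steps_here, n_particles), dtype=np.float32)
            if blink and eps_g > 0
            else empty
        )
        u_r = (
            rng.random((steps_here, n_particles), dtype=np.float32)
            if blink and eps_r > 0
            else empty
        )
        propagate_chunk(
            lam_g,
            lam_r,
            first_bin,
            substeps,
            xs,
            ys,
            zs,
            bright_g,
            bright_r,
            normals,
            u_g,
            u_r,
            step_sd,
            side,
            2.0 / green_vol.waist**2,
            2.0 / green_vol.axial**2,
            2.0 / red_vol.waist**2,
            2.0 / red_vol.axial**2,
            p_bd,
            p_db,
            eps_g * dt_s,
            eps_r * dt_s,
        )
        first_bin += bins_here
    assert first_bin * substeps == total_steps


def simulate_fccs_trace(
    mix: SpeciesMix,
    green_vol: DetectionVolume,
    red_vol: DetectionVolume,
    box: SimulationBox,
    *,
    exact_particle_numbers: bool = False,
) -> PhotonTrace:
    """Simulate one two-colour recording of a binding mixture.

    Particles of each species are placed Poisson-distributed at
    concentration x box volume, propagated by isotropic Brownian steps with
    periodic wrapping, blink through a two-state triplet telegraph process,
    and emit photons through the channel-specific Gaussian detection
    profiles; per-bin photon counts are Poisson draws around the accumulated
    expectation. Complexes carry both fluorophores. Deterministic given
    ``box.seed``.

    With ``exact_particle_numbers`` the per-species particle count is the
    rounded expectation instead of a Poisson draw — emulating a measurement
    in a macroscopic reservoir whose concentration is known exactly, as in
    a reference-dye dilution; the default Poisson draw emulates the
    expression variability of individual cells.
    """
    if box.side_length < 10.0 * max(green_vol.waist, red_vol.waist):
        raise ConfigurationError(
            "box side must be at least 10x the largest beam waist "
            f"({box.side_length} µm < 10 x {max(green_vol.waist, red_vol.waist)} µm)"
        )
    n_bins = box.n_bins
    lam_g = np.zeros(n_bins)
    lam_r = np.zeros(n_bins)
    eps_g = float(mix.brightness["green"])
    eps_r = float(mix.brightness["red"])
    species = (
        ("free_green", mix.free_green, eps_g, 0.0),
        ("free_red", mix.free_red, 0.0, eps_r),
        ("complex", mix.complex, eps_g, eps_r),
    )
    min_waist = min(green_vol.waist, red_vol.waist)
    rng = np.random.default_rng(np.random.SeedSequence((int(box.seed), 0)))
    n_particles_drawn = {}
    for idx, (name, conc, e_g, e_r) in enumerate(species):
        mean_n = conc * box.volume_fl * MOLECULES_PER_NM_FL
        if exact_particle_numbers:
            n = int(round(mean_n))
        else:
            n = int(rng.poisson(mean_n)) if mean_n > 0 else 0
        n_particles_drawn[name] = n
        if n == 0:
            continue
        d = float(mix.diffusion[name])
        species_rng = np.random.default_rng(
            np.random.SeedSequence((int(box.seed), 1, idx))
        )
        _simulate_species(
            species_rng,
            lam_g,
            lam_r,
            n,
            d,
            e_g,
            e_r,
            mix,
            green_vol,
            red_vol,
            box,
            _substeps(box, d, min_waist),
        )
    counts_g = rng.poisson(lam_g).astype(np.int64)
    counts_r = rng.poisson(lam_r).astype(np.int64)
    return PhotonTrace(
        counts_green=counts_g,
        counts_red=counts_r,
        bin_width=box.bin_width,
        duration=box.duration,
        metadata={
            "seed": box.seed,
            "kd_true": mix.kd_true,
            "total_green": mix.total_green,
            "total_red": mix.total_red,
            "complex": mix.complex,
            "n_particles": n_particles_drawn,
        },
    )


def expected_count_rate(
    mix: SpeciesMix,
    green_vol: DetectionVolume,
    red_vol: DetectionVolume,
    box: SimulationBox | None = None,
) -> tuple[float, float]:
    """Analytic mean count rates (Hz) of a simulated trace.

    With the peak-normalised Gaussian detection profile, each species
    contributes  C · N_A · ε · ∫W = C · N_A · ε · V_ef / 2^{3/2}  per
    channel, reduced by the bright-state fraction (1 − T). When ``box`` is
    given, the detection-profile integral is truncated to the periodic box
    (erf factors per axis), matching what a finite simulation volume emits.
    """

    def trunc(vol: DetectionVolume) -> float:
        if box is None:
            return 1.0
        h = box.side_length / 2.0
        lat = math.erf(math.sqrt(2.0) * h / vol.waist)
        ax = math.erf(math.sqrt(2.0) * h / vol.axial)
        return lat * lat * ax

    bright = 1.0 - mix.triplet_fraction
    g = (
        (mix.free_green + mix.complex)
        * green_vol.v_eff
        * MOLECULES_PER_NM_FL
        * mix.brightness["green"]
        / 2**1.5
        * bright
        * trunc(green_vol)
    )
    r = (
        (mix.free_red + mix.complex)
        * red_vol.v_eff
        * MOLECULES_PER_NM_FL
        * mix.brightness["red"]
        / 2**1.5
        * bright
        * trunc(red_vol)
    )
    return float(g), float(r)


# ---------------------------------------------------------------------------
# TCSPC decays


def simulate_tcspc(
    components: Sequence[tuple[float, float]],
    n_photons: int,
    irf_sigma: float = 0.1,
    bin_width: float = 0.05,
    t_range: float = 25.0,
    seed: int = 0,
) -> TcspcDecay:
    """Simulate a TCSPC decay histogram from an exponential mixture.

    ``components`` is a sequence of ``(amplitude_fraction, lifetime_ns)``
    pairs whose fractions sum to 1. Each photon picks a component by its
    fraction, draws an exponential arrival time and adds Gaussian jitter of
    width ``irf_sigma`` (the instrument response); arrivals are histogrammed
    on [0, t_range) ns. ``n_photons = 0`` yields a valid, flagged empty
    histogram.
    """
    fracs = np.array([c[0] for c in components], dtype=float)
    taus = np.array([c[1] for c in components], dtype=float)
    if (taus <= 0).any():
        raise ValueError("lifetimes must be positive")
    if (fracs < 0).any() or abs(fracs.sum() - 1.0) > 1e-9:
        raise ValueError("amplitude fractions must be non-negative and sum to 1")
    if n_photons < 0:
        raise ValueError("n_photons must be non-negative")
    edges = np.arange(0.0, t_range + bin_width / 2, bin_width)
    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 2)))
    if n_photons == 0:
        counts = np.zeros(len(edges) - 1, dtype=np.int64)
    else:
        comp = rng.choice(len(fracs), size=n_photons, p=fracs)
        t = rng.exponential(taus[comp])
        if irf_sigma > 0:
            t = t + rng.normal(0.0, irf_sigma, size=n_photons)
        counts, _ = np.histogram(t, bins=edges)
        counts = counts.astype(np.int64)
    return TcspcDecay(
        bin_edges=edges,
        counts=counts,
        irf_sigma=irf_sigma,
        metadata={
            "seed": seed,
            "components": [(float(f), float(t)) for f, t in components],
            "n_photons_drawn": int(n_photons),
        },
    )


# ---------------------------------------------------------------------------
# Labelled cell grids (kinase translocation reporter fixtures)


@dataclass(frozen=True)
class CellRecord:
    """One cell: graph distance from the clone and reporter intensities."""

    row_distance: int  # 0 iff part of the signal-producing clone
    is_clone: bool
    nuclear_intensity: float  # a.u.
    cytoplasmic_intensity: float  # a.u.

    def __post_init__(self) -> None:
        if self.nuclear_intensity < 0 or self.cytoplasmic_intensity < 0:
            raise ValueError("intensities must be non-negative")
        if (self.row_distance == 0) != self.is_clone:
            raise ValueError("row_distance is 0 exactly for clone cells")


@dataclass(frozen=True)
class CellGrid:
    """A field of cells around a signal-producing clone."""

    cells: tuple[CellRecord, ...]

    def __post_init__(self) -> None:
        if not any(c.is_clone for c in self.cells):
            raise ValueError("grid contains no clone cells")


def generate_cell_grid(
    n_rows: int,
    n_cols: int,
    clone_cells: Sequence[tuple[int, int]],
    activity_vs_row: Mapping[int, float],
    seed: int = 0,
    *,
    threshold: float = 1.0,
) -> CellGrid:
    """Generate a labelled cell grid with known per-row activity.

    ``clone_cells`` are (row, col) indices of the signal-producing clone;
    every other cell's distance is the breadth-first (4-neighbour) graph
    distance to the clone — the paracrine profile counts cell rows, not
    micrometres. A cell at distance d is active with probability
    ``activity_vs_row.get(d, 0)``; active cells draw a nuclear/cytoplasmic
    reporter ratio below the call ``threshold`` (nuclear exclusion), inactive
    cells above it.
    """
    for p in activity_vs_row.values():
        if not 0.0 <= p <= 1.0:
            raise ValueError("activity probabilities must be in [0, 1]")
    clone = set()
    for r, c in clone_cells:
        if not (0 <= r < n_rows and 0 <= c < n_cols):
            raise ValueError(f"clone cell {(r, c)} outside the {n_rows}x{n_cols} grid")
        clone.add((r, c))
    if not clone:
        raise ValueError("at least one clone cell required")

    # Breadth-first distances over 4-neighbour adjacency.
    dist = {cell: 0 for cell in clone}
    frontier = list(clone)
    while frontier:
        nxt = []
        for r, c in frontier:
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if 0 <= rr < n_rows and 0 <= cc < n_cols and (rr, cc) not in dist:
                    dist[(rr, cc)] = dist[(r, c)] + 1
                    nxt.append((rr, cc))
        frontier = nxt

    rng = np.random.default_rng(np.random.SeedSequence((int(seed), 3)))
    cells = []
    for r in range(n_rows):
        for c in range(n_cols):
            d = dist[(r, c)]
            is_clone = d == 0
            cyto = rng.uniform(80.0, 120.0)
            if is_clone:
                ratio = rng.uniform(0.2, 0.8) * threshold  # clones signal autocrinely
            else:
                active = rng.random() < activity_vs_row.get(d, 0.0)
                if active:
                    ratio = rng.uniform(0.2, 0.8) * threshold
                else:
                    ratio = rng.uniform(1.2, 2.0) * threshold
            cells.append(
                CellRecord(
                    row_distance=d,
                    is_clone=is_clone,
                    nuclear_intensity=ratio * cyto,
                    cytoplasmic_intensity=cyto,
                )
            )
    return CellGrid(cells=tuple(cells))
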