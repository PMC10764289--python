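"""Shared fixtures: small synthetic datasets reused across the suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from cytofccs.calibration import CalibrationResult, cross_volume
from cytofccs.config import RunConfig
from cytofccs.pipeline import make_calibration
from cytofccs.synthetic import (
    SimulationBox,
    default_optics,
    equilibrium_mixture,
    simulate_fccs_trace,
)

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def optics():
    """Ground-truth detection volumes of the generator."""
    return default_optics()


@pytest.fixture(scope="session")
def exact_calibration(optics):
    """Calibration carrying the generator's true geometry.

    Used where a test isolates the estimator chain from calibration error.
    """
    green, red = optics
    return CalibrationResult(
        green=green, red=red, v_cc=cross_volume(green, red), dye_diffusion=400.0
    )


@pytest.fixture(scope="session")
def dye_calibration():
    """A dye-trace-derived calibration (2.5-s dye recordings).

    Built once per session and shared by every test that needs a realistic
    (rather than ground-truth) calibration.
    """
    cfg = RunConfig.model_validate({"seed": 7, "calibration": {"duration_s": 2.5}})
    return make_calibration(cfg)


def make_single_species_trace(
    *,
    concentration_nm: float = 10.0,
    diffusion: float = 50.0,
    duration: float = 0.8,
    bin_width: float = 4.0,
    seed: int = 0,
    channel: str = "green",
    triplet_fraction: float = 0.0,
    triplet_tau: float = 5.0,
    brightness: float = 60_000.0,
    side_factor: float = 12.0,
    exact_particle_numbers: bool = True,
):
    """One-species recording on a small box; cheap enough for unit tests."""
    green, red = default_optics()
    mix = equilibrium_mixture(
        concentration_nm if channel == "green" else 0.0,
        concentration_nm if channel == "red" else 0.0,
        float("inf"),
        diffusion={"free_green": diffusion, "free_red": diffusion, "complex": diffusion},
        brightness={"green": brightness, "red": brightness},
        triplet_fraction=triplet_fraction,
        triplet_tau=triplet_tau,
    )
    side = side_factor * max(green.waist, red.waist)
    box = SimulationBox(side_length=side, bin_width=bin_width, duration=duration, seed=seed)
    return (
        simulate_fccs_trace(
            mix, green, red, box, exact_particle_numbers=exact_particle_numbers
        ),
        mix,
        box,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
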