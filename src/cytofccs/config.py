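"""Run configuration: a strict, fully-defaulted schema for pipeline runs.

Configurations are YAML documents validated against pydantic models with
unknown keys rejected, so every "paper-silent" default is explicit and
auditable; the resolved configuration (defaults included) is recorded in
the run manifest.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class OpticsConfig(_Strict):
    """Ground-truth detection geometry used by the simulator."""

    green_waist_um: float = Field(0.20, gt=0)
    green_axial_um: float = Field(0.60, gt=0)
    red_waist_um: float = Field(0.22, gt=0)
    red_axial_um: float = Field(0.66, gt=0)
    box_side_factor: float = Field(10.0, ge=10.0)


class CalibrationConfig(_Strict):
    """Reference-dye calibration settings."""

    dye_diffusion_um2_s: float = Field(400.0, gt=0)
    green_concentrations_nm: list[float] = [3.0, 6.0]
    red_concentrations_nm: list[float] = [4.0, 8.0]
    duration_s: float = Field(3.0, gt=0)
    bin_width_us: float = Field(1.0, gt=0)
    # The dye is fast, so calibration fits use the curve shape out to the
    # axial-decay tail; a roomier box keeps that tail free of wrap effects.
    box_side_factor: float = Field(16.0, ge=10.0)
    dye_brightness_hz: float = Field(60000.0, gt=0)
    dye_triplet_fraction: float = Field(0.1, ge=0, lt=1)
    dye_triplet_tau_us: float = Field(3.0, gt=0)
    # Quality gate: maximum relative spread of fitted diffusion times
    # across the dilution series; scaled-down runs may need it wider.
    max_tau_d_spread: float = Field(0.2, gt=0)


class SampleConfig(_Strict):
    """Binding-mixture measurement settings."""

    kd_true_nm: float = Field(440.0, ge=0)
    total_green_nm: float = Field(300.0, ge=0)
    total_red_nm: float = Field(300.0, ge=0)
    n_traces: int = Field(20, ge=1)
    duration_s: float = Field(10.0, gt=0)
    bin_width_us: float = Field(250.0, gt=0)
    diffusion_free_um2_s: float = Field(0.8, gt=0)
    diffusion_complex_um2_s: float = Field(0.5, gt=0)
    brightness_hz: float = Field(30000.0, gt=0)
    triplet_fraction: float = Field(0.15, ge=0, lt=1)
    triplet_tau_us: float = Field(5.0, gt=0)


class CorrelatorConfig(_Strict):
    points_per_octave: int = Field(16, ge=4)
    n_segments: int = Field(10, ge=2)
    # Sample fits use the amplitude-sensitive early curve; the slow tail's
    # correlated noise would otherwise bias the cross-amplitude low.
    fit_max_lag_us: float | None = Field(30_000.0, gt=0)


class AffinityConfig(_Strict):
    exclusion_threshold_nm: float = Field(2000.0, gt=0)
    exclusion_rule: str = "either"
    kd_bin_edges_nm: list[float] = [0.0, 200.0, 400.0, 600.0, 800.0, 1000.0, 2000.0]

    @model_validator(mode="after")
    def _check(self):
        if self.exclusion_rule not in ("either", "both"):
            raise ValueError("exclusion_rule must be 'either' or 'both'")
        if sorted(self.kd_bin_edges_nm) != self.kd_bin_edges_nm:
            raise ValueError("kd_bin_edges_nm must be increasing")
        return self


class FlimConfig(_Strict):
    donor_lifetime_ns: float = Field(2.5, gt=0)
    true_efficiency: float = Field(0.11, ge=0, lt=1)
    n_donor_rois: int = Field(5, ge=1)
    n_sample_rois: int = Field(5, ge=1)
    n_photons: int = Field(100_000, ge=0)
    irf_sigma_ns: float = Field(0.1, ge=0)
    bin_width_ns: float = Field(0.05, gt=0)
    t_range_ns: float = Field(25.0, gt=0)
    forster_r0_angstrom: float = Field(52.4, gt=0)
    n_fit_components: int = Field(1, ge=1, le=2)


class MorphoConfig(_Strict):
    n_rows: int = Field(9, ge=3)
    n_cols: int = Field(9, ge=3)
    activity_by_row: dict[int, float] = {1: 0.8, 2: 0.7, 3: 0.5, 4: 0.3, 5: 0.2}
    ktr_threshold: float = Field(1.0, gt=0)
    filopodia_bin_edges_um: list[float] = [0.0, 5.0, 10.0, 20.0, 50.0]


class RunConfig(_Strict):
    """Top-level configuration of one reproducible pipeline run."""

    seed: int = Field(0, ge=0)
    output_dir: Path = Path("run_output")
    use_text_traces: bool = False
    optics: OpticsConfig = OpticsConfig()
    calibration: CalibrationConfig = CalibrationConfig()
    sample: SampleConfig = SampleConfig()
    correlator: CorrelatorConfig = CorrelatorConfig()
    affinity: AffinityConfig = AffinityConfig()
    flim: FlimConfig = FlimConfig()
    morpho: MorphoConfig = MorphoConfig()


def load_config(path: str | Path) -> RunConfig:
    """Load and strictly validate a YAML run configuration."""
    with open(path) as f:
        data = yaml.safe_load(f) or {}
    return RunConfig.model_validate(data)


def dump_config(config: RunConfig) -> str:
    """Serialise a configuration, defaults included, to canonical YAML."""
    data = config.model_dump(mode="json")
    return yaml.safe_dump(data, sort_keys=True)
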