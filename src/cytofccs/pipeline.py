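"""Configuration-driven pipeline binding all stages into reproducible runs.

Stages (``simulate → calibrate → correlate → fit → kd`` for FCCS, plus the
independent ``flim`` and ``morpho`` stages, or ``all``) read and write
well-defined artifacts under the configured output directory, and a JSON
manifest records the resolved configuration, its hash, seeds and a content
hash of every output, so that a rerun with the same configuration is
verifiably identical for the deterministic stages.

The module also exposes the in-memory experiment helpers
(`make_calibration`, `simulate_measurement_traces`, `kd_recovery_experiment`,
`flim_recovery_experiment`) that tests and the acceptance analysis reuse.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from . import __version__
from .affinity import (
    aggregate_kd,
    analyze_trace,
    apply_exclusion,
    bin_kd,
    fit_measurement_curves,
    measurement_from_fits,
)
from .calibration import CalibrationResult, DetectionVolume, calibrate
from .config import RunConfig, dump_config
from .correlate import PhotonTrace, multi_tau_correlate
from .flim import roi_fret_analysis
from .io import (
    read_curve_text,
    read_decay_text,
    read_json,
    read_traces_h5,
    write_curve_text,
    write_decay_text,
    write_json,
    write_measurements_jsonl,
    write_traces_h5,
)
from .morphometrics import paracrine_profile
from .synthetic import (
    SimulationBox,
    SpeciesMix,
    default_box,
    equilibrium_mixture,
    generate_cell_grid,
    simulate_fccs_trace,
    simulate_tcspc,
    spawn_seed,
)

__all__ = [
    "DependencyError",
    "run_pipeline",
    "STAGES",
    "make_calibration",
    "simulate_measurement_traces",
    "kd_recovery_experiment",
    "flim_recovery_experiment",
]

STAGES = ("simulate", "calibrate", "correlate", "fit", "kd", "flim", "morpho", "all")

# Seed-stream identifiers for the counter-based fan-out.
_STREAM_CAL_GREEN = 10
_STREAM_CAL_RED = 11
_STREAM_SAMPLE = 12
_STREAM_FLIM_DONOR = 13
_STREAM_FLIM_SAMPLE = 14
_STREAM_MORPHO = 15


class DependencyError(RuntimeError):
    """An upstream artifact required by the requested stage is missing."""


# ---------------------------------------------------------------------------
# In-memory experiment helpers


def _optics(config: RunConfig) -> tuple[DetectionVolume, DetectionVolume]:
    o = config.optics
    return (
        DetectionVolume(waist=o.green_waist_um, axial=o.green_axial_um, channel="green"),
        DetectionVolume(waist=o.red_waist_um, axial=o.red_axial_um, channel="red"),
    )


def _dye_mix(concentration: float, channel: str, config: RunConfig) -> SpeciesMix:
    cal = config.calibration
    return equilibrium_mixture(
        total_green=concentration if channel == "green" else 0.0,
        total_red=concentration if channel == "red" else 0.0,
        kd_true=float("inf"),
        diffusion={
            "free_green": cal.dye_diffusion_um2_s,
            "free_red": cal.dye_diffusion_um2_s,
            "complex": cal.dye_diffusion_um2_s,
        },
        brightness={"green": cal.dye_brightness_hz, "red": cal.dye_brightness_hz},
        triplet_fraction=cal.dye_triplet_fraction,
        triplet_tau=cal.dye_triplet_tau_us,
    )


def simulate_calibration_traces(
    config: RunConfig,
) -> tuple[list[PhotonTrace], list[PhotonTrace]]:
    """Simulate the reference-dye dilution series for both channels."""
    green_vol, red_vol = _optics(config)
    cal = config.calibration
    out: dict[str, list[PhotonTrace]] = {"green": [], "red": []}
    for channel, stream, concs in (
        ("green", _STREAM_CAL_GREEN, cal.green_concentrations_nm),
        ("red", _STREAM_CAL_RED, cal.red_concentrations_nm),
    ):
        for i, conc in enumerate(concs):
            box = default_box(
                green_vol,
                red_vol,
                bin_width=cal.bin_width_us,
                duration=cal.duration_s,
                seed=spawn_seed(config.seed, stream, i),
                side_factor=cal.box_side_factor,
            )
            out[channel].append(
                simulate_fccs_trace(
                    _dye_mix(conc, channel, config),
                    green_vol,
                    red_vol,
                    box,
                    exact_particle_numbers=True,
                )
            )
    return out["green"], out["red"]


def make_calibration(config: RunConfig, max_attempts: int = 3) -> CalibrationResult:
    """Simulate dye traces and calibrate both channels from them.

    If the dilution-consistency gate rejects a calibration (the fitted
    diffusion times disagree beyond the allowed spread), a fresh dilution
    series is acquired — mirroring lab practice, where a failed calibration
    is simply re-measured — up to ``max_attempts`` times before the
    rejection propagates.
    """
    from .calibration import CalibrationError

    last_error: CalibrationError | None = None
    for attempt in range(max_attempts):
        cfg = config if attempt == 0 else config.model_copy(
            update={"seed": spawn_seed(config.seed, 99, attempt)}
        )
        green_traces, red_traces = simulate_calibration_traces(cfg)
        try:
            return calibrate(
                green_traces,
                config.calibration.green_concentrations_nm,
                red_traces,
                config.calibration.red_concentrations_nm,
                dye_diffusion=config.calibration.dye_diffusion_um2_s,
                m=config.correlator.points_per_octave,
                n_segments=config.correlator.n_segments,
                max_tau_d_spread=config.calibration.max_tau_d_spread,
                # dye photophysics are known for reference dyes; fixing the
                # triplet relaxation time decouples it from tau_D
                fit_fixed={"triplet_tau": config.calibration.dye_triplet_tau_us},
            )
        except CalibrationError as err:
            last_error = err
    raise last_error


def sample_mixture(config: RunConfig) -> SpeciesMix:
    s = config.sample
    return equilibrium_mixture(
        s.total_green_nm,
        s.total_red_nm,
        s.kd_true_nm,
        diffusion={
            "free_green": s.diffusion_free_um2_s,
            "free_red": s.diffusion_free_um2_s,
            "complex": s.diffusion_complex_um2_s,
        },
        brightness={"green": s.brightness_hz, "red": s.brightness_hz},
        triplet_fraction=s.triplet_fraction,
        triplet_tau=s.triplet_tau_us,
    )


def simulate_measurement_traces(config: RunConfig) -> list[PhotonTrace]:
    """Simulate the configured number of sample measurement recordings."""
    green_vol, red_vol = _optics(config)
    mix = sample_mixture(config)
    traces = []
    for i in range(config.sample.n_traces):
        box = default_box(
            green_vol,
            red_vol,
            bin_width=config.sample.bin_width_us,
            duration=config.sample.duration_s,
            seed=spawn_seed(config.seed, _STREAM_SAMPLE, i),
            side_factor=config.optics.box_side_factor,
        )
        traces.append(simulate_fccs_trace(mix, green_vol, red_vol, box))
    return traces


def kd_recovery_experiment(
    config: RunConfig, calibration: CalibrationResult | None = None
) -> dict:
    """Full end-to-end K_d recovery: simulate, calibrate, measure, aggregate.

    Returns the calibration, the per-trace measurements (exclusion applied)
    and the aggregate K_d summary.
    """
    if calibration is None:
        calibration = make_calibration(config)
    traces = simulate_measurement_traces(config)
    measurements = [
        analyze_trace(
            t,
            calibration,
            m=config.correlator.points_per_octave,
            n_segments=config.correlator.n_segments,
            max_fit_lag_us=config.correlator.fit_max_lag_us,
        )
        for t in traces
    ]
    retained, excluded = apply_exclusion(
        measurements,
        config.affinity.exclusion_threshold_nm,
        rule=config.affinity.exclusion_rule,
    )
    summary = aggregate_kd(retained) if retained else None
    return {
        "calibration": calibration,
        "measurements": retained + excluded,
        "retained": retained,
        "excluded": excluded,
        "summary": summary,
        "kd_true": config.sample.kd_true_nm,
    }


def flim_recovery_experiment(config: RunConfig) -> dict:
    """Simulate donor-only and quenched decay sets and run the FRET analysis."""
    f = config.flim
    tau_d = f.donor_lifetime_ns
    tau_da = tau_d * (1.0 - f.true_efficiency)
    donors = [
        simulate_tcspc(
            [(1.0, tau_d)],
            f.n_photons,
            irf_sigma=f.irf_sigma_ns,
            bin_width=f.bin_width_ns,
            t_range=f.t_range_ns,
            seed=spawn_seed(config.seed, _STREAM_FLIM_DONOR, i),
        )
        for i in range(f.n_donor_rois)
    ]
    samples = [
        simulate_tcspc(
            [(1.0, tau_da)],
            f.n_photons,
            irf_sigma=f.irf_sigma_ns,
            bin_width=f.bin_width_ns,
            t_range=f.t_range_ns,
            seed=spawn_seed(config.seed, _STREAM_FLIM_SAMPLE, i),
        )
        for i in range(f.n_sample_rois)
    ]
    results = roi_fret_analysis(
        donors,
        samples,
        n_components=f.n_fit_components,
        forster_r0=f.forster_r0_angstrom,
    )
    return {
        "donor_decays": donors,
        "sample_decays": samples,
        "results": results,
        "mean_efficiency": float(np.mean([r.efficiency for r in results])),
        "true_efficiency": f.true_efficiency,
    }


# ---------------------------------------------------------------------------
# Staged, on-disk pipeline


def _hash_bytes(*chunks: bytes) -> str:
    h = hashlib.sha256()
    for c in chunks:
        h.update(c)
    return h.hexdigest()


def _trace_content_hash(trace: PhotonTrace) -> str:
    return _hash_bytes(
        np.ascontiguousarray(trace.counts_green, dtype=np.int64).tobytes(),
        np.ascontiguousarray(trace.counts_red, dtype=np.int64).tobytes(),
        repr((trace.bin_width, trace.duration)).encode(),
    )


def _file_hash(path: Path) -> str:
    return _hash_bytes(path.read_bytes())


class _Run:
    """Bookkeeping for one pipeline invocation."""

    def __init__(self, config: RunConfig):
        self.config = config
        self.out = Path(config.output_dir)
        self.out.mkdir(parents=True, exist_ok=True)
        self.outputs: dict[str, str] = {}

    def path(self, name: str) -> Path:
        return self.out / name

    def record(self, name: str, content_hash: str | None = None) -> None:
        p = self.path(name)
        self.outputs[name] = content_hash if content_hash else _file_hash(p)

    def require(self, name: str, stage: str) -> Path:
        p = self.path(name)
        if not p.exists():
            raise DependencyError(
                f"stage {stage!r} requires {name}, which has not been produced; "
                f"run the upstream stage first"
            )
        return p


def _stage_simulate(run: _Run) -> None:
    cfg = run.config
    green_traces, red_traces = simulate_calibration_traces(cfg)
    cal_traces = {
        **{f"cal_green_{i}": t for i, t in enumerate(green_traces)},
        **{f"cal_red_{i}": t for i, t in enumerate(red_traces)},
    }
    sample_traces = {
        f"sample_{i}": t for i, t in enumerate(simulate_measurement_traces(cfg))
    }
    write_traces_h5(run.path("traces_calibration.h5"), cal_traces)
    write_traces_h5(run.path("traces_samples.h5"), sample_traces)
    run.record(
        "traces_calibration.h5",
        _hash_bytes(*[_trace_content_hash(t).encode() for t in cal_traces.values()]),
    )
    run.record(
        "traces_samples.h5",
        _hash_bytes(*[_trace_content_hash(t).encode() for t in sample_traces.values()]),
    )
    mix = sample_mixture(cfg)
    write_json(
        run.path("ground_truth.json"),
        {
            "kd_true_nm": mix.kd_true,
            "total_green_nm": mix.total_green,
            "total_red_nm": mix.total_red,
            "free_green_nm": mix.free_green,
            "free_red_nm": mix.free_red,
            "complex_nm": mix.complex,
        },
    )
    run.record("ground_truth.json")

    decay_dir = run.path("decays")
    decay_dir.mkdir(exist_ok=True)
    flim = flim_recovery_experiment(cfg)
    for i, d in enumerate(flim["donor_decays"]):
        write_decay_text(decay_dir / f"donor_{i}.tsv", d)
        run.record(f"decays/donor_{i}.tsv")
    for i, d in enumerate(flim["sample_decays"]):
        write_decay_text(decay_dir / f"sample_{i}.tsv", d)
        run.record(f"decays/sample_{i}.tsv")


def _stage_calibrate(run: _Run) -> None:
    cfg = run.config
    path = run.require("traces_calibration.h5", "calibrate")
    traces = read_traces_h5(path)
    n_green = len(cfg.calibration.green_concentrations_nm)
    n_red = len(cfg.calibration.red_concentrations_nm)
    green = [traces[f"cal_green_{i}"] for i in range(n_green)]
    red = [traces[f"cal_red_{i}"] for i in range(n_red)]
    cal = calibrate(
        green,
        cfg.calibration.green_concentrations_nm,
        red,
        cfg.calibration.red_concentrations_nm,
        dye_diffusion=cfg.calibration.dye_diffusion_um2_s,
        m=cfg.correlator.points_per_octave,
        n_segments=cfg.correlator.n_segments,
        max_tau_d_spread=cfg.calibration.max_tau_d_spread,
        fit_fixed={"triplet_tau": cfg.calibration.dye_triplet_tau_us},
    )
    write_json(
        run.path("calibration.json"),
        {
            "green": {"waist_um": cal.green.waist, "axial_um": cal.green.axial, "v_eff_fl": cal.green.v_eff},
            "red": {"waist_um": cal.red.waist, "axial_um": cal.red.axial, "v_eff_fl": cal.red.v_eff},
            "v_cc_fl": cal.v_cc,
            "dye_diffusion_um2_s": cal.dye_diffusion,
            "n_concentration_ratio": {
                ch: cal.channel_details[ch].n_concentration_ratio
                for ch in ("green", "red")
            },
        },
    )
    run.record("calibration.json")


def _load_calibration(run: _Run, stage: str) -> CalibrationResult:
    data = read_json(run.require("calibration.json", stage))
    green = DetectionVolume(
        waist=data["green"]["waist_um"], axial=data["green"]["axial_um"], channel="green"
    )
    red = DetectionVolume(
        waist=data["red"]["waist_um"], axial=data["red"]["axial_um"], channel="red"
    )
    return CalibrationResult(
        green=green, red=red, v_cc=data["v_cc_fl"], dye_diffusion=data["dye_diffusion_um2_s"]
    )


def _stage_correlate(run: _Run) -> None:
    cfg = run.config
    traces = read_traces_h5(run.require("traces_samples.h5", "correlate"))
    curve_dir = run.path("curves")
    curve_dir.mkdir(exist_ok=True)
    for name in sorted(traces):
        for kind in ("auto_green", "auto_red", "cross"):
            curve = multi_tau_correlate(
                traces[name],
                kind,
                m=cfg.correlator.points_per_octave,
                n_segments=cfg.correlator.n_segments,
            )
            fname = f"curves/{name}_{kind}.tsv"
            write_curve_text(run.path(fname), curve)
            run.record(fname)


def _stage_fit(run: _Run) -> None:
    cal = _load_calibration(run, "fit")
    curve_dir = run.require("curves", "fit")
    names = sorted(
        {p.name.rsplit("_auto_green.tsv", 1)[0] for p in curve_dir.glob("*_auto_green.tsv")}
    )
    if not names:
        raise DependencyError("stage 'fit' found no correlation curves")
    records = {}
    cap = run.config.correlator.fit_max_lag_us
    for name in names:
        curves = {
            kind: read_curve_text(curve_dir / f"{name}_{kind}.tsv")
            for kind in ("auto_green", "auto_red", "cross")
        }
        if cap is not None:
            curves = {
                k: (c.restrict(cap) if cap < c.lags[-1] else c)
                for k, c in curves.items()
            }
        fits = fit_measurement_curves(
            curves["auto_green"], curves["auto_red"], curves["cross"], cal
        )
        rec = {"cross_noise_floor": fits["cross_noise_floor"]}
        for kind in ("auto_green", "auto_red"):
            f = fits[kind]
            rec[kind] = {
                "n_molecules": f.n_molecules,
                "tau_d_us": f.tau_d,
                "triplet_fraction": f.triplet_fraction,
                "triplet_tau_us": f.triplet_tau,
                "structure_parameter": f.structure_parameter,
                "chi2": f.chi2,
            }
        rec["cross"] = (
            None
            if fits["cross"] is None
            else {
                "n_molecules": fits["cross"].n_molecules,
                "tau_d_us": fits["cross"].tau_d,
                "structure_parameter": fits["cross"].structure_parameter,
                "chi2": fits["cross"].chi2,
            }
        )
        records[name] = rec
    write_json(run.path("fits.json"), records)
    run.record("fits.json")


def _stage_kd(run: _Run) -> None:
    cfg = run.config
    cal = _load_calibration(run, "kd")
    fits = read_json(run.require("fits.json", "kd"))
    from .models import DiffusionFit, TripletDiffusionFit  # local: record rebuild

    measurements = []
    for name in sorted(fits):
        rec = fits[name]
        fg = TripletDiffusionFit(
            n_molecules=rec["auto_green"]["n_molecules"],
            tau_d=rec["auto_green"]["tau_d_us"],
            triplet_fraction=rec["auto_green"]["triplet_fraction"],
            triplet_tau=rec["auto_green"]["triplet_tau_us"],
            structure_parameter=rec["auto_green"]["structure_parameter"],
            chi2=rec["auto_green"]["chi2"],
        )
        fr = TripletDiffusionFit(
            n_molecules=rec["auto_red"]["n_molecules"],
            tau_d=rec["auto_red"]["tau_d_us"],
            triplet_fraction=rec["auto_red"]["triplet_fraction"],
            triplet_tau=rec["auto_red"]["triplet_tau_us"],
            structure_parameter=rec["auto_red"]["structure_parameter"],
            chi2=rec["auto_red"]["chi2"],
        )
        fc = (
            None
            if rec["cross"] is None
            else DiffusionFit(
                n_molecules=rec["cross"]["n_molecules"],
                tau_d=rec["cross"]["tau_d_us"],
                structure_parameter=rec["cross"]["structure_parameter"],
                chi2=rec["cross"]["chi2"],
            )
        )
        measurements.append(
            measurement_from_fits(
                fg, fr, fc, rec["cross_noise_floor"], cal, location_label=name
            )
        )
    retained, excluded = apply_exclusion(
        measurements, cfg.affinity.exclusion_threshold_nm, rule=cfg.affinity.exclusion_rule
    )
    write_measurements_jsonl(run.path("measurements.jsonl"), retained + excluded)
    run.record("measurements.jsonl")
    import pandas as pd

    table = pd.DataFrame(
        [
            {
                "measurement": m.location_label,
                "c_green_nM": m.c_green,
                "c_red_nM": m.c_red,
                "c_cc_nM": m.c_cc,
                "kd_nM": m.kd,
                "kd_is_lower_bound": m.kd_is_lower_bound,
                "excluded": m.excluded,
            }
            for m in retained + excluded
        ]
    )
    table.to_csv(run.path("kd_table.tsv"), sep="\t", index=False)
    run.record("kd_table.tsv")
    summary: dict = {"n_excluded": len(excluded)}
    if any(not m.kd_is_lower_bound for m in retained):
        agg = aggregate_kd(retained)
        summary.update(
            {"kd_mean_nm": agg.mean, "kd_sd_nm": agg.sd, "n": agg.n, "lower_bounds_nm": list(agg.lower_bounds)}
        )
        counts, pct = bin_kd(retained, cfg.affinity.kd_bin_edges_nm)
        summary["bins"] = {
            "edges_nm": list(cfg.affinity.kd_bin_edges_nm),
            "counts": counts.tolist(),
            "percent": pct.tolist(),
        }
    else:
        summary["lower_bounds_nm"] = [m.kd for m in retained if m.kd_is_lower_bound]
    write_json(run.path("kd_summary.json"), summary)
    run.record("kd_summary.json")


def _stage_flim(run: _Run) -> None:
    cfg = run.config
    decay_dir = run.require("decays", "flim")
    donors = sorted(decay_dir.glob("donor_*.tsv"))
    samples = sorted(decay_dir.glob("sample_*.tsv"))
    if not donors or not samples:
        raise DependencyError("stage 'flim' requires simulated decay histograms")
    results = roi_fret_analysis(
        [read_decay_text(p) for p in donors],
        [read_decay_text(p) for p in samples],
        n_components=cfg.flim.n_fit_components,
        forster_r0=cfg.flim.forster_r0_angstrom,
    )
    write_json(
        run.path("fret.json"),
        {
            "tau_donor_unquenched_ns": results[0].tau_donor_unquenched,
            "rois": [
                {
                    "tau_da_ns": r.tau_da,
                    "efficiency_percent": 100.0 * r.efficiency,
                    "distance_angstrom": r.distance if r.distance_detectable else None,
                    "detectable": r.distance_detectable,
                }
                for r in results
            ],
            "mean_efficiency_percent": 100.0 * float(np.mean([r.efficiency for r in results])),
        },
    )
    run.record("fret.json")


def _stage_morpho(run: _Run) -> None:
    cfg = run.config
    m = cfg.morpho
    clone = [(m.n_rows // 2, m.n_cols // 2)]
    grid = generate_cell_grid(
        m.n_rows,
        m.n_cols,
        clone,
        m.activity_by_row,
        seed=spawn_seed(cfg.seed, _STREAM_MORPHO),
        threshold=m.ktr_threshold,
    )
    profile = paracrine_profile(grid, max_rows=5, threshold=m.ktr_threshold)
    profile.to_csv(run.path("paracrine_profile.tsv"), sep="\t", index=False)
    run.record("paracrine_profile.tsv")


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "calibrate": _stage_calibrate,
    "correlate": _stage_correlate,
    "fit": _stage_fit,
    "kd": _stage_kd,
    "flim": _stage_flim,
    "morpho": _stage_morpho,
}


def run_pipeline(config: RunConfig, stage: str = "all") -> dict:
    """Execute one pipeline stage (or all of them) and write a manifest.

    Returns the manifest dictionary. The manifest records the resolved
    configuration and its hash, the package version, the stages executed and
    a content hash per output artifact; deterministic stages reproduce
    identical hashes on rerun with the same configuration.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    run = _Run(config)
    stages = list(STAGES[:-1]) if stage == "all" else [stage]
    for s in stages:
        _STAGE_FUNCS[s](run)
    config_yaml = dump_config(config)
    manifest = {
        "package": "cytofccs",
        "version": __version__,
        "seed": config.seed,
        "stages": stages,
        "config": config_yaml,
        "config_hash": _hash_bytes(config_yaml.encode()),
        "outputs": dict(sorted(run.outputs.items())),
    }
    manifest["manifest_hash"] = _hash_bytes(
        json.dumps(
            {k: manifest[k] for k in ("config_hash", "outputs", "stages")}, sort_keys=True
        ).encode()
    )
    write_json(run.path("manifest.json"), manifest)
    return manifest
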