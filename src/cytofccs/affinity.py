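"""From fitted correlation amplitudes to concentrations and dissociation constants.

The chain implemented here is the standard two-colour FCCS affinity readout:

    C_green = N1 / (V_ef,g · N_A)
    C_red   = N2 / (V_ef,r · N_A)
    C_cc    = (N1·N2 / N_cc) · 1 / (V_cc · N_A)
    K_d     = (C_green − C_cc)(C_red − C_cc) / C_cc

where N1 and N2 are the molecule numbers fitted to the two autocorrelations
and N_cc is the amplitude-reciprocal (1/G_cc(0)) fitted to the
cross-correlation — under that reading N1·N2/N_cc is the number of bound
(co-diffusing) molecules in V_cc, which is what makes the C_cc expression a
complex concentration.

Measurements whose per-channel concentration exceeds an exclusion threshold
(default 2,000 nM: strongly over-expressing cells) are excluded but kept for
audit. When the cross-correlation amplitude is indistinguishable from its
noise floor, K_d is reported as a lower bound rather than a point estimate.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .calibration import CalibrationResult
from .correlate import CorrelationCurve, PhotonTrace, multi_tau_correlate
from .models import DiffusionFit, FitError, TripletDiffusionFit, fit_curve
from .units import concentration_nm

__all__ = [
    "FccsMeasurement",
    "KdSummary",
    "EXCLUSION_THRESHOLD_NM",
    "channel_concentration",
    "complex_concentration",
    "dissociation_constant",
    "apply_exclusion",
    "aggregate_kd",
    "relative_affinity",
    "bin_kd",
    "cross_noise_floor",
    "fit_measurement_curves",
    "measurement_from_fits",
    "analyze_trace",
]

#: Per-channel concentration above which a measurement is excluded, nM.
EXCLUSION_THRESHOLD_NM = 2000.0

#: Cross-correlation amplitudes below this multiple of the amplitude noise
#: floor are treated as "no detectable cross-correlation" (lower-bound K_d).
NOISE_FLOOR_SIGMA = 3.0


@dataclass
class FccsMeasurement:
    """One FCCS measurement: fitted numbers, concentrations and K_d.

    ``kd_is_lower_bound`` marks records where the cross-correlation was
    below its noise floor; ``kd`` then holds the bound, to be reported as
    "K_d > value" and never averaged together with point estimates.
    """

    n1: float
    n2: float
    ncc: float
    c_green: float  # nM
    c_red: float  # nM
    c_cc: float  # nM
    kd: float  # nM
    kd_is_lower_bound: bool = False
    excluded: bool = False
    exclusion_reason: str = ""
    location_label: str = ""
    flags: list[str] = field(default_factory=list)
    fits: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kd < 0:
            raise ValueError("K_d must be non-negative")
        if self.c_cc > min(self.c_green, self.c_red) * (1 + 1e-9) + 1e-9:
            raise ValueError("complex concentration exceeds a channel concentration")


@dataclass
class KdSummary:
    """Aggregate of K_d point estimates; bounds reported separately."""

    mean: float
    sd: float  # nan for a single value
    n: int
    lower_bounds: tuple[float, ...] = ()

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        sd = "n/a" if math.isnan(self.sd) else f"{self.sd:.0f}"
        s = f"K_d = {self.mean:.0f} ± {sd} nM (n = {self.n})"
        if self.lower_bounds:
            bounds = ", ".join(f">{b:.0f}" for b in self.lower_bounds)
            s += f"; lower bounds: {bounds} nM"
        return s


def channel_concentration(n_molecules: float, v_eff: float) -> float:
    """Concentration (nM) of N molecules observed in an effective volume (fl)."""
    if v_eff <= 0:
        raise ValueError("effective volume must be positive")
    if n_molecules < 0:
        raise ValueError("molecule number must be non-negative")
    return concentration_nm(n_molecules, v_eff)


def complex_concentration(n1: float, n2: float, ncc: float, v_cc: float) -> float:
    """Complex concentration C_cc = (N1·N2/N_cc) / (V_cc·N_A), in nM.

    ``ncc`` is the amplitude-reciprocal of the cross-correlation fit
    (1/G_cc(0)); N1·N2/N_cc is then the bound-molecule count in V_cc.
    """
    if ncc <= 0:
        raise ValueError("no detectable cross-correlation (N_cc <= 0)")
    return concentration_nm(n1 * n2 / ncc, v_cc)


def dissociation_constant(c_green: float, c_red: float, c_cc: float) -> float:
    """K_d = (C_green − C_cc)(C_red − C_cc) / C_cc, all in nM.

    A complex concentration exceeding a channel concentration (possible
    through fit noise) is clipped to that channel's value with a warning.
    """
    if c_cc <= 0:
        raise ValueError("c_cc must be positive; use the lower-bound path instead")
    cmin = min(c_green, c_red)
    if c_cc > cmin:
        warnings.warn(
            f"c_cc={c_cc:.3g} nM exceeds a channel concentration; clipped to {cmin:.3g} nM",
            stacklevel=2,
        )
        c_cc = cmin
    return (c_green - c_cc) * (c_red - c_cc) / c_cc


def apply_exclusion(
    measurements: Sequence[FccsMeasurement],
    threshold: float = EXCLUSION_THRESHOLD_NM,
    *,
    rule: str = "either",
) -> tuple[list[FccsMeasurement], list[FccsMeasurement]]:
    """Partition measurements by the over-expression exclusion rule.

    A measurement is excluded when a channel concentration strictly exceeds
    ``threshold`` (default 2,000 nM); boundary values are retained. ``rule``
    selects whether one offending channel suffices (``"either"``, the
    conservative default) or both must offend (``"both"``). Excluded records
    keep their flag and reason for audit; nothing is dropped.
    """
    if rule not in ("either", "both"):
        raise ValueError("rule must be 'either' or 'both'")
    retained: list[FccsMeasurement] = []
    excluded: list[FccsMeasurement] = []
    for meas in measurements:
        over_g = meas.c_green > threshold
        over_r = meas.c_red > threshold
        over = (over_g or over_r) if rule == "either" else (over_g and over_r)
        if over:
            chans = [c for c, o in (("green", over_g), ("red", over_r)) if o]
            excluded.append(
                replace(
                    meas,
                    excluded=True,
                    exclusion_reason=f"{'/'.join(chans)} channel over {threshold:g} nM",
                )
            )
        else:
            retained.append(replace(meas, excluded=False, exclusion_reason=""))
    return retained, excluded


def aggregate_kd(measurements: Sequence[FccsMeasurement]) -> KdSummary:
    """Mean ± s.d. of finite K_d point estimates; bounds listed separately."""
    points = [m.kd for m in measurements if not m.kd_is_lower_bound]
    bounds = tuple(sorted(m.kd for m in measurements if m.kd_is_lower_bound))
    if not points:
        raise ValueError("no K_d point estimates to aggregate")
    mean = float(np.mean(points))
    sd = float(np.std(points, ddof=1)) if len(points) > 1 else math.nan
    return KdSummary(mean=mean, sd=sd, n=len(points), lower_bounds=bounds)


def relative_affinity(
    kd: float, kd_negative_anchor: float, kd_positive_anchor: float
) -> float:
    """Rescale an affinity onto a 0–100 scale between two anchor pairs.

    The affinity measure is a = 1/K_d, linearly rescaled so the negative
    anchor (weak binder) maps to 0 and the positive anchor (strong binder)
    to 100. K_d = 0 saturates at the scale maximum with a warning. Values
    outside the anchors extrapolate beyond [0, 100].
    """
    for name, v in (("negative", kd_negative_anchor), ("positive", kd_positive_anchor)):
        if v <= 0:
            raise ValueError(f"{name} anchor K_d must be positive")
    if kd_negative_anchor == kd_positive_anchor:
        raise ValueError("anchors must be distinct")
    a_neg = 1.0 / kd_negative_anchor
    a_pos = 1.0 / kd_positive_anchor
    if kd < 0:
        raise ValueError("K_d must be non-negative")
    if kd == 0:
        warnings.warn("K_d = 0 saturates the relative-affinity scale", stacklevel=2)
        return 100.0
    a = 1.0 / kd
    score = 100.0 * (a - a_neg) / (a_pos - a_neg)
    return float(score)


def bin_kd(
    measurements: Sequence[FccsMeasurement] | Sequence[float],
    bin_edges: Sequence[float],
) -> tuple[np.ndarray, np.ndarray]:
    """Histogram K_d point estimates into the given bins.

    Returns (counts, percentages); percentages sum to 100 over non-empty
    input. Lower-bound records are not binned.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be strictly increasing")
    values = [
        m.kd if isinstance(m, FccsMeasurement) else float(m)
        for m in measurements
        if not (isinstance(m, FccsMeasurement) and m.kd_is_lower_bound)
    ]
    counts, _ = np.histogram(values, bins=edges)
    total = counts.sum()
    pct = counts * 100.0 / total if total > 0 else np.zeros_like(counts, dtype=float)
    return counts, pct


def cross_noise_floor(cross: "CorrelationCurve", m: int = 16) -> float:
    """Amplitude noise floor of a cross-correlation curve.

    `NOISE_FLOOR_SIGMA` times the typical (median) per-lag standard error
    over the first octave of lags; 0 when no uncertainties are available.
    """
    if cross.sigma is not None and np.any(cross.sigma[:m] > 0):
        return NOISE_FLOOR_SIGMA * float(np.median(cross.sigma[:m]))
    return 0.0


def fit_measurement_curves(
    auto_green: "CorrelationCurve",
    auto_red: "CorrelationCurve",
    cross: "CorrelationCurve",
    calibration: CalibrationResult,
) -> dict:
    """Fit the three curves of one measurement with calibrated geometry.

    Autocorrelations are fitted with the triplet-diffusion model, the
    cross-correlation with the pure-diffusion model; the structure
    parameters are fixed at their calibrated values (the cross fit uses the
    two-channel mean). Returns the fits plus the cross amplitude noise
    floor; a failed cross fit is recorded as None rather than raised, since
    an absent cross-correlation is a valid (lower-bound) outcome.
    """
    s_green = calibration.green.structure_parameter
    s_red = calibration.red.structure_parameter
    fit_g: TripletDiffusionFit = fit_curve(
        auto_green, "triplet_diffusion", fixed={"structure_parameter": s_green}
    )
    fit_r: TripletDiffusionFit = fit_curve(
        auto_red, "triplet_diffusion", fixed={"structure_parameter": s_red}
    )
    cross_fit: DiffusionFit | None
    try:
        cross_fit = fit_curve(
            cross,
            "pure_diffusion",
            fixed={"structure_parameter": 0.5 * (s_green + s_red)},
        )
    except FitError:
        cross_fit = None
    return {
        "auto_green": fit_g,
        "auto_red": fit_r,
        "cross": cross_fit,
        "cross_noise_floor": cross_noise_floor(cross),
    }


def measurement_from_fits(
    fit_green: TripletDiffusionFit,
    fit_red: TripletDiffusionFit,
    cross_fit: DiffusionFit | None,
    cross_noise_floor_g: float,
    calibration: CalibrationResult,
    *,
    location_label: str = "",
) -> FccsMeasurement:
    """Evaluate concentrations and K_d from the three fitted amplitudes.

    If the fitted cross-correlation amplitude 1/N_cc falls below the
    amplitude noise floor — or the cross fit failed — the noise floor itself
    is converted to a concentration and K_d is reported as a lower bound,
    reproducing the "K_d > value" convention for non-cross-correlating
    pairs.
    """
    n1 = fit_green.n_molecules
    n2 = fit_red.n_molecules
    c_green = channel_concentration(n1, calibration.green.v_eff)
    c_red = channel_concentration(n2, calibration.red.v_eff)

    flags: list[str] = []
    if cross_fit is None:
        flags.append("cross_fit_failed")
    lower_bound = cross_fit is None or (
        cross_noise_floor_g > 0 and 1.0 / cross_fit.n_molecules < cross_noise_floor_g
    )
    if lower_bound:
        if cross_noise_floor_g <= 0:
            raise FitError("cross-correlation unusable and no noise floor available")
        ncc = 1.0 / cross_noise_floor_g  # amplitude floor as a molecule number
        flags.append("cross_amplitude_below_noise_floor")
    else:
        ncc = cross_fit.n_molecules

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c_cc = complex_concentration(n1, n2, ncc, calibration.v_cc)
        c_cc = min(c_cc, c_green, c_red)
        kd = dissociation_constant(c_green, c_red, c_cc)

    return FccsMeasurement(
        n1=n1,
        n2=n2,
        ncc=ncc,
        c_green=c_green,
        c_red=c_red,
        c_cc=c_cc,
        kd=kd,
        kd_is_lower_bound=lower_bound,
        location_label=location_label,
        flags=flags,
        fits={"auto_green": fit_green, "auto_red": fit_red, "cross": cross_fit},
    )


def analyze_trace(
    trace: PhotonTrace,
    calibration: CalibrationResult,
    *,
    m: int = 16,
    n_segments: int = 10,
    max_fit_lag_us: float | None = 30_000.0,
    location_label: str = "",
) -> FccsMeasurement:
    """Run the full per-measurement FCCS analysis on one photon trace.

    Correlates both autocorrelations and the cross-correlation, fits them
    with the calibrated geometry (`fit_measurement_curves`) and converts the
    amplitudes to concentrations and a K_d (`measurement_from_fits`).

    ``max_fit_lag_us`` restricts the fits to the amplitude-sensitive early
    part of the curves; the slow tail adds no amplitude information but
    carries correlated noise that the per-lag standard errors understate,
    which would otherwise bias the fitted cross-amplitude low.
    """
    auto_g = multi_tau_correlate(trace, "auto_green", m=m, n_segments=n_segments)
    auto_r = multi_tau_correlate(trace, "auto_red", m=m, n_segments=n_segments)
    cross = multi_tau_correlate(trace, "cross", m=m, n_segments=n_segments)
    if max_fit_lag_us is not None and max_fit_lag_us < auto_g.lags[-1]:
        auto_g = auto_g.restrict(max_fit_lag_us)
        auto_r = auto_r.restrict(max_fit_lag_us)
        cross = cross.restrict(max_fit_lag_us)
    fits = fit_measurement_curves(auto_g, auto_r, cross, calibration)
    return measurement_from_fits(
        fits["auto_green"],
        fits["auto_red"],
        fits["cross"],
        fits["cross_noise_floor"],
        calibration,
        location_label=location_label,
    )
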