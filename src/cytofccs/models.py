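"""FCS correlation models and weighted least-squares curve fitting.

Two model families are provided, matching standard confocal FCS practice:

``triplet_diffusion`` (for autocorrelations of blinking fluorophores)

    G(τ) = (1/N) · (1 + T/(1−T) · e^{−τ/τ_tr})
                 · (1 + τ/τ_D)^{−1} · (1 + τ/(S²τ_D))^{−1/2}

``pure_diffusion`` (for cross-correlations, where independent blinking of
the two fluorophores cancels)

    G(τ) = (1/N) · (1 + τ/τ_D)^{−1} · (1 + τ/(S²τ_D))^{−1/2}

N is the mean number of (co-)diffusing molecules in the effective volume,
τ_D the lateral diffusion time in µs, T the triplet (dark-state) fraction,
τ_tr the triplet relaxation time in µs and S = z/ω the structure parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .correlate import CorrelationCurve

__all__ = [
    "TripletDiffusionFit",
    "DiffusionFit",
    "FitError",
    "triplet_diffusion_model",
    "pure_diffusion_model",
    "fit_curve",
]


class FitError(RuntimeError):
    """Raised when a curve cannot be fitted; callers must flag, not drop."""


# Free parameters (order matters) per model.
_PARAMS = {
    "triplet_diffusion": ("n_molecules", "tau_d", "triplet_fraction", "triplet_tau", "structure_parameter"),
    "pure_diffusion": ("n_molecules", "tau_d", "structure_parameter"),
}

_DEFAULT_BOUNDS = {
    "n_molecules": (1e-4, 1e7),
    "tau_d": (1e-2, 1e7),
    "triplet_fraction": (0.0, 0.8),
    "triplet_tau": (1.0, 50.0),
    "structure_parameter": (1.0, 20.0),
}

#: Require τ_tr < τ_D / TRIPLET_SEPARATION when T is materially non-zero, to
#: prevent the triplet term from swapping roles with the diffusion term.
TRIPLET_SEPARATION = 5.0


def triplet_diffusion_model(
    tau: np.ndarray | float,
    n_molecules: float,
    tau_d: float,
    triplet_fraction: float,
    triplet_tau: float,
    structure_parameter: float,
) -> np.ndarray | float:
    """Evaluate the triplet-diffusion autocorrelation model at lag(s) τ (µs)."""
    if n_molecules <= 0 or tau_d <= 0 or structure_parameter <= 0:
        raise ValueError("N, tau_d and structure parameter must be positive")
    if not 0.0 <= triplet_fraction < 1.0:
        raise ValueError("triplet fraction must be in [0, 1)")
    tau = np.asarray(tau, dtype=float)
    g = (
        (1.0 / n_molecules)
        * (1.0 + tau / tau_d) ** -1.0
        * (1.0 + tau / (structure_parameter**2 * tau_d)) ** -0.5
    )
    if triplet_fraction > 0.0:
        if triplet_tau <= 0:
            raise ValueError("triplet relaxation time must be positive")
        g = g * (
            1.0
            + triplet_fraction / (1.0 - triplet_fraction) * np.exp(-tau / triplet_tau)
        )
    return g if g.ndim else float(g)


def pure_diffusion_model(
    tau: np.ndarray | float,
    n_molecules: float,
    tau_d: float,
    structure_parameter: float,
) -> np.ndarray | float:
    """Diffusion-only model: the triplet-diffusion model with T = 0."""
    return triplet_diffusion_model(
        tau, n_molecules, tau_d, 0.0, 1.0, structure_parameter
    )


@dataclass
class TripletDiffusionFit:
    """Fitted triplet-diffusion parameters for one autocorrelation curve."""

    n_molecules: float
    tau_d: float  # µs
    triplet_fraction: float
    triplet_tau: float  # µs
    structure_parameter: float
    chi2: float
    covariance: dict[str, float] = field(default_factory=dict)  # 1σ errors

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.tau_d <= 0 or self.structure_parameter <= 0:
            raise ValueError("invalid fitted parameters")
        if not 0.0 <= self.triplet_fraction < 1.0:
            raise ValueError("triplet fraction out of range")

    def __call__(self, tau):
        return triplet_diffusion_model(
            tau,
            self.n_molecules,
            self.tau_d,
            self.triplet_fraction,
            self.triplet_tau,
            self.structure_parameter,
        )


@dataclass
class DiffusionFit:
    """Fitted pure-diffusion parameters for one (cross-)correlation curve."""

    n_molecules: float
    tau_d: float  # µs
    structure_parameter: float
    chi2: float
    covariance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_molecules <= 0 or self.tau_d <= 0 or self.structure_parameter <= 0:
            raise ValueError("invalid fitted parameters")

    def __call__(self, tau):
        return pure_diffusion_model(
            tau, self.n_molecules, self.tau_d, self.structure_parameter
        )


def _model_eval(model: str, tau, params: dict[str, float]):
    if model == "triplet_diffusion":
        return triplet_diffusion_model(
            tau,
            params["n_molecules"],
            params["tau_d"],
            params["triplet_fraction"],
            params["triplet_tau"],
            params["structure_parameter"],
        )
    return pure_diffusion_model(
        tau, params["n_molecules"], params["tau_d"], params["structure_parameter"]
    )


def _default_init(curve: CorrelationCurve, model: str) -> dict[str, float]:
    g0 = float(np.max(curve.g[: max(3, len(curve) // 8)]))
    n0 = 1.0 / g0 if g0 > 0 else 10.0
    # lag at which G first drops below half its initial value
    half = g0 / 2.0
    below = np.nonzero(curve.g < half)[0]
    tau_d0 = float(curve.lags[below[0]]) if below.size else float(np.median(curve.lags))
    return {
        "n_molecules": n0,
        "tau_d": max(tau_d0, float(curve.lags[0])),
        "triplet_fraction": 0.1,
        "triplet_tau": 5.0,
        "structure_parameter": 5.0,
    }


def fit_curve(
    curve: CorrelationCurve,
    model: str = "triplet_diffusion",
    *,
    fixed: dict[str, float] | None = None,
    init: dict[str, float] | None = None,
    bounds: dict[str, tuple[float, float]] | None = None,
    n_starts: int = 5,
):
    """Weighted least-squares fit of an FCS model to a correlation curve.

    Weights are 1/σ² where the curve carries per-lag uncertainties (lags with
    σ = 0 get the smallest positive σ), falling back to unweighted residuals
    otherwise. The optimisation is multi-start: the data-driven initial guess
    plus ``n_starts`` deterministic log-normal perturbations of it; the
    solution with the lowest chi², breaking ties by the lower τ_D, is kept.

    Parameters named in ``fixed`` (e.g. the structure parameter after
    calibration, or the triplet relaxation time) are held constant.

    Returns a `TripletDiffusionFit` or `DiffusionFit`.

    Raises
    ------
    FitError
        If no start converges to a valid solution. Callers should record the
        failure and flag the measurement rather than dropping it silently.
    """
    if model not in _PARAMS:
        raise ValueError(f"unknown model {model!r}")
    fixed = dict(fixed or {})
    names = [p for p in _PARAMS[model] if p not in fixed]
    if len(curve) < 3 * max(1, len(names)):
        raise FitError(
            f"curve has {len(curve)} lags; need >= 3x the {len(names)} free parameters"
        )

    base = _default_init(curve, model)
    if init:
        base.update(init)
    bnds = dict(_DEFAULT_BOUNDS)
    if bounds:
        bnds.update(bounds)

    lags = curve.lags
    gdata = curve.g
    if curve.sigma is not None and np.any(curve.sigma > 0):
        sig = curve.sigma.copy()
        sig[sig <= 0] = sig[sig > 0].min()
        weights = 1.0 / sig
    else:
        weights = np.ones_like(gdata)

    lo = np.array([bnds[p][0] for p in names])
    hi = np.array([bnds[p][1] for p in names])

    def residuals(x):
        params = dict(fixed)
        params.update(dict(zip(names, x)))
        return (_model_eval(model, lags, params) - gdata) * weights

    x0 = np.clip(np.array([base[p] for p in names]), lo, hi)
    # Deterministic multi-start: fixed seed so fits are reproducible.
    rng = np.random.default_rng(20240817)
    starts = [x0]
    for _ in range(max(0, n_starts - 1)):
        starts.append(np.clip(x0 * np.exp(rng.normal(0.0, 0.5, size=x0.size)), lo, hi))

    best = None
    for s in starts:
        try:
            sol = least_squares(residuals, s, bounds=(lo, hi), method="trf", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        if not np.isfinite(sol.cost):
            continue
        params = dict(fixed)
        params.update(dict(zip(names, sol.x)))
        if model == "triplet_diffusion":
            t = params["triplet_fraction"]
            if t > 0.01 and params["triplet_tau"] >= params["tau_d"] / TRIPLET_SEPARATION:
                continue  # triplet and diffusion terms swapped roles
        chi2 = 2.0 * sol.cost
        key = (chi2, params["tau_d"])
        if best is None or key < best[0]:
            best = (key, params, sol)
    if best is None:
        # All solutions either failed or put the triplet term on top of the
        # diffusion decay (unidentifiable triplet); resolve by dropping it.
        if model == "triplet_diffusion" and "triplet_fraction" not in fixed:
            return fit_curve(
                curve,
                model,
                fixed={**fixed, "triplet_fraction": 0.0, "triplet_tau": 1.0},
                init=init,
                bounds=bounds,
                n_starts=n_starts,
            )
        raise FitError(f"no convergent {model} fit after {len(starts)} starts")

    _, params, sol = best
    cov = _covariance(sol, names)
    if model == "triplet_diffusion":
        return TripletDiffusionFit(
            n_molecules=params["n_molecules"],
            tau_d=params["tau_d"],
            triplet_fraction=params["triplet_fraction"],
            triplet_tau=params["triplet_tau"],
            structure_parameter=params["structure_parameter"],
            chi2=best[0][0],
            covariance=cov,
        )
    return DiffusionFit(
        n_molecules=params["n_molecules"],
        tau_d=params["tau_d"],
        structure_parameter=params["structure_parameter"],
        chi2=best[0][0],
        covariance=cov,
    )


def _covariance(sol, names) -> dict[str, float]:
    """Approximate 1σ parameter errors from the Jacobian at the solution."""
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(1, sol.fun.size - len(names))
        cov = np.linalg.inv(jtj) * (2.0 * sol.cost / dof)
        return {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    except np.linalg.LinAlgError:
        return {}
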