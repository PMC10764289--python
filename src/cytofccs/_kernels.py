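"""Numba kernels for Brownian-dynamics photon-trace simulation.

The kernels accumulate, per time bin, the expected photon count produced by
one molecular species diffusing through two overlapping 3D Gaussian
detection profiles. Random numbers (Gaussian steps, telegraph uniforms) are
drawn in bulk by the caller with numpy's generator — much faster than
per-call draws inside the jitted loop — and consumed here in a fixed order,
so traces are bit-reproducible given the seed. Photon (Poisson) noise is
applied afterwards by the caller.

Detection profile (peak-normalised): W(x, y, z) = exp(-2(x²+y²)/ω² - 2z²/z_z²).
A molecule of peak brightness ε (counts/s) at position r contributes
ε·W(r)·Δt expected counts during a sub-step of length Δt.

Triplet blinking is a two-state telegraph process per fluorophore with
stationary dark fraction T and relaxation time τ_tr; the discrete-time
transition probabilities are the exact two-state propagator over Δt:

    P(bright→dark) = T · (1 - e^{-Δt/τ_tr})
    P(dark→bright) = (1 - T) · (1 - e^{-Δt/τ_tr})
"""

from __future__ import annotations

import numpy as np
from numba import njit

# exp(-q) below this exponent contributes < 2e-15 of the peak; skip it.
_Q_CUTOFF = 34.0


@njit(cache=True, fastmath=True)
def propagate_chunk(
    lam_green,
    lam_red,
    first_bin,
    substeps,
    xs,
    ys,
    zs,
    bright_g,
    bright_r,
    normals,  # (n_steps, n_particles, 3) standard normals
    u_green,  # (n_steps, n_particles) uniforms, or (0, 0) when unused
    u_red,
    step_sd,
    side,
    inv_wg2,  # 2/ω_g²
    inv_zg2,  # 2/z_g²
    inv_wr2,
    inv_zr2,
    p_bd,
    p_db,
    weight_g,  # ε_g · Δt_substep  (0 disables the channel)
    weight_r,
):  # pragma: no cover - exercised via simulate_fccs_trace
    n_steps = normals.shape[0]
    n = xs.shape[0]
    half = side / 2.0
    has_g = weight_g > 0.0
    has_r = weight_r > 0.0
    blink_g = has_g and u_green.shape[0] > 0
    blink_r = has_r and u_red.shape[0] > 0
    for s in range(n_steps):
        b = first_bin + s // substeps
        acc_g = 0.0
        acc_r = 0.0
        for i in range(n):
            x = xs[i] + step_sd * normals[s, i, 0]
            y = ys[i] + step_sd * normals[s, i, 1]
            z = zs[i] + step_sd * normals[s, i, 2]
            if x > half:
                x -= side
            elif x < -half:
                x += side
            if y > half:
                y -= side
            elif y < -half:
                y += side
            if z > half:
                z -= side
            elif z < -half:
                z += side
            xs[i] = x
            ys[i] = y
            zs[i] = z

            if blink_g:
                if bright_g[i] == 1:
                    if u_green[s, i] < p_bd:
                        bright_g[i] = 0
                else:
                    if u_green[s, i] < p_db:
                        bright_g[i] = 1
            if blink_r:
                if bright_r[i] == 1:
                    if u_red[s, i] < p_bd:
                        bright_r[i] = 0
                else:
                    if u_red[s, i] < p_db:
                        bright_r[i] = 1

            rho2 = x * x + y * y
            if has_g and bright_g[i] == 1:
                q = rho2 * inv_wg2 + z * z * inv_zg2
                if q < _Q_CUTOFF:
                    acc_g += np.exp(-q)
            if has_r and bright_r[i] == 1:
                q = rho2 * inv_wr2 + z * z * inv_zr2
                if q < _Q_CUTOFF:
                    acc_r += np.exp(-q)
        if has_g:
            lam_green[b] += weight_g * acc_g
        if has_r:
            lam_red[b] += weight_r * acc_r


@njit(cache=True)
def telegraph_dark_fraction(
    triplet_fraction, triplet_tau_us, dt_us, n_steps, seed
):  # pragma: no cover - exercised via tests
    """Time-averaged dark-state occupancy of a single telegraph fluorophore.

    Used to verify that the blinking process implemented in
    `propagate_chunk` has the requested stationary dark fraction.
    """
    np.random.seed(seed)
    relax = 1.0 - np.exp(-dt_us / triplet_tau_us)
    p_bd = triplet_fraction * relax
    p_db = (1.0 - triplet_fraction) * relax
    dark = 1 if np.random.random() < triplet_fraction else 0
    n_dark = 0
    for _ in range(n_steps):
        if dark == 0:
            if np.random.random() < p_bd:
                dark = 1
        else:
            if np.random.random() < p_db:
                dark = 0
        n_dark += dark
    return n_dark / n_steps
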