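"""Independent numerical oracles used by the test suite.

These deliberately avoid the closed-form Bessel machinery of the package:
the pulsatile pipe-flow oracle is a finite-difference Crank-Nicolson solver
of the axisymmetric Stokes momentum equation, time-stepped to its periodic
state and Fourier-analysed, and normalised by its *numerically integrated*
flow rate.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import solve_banded


def oscillatory_pipe_flow_fd(
    radius_m: float,
    nu: float,
    omega: float,
    forcing: float = 1.0,
    n_r: int = 201,
    periods: int = 10,
    steps_per_period: int = 2000,
):
    """Periodic solution of du/dt = forcing*cos(omega t) + nu*(u'' + u'/r).

    Rigid no-slip wall at r = radius_m, symmetry at the axis.  Returns
    ``(r, u_hat, q_hat)``: the radial nodes (m), the complex velocity
    amplitude at the driving frequency (m/s, convention
    u(r, t) = Re[u_hat exp(i omega t)]), and the complex flow-rate
    amplitude (m^3/s) obtained by numerical quadrature.
    """
    n = n_r - 1  # unknowns 0..n-1 (wall node eliminated)
    dr = radius_m / n
    r = np.arange(n_r) * dr

    lap = np.zeros((3, n))  # banded (upper, diag, lower)
    # axis: L u = 4 (u1 - u0) / dr^2
    lap[1, 0] = -4.0 / dr**2
    lap[0, 1] = 4.0 / dr**2
    for i in range(1, n):
        ri = r[i]
        lap[1, i] = -2.0 / dr**2
        if i + 1 < n:
            lap[0, i + 1] = 1.0 / dr**2 + 1.0 / (2 * ri * dr)
        lap[2, i - 1] = 1.0 / dr**2 - 1.0 / (2 * ri * dr)

    period = 2.0 * np.pi / omega
    dt = period / steps_per_period
    lhs = -0.5 * dt * nu * lap
    lhs[1] += 1.0
    rhs_m = 0.5 * dt * nu * lap
    rhs_m[1] += 1.0

    def apply_banded(mat, u):
        out = mat[1] * u
        out[:-1] += mat[0, 1:] * u[1:]
        out[1:] += mat[2, :-1] * u[:-1]
        return out

    u = np.zeros(n)
    total_steps = periods * steps_per_period
    u_hat = np.zeros(n_r, dtype=complex)
    for step in range(total_steps):
        t_mid = (step + 0.5) * dt
        rhs = apply_banded(rhs_m, u) + dt * forcing * np.cos(omega * t_mid)
        u = solve_banded((1, 1), lhs, rhs)
        if step >= total_steps - steps_per_period:
            t_new = (step + 1) * dt
            u_hat[:n] += 2.0 * u * np.exp(-1j * omega * t_new) * dt / period
    q_hat = 2.0 * np.pi * np.trapezoid(u_hat * r, r)
    return r, u_hat, q_hat


def plug_disk_series(
    radius_mm: float,
    v0: float,
    spacing_mm: float,
    n_frames: int = 4,
    fov_mm: float = 12.8,
    frame_duration_ms: float = 100.0,
    subsamples: int = 32,
    rng: np.random.Generator | None = None,
    noise_sigma: float = 0.0,
):
    """Cine series of a top-hat ("plug") disk of moving fluid.

    Pixel values are the intravoxel fluid coverage fraction times ``v0``
    (computed by dense subsampling), i.e. ideal partial-volume rendering of
    a discontinuous velocity profile that the analytic generator does not
    produce.  Used as a sharp-edged segmentation target.
    """
    from cineshear import CineVelocitySeries

    n = int(np.ceil(fov_mm / spacing_mm))
    center = n * spacing_mm / 2.0
    sub = (np.arange(n * subsamples) + 0.5) / subsamples * spacing_mm
    xs, ys = np.meshgrid(sub - center, sub - center, indexing="xy")
    inside = (np.hypot(xs, ys) <= radius_mm).astype(float)
    frac = inside.reshape(n, subsamples, n, subsamples).mean(axis=(1, 3))
    velocities = np.zeros((n_frames, n, n, 3))
    velocities[..., 2] = v0 * frac
    if noise_sigma > 0:
        rng = rng or np.random.default_rng(0)
        velocities += rng.normal(0.0, noise_sigma, size=velocities.shape)
    magnitude = np.broadcast_to(0.2 + 0.8 * frac, (n_frames, n, n)).copy()
    return CineVelocitySeries(
        velocities=velocities,
        magnitude=magnitude,
        pixel_spacing=spacing_mm,
        frame_duration=frame_duration_ms,
        period=n_frames * frame_duration_ms * 1e-3,
    )


def ols_closed_form(x: np.ndarray, y: np.ndarray):
    """Closed-form simple OLS: slope, intercept, r^2 via moment ratios."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    sxy = np.sum((x - xm) * (y - ym))
    syy = np.sum((y - ym) ** 2)
    slope = sxy / sxx
    intercept = ym - slope * xm
    r2 = 0.0 if syy == 0 else sxy**2 / (sxx * syy)
    return slope, intercept, r2
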