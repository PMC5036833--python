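"""Analytic pulsatile velocity profiles: Womersley modes and a skewed profile.

These closed-form fields are the ground truth that the synthetic PC-MRI
renderer samples.  The axisymmetric solution follows Womersley's classic
result for fully developed oscillatory flow of a Newtonian fluid in a rigid
circular tube: for each flow harmonic ``Q_k exp(i omega_k t)`` the complex
velocity profile is

    u_k(r) = Q_k / (pi R^2) * (1 - J0(L r/R)/J0(L)) / (1 - 2 J1(L)/(L J0(L)))

with ``L = i^(3/2) alpha`` and Womersley number ``alpha = R sqrt(omega/nu)``.
The normalisation makes the cross-section-integrated flow of each mode equal
its prescribed harmonic amplitude; the no-slip condition u(R) = 0 holds
exactly.  Harmonic 0 is the Poiseuille profile ``2 Q0/(pi R^2) (1 - r^2/R^2)``.

The eccentric-skewed profile is a quasi-steady stand-in for the asymmetric
velocity distribution downstream of a bifurcation: parabolic along every ray
from a displaced apex, zero on the wall, rescaled each instant so its area
integral equals Q(t).
"""

from __future__ import annotations

import numpy as np
from scipy.special import jv

from .errors import ConfigurationError, OutOfDomainError
from .geometry import PROFILE_ECCENTRIC, VesselGeometry
from .waveform import WaveformSpec

__all__ = [
    "womersley_number",
    "womersley_mode",
    "womersley_velocity",
    "skewed_profile_shape",
    "skewed_shape_integral",
    "skewed_velocity",
    "FieldEvaluator",
    "analytic_velocity_field",
]


def womersley_number(geometry: VesselGeometry, omega: float) -> float:
    """alpha = R sqrt(omega / nu) for angular frequency ``omega`` (rad/s)."""
    r_m = geometry.radius * 1e-3
    return float(r_m * np.sqrt(omega / geometry.kinematic_viscosity))


def womersley_mode(geometry: VesselGeometry, omega: float, q_k: complex, r) -> np.ndarray:
    """Complex velocity amplitude (m/s) of one flow harmonic at radii ``r`` (mm).

    The physical velocity contribution is ``Re[mode * exp(i omega t)]``.
    ``q_k`` is the complex flow amplitude in mL/s.  ``omega`` must be > 0;
    harmonic 0 is handled by the Poiseuille branch of
    :func:`womersley_velocity`.
    """
    if omega <= 0:
        raise ConfigurationError("womersley_mode requires omega > 0")
    r = np.asarray(r, dtype=float)
    r_ratio = r / geometry.radius
    alpha = womersley_number(geometry, omega)
    lam = 1j**1.5 * alpha
    j0_wall = jv(0, lam)
    shape = 1.0 - jv(0, lam * r_ratio) / j0_wall
    flow_factor = 1.0 - 2.0 * jv(1, lam) / (lam * j0_wall)
    area_m2 = np.pi * (geometry.radius * 1e-3) ** 2
    q_m3 = q_k * 1e-6  # mL/s -> m^3/s
    return q_m3 / area_m2 * shape / flow_factor


def womersley_velocity(geometry: VesselGeometry, waveform: WaveformSpec, radial_position, time):
    """Axial velocity (m/s) of the Womersley solution at radius ``r`` and time ``t``.

    Parameters
    ----------
    radial_position : float or ndarray
        Radius in mm; must satisfy 0 <= r <= R.
    time : float or ndarray
        Time in seconds.  ``radial_position`` and ``time`` broadcast.

    Returns
    -------
    float or ndarray
        Real axial velocity.  Exactly zero at r = R.
    """
    r = np.asarray(radial_position, dtype=float)
    t = np.asarray(time, dtype=float)
    if np.any(r < 0) or np.any(r > geometry.radius * (1 + 1e-12)):
        raise OutOfDomainError("radial position outside [0, R]")
    r = np.minimum(r, geometry.radius)
    area_m2 = np.pi * (geometry.radius * 1e-3) ** 2
    q0 = waveform.mean_flow * 1e-6
    u = 2.0 * q0 / area_m2 * (1.0 - (r / geometry.radius) ** 2)
    u = np.broadcast_to(u, np.broadcast_shapes(r.shape, t.shape)).astype(float).copy()
    omegas = waveform.angular_frequencies()
    for k in range(1, waveform.coefficients.size):
        mode = womersley_mode(geometry, omegas[k], waveform.coefficients[k], r)
        u += (mode * np.exp(1j * omegas[k] * t)).real
    return float(u) if u.ndim == 0 else u


def _ray_lengths(geometry: VesselGeometry, directions: np.ndarray) -> np.ndarray:
    """Distance from the apex point to the wall circle along unit ``directions``."""
    c = np.asarray(geometry.apex_offset, dtype=float)
    cd = directions @ c
    disc = geometry.radius**2 - c @ c + cd**2
    return -cd + np.sqrt(disc)


def skewed_profile_shape(geometry: VesselGeometry, positions) -> np.ndarray:
    """Dimensionless profile f(p) in [0, 1]: 1 at the apex, 0 on the wall.

    Along each ray from the apex the profile is parabolic in the fractional
    distance to the wall, so its ridge line is displaced like the skewed
    velocity distribution of a curved/branching vessel.  ``positions`` is
    (..., 2) in mm relative to the lumen centre; points outside the lumen
    map to 0.
    """
    p = np.asarray(positions, dtype=float)
    rel = p - np.asarray(geometry.apex_offset)
    rho = np.linalg.norm(rel, axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        dirs = np.where(rho[..., None] > 0, rel / np.where(rho[..., None] > 0, rho[..., None], 1.0), 0.0)
    lengths = _ray_lengths(geometry, dirs)
    frac = np.where(rho > 0, rho / lengths, 0.0)
    f = 1.0 - frac**2
    inside = np.linalg.norm(p, axis=-1) <= geometry.radius * (1 + 1e-12)
    return np.where(inside, np.clip(f, 0.0, 1.0), 0.0)


def skewed_shape_integral(geometry: VesselGeometry, n_theta: int = 8192) -> float:
    """Area integral of the shape function over the lumen (mm^2).

    For the ray-parabolic profile the radial integral is closed-form,
    leaving (1/4) * integral of L(theta)^2 d theta, evaluated by the
    trapezoid rule on the periodic integrand (spectrally accurate).
    """
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    dirs = np.stack([np.cos(theta), np.sin(theta)], axis=-1)
    lengths = _ray_lengths(geometry, dirs)
    return float(0.25 * np.mean(lengths**2) * 2.0 * np.pi)


def skewed_velocity(geometry: VesselGeometry, waveform: WaveformSpec, position, time):
    """Axial velocity (m/s) of the eccentric-skewed profile.

    ``position`` is (..., 2) mm relative to the lumen centre, ``time`` in
    seconds.  The profile is rescaled every instant so that its area
    integral equals Q(t); with zero apex offset it reduces to the parabolic
    profile with the same flow rate.
    """
    p = np.asarray(position, dtype=float)
    if np.any(np.linalg.norm(np.atleast_2d(p), axis=-1) > geometry.radius * (1 + 1e-12)):
        raise OutOfDomainError("position outside the lumen")
    f = skewed_profile_shape(geometry, p)
    integral = skewed_shape_integral(geometry)
    q = waveform.flow_rate(time)
    u = np.multiply.outer(np.asarray(q, dtype=float), f) / integral  # mL/s / mm^2 = m/s
    u = np.squeeze(u)
    return float(u) if u.ndim == 0 else u


class FieldEvaluator:
    """Precomputed evaluator of the analytic through-plane field at fixed points.

    Factors the expensive per-position work (Bessel modal amplitudes or the
    skewed shape function) out of repeated time evaluations, so rendering a
    cine series costs one small matrix product per frame.  ``positions`` is
    (N, 2) mm relative to the lumen centre; points outside the lumen
    evaluate to 0 (static surround).
    """

    def __init__(self, geometry: VesselGeometry, waveform: WaveformSpec, positions):
        p = np.atleast_2d(np.asarray(positions, dtype=float))
        self.geometry = geometry
        self.waveform = waveform
        self.n_points = p.shape[0]
        radii = np.linalg.norm(p, axis=-1)
        self._inside = radii <= geometry.radius
        if geometry.profile == PROFILE_ECCENTRIC:
            self._shape = skewed_profile_shape(geometry, p) / skewed_shape_integral(geometry)
            self._amps = None
        else:
            r_in = np.minimum(radii[self._inside], geometry.radius)
            n_h = waveform.coefficients.size
            amps = np.zeros((r_in.size, n_h), dtype=complex)
            area_m2 = np.pi * (geometry.radius * 1e-3) ** 2
            amps[:, 0] = (
                2.0 * waveform.mean_flow * 1e-6 / area_m2 * (1.0 - (r_in / geometry.radius) ** 2)
            )
            omegas = waveform.angular_frequencies()
            # For large point sets the Bessel modes are tabulated on a dense
            # radial grid and linearly interpolated (the modes are smooth on
            # the scale of the table spacing R/4096).
            use_table = r_in.size > 4096
            r_tab = np.linspace(0.0, geometry.radius, 4097) if use_table else None
            for k in range(1, n_h):
                if use_table:
                    tab = womersley_mode(geometry, omegas[k], waveform.coefficients[k], r_tab)
                    amps[:, k] = np.interp(r_in, r_tab, tab.real) + 1j * np.interp(
                        r_in, r_tab, tab.imag
                    )
                else:
                    amps[:, k] = womersley_mode(geometry, omegas[k], waveform.coefficients[k], r_in)
            self._amps = amps
            self._shape = None

    def at_times(self, times) -> np.ndarray:
        """Velocity (m/s) at the fixed positions for each time; shape (M, N)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        out = np.zeros((t.size, self.n_points))
        if self._shape is not None:
            q = np.asarray(self.waveform.flow_rate(t), dtype=float)
            out = np.outer(q, self._shape)
        else:
            omegas = self.waveform.angular_frequencies()
            phases = np.exp(1j * np.outer(omegas, t))
            phases[0] = 1.0
            out[:, self._inside] = (self._amps @ phases).real.T
        return out


def analytic_velocity_field(geometry: VesselGeometry, waveform: WaveformSpec, positions, times) -> np.ndarray:
    """Through-plane velocity (m/s) at in-plane ``positions`` for each of ``times``.

    ``positions`` is (N, 2) mm relative to the lumen centre, ``times`` is
    (M,) seconds; returns (M, N).  Points outside the lumen are 0.
    """
    return FieldEvaluator(geometry, waveform, positions).at_times(times)
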