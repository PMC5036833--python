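"""Vessel cross-section geometry and fluid properties."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["VesselGeometry", "cca_like", "ica_like"]

PROFILE_CIRCULAR = "circular"
PROFILE_ECCENTRIC = "eccentric-skewed"


@dataclass(frozen=True)
class VesselGeometry:
    """Circular vessel cross-section with a velocity-profile type.

    Parameters
    ----------
    radius : float
        Lumen radius R in mm.
    profile : str
        ``"circular"`` (axisymmetric Womersley/Poiseuille profile) or
        ``"eccentric-skewed"`` (paraboloid-like profile whose apex is
        displaced from the lumen centre, as seen distal to a bifurcation).
    apex_offset : tuple of float
        In-plane offset (mm) of the velocity-profile apex from the lumen
        centre; only meaningful for the eccentric profile.  Image
        convention: x to the right, y down.
    viscosity : float
        Dynamic viscosity mu in Pa·s (default: water, 1.0e-3).
    density : float
        Fluid density rho in kg/m^3 (default: water, 1000).
    """

    radius: float
    profile: str = PROFILE_CIRCULAR
    apex_offset: tuple[float, float] = (0.0, 0.0)
    viscosity: float = 1.0e-3
    density: float = 1000.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ConfigurationError("radius must be positive")
        if self.viscosity <= 0:
            raise ConfigurationError("viscosity must be positive")
        if self.density <= 0:
            raise ConfigurationError("density must be positive")
        if self.profile not in (PROFILE_CIRCULAR, PROFILE_ECCENTRIC):
            raise ConfigurationError(f"unknown profile type {self.profile!r}")
        off = np.hypot(*self.apex_offset)
        if off >= self.radius:
            raise ConfigurationError("apex offset magnitude must be < radius")

    @property
    def area(self) -> float:
        """Lumen area pi R^2 in mm^2."""
        return float(np.pi * self.radius**2)

    @property
    def kinematic_viscosity(self) -> float:
        """nu = mu / rho in m^2/s."""
        return self.viscosity / self.density


def cca_like(radius: float = 2.8) -> VesselGeometry:
    """Common-carotid-like section: near-parabolic axisymmetric profile.

    The default radius gives an area of ~24.6 mm^2.
    """
    return VesselGeometry(radius=radius, profile=PROFILE_CIRCULAR)


def ica_like(radius: float = 3.04, apex_offset: tuple[float, float] = (0.8, 0.8)) -> VesselGeometry:
    """Internal-carotid-like section: skewed profile, apex toward bottom-right.

    The default radius gives an area of ~29 mm^2; the apex offset points
    toward +x/+y, i.e. the bottom-right image quadrant.
    """
    return VesselGeometry(radius=radius, profile=PROFILE_ECCENTRIC, apex_offset=apex_offset)
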