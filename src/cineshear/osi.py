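"""Oscillatory shear index.

OSI(s) = 0.5 * (1 - |sum_t WSS(s, t) dt| / sum_t |WSS(s, t)| dt)

computed per wall point from the tangential-projected WSS vectors.  OSI is
0 for unidirectional shear and 0.5 for shear whose time integral cancels;
the triangle inequality bounds it to [0, 0.5].  A wall point with zero WSS
throughout the cycle is assigned OSI 0 (no direction change is observable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .wss import WSSField

__all__ = ["OSIField", "osi"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class OSIField:
    """Per-wall-point OSI values, each in [0, 0.5]."""

    values: np.ndarray
    wall_points: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0) or np.any(v > 0.5):
            raise ConfigurationError("OSI values must lie in [0, 0.5]")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def circumferential_mean(self) -> float:
        """Arithmetic mean over wall points."""
        return float(self.values.mean())


def osi(field: WSSField, frame_durations=None, period: float | None = None) -> OSIField:
    """OSI per wall point from a time-resolved WSS field.

    Parameters
    ----------
    field : WSSField
        Needs >= 2 frames.
    frame_durations : array-like, optional
        Per-frame durations; must be uniform (cine acquisitions reconstruct
        evenly spaced frames).  Defaults to the field's frame duration.
    period : float, optional
        Cardiac cycle length (s).  If the frames cover clearly less than
        the cycle (prospective partial-cycle series), the sums run over the
        available frames and a warning is logged.
    """
    if field.n_frames < 2:
        raise ConfigurationError("OSI needs at least 2 frames")
    if frame_durations is not None:
        dts = np.asarray(frame_durations, dtype=float)
        if dts.size != field.n_frames:
            raise ConfigurationError("frame_durations length must match frames")
        if not np.allclose(dts, dts[0]):
            raise ConfigurationError("OSI requires uniform frame durations")
        dt = float(dts[0])
    else:
        dt = field.frame_duration
    if period is not None and field.n_frames * dt * 1e-3 < 0.98 * period:
        logger.warning(
            "WSS frames cover %.0f ms of a %.0f ms cycle; OSI computed over "
            "the available (prospective) frames only",
            field.n_frames * dt,
            period * 1e3,
        )
    vector_sum = np.linalg.norm(field.vectors.sum(axis=1) * dt, axis=1)
    magnitude_sum = field.magnitude.sum(axis=1) * dt
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(magnitude_sum > 0, vector_sum / np.where(magnitude_sum > 0, magnitude_sum, 1.0), 1.0)
    values = 0.5 * (1.0 - ratio)
    # Guard against tiny negative values from floating-point cancellation.
    values = np.clip(values, 0.0, 0.5)
    return OSIField(values=values, wall_points=field.wall_points.copy())
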