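"""Wall shear stress estimation from cine PC-MRI velocity fields.

At each wall point the velocity is sampled along the inward normal at two
offsets (default 1.5 and 3.0 mm, as used for carotid PC-MRI), the wall value
is pinned to zero, and the unique quadratic through the three points — the
not-a-knot cubic spline on three knots — gives the wall shear rate as its
derivative at the wall.  WSS = mu * WSR, projected onto the wall-tangential
subspace.  Cycle averaging is mean-of-magnitudes per point, then a
circumferential mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .acquisition import CineVelocitySeries
from .errors import ConfigurationError, OutOfDomainError
from .segmentation import LumenContour

__all__ = [
    "WallPointSample",
    "WSSField",
    "inward_normals",
    "sample_normal_velocities",
    "wall_shear_rate",
    "wss_field",
    "mean_wss",
]

DEFAULT_OFFSETS = (1.5, 3.0)


def inward_normals(contour: LumenContour) -> tuple[np.ndarray, np.ndarray]:
    """Wall positions and inward unit normals at every contour vertex.

    The normal at vertex i is perpendicular to the central-difference
    tangent (vertices i-1, i+1), oriented toward the centroid side.

    Returns
    -------
    (points, normals) : ndarrays of shape (n, 2)
    """
    v = contour.vertices
    if np.any(np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1) == 0):
        raise ConfigurationError("duplicate adjacent vertices in contour")
    tangent = np.roll(v, -1, axis=0) - np.roll(v, 1, axis=0)
    normal = np.column_stack([-tangent[:, 1], tangent[:, 0]])
    normal /= np.linalg.norm(normal, axis=1, keepdims=True)
    to_centroid = contour.centroid - v
    flip = np.sum(normal * to_centroid, axis=1) < 0
    normal[flip] *= -1
    return v.copy(), normal


@dataclass(frozen=True)
class WallPointSample:
    """Velocity samples along one wall point's inward normal.

    ``velocities`` has shape (3, 3): rows are offsets (0, d1, d2), columns
    the (vx, vy, vz) components.  The wall row is exactly zero (no slip is
    imposed, not measured).  Offsets are in mm.
    """

    position: np.ndarray
    normal: np.ndarray
    offsets: tuple[float, float]
    velocities: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.normal, dtype=float)
        if abs(np.linalg.norm(n) - 1.0) > 1e-9:
            raise ConfigurationError("normal must be a unit vector")
        v = np.asarray(self.velocities, dtype=float)
        if v.shape != (3, 3):
            raise ConfigurationError("velocities must have shape (3, 3)")
        v = v.copy()
        v[0] = 0.0  # wall velocity pinned to zero
        v.setflags(write=False)
        object.__setattr__(self, "velocities", v)
        d1, d2 = self.offsets
        if not 0 < d1 < d2:
            raise ConfigurationError("offsets must satisfy 0 < d1 < d2")


def _bilinear(series: CineVelocitySeries, points: np.ndarray, frame: int) -> np.ndarray:
    """Bilinear sample of all 3 components at mm ``points`` for one frame."""
    ny, nx = series.grid_shape
    h = series.pixel_spacing
    if (
        points[:, 0].min() < 0
        or points[:, 1].min() < 0
        or points[:, 0].max() > nx * h
        or points[:, 1].max() > ny * h
    ):
        raise OutOfDomainError("sample point outside the field of view")
    cols = points[:, 0] / h - 0.5
    rows = points[:, 1] / h - 0.5
    out = np.empty((points.shape[0], 3))
    for c in range(3):
        out[:, c] = ndimage.map_coordinates(
            series.velocities[frame, :, :, c], [rows, cols], order=1, mode="nearest"
        )
    return out


def sample_normal_velocities(
    series: CineVelocitySeries,
    point,
    normal,
    offsets: tuple[float, float] = DEFAULT_OFFSETS,
    frame: int = 0,
) -> WallPointSample:
    """Sample velocities at wall + d * normal for d in (0, d1, d2), one frame."""
    point = np.asarray(point, dtype=float)
    normal = np.asarray(normal, dtype=float)
    d1, d2 = offsets
    targets = np.stack([point + d1 * normal, point + d2 * normal])
    sampled = _bilinear(series, targets, frame)
    velocities = np.vstack([np.zeros(3), sampled])
    return WallPointSample(position=point, normal=normal, offsets=offsets, velocities=velocities)


def _quadratic_wall_slope(d1: float, d2: float, v1: np.ndarray, v2: np.ndarray) -> np.ndarray:
    # Unique quadratic through (0,0), (d1,v1), (d2,v2); slope at 0.
    return (v1 * d2**2 - v2 * d1**2) / (d1 * d2 * (d2 - d1))


def wall_shear_rate(sample: WallPointSample) -> np.ndarray:
    """Wall shear rate vector (1/s) from one wall-point sample.

    Per velocity component the interpolating spline through the zero wall
    value and the two offset samples (for three points: the unique
    quadratic) is differentiated at the wall.  Offsets are converted to
    metres so the derivative is in 1/s.
    """
    d1, d2 = (d * 1e-3 for d in sample.offsets)
    return _quadratic_wall_slope(d1, d2, sample.velocities[1], sample.velocities[2])


@dataclass
class WSSField:
    """Time-resolved wall shear stress vectors at each wall point.

    ``vectors`` has shape (n_points, n_frames, 3) in Pa, already projected
    onto the wall-tangential subspace (zero component along the inward
    normal).
    """

    vectors: np.ndarray
    wall_points: np.ndarray
    normals: np.ndarray
    frame_duration: float
    viscosity: float

    @property
    def n_points(self) -> int:
        return self.vectors.shape[0]

    @property
    def n_frames(self) -> int:
        return self.vectors.shape[1]

    @property
    def magnitude(self) -> np.ndarray:
        """|WSS| per point and frame, shape (n_points, n_frames), Pa."""
        return np.linalg.norm(self.vectors, axis=2)


def wss_field(
    series: CineVelocitySeries,
    contour: LumenContour,
    viscosity: float = 1.0e-3,
    offsets: tuple[float, float] = DEFAULT_OFFSETS,
) -> WSSField:
    """Time-resolved WSS vectors at every contour vertex.

    WSS = viscosity * WSR per frame, then the component along the inward
    normal is removed (the physical wall traction from shear is
    wall-tangential).  Default viscosity is water, 1.0e-3 Pa·s.
    """
    d1, d2 = offsets
    if not 0 < d1 < d2:
        raise ConfigurationError("offsets must satisfy 0 < d1 < d2")
    points, normals = inward_normals(contour)
    p1 = points + d1 * normals
    p2 = points + d2 * normals
    d1_m, d2_m = d1 * 1e-3, d2 * 1e-3
    n3 = np.column_stack([normals, np.zeros(len(normals))])
    vectors = np.empty((len(points), series.n_frames, 3))
    for f in range(series.n_frames):
        v1 = _bilinear(series, p1, f)
        v2 = _bilinear(series, p2, f)
        wsr = _quadratic_wall_slope(d1_m, d2_m, v1, v2)
        wss = viscosity * wsr
        wss -= np.sum(wss * n3, axis=1, keepdims=True) * n3
        vectors[:, f, :] = wss
    return WSSField(
        vectors=vectors,
        wall_points=points,
        normals=normals,
        frame_duration=series.frame_duration,
        viscosity=viscosity,
    )


def mean_wss(field: WSSField) -> tuple[float, np.ndarray]:
    """Cycle- then circumference-averaged WSS magnitude.

    Returns
    -------
    (scalar, per_point) : float, ndarray
        Per wall point the cycle mean of |WSS| over frames; the scalar is
        the arithmetic mean of those per-point means (Pa).
    """
    if field.n_frames < 1:
        raise ConfigurationError("WSS field has no frames")
    per_point = field.magnitude.mean(axis=1)
    return float(per_point.mean()), per_point
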