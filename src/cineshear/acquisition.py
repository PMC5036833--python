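"""Cine PC-MRI acquisition emulation.

Renders the analytic velocity field as a 2D cine phase-contrast series at a
given spatial/temporal resolution, with the degradations that matter for
wall-shear analysis:

* partial-volume averaging — each pixel is the box average of the analytic
  field over a supersampled grid inside the pixel footprint;
* temporal-bin averaging — each cine frame is the average of the field over
  the frame's time window;
* venc-scaled Gaussian velocity noise, ``sigma_v = sqrt(2) venc / (pi SNR)``
  per component (the standard PC-MRI velocity-noise relation);
* an optional first-order (planar) phase-offset error per component.

Coordinate conventions (project-wide): image frame, x to the right, y down,
origin at the grid corner, pixel centres at ``(i + 0.5) * spacing`` mm.
Velocities are m/s; pixel spacing mm; frame duration ms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .geometry import VesselGeometry
from .waveform import WaveformSpec
from .womersley import FieldEvaluator

__all__ = [
    "AcquisitionSpec",
    "CineVelocitySeries",
    "render_series",
    "phase_offset_correct",
    "static_background_mask",
]

logger = logging.getLogger(__name__)

RETROSPECTIVE = "retrospective"
PROSPECTIVE = "prospective"


@dataclass(frozen=True)
class AcquisitionSpec:
    """Acquisition settings for one synthetic cine PC-MRI measurement.

    Parameters
    ----------
    pixel_spacing : float
        Isotropic in-plane pixel size (mm).
    frame_duration : float
        Temporal resolution (ms); must be shorter than the cycle.
    venc : float
        Velocity-encoding limit (cm/s).  Scales the noise floor.
    snr : float, optional
        Velocity-to-noise ratio; ``None`` renders noise-free.
    phase_offset : array-like (3, 3), optional
        Per-component plane coefficients (a, b, c): the offset
        ``a x + b y + c`` (x, y in mm) is added to that component.
    supersampling : int
        Subsamples per pixel edge for partial-volume box averaging.
    n_time_samples : int
        Analytic time samples averaged per frame window.
    field_of_view : float
        Square FOV edge (mm); the vessel axis pierces the FOV centre.
    gating : str
        ``"retrospective"`` (frames tile the full cycle) or
        ``"prospective"`` (frames tile only the first
        ``prospective_fraction`` of the cycle).
    prospective_fraction : float
        Cycle fraction covered in prospective mode.
    seed : int, optional
        Seed for the noise generator; fixed seed gives bit-identical output.
    """

    pixel_spacing: float
    frame_duration: float
    venc: float = 100.0
    snr: float | None = 20.0
    phase_offset: np.ndarray | None = None
    supersampling: int = 8
    n_time_samples: int = 9
    field_of_view: float = 12.8
    gating: str = RETROSPECTIVE
    prospective_fraction: float = 0.8
    seed: int | None = None

    def __post_init__(self):
        if self.pixel_spacing <= 0:
            raise ConfigurationError("pixel spacing must be positive")
        if self.frame_duration <= 0:
            raise ConfigurationError("frame duration must be positive")
        if self.venc <= 0:
            raise ConfigurationError("venc must be positive")
        if self.snr is not None and self.snr <= 0:
            raise ConfigurationError("SNR must be positive when set")
        if int(self.supersampling) < 1:
            raise ConfigurationError("supersampling factor must be >= 1")
        if self.n_time_samples < 1:
            raise ConfigurationError("n_time_samples must be >= 1")
        if self.field_of_view <= 0:
            raise ConfigurationError("field of view must be positive")
        if self.gating not in (RETROSPECTIVE, PROSPECTIVE):
            raise ConfigurationError(f"unknown gating mode {self.gating!r}")
        if not 0 < self.prospective_fraction <= 1:
            raise ConfigurationError("prospective fraction must be in (0, 1]")
        if self.phase_offset is not None:
            po = np.asarray(self.phase_offset, dtype=float)
            if po.shape != (3, 3):
                raise ConfigurationError("phase_offset must have shape (3, 3)")
            object.__setattr__(self, "phase_offset", po)

    @property
    def noise_sigma(self) -> float:
        """Per-component velocity noise s.d. in m/s (0 when SNR unset)."""
        if self.snr is None:
            return 0.0
        return float(np.sqrt(2.0) * self.venc * 1e-2 / (np.pi * self.snr))


@dataclass
class CineVelocitySeries:
    """A measured or simulated 2D cine series of 3-component velocities.

    Attributes
    ----------
    velocities : ndarray, shape (n_frames, ny, nx, 3)
        Velocity in m/s; component order (vx, vy, vz) with vz through-plane.
    magnitude : ndarray, shape (n_frames, ny, nx)
        Magnitude image (arbitrary units).
    pixel_spacing : float
        Isotropic pixel size (mm).
    frame_duration : float
        Frame duration (ms).
    period : float, optional
        Cardiac cycle length (s) when known.  For retrospective series
        n_frames * frame_duration approximates the period.
    """

    velocities: np.ndarray
    magnitude: np.ndarray
    pixel_spacing: float
    frame_duration: float
    venc: float = 100.0
    period: float | None = None

    def __post_init__(self):
        v = np.asarray(self.velocities, dtype=float)
        if v.ndim != 4 or v.shape[-1] != 3:
            raise ConfigurationError("velocities must have shape (n_frames, ny, nx, 3)")
        if not np.all(np.isfinite(v)):
            raise ConfigurationError("velocities must be finite")
        m = np.asarray(self.magnitude, dtype=float)
        if m.shape != v.shape[:3]:
            raise ConfigurationError("magnitude shape must match velocity frames")
        if self.pixel_spacing <= 0 or self.frame_duration <= 0:
            raise ConfigurationError("pixel spacing and frame duration must be positive")
        self.velocities = v
        self.magnitude = m

    @property
    def n_frames(self) -> int:
        return self.velocities.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int]:
        """(ny, nx)."""
        return self.velocities.shape[1:3]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-centre times in seconds."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration * 1e-3

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates in mm: x along columns, y along rows."""
        ny, nx = self.grid_shape
        x = (np.arange(nx) + 0.5) * self.pixel_spacing
        y = (np.arange(ny) + 0.5) * self.pixel_spacing
        return x, y

    def through_plane(self) -> np.ndarray:
        """Through-plane component, shape (n_frames, ny, nx)."""
        return self.velocities[..., 2]

    def mean_speed_image(self) -> np.ndarray:
        """Temporal mean of |through-plane velocity| (m/s)."""
        return np.abs(self.through_plane()).mean(axis=0)

    def copy(self) -> "CineVelocitySeries":
        return CineVelocitySeries(
            velocities=self.velocities.copy(),
            magnitude=self.magnitude.copy(),
            pixel_spacing=self.pixel_spacing,
            frame_duration=self.frame_duration,
            venc=self.venc,
            period=self.period,
        )


def _frame_count(acq: AcquisitionSpec, period: float) -> int:
    dt_s = acq.frame_duration * 1e-3
    if acq.gating == RETROSPECTIVE:
        return max(1, int(round(period / dt_s)))
    return max(1, int(np.floor(acq.prospective_fraction * period / dt_s)))


def render_series(
    geometry: VesselGeometry, waveform: WaveformSpec, acq: AcquisitionSpec
) -> CineVelocitySeries:
    """Render the analytic pulsatile field as a cine PC-MRI series.

    Each pixel value is the analytic through-plane velocity box-averaged over
    ``supersampling^2`` subsamples of the pixel footprint and over
    ``n_time_samples`` midpoint time samples of the frame window.  In-plane
    components are zero before noise (purely axial flow).  The magnitude
    image encodes the intravoxel fluid fraction.

    Raises
    ------
    ConfigurationError
        If the frame duration is not shorter than the cycle.
    """
    period = waveform.period
    dt_s = acq.frame_duration * 1e-3
    if dt_s >= period:
        raise ConfigurationError("frame duration must be shorter than the cycle period")
    ss = int(acq.supersampling)
    n = int(np.ceil(acq.field_of_view / acq.pixel_spacing))
    center = n * acq.pixel_spacing / 2.0
    if geometry.radius >= center:
        raise ConfigurationError("field of view too small for the vessel")

    # Subsample coordinates relative to the lumen centre, row-major (y, x).
    sub = (np.arange(n * ss) + 0.5) / ss * acq.pixel_spacing
    xs, ys = np.meshgrid(sub - center, sub - center, indexing="xy")
    positions = np.column_stack([xs.ravel(), ys.ravel()])
    evaluator = FieldEvaluator(geometry, waveform, positions)

    n_frames = _frame_count(acq, period)
    nts = acq.n_time_samples
    vz = np.empty((n_frames, n, n))
    for i in range(n_frames):
        t0 = i * dt_s
        t_samples = t0 + (np.arange(nts) + 0.5) / nts * dt_s
        field = evaluator.at_times(t_samples).mean(axis=0)
        vz[i] = field.reshape(n, ss, n, ss).mean(axis=(1, 3))

    velocities = np.zeros((n_frames, n, n, 3))
    velocities[..., 2] = vz

    inside = (np.hypot(xs, ys) <= geometry.radius).astype(float)
    fraction = inside.reshape(n, ss, n, ss).mean(axis=(1, 3))
    magnitude = np.broadcast_to(0.2 + 0.8 * fraction, (n_frames, n, n)).copy()

    if acq.phase_offset is not None:
        x = (np.arange(n) + 0.5) * acq.pixel_spacing
        xg, yg = np.meshgrid(x, x, indexing="xy")
        for c in range(3):
            a, b, const = acq.phase_offset[c]
            velocities[..., c] += a * xg + b * yg + const

    if acq.snr is not None:
        rng = np.random.default_rng(acq.seed)
        velocities += rng.normal(0.0, acq.noise_sigma, size=velocities.shape)

    return CineVelocitySeries(
        velocities=velocities,
        magnitude=magnitude,
        pixel_spacing=acq.pixel_spacing,
        frame_duration=acq.frame_duration,
        venc=acq.venc,
        period=period,
    )


def static_background_mask(
    series: CineVelocitySeries, lumen_radius: float, margin: float = 1.5
) -> np.ndarray:
    """Pixels farther than ``lumen_radius + margin`` (mm) from the FOV centre."""
    x, y = series.pixel_centers()
    cx = x.mean()
    cy = y.mean()
    xg, yg = np.meshgrid(x - cx, y - cy, indexing="xy")
    return np.hypot(xg, yg) > lumen_radius + margin


def phase_offset_correct(
    series: CineVelocitySeries,
    static_mask: np.ndarray,
    lumen_mask: np.ndarray | None = None,
) -> CineVelocitySeries:
    """Remove first-order (planar) phase-offset errors.

    Fits a plane ``a x + b y + c`` (x, y in mm) per velocity component to the
    temporal-mean velocity over ``static_mask`` by least squares and
    subtracts it from every frame.

    Parameters
    ----------
    static_mask : ndarray of bool, shape (ny, nx)
        Static-tissue pixels used for the fit; at least 10, none inside the
        lumen.
    lumen_mask : ndarray of bool, optional
        If given, overlap with ``static_mask`` raises.
    """
    static_mask = np.asarray(static_mask, dtype=bool)
    if static_mask.shape != series.grid_shape:
        raise ConfigurationError("static mask shape must match the series grid")
    if static_mask.sum() < 10:
        raise ConfigurationError("static mask must contain at least 10 pixels")
    if lumen_mask is not None and np.any(static_mask & np.asarray(lumen_mask, dtype=bool)):
        raise ConfigurationError("static mask overlaps the segmented lumen")

    x, y = series.pixel_centers()
    xg, yg = np.meshgrid(x, y, indexing="xy")
    design = np.column_stack(
        [xg[static_mask], yg[static_mask], np.ones(int(static_mask.sum()))]
    )
    corrected = series.copy()
    mean_v = series.velocities.mean(axis=0)
    for c in range(3):
        coef, *_ = np.linalg.lstsq(design, mean_v[..., c][static_mask], rcond=None)
        plane = coef[0] * xg + coef[1] * yg + coef[2]
        corrected.velocities[..., c] -= plane
        logger.debug("phase-offset plane component %d: a=%.3g b=%.3g c=%.3g", c, *coef)
    return corrected
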