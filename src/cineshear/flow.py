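"""Flow quantification: waveform, mean flow, peak flow, lumen area.

With velocities in m/s and pixel areas in mm^2, the product is directly in
mL/s (1 m/s * 1 mm^2 = 1e-6 m^3/s = 1 mL/s), so no unit factor appears in
the summation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import CineVelocitySeries
from .errors import ConfigurationError
from .waveform import WaveformSpec

__all__ = [
    "FlowWaveform",
    "flow_waveform",
    "reference_waveform",
    "WaveformComparison",
    "waveform_comparison",
]


@dataclass(frozen=True)
class FlowWaveform:
    """Per-frame flow rate through a lumen mask.

    Attributes
    ----------
    q : ndarray
        Flow rate per frame (mL/s), frames centred at
        ``(i + 0.5) * frame_duration``.
    frame_duration : float
        Frame duration (ms).
    lumen_area : float
        Area of the summation mask (mm^2).
    """

    q: np.ndarray
    frame_duration: float
    lumen_area: float

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if q.ndim != 1 or q.size < 1:
            raise ConfigurationError("q must be a 1-D array with >= 1 frame")
        if self.frame_duration <= 0:
            raise ConfigurationError("frame duration must be positive")
        if self.lumen_area <= 0:
            raise ConfigurationError("lumen area must be positive")
        q = q.copy()
        q.setflags(write=False)
        object.__setattr__(self, "q", q)

    @property
    def n_frames(self) -> int:
        return self.q.size

    @property
    def period(self) -> float:
        """Covered duration n_frames * frame_duration, in seconds."""
        return self.n_frames * self.frame_duration * 1e-3

    @property
    def frame_times(self) -> np.ndarray:
        """Frame-centre times (s)."""
        return (np.arange(self.n_frames) + 0.5) * self.frame_duration * 1e-3

    @property
    def mean_flow(self) -> float:
        """Arithmetic mean over frames (mL/s)."""
        return float(self.q.mean())

    @property
    def peak_flow(self) -> float:
        """Maximum frame value (mL/s), no interpolation."""
        return float(self.q.max())


def flow_waveform(series: CineVelocitySeries, mask: np.ndarray) -> FlowWaveform:
    """Flow waveform Q(t) = sum over mask of v_z * pixel area (mL/s)."""
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.grid_shape:
        raise ConfigurationError("mask shape must match the series grid")
    if not mask.any():
        raise ConfigurationError("empty lumen mask")
    pixel_area = series.pixel_spacing**2
    q = series.through_plane()[:, mask].sum(axis=1) * pixel_area
    return FlowWaveform(
        q=q, frame_duration=series.frame_duration, lumen_area=float(mask.sum() * pixel_area)
    )


def reference_waveform(
    waveform: WaveformSpec, n_samples: int = 1000, lumen_area: float = 1.0
) -> FlowWaveform:
    """Densely sampled analytic waveform, standing in for the flow-probe trace."""
    dt_ms = waveform.period * 1e3 / n_samples
    t = (np.arange(n_samples) + 0.5) * dt_ms * 1e-3
    return FlowWaveform(q=waveform.flow_rate(t), frame_duration=dt_ms, lumen_area=lumen_area)


@dataclass(frozen=True)
class WaveformComparison:
    """Measured-vs-reference waveform comparison.

    ``pairs`` holds one (reference, measured) flow pair per measured frame,
    with the reference linearly resampled (periodically) to the measured
    frame times — the per-frame scatter of a probe-validation plot.
    """

    mean_ratio_pct: float
    pairs: np.ndarray  # (n_frames, 2): columns (reference, measured)

    @property
    def n_frames(self) -> int:
        return self.pairs.shape[0]


def waveform_comparison(measured: FlowWaveform, reference: FlowWaveform) -> WaveformComparison:
    """Compare a measured flow waveform against a reference on the same cycle.

    The reference is resampled to the measured frame times by periodic
    linear interpolation.  The headline number is the mean-flow ratio in
    percent (measured / reference * 100).

    Raises
    ------
    ConfigurationError
        If the two waveforms do not cover the same period (>2% mismatch).
    """
    if abs(measured.period - reference.period) > 0.02 * reference.period:
        raise ConfigurationError(
            f"mismatched periods: measured {measured.period:.4f} s, "
            f"reference {reference.period:.4f} s"
        )
    period = reference.period
    t_ref = reference.frame_times
    # Periodic extension for interpolation at times near the cycle edges.
    t_ext = np.concatenate([t_ref - period, t_ref, t_ref + period])
    q_ext = np.tile(reference.q, 3)
    resampled = np.interp(measured.frame_times, t_ext, q_ext)
    ratio = measured.mean_flow / reference.mean_flow * 100.0
    pairs = np.column_stack([resampled, measured.q])
    return WaveformComparison(mean_ratio_pct=float(ratio), pairs=pairs)
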