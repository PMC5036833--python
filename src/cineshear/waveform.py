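"""Periodic flow-rate waveforms expressed as truncated Fourier series.

A waveform is the volumetric flow rate Q(t) through the vessel cross-section,
stored as complex harmonic coefficients ``c_0..c_K`` (mL/s) of period ``T``:

    Q(t) = c_0 + sum_{k>=1} Re[c_k exp(i 2 pi k t / T)]

``c_0`` is real and equals the cycle-mean flow.  The carotid-like factory
reproduces the pulse the flow phantom was tuned to: period 1 s, mean
~2.7 mL/s, systolic peak ~9.1 mL/s, with a dicrotic shoulder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError

__all__ = ["WaveformSpec", "carotid_waveform", "steady_waveform"]


@dataclass(frozen=True)
class WaveformSpec:
    """Flow-rate waveform Q(t) as a truncated Fourier series.

    Parameters
    ----------
    period : float
        Cycle duration in seconds.
    coefficients : ndarray of complex, shape (K+1,)
        Harmonic amplitudes in mL/s.  ``coefficients[0]`` must be real
        (the mean flow); harmonic k contributes
        ``Re[c_k exp(i 2 pi k t/period)]``.
    label : str
        Free-text description.
    """

    period: float
    coefficients: np.ndarray
    label: str = ""

    def __post_init__(self):
        coeff = np.atleast_1d(np.asarray(self.coefficients, dtype=complex))
        if self.period <= 0:
            raise ConfigurationError("waveform period must be positive")
        if coeff.ndim != 1 or coeff.size < 1:
            raise ConfigurationError("coefficients must be a 1-D array")
        if not np.all(np.isfinite(coeff)):
            raise ConfigurationError("harmonic coefficients must be finite")
        if abs(coeff[0].imag) > 1e-12 * max(1.0, abs(coeff[0].real)):
            raise ConfigurationError("harmonic 0 must be real (mean flow)")
        coeff = coeff.copy()
        coeff[0] = coeff[0].real
        coeff.setflags(write=False)
        object.__setattr__(self, "coefficients", coeff)

    @property
    def n_harmonics(self) -> int:
        """Highest harmonic index K."""
        return self.coefficients.size - 1

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow rate (mL/s); equals harmonic 0."""
        return float(self.coefficients[0].real)

    def angular_frequencies(self) -> np.ndarray:
        """omega_k = 2 pi k / T for k = 0..K (rad/s)."""
        return 2.0 * np.pi * np.arange(self.coefficients.size) / self.period

    def flow_rate(self, t) -> np.ndarray | float:
        """Evaluate Q(t) in mL/s at time(s) ``t`` (seconds)."""
        t = np.asarray(t, dtype=float)
        k = np.arange(1, self.coefficients.size)
        phases = np.exp(2j * np.pi * np.multiply.outer(t, k) / self.period)
        q = self.mean_flow + (phases * self.coefficients[1:]).real.sum(axis=-1)
        return float(q) if q.ndim == 0 else q

    def peak_flow(self, n: int = 4096) -> float:
        """Maximum of Q(t) over one cycle, sampled on a dense grid."""
        t = np.linspace(0.0, self.period, n, endpoint=False)
        return float(np.max(self.flow_rate(t)))


def steady_waveform(q: float, period: float = 1.0, label: str = "steady") -> WaveformSpec:
    """Constant flow of ``q`` mL/s (harmonic 0 only)."""
    return WaveformSpec(period=period, coefficients=np.array([q + 0j]), label=label)


def _pulse_shape(t: np.ndarray) -> np.ndarray:
    # Unit-scale carotid-like template: sharp systolic peak plus a dicrotic
    # shoulder.  Amplitudes are relative; the factory rescales to the target
    # mean/peak after harmonic truncation.
    s = np.exp(-0.5 * ((t - 0.15) / 0.050) ** 2)
    s = s + 0.36 * np.exp(-0.5 * ((t - 0.40) / 0.085) ** 2)
    s = s + 0.12 * np.exp(-0.5 * ((t - 0.62) / 0.16) ** 2)
    return s


def carotid_waveform(
    mean: float = 2.7,
    peak: float = 9.1,
    period: float = 1.0,
    n_harmonics: int = 8,
    label: str = "carotid-like",
) -> WaveformSpec:
    """Carotid-like pulsatile waveform with prescribed mean and peak flow.

    The template pulse is Fourier-truncated to ``n_harmonics`` and its
    pulsatile amplitude iteratively rescaled so that the *truncated*
    reconstruction attains the requested peak while the mean is matched
    exactly by harmonic 0.  The default mean 2.7 mL/s / peak 9.1 mL/s and
    1 s period emulate the flow-probe-calibrated phantom pulse.
    """
    if peak <= mean:
        raise ConfigurationError("peak flow must exceed mean flow")
    n = 2048
    t = np.linspace(0.0, period, n, endpoint=False)
    s = _pulse_shape(t / period)
    s_mean = s.mean()
    amp = (peak - mean) / (s.max() - s_mean)
    for _ in range(30):
        q = mean + amp * (s - s_mean)
        spec = np.fft.rfft(q) / n
        coeff = np.empty(n_harmonics + 1, dtype=complex)
        coeff[0] = spec[0].real
        coeff[1:] = 2.0 * spec[1 : n_harmonics + 1]
        wf = WaveformSpec(period=period, coefficients=coeff, label=label)
        trunc_peak = wf.peak_flow()
        if abs(trunc_peak - peak) < 1e-9 * peak:
            break
        amp *= (peak - mean) / (trunc_peak - mean)
    return wf
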