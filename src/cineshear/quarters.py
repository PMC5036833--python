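"""Quarter-wise regional distribution of wall parameters.

Wall vertices are partitioned into the four image-frame quadrants around
the contour centroid (top-left, top-right, bottom-left, bottom-right; image
convention, y down).  Per-sector means of WSS and OSI localise the high and
low shear regions, and concordance counts how often the extreme sectors
agree across measurements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .segmentation import LumenContour

__all__ = [
    "SECTOR_LABELS",
    "SectorMeans",
    "QuarterSummary",
    "quarter_labels",
    "quarter_means",
    "quarter_summary",
    "concordance",
]

#: Sector index order used everywhere.
SECTOR_LABELS = ("top-left", "top-right", "bottom-left", "bottom-right")

# Display-frame quadrant (from atan2 with y flipped) -> sector index above.
_QUADRANT_TO_SECTOR = {0: 1, 1: 0, 2: 2, 3: 3}


def quarter_labels(contour: LumenContour) -> np.ndarray:
    """Sector index (0..3, order of ``SECTOR_LABELS``) per wall vertex.

    A vertex is assigned by the sign pair of its offset from the centroid in
    image coordinates.  Vertices exactly on a quadrant boundary go to the
    counterclockwise-prior sector (counterclockwise as displayed, i.e. with
    y up), which makes the assignment deterministic.
    """
    d = contour.vertices - contour.centroid
    # Snap numerically-tiny offsets to zero so the boundary tie rule is
    # robust to floating-point noise in the centroid.
    scale = np.abs(d).max()
    d = np.where(np.abs(d) < 1e-9 * scale, 0.0, d)
    # Display angle (y up) in (0, 2*pi]; boundary angles land on the upper
    # edge of the prior quadrant.
    phi = np.arctan2(-d[:, 1], d[:, 0])
    phi = np.mod(phi, 2.0 * np.pi)
    phi[phi == 0.0] = 2.0 * np.pi
    quadrant = np.ceil(phi / (0.5 * np.pi)).astype(int) - 1
    return np.array([_QUADRANT_TO_SECTOR[q] for q in quadrant])


@dataclass(frozen=True)
class SectorMeans:
    """Per-sector means of one wall quantity, with extreme sectors.

    Ties for highest/lowest resolve to the lowest sector index.
    """

    means: np.ndarray  # (4,)
    counts: np.ndarray  # (4,)
    highest: int
    lowest: int

    @property
    def labels(self) -> tuple[str, ...]:
        return SECTOR_LABELS


def quarter_means(values, labels) -> SectorMeans:
    """Arithmetic mean of ``values`` per sector.

    Raises
    ------
    ConfigurationError
        If values/labels are misaligned or a sector is empty.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if values.shape != labels.shape:
        raise ConfigurationError("values and labels must be aligned")
    means = np.empty(4)
    counts = np.empty(4, dtype=int)
    for s in range(4):
        sel = labels == s
        counts[s] = sel.sum()
        if counts[s] == 0:
            raise ConfigurationError(f"empty sector {SECTOR_LABELS[s]!r}")
        means[s] = values[sel].mean()
    return SectorMeans(
        means=means, counts=counts, highest=int(np.argmax(means)), lowest=int(np.argmin(means))
    )


@dataclass(frozen=True)
class QuarterSummary:
    """Quarter-wise WSS and OSI summary for one measurement."""

    wss: SectorMeans
    osi: SectorMeans


def quarter_summary(contour: LumenContour, wss_per_point, osi_per_point) -> QuarterSummary:
    """Build the quarter summary from per-vertex cycle-mean WSS and OSI."""
    labels = quarter_labels(contour)
    return QuarterSummary(
        wss=quarter_means(wss_per_point, labels), osi=quarter_means(osi_per_point, labels)
    )


def concordance(records, reference, quantity: str = "wss") -> tuple[int, int, int]:
    """Count measurements whose extreme sectors match a reference.

    Parameters
    ----------
    records : sequence of QuarterSummary
    reference : QuarterSummary
    quantity : str
        ``"wss"`` or ``"osi"``.

    Returns
    -------
    (n_match_high, n_match_low, n_total)
    """
    if len(records) < 1:
        raise ConfigurationError("concordance needs at least one record")
    ref = getattr(reference, quantity)
    n_high = sum(1 for r in records if getattr(r, quantity).highest == ref.highest)
    n_low = sum(1 for r in records if getattr(r, quantity).lowest == ref.lowest)
    return n_high, n_low, len(records)
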