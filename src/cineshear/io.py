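"""On-disk containers and result tables.

Velocity series container: a directory of per-frame, per-component 2-D
``.npy`` arrays plus a ``series.json`` sidecar carrying the acquisition
metadata (pixel spacing, frame duration, venc, period).  Results are plain
CSV.  Contours are CSV polygon lists in mm.  All writers are byte-stable
for fixed inputs (no timestamps).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .acquisition import CineVelocitySeries
from .errors import FormatError
from .segmentation import LumenContour
from .sweep import records_to_frame

__all__ = [
    "write_velocity_series",
    "read_velocity_series",
    "write_contour_csv",
    "read_contour_csv",
    "write_results",
    "read_summary_table",
    "SUMMARY_COLUMNS",
]

_COMPONENTS = ("vx", "vy", "vz")

#: Column schema accepted by the summary-ingestion pathway (one row per
#: measurement).  ``site`` is free text (e.g. CCA / ICA).
SUMMARY_COLUMNS = (
    "measure_no",
    "spatial_resolution_mm",
    "temporal_resolution_ms",
    "site",
    "area_mm2",
    "mean_flow_ml_s",
    "peak_flow_ml_s",
    "mean_wss_pa",
    "mean_osi",
)


def write_velocity_series(series: CineVelocitySeries, path) -> Path:
    """Write a series to a directory container; returns the directory path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for f in range(series.n_frames):
        for c, name in enumerate(_COMPONENTS):
            np.save(path / f"{name}_f{f:03d}.npy", series.velocities[f, :, :, c])
        np.save(path / f"mag_f{f:03d}.npy", series.magnitude[f])
    ny, nx = series.grid_shape
    sidecar = {
        "pixel_spacing_mm": series.pixel_spacing,
        "frame_duration_ms": series.frame_duration,
        "venc_cms": series.venc,
        "period_s": series.period,
        "n_frames": series.n_frames,
        "shape": [ny, nx],
    }
    (path / "series.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True) + "\n")
    return path


def read_velocity_series(path) -> CineVelocitySeries:
    """Read a series from the directory container written by
    :func:`write_velocity_series`.

    Raises
    ------
    FormatError
        Naming the missing metadata field, or describing inconsistent
        frame shapes.
    """
    path = Path(path)
    sidecar_path = path / "series.json"
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}", field="series.json")
    meta = json.loads(sidecar_path.read_text())
    for fieldname in ("pixel_spacing_mm", "frame_duration_ms", "venc_cms", "n_frames", "shape"):
        if fieldname not in meta:
            raise FormatError(f"sidecar misses required field {fieldname!r}", field=fieldname)
    n_frames = int(meta["n_frames"])
    ny, nx = (int(v) for v in meta["shape"])
    velocities = np.empty((n_frames, ny, nx, 3))
    magnitude = np.empty((n_frames, ny, nx))
    for f in range(n_frames):
        for c, name in enumerate(_COMPONENTS):
            arr = np.load(path / f"{name}_f{f:03d}.npy")
            if arr.shape != (ny, nx):
                raise FormatError(
                    f"frame {f} component {name} has shape {arr.shape}, expected {(ny, nx)}"
                )
            velocities[f, :, :, c] = arr
        magnitude[f] = np.load(path / f"mag_f{f:03d}.npy")
    return CineVelocitySeries(
        velocities=velocities,
        magnitude=magnitude,
        pixel_spacing=float(meta["pixel_spacing_mm"]),
        frame_duration=float(meta["frame_duration_ms"]),
        venc=float(meta["venc_cms"]),
        period=meta.get("period_s"),
    )


def write_contour_csv(contour: LumenContour, path) -> Path:
    """Write a contour as a CSV polygon list (x_mm, y_mm; counterclockwise)."""
    path = Path(path)
    df = pd.DataFrame(contour.vertices, columns=["x_mm", "y_mm"])
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_contour_csv(path, source_spacing: float) -> LumenContour:
    df = pd.read_csv(path)
    for col in ("x_mm", "y_mm"):
        if col not in df.columns:
            raise FormatError(f"contour CSV misses column {col!r}", field=col)
    return LumenContour(vertices=df[["x_mm", "y_mm"]].to_numpy(), source_spacing=source_spacing)


def _regressions_to_frame(regressions) -> pd.DataFrame:
    rows = []
    for r in regressions:
        rows.append(
            {
                "response": r.response,
                "predictor": r.predictor,
                "slope": r.slope,
                "intercept": r.intercept,
                "normalized_slope": r.normalized_slope,
                "units": r.units,
                "r_squared": r.r_squared,
                "p_value": r.p_value,
                "significant": r.significant,
                "n": r.n,
            }
        )
    return pd.DataFrame(rows)


def write_results(records, regressions, path, plots: bool = False) -> dict[str, Path]:
    """Write the per-measurement and regression CSVs (and optional plots).

    Parameters
    ----------
    records : sequence of MeasurementRecord
    regressions : sequence of RegressionResult
    path : output directory
    plots : bool
        Also write summary figures (flow/WSS/OSI vs resolution scatter).

    Returns
    -------
    dict mapping logical names to written paths.
    """
    if len(records) == 0:
        raise FormatError("no measurement records to write")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    out: dict[str, Path] = {}
    meas = records_to_frame(records)
    out["measurements"] = path / "measurements.csv"
    meas.to_csv(out["measurements"], index=False, float_format="%.12g")
    reg = _regressions_to_frame(regressions)
    out["regressions"] = path / "regressions.csv"
    reg.to_csv(out["regressions"], index=False, float_format="%.12g")
    if plots:
        from .plotting import plot_resolution_scatter

        out["scatter"] = path / "resolution_scatter.png"
        plot_resolution_scatter(records, out["scatter"])
    return out


def read_summary_table(path) -> pd.DataFrame:
    """Read an external per-measurement summary table (ingest pathway).

    The file must be CSV with at least the columns in
    :data:`SUMMARY_COLUMNS` (extra columns are kept).  This is the entry
    point for re-analysing published per-measurement values without raw
    velocity data; mapping a third-party spreadsheet onto the schema is a
    one-time manual step.
    """
    df = pd.read_csv(path)
    for col in SUMMARY_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"summary table misses column {col!r}", field=col)
    return df


class _SummaryRow:
    """Adapter giving a summary-table row the MeasurementRecord attributes."""

    def __init__(self, row: pd.Series):
        self.measure_no = int(row["measure_no"])
        self.spatial_resolution = float(row["spatial_resolution_mm"])
        self.temporal_resolution = float(row["temporal_resolution_ms"])
        self.area = float(row["area_mm2"])
        self.mean_flow = float(row["mean_flow_ml_s"])
        self.peak_flow = float(row["peak_flow_ml_s"])
        self.mean_wss = float(row["mean_wss_pa"])
        self.mean_osi = float(row["mean_osi"])


def summary_rows(df: pd.DataFrame, site: str | None = None) -> list[_SummaryRow]:
    """Regression-ready rows from an ingested summary table."""
    if site is not None:
        df = df[df["site"] == site]
    return [_SummaryRow(row) for _, row in df.iterrows()]
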