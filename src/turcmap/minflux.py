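"""MINFLUX localization post-processing.

The pipeline mirrors standard practice for iterative MINFLUX recordings:
keep only final-iteration localizations, correct the optical-axis
compression of z-coordinates (factor 0.7), drop low-quality rows by their
effective frequency at offset (EFO), discard traces left with fewer than
four localizations, average each trace to an emitter center, and fit a
per-structure cylinder axis through the collective centroid by minimizing
squared radial distances.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import Axis, fit_axis_tls
from .spatial import RadialAxialProfile, percentile_median_unbiased, radial_axial_profile

logger = logging.getLogger(__name__)

__all__ = [
    "TraceCenter",
    "PrecisionSummary",
    "filter_localizations",
    "aggregate_traces",
    "precision_summary",
    "fit_structure_axis",
]


@dataclass
class TraceCenter:
    """Mean position of one trace's localizations (z already corrected)
    with per-axis sample standard deviations (n-1 denominator)."""

    trace_id: str
    structure_id: str
    center: np.ndarray
    n_localizations: int
    sd: np.ndarray  # (sigma_x, sigma_y, sigma_z)


@dataclass
class PrecisionSummary:
    """Cross-structure averages of per-structure median trace-wise
    localization spreads; sigma_xy is the mean of the x and y values."""

    per_structure: pd.DataFrame  # columns structure_id, sigma_x, sigma_y, sigma_z
    sigma_x: float
    sigma_y: float
    sigma_z: float
    sigma_xy: float


def filter_localizations(
    table: pd.DataFrame,
    valid_iteration: int = 9,
    efo_max_khz: float = 100.0,
    min_locs: int = 4,
    z_scale: float = 0.7,
) -> pd.DataFrame:
    """Validity filtering and z correction, in fixed order:

    1. keep rows of the valid iteration;
    2. multiply z by ``z_scale`` (applied once; the returned table is
       marked so a second pass is a no-op);
    3. drop rows with EFO >= ``efo_max_khz`` (strict ``<`` keeps);
    4. drop whole traces with fewer than ``min_locs`` surviving rows.

    Row order is preserved; an empty result is allowed and logged.
    """
    n0 = len(table)
    df = table[table["iteration"] == valid_iteration].copy()
    if not table.attrs.get("z_corrected", False):
        df["z_nm"] = df["z_nm"] * z_scale
    df = df[df["efo_khz"] < efo_max_khz]
    counts = df.groupby("trace_id")["trace_id"].transform("size")
    df = df[counts >= min_locs]
    df.attrs["z_corrected"] = True
    logger.info(
        "filter_localizations: %d -> %d rows (%d traces)",
        n0,
        len(df),
        df["trace_id"].nunique(),
    )
    return df


def aggregate_traces(table: pd.DataFrame) -> list:
    """One :class:`TraceCenter` per trace: arithmetic mean of the member
    localizations and per-axis sample standard deviation."""
    centers = []
    for (trace_id, structure_id), grp in table.groupby(["trace_id", "structure_id"], sort=True):
        xyz = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        sd = xyz.std(axis=0, ddof=1) if len(xyz) > 1 else np.zeros(3)
        centers.append(
            TraceCenter(
                trace_id=str(trace_id),
                structure_id=str(structure_id),
                center=xyz.mean(axis=0),
                n_localizations=len(xyz),
                sd=sd,
            )
        )
    return centers


def precision_summary(centers) -> PrecisionSummary:
    """Per-structure median (type 8) of trace-wise standard deviations per
    axis, then unweighted cross-structure means."""
    if not centers:
        raise ValueError("no trace centers to summarize")
    rows = []
    by_structure: dict[str, list] = {}
    for c in centers:
        by_structure.setdefault(c.structure_id, []).append(c.sd)
    for sid in sorted(by_structure):
        sds = np.array(by_structure[sid])
        rows.append(
            {
                "structure_id": sid,
                "sigma_x": percentile_median_unbiased(sds[:, 0], 0.5),
                "sigma_y": percentile_median_unbiased(sds[:, 1], 0.5),
                "sigma_z": percentile_median_unbiased(sds[:, 2], 0.5),
            }
        )
    per = pd.DataFrame(rows)
    sx = float(per["sigma_x"].mean())
    sy = float(per["sigma_y"].mean())
    sz = float(per["sigma_z"].mean())
    return PrecisionSummary(per, sx, sy, sz, (sx + sy) / 2.0)


def fit_structure_axis(centers, bins=50) -> tuple[Axis, RadialAxialProfile]:
    """Cylinder axis of one structure's trace centers: total-least-squares
    line through the collective centroid (squared radial distances
    minimized), plus the radial/axial profile of the centers about it."""
    pts = np.array([c.center for c in centers])
    axis = fit_axis_tls(pts)
    return axis, radial_axial_profile(pts, axis, bins=bins)
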