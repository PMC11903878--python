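"""Pool classification, distance distributions, and median-unbiased
percentile summaries.

Distances are center-to-center in nm.  Following the convention used for
centriole cross-sections, lumenal gamma-TuRCs carry *negative* signed
distances to the nearest microtubule-triplet (MTT) B-tubule centerline and
pericentriolar ones *positive* distances.  Summary statistics use the
median-unbiased (Hyndman-Fan type 8) quantile estimator throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .geometry import Axis, point_to_polyline

__all__ = [
    "DistanceSummary",
    "RadialAxialProfile",
    "percentile_median_unbiased",
    "summarize_distribution",
    "classify_pools",
    "signed_mtt_distances",
    "nearest_neighbor_distances",
    "radial_axial_profile",
]


def percentile_median_unbiased(values, p: float) -> float:
    """Median-unbiased quantile (Hyndman-Fan type 8).

    Uses the plotting position h = p*(n + 1/3) + 1/3 with linear
    interpolation between order statistics, clamped to [min, max]; this
    estimator is approximately median-unbiased regardless of the
    underlying distribution.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("percentile of an empty sample is undefined")
    if not np.all(np.isfinite(v)):
        raise ValueError("percentile requires finite values")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability p={p} outside [0, 1]")
    v = np.sort(v)
    n = v.size
    h = p * (n + 1.0 / 3.0) + 1.0 / 3.0
    h = min(max(h, 1.0), float(n))
    lo = int(np.floor(h))
    frac = h - lo
    if lo >= n:
        return float(v[-1])
    return float(v[lo - 1] + frac * (v[lo] - v[lo - 1]))


@dataclass
class DistanceSummary:
    """Five-number-style summary: median plus median-unbiased 90% and 95%
    central intervals."""

    n: int
    median: float
    interval_90: tuple[float, float]
    interval_95: tuple[float, float]
    per_pool: dict[str, "DistanceSummary"] = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {
            "n": self.n,
            "median": self.median,
            "p05": self.interval_90[0],
            "p95": self.interval_90[1],
            "p025": self.interval_95[0],
            "p975": self.interval_95[1],
        }
        if self.per_pool:
            d["per_pool"] = {k: s.as_dict() for k, s in self.per_pool.items()}
        return d


def summarize_distribution(values) -> DistanceSummary:
    """Median and central 90%/95% intervals of a sample, all estimated with
    the median-unbiased (type 8) quantile."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot summarize an empty sample")
    q = lambda p: percentile_median_unbiased(v, p)
    return DistanceSummary(
        n=int(v.size),
        median=q(0.5),
        interval_90=(q(0.05), q(0.95)),
        interval_95=(q(0.025), q(0.975)),
    )


@dataclass
class RadialAxialProfile:
    """Cylindrical coordinates of points about an axis plus an r-histogram."""

    r: np.ndarray
    s: np.ndarray
    bin_edges: np.ndarray
    counts: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_left": self.bin_edges[:-1],
                "bin_right": self.bin_edges[1:],
                "count": self.counts,
            }
        )


def radial_axial_profile(points, axis: Axis, bins=50) -> RadialAxialProfile:
    """Radial distance r and signed axial coordinate s of every point
    about ``axis``, with a histogram of r over ``bins``."""
    r, s = axis.radial_axial(points)
    if np.isscalar(bins) and np.ptp(r) <= 1e-9 * max(1.0, float(np.max(r, initial=0.0))):
        # constant radius (e.g. a noiseless cylinder): pad a finite range
        pad = max(abs(r[0]), 1.0) * 0.05
        counts, edges = np.histogram(r, bins=int(bins), range=(r[0] - pad, r[0] + pad))
    else:
        counts, edges = np.histogram(r, bins=bins)
    return RadialAxialProfile(r=r, s=s, bin_edges=edges, counts=counts)


def classify_pools(particles: pd.DataFrame, model, margin: float = 10.0) -> pd.DataFrame:
    """Label every particle lumenal or pericentriolar.

    A particle is lumenal iff its radial coordinate about the centriole
    axis is below ``wall_radius - margin`` *and* its axial coordinate
    falls within the centriole length extent widened by ``margin``;
    otherwise it is pericentriolar.  This deterministic rule replaces a
    visual split; ``margin`` (nm) absorbs wall thickness and axis-fit
    slack.
    """
    df = particles.copy()
    pts = df[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    r, s = model.axis.radial_axial(pts)
    s0, s1 = model.axial_extent
    lumenal = (r < model.wall_radius - margin) & (s >= s0 - margin) & (s <= s1 + margin)
    df["pool"] = np.where(lumenal, "lumenal", "pericentriolar")
    return df


def signed_mtt_distances(particles: pd.DataFrame, model) -> tuple[np.ndarray, DistanceSummary]:
    """Signed center-to-center distance from each particle to the nearest
    MTT B-tubule centerline.

    Magnitude is the minimum point-to-polyline distance over the nine
    B-tubule lines; the sign is negative for lumenal particles and
    positive for pericentriolar ones.  Particles must be pool-labeled
    (run :func:`classify_pools` first).
    """
    pools = particles["pool"] if "pool" in particles.columns else pd.Series(dtype=str)
    if pools.empty or (pools == "unassigned").any():
        raise ValueError("particles carry unassigned pool labels; run classify_pools first")
    pts = particles[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
    mags = np.array(
        [min(point_to_polyline(p, line)[0] for line in model.mtt_b_tubule_lines) for p in pts]
    )
    signs = np.where(particles["pool"].to_numpy() == "lumenal", -1.0, 1.0)
    signed = signs * mags
    summary = summarize_distribution(np.abs(signed))
    for pool in ("lumenal", "pericentriolar"):
        sel = signed[particles["pool"].to_numpy() == pool]
        if sel.size:
            summary.per_pool[pool] = summarize_distribution(np.abs(sel))
    return signed, summary


def nearest_neighbor_distances(
    particles: pd.DataFrame, within_pool: bool = True
) -> tuple[np.ndarray, DistanceSummary]:
    """Distance from every particle to its closest neighbor.

    Groups are formed per tomogram (and per pool when ``within_pool``);
    each particle contributes one value, so symmetric closest pairs count
    twice.  Singleton groups are excluded with a warning.
    """
    group_cols = ["tomo_id", "pool"] if within_pool and "pool" in particles.columns else ["tomo_id"]
    out = []
    for key, grp in particles.groupby(group_cols, sort=True):
        pts = grp[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=float)
        if len(pts) < 2:
            warnings.warn(f"group {key} has a single particle; excluded from NN statistics")
            continue
        d, _ = cKDTree(pts).query(pts, k=2)
        out.append(d[:, 1])
    if not out:
        raise ValueError("no group with >= 2 particles; nearest-neighbor analysis impossible")
    values = np.concatenate(out)
    return values, summarize_distribution(values)
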