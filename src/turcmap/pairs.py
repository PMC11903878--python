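"""Gamma-TuRC--MTT pair-configuration analysis.

Each gamma-TuRC is paired with its closest accepted microtubule-triplet
(MTT) segment; the pair is reduced to a rigid-motion-invariant 7D feature
(local-frame shift scaled to the quaternion range, plus the canonicalized
relative orientation quaternion), filtered to a 60-120 nm center-of-mass
distance window, and grouped by k-means.  The largest cluster summarizes
the preferred relative arrangement; the wall-facing angle quantifies which
spoke sector of the ring points at the triplet.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .geometry import (
    quat_angle,
    quat_canonicalize,
    quat_conjugate,
    quat_mean,
    quat_multiply,
    rotate_vector,
)
from .synth import CentrioleModel, _mtt_frame_at, spoke_sector_azimuth_deg

logger = logging.getLogger(__name__)

__all__ = [
    "MttSegment",
    "PairConfiguration",
    "ClusterResult",
    "mtt_segments_from_model",
    "pair_particles_to_mtts",
    "build_pair_feature",
    "filter_pairs_by_distance",
    "cluster_pair_configurations",
    "wall_facing_angle",
]

DEFAULT_SHIFT_SCALE = 60.0  # nm; half the upper center-of-mass distance cutoff


@dataclass(frozen=True)
class MttSegment:
    """One refined MTT segment: center (nm), orientation (local +z along
    the triplet axis, +x radially inward), parent MTT id, and the locally
    interpolated axis direction used for orientation-consistency checks."""

    segment_id: str
    mtt_id: int
    center: np.ndarray
    orientation: np.ndarray
    axis_direction: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        object.__setattr__(self, "orientation", quat_canonicalize(self.orientation))
        d = np.asarray(self.axis_direction, dtype=float).reshape(3)
        object.__setattr__(self, "axis_direction", d / np.linalg.norm(d))


@dataclass
class PairConfiguration:
    """One gamma-TuRC--MTT pair reduced to its 7D feature."""

    turc_id: str
    mtt_segment_id: str
    com_distance: float
    shift_local: np.ndarray  # nm, world shift rotated into the gamma-TuRC frame
    q_rel: np.ndarray  # canonicalized relative orientation turc -> segment
    feature7: np.ndarray
    pool: str = "unassigned"


@dataclass
class ClusterResult:
    k: int
    assignments: np.ndarray
    sizes: np.ndarray
    main_cluster_index: int
    main_fraction_all: float
    main_fraction_lumenal: float
    mean_shift_local: np.ndarray
    mean_q_rel: np.ndarray
    angular_spread_deg: float
    inertia: float = field(default=float("nan"))


def mtt_segments_from_model(model: CentrioleModel, spacing_nm: float = 8.0) -> list:
    """Sample MTT segments (with local frames) along each B-tubule line of
    a centriole model at roughly ``spacing_nm`` intervals."""
    segments = []
    for m, line in enumerate(model.mtt_b_tubule_lines):
        n = max(2, int(round(line.total_length / spacing_nm)) + 1)
        for j, frac in enumerate(np.linspace(0.0, 1.0, n)):
            pos, q = _mtt_frame_at(model, m, float(frac))
            tangent = rotate_vector(q, [0.0, 0.0, 1.0])
            segments.append(
                MttSegment(f"mtt{m}_seg{j:03d}", m, pos, q, tangent)
            )
    return segments


def build_pair_feature(
    turc_position,
    turc_orientation,
    seg: MttSegment,
    turc_id: str = "",
    shift_scale: float = DEFAULT_SHIFT_SCALE,
    pool: str = "unassigned",
) -> PairConfiguration:
    """7D feature of one pair: shift vector rotated into the gamma-TuRC
    local frame and scaled by ``shift_scale``, concatenated with the
    canonicalized relative quaternion.  Exactly invariant under any global
    rigid transform applied to both poses."""
    p_turc = np.asarray(turc_position, dtype=float)
    q_turc = quat_canonicalize(turc_orientation)
    world_shift = seg.center - p_turc
    shift_local = rotate_vector(quat_conjugate(q_turc), world_shift)
    q_rel = quat_canonicalize(quat_multiply(quat_conjugate(q_turc), seg.orientation))
    feature = np.concatenate([shift_local / shift_scale, q_rel])
    return PairConfiguration(
        turc_id=turc_id,
        mtt_segment_id=seg.segment_id,
        com_distance=float(np.linalg.norm(world_shift)),
        shift_local=shift_local,
        q_rel=q_rel,
        feature7=feature,
        pool=pool,
    )


def pair_particles_to_mtts(
    turcs: pd.DataFrame,
    segments: list,
    axis_tolerance_deg: float = 30.0,
    shift_scale: float = DEFAULT_SHIFT_SCALE,
) -> list:
    """Pair every gamma-TuRC with its closest accepted MTT segment.

    Segments whose refined local +z deviates from the interpolated MTT
    axis by more than ``axis_tolerance_deg`` are rejected before pairing
    (orientation-consistency filter); particles left without any accepted
    segment are dropped with a logged count.
    """
    if not segments:
        raise ValueError("empty MTT segment list")
    accepted = []
    for s in segments:
        local_z = rotate_vector(s.orientation, [0.0, 0.0, 1.0])
        dev = math.degrees(
            math.acos(min(1.0, abs(float(np.dot(local_z, s.axis_direction)))))
        )
        if dev <= axis_tolerance_deg:
            accepted.append(s)
    n_rejected = len(segments) - len(accepted)
    if n_rejected:
        logger.info("rejected %d/%d MTT segments by axis consistency", n_rejected, len(segments))
    if not accepted:
        raise ValueError("all MTT segments rejected by the axis-consistency filter")
    centers = np.array([s.center for s in accepted])
    pairs = []
    for row in turcs.itertuples():
        p = np.array([row.x_nm, row.y_nm, row.z_nm])
        i = int(np.argmin(np.linalg.norm(centers - p, axis=1)))
        pairs.append(
            build_pair_feature(
                p,
                [row.qw, row.qx, row.qy, row.qz],
                accepted[i],
                turc_id=str(row.particle_id),
                shift_scale=shift_scale,
                pool=getattr(row, "pool", "unassigned"),
            )
        )
    return pairs


def filter_pairs_by_distance(pairs, d_min: float = 60.0, d_max: float = 120.0) -> list:
    """Keep pairs whose center-of-mass distance lies in [d_min, d_max] nm
    (inclusive bounds)."""
    if d_min > d_max:
        raise ValueError(f"d_min ({d_min}) must not exceed d_max ({d_max})")
    return [p for p in pairs if d_min <= p.com_distance <= d_max]


def cluster_pair_configurations(
    pairs, k: int = 8, seed: int = 0, restarts: int = 20
) -> ClusterResult:
    """k-means over the 7D pair features.

    Lloyd's algorithm with k-means++ initialization (``restarts``
    restarts, best inertia kept).  Rows are sorted lexicographically
    before clustering and assignments mapped back, so the result is
    invariant under input-order permutation at fixed seed.  The main
    cluster is the largest; its mean relative orientation uses the
    eigenvector quaternion mean and its mean shift the arithmetic mean in
    nm (unscaled).
    """
    n = len(pairs)
    if k < 1 or n < k:
        raise ValueError(f"need n >= k >= 1, got n={n}, k={k}")
    feats = np.array([p.feature7 for p in pairs])
    order = np.lexsort(feats.T[::-1])
    km = KMeans(n_clusters=k, n_init=restarts, random_state=seed, algorithm="lloyd")
    sorted_labels = km.fit_predict(feats[order])
    labels = np.empty(n, dtype=int)
    labels[order] = sorted_labels
    sizes = np.bincount(labels, minlength=k)
    main = int(np.argmax(sizes))
    members = [p for p, l in zip(pairs, labels) if l == main]
    pools = np.array([p.pool for p in pairs])
    n_lumenal = int((pools == "lumenal").sum())
    n_lumenal_main = int(sum(1 for p in members if p.pool == "lumenal"))
    mean_q = quat_mean([p.q_rel for p in members])
    mean_shift = np.mean([p.shift_local for p in members], axis=0)
    spread = float(np.mean([quat_angle(p.q_rel, mean_q) for p in members]))
    return ClusterResult(
        k=k,
        assignments=labels,
        sizes=sizes,
        main_cluster_index=main,
        main_fraction_all=float(sizes[main] / n),
        main_fraction_lumenal=(n_lumenal_main / n_lumenal) if n_lumenal else float("nan"),
        mean_shift_local=mean_shift,
        mean_q_rel=mean_q,
        angular_spread_deg=spread,
        inertia=float(km.inertia_),
    )


def wall_facing_angle(
    config: PairConfiguration, sector=(9, 12), spokes_per_turn: int = 13
) -> float:
    """Angle (degrees) between the mean azimuthal direction of a spoke
    sector in the gamma-TuRC local frame and the in-plane projection of
    the local shift toward the MTT; 0 means the sector faces the triplet."""
    theta = math.radians(spoke_sector_azimuth_deg(sector, spokes_per_turn))
    sector_dir = np.array([math.cos(theta), math.sin(theta)])
    in_plane = config.shift_local[:2]
    norm = np.linalg.norm(in_plane)
    if norm < 1e-12:
        raise ValueError("shift has no in-plane component; wall-facing angle undefined")
    c = float(np.dot(sector_dir, in_plane / norm))
    return math.degrees(math.acos(max(-1.0, min(1.0, c))))
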