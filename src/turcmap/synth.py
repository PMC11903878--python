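"""Synthetic centrioles, oriented gamma-TuRC particle sets, and MINFLUX
localization tables with planted, recoverable geometry.

The generators emulate the study conditions every analysis stage is
benchmarked against:

* a nine-fold microtubule-triplet (MTT) centriole wall (wall radius
  115 nm, length 450 nm),
* a condensed centriole-lumenal gamma-TuRC cluster at a planted
  75 +/- 6 nm center-to-center distance from the nearest B-tubule, with a
  planted preferred orientation relative to the nearest MTT frame plus an
  orientation-random background fraction,
* a broad pericentriolar pool (truncated Gaussian, 85 +/- 26 nm, minimum
  30 nm) with uniform orientations,
* MINFLUX traces on a cylindrical shell (radius 35 nm) with Gaussian
  localization error (sigma_xy 6 nm, sigma_z 5 nm after the 0.7 z
  correction), an EFO mixture with a configured outlier fraction, short
  decoy traces, and wrong-iteration decoy rows.

Every generator is bit-reproducible given its seed (one seeded
``numpy.random.Generator`` per call).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .geometry import (
    Axis,
    Polyline,
    quat_canonicalize,
    quat_conjugate,
    quat_from_matrix,
    quat_multiply,
    quat_to_matrix,
    random_rotation,
    rotate_vector,
)

__all__ = [
    "ConfigError",
    "MinfluxConfig",
    "SimulationConfig",
    "CentrioleModel",
    "default_planted_orientation",
    "spoke_sector_azimuth_deg",
    "simulate_centriole",
    "simulate_lumenal_turcs",
    "simulate_pericentriolar_turcs",
    "simulate_minflux_structures",
    "simulate_pair_benchmark",
    "make_ring_model",
]


class ConfigError(ValueError):
    """Raised for physically infeasible or inconsistent configuration."""


def spoke_sector_azimuth_deg(sector=(9, 12), spokes_per_turn: int = 13) -> float:
    """Mean azimuth (degrees, from local +x) of a spoke index range in the
    gamma-TuRC local frame; spoke k sits at azimuth (k-1)*360/spokes_per_turn."""
    lo, hi = int(sector[0]), int(sector[1])
    if not (1 <= lo <= hi <= 14):
        raise ConfigError(f"spoke sector {sector} outside 1..14")
    azimuths = [(k - 1) * 360.0 / spokes_per_turn for k in range(lo, hi + 1)]
    return float(np.mean(azimuths))


def _rotz(deg: float) -> np.ndarray:
    a = math.radians(deg)
    return np.array(
        [[math.cos(a), -math.sin(a), 0.0], [math.sin(a), math.cos(a), 0.0], [0.0, 0.0, 1.0]]
    )


def default_planted_orientation(sector=(9, 12), spokes_per_turn: int = 13) -> np.ndarray:
    """Preferred gamma-TuRC orientation relative to the nearest MTT frame
    such that the given spoke sector faces the centriolar wall.

    Both frames share their +z with the centriole axis; the relative
    rotation is then a pure twist about z placing the sector's mean
    azimuth on the wall-pointing direction.
    """
    theta = spoke_sector_azimuth_deg(sector, spokes_per_turn)
    return quat_from_matrix(_rotz(theta + 180.0))


@dataclass
class MinfluxConfig:
    """Cylindrical-shell MINFLUX emulation parameters (lengths in nm)."""

    n_structures: int = 17
    cylinder_radius: float = 35.0
    cylinder_length: float = 300.0
    traces_per_structure: int = 200
    mean_locs_per_trace: float = 8.0  # valid traces: 4 + Poisson(mean - 4)
    short_trace_fraction: float = 0.05  # traces with < 4 localizations
    sigma_xy: float = 6.0  # lateral localization error, nm
    sigma_z: float = 5.0  # axial error after the 0.7 z correction, nm
    efo_outlier_fraction: float = 0.10  # rows with EFO >= 100 kHz
    efo_median_khz: float = 40.0
    valid_iteration: int = 9
    decoys_per_trace: int = 2  # wrong-iteration decoy rows per trace
    z_scale: float = 0.7

    def validate(self) -> None:
        if self.cylinder_radius <= 0 or self.cylinder_length <= 0:
            raise ConfigError("cylinder radius and length must be positive")
        if not 0 <= self.short_trace_fraction <= 1 or not 0 <= self.efo_outlier_fraction <= 1:
            raise ConfigError("fractions must lie in [0, 1]")
        if self.sigma_xy <= 0 or self.sigma_z <= 0:
            raise ConfigError("localization noise sigmas must be positive")
        if min(self.n_structures, self.traces_per_structure) < 1:
            raise ConfigError("counts must be >= 1")
        if not 0 < self.z_scale <= 1:
            raise ConfigError("z_scale must be in (0, 1]")


@dataclass
class SimulationConfig:
    """Study-condition parameters for the synthetic centrosome."""

    seed: int = 1
    # centriole geometry
    wall_radius: float = 115.0  # nm, radial coordinate of B-tubule centerlines
    centriole_length: float = 450.0  # nm
    mtt_twist_deg_per_nm: float = 0.0
    axis_point: tuple = (0.0, 0.0, 0.0)
    axis_direction: tuple = (0.0, 0.0, 1.0)
    n_line_vertices: int = 31
    # lumenal pool
    n_lumenal: int = 300
    planted_b_tubule_distance: float = 75.0  # nm, center-to-center
    planted_distance_sd: float = 6.0
    planted_orientation: tuple = tuple(default_planted_orientation())
    orientation_noise_deg: float = 5.0
    background_fraction: float = 0.37  # orientation-random lumenal fraction
    # tilt of the placement ray about the line tangent; bounded so the
    # chosen B-tubule line remains the nearest one over the distance law
    placement_jitter_deg: float = 5.0
    min_separation: float = 18.0  # nm, rejection-sampling target packing
    max_placement_tries: int = 50
    # pericentriolar pool
    n_pericentriolar: int = 500
    pericentriolar_mean: float = 85.0  # nm
    pericentriolar_sd: float = 26.0
    pericentriolar_min: float = 30.0
    # MINFLUX block
    minflux: MinfluxConfig = field(default_factory=MinfluxConfig)

    def validate(self) -> None:
        if self.wall_radius <= 0:
            raise ConfigError("wall_radius must be positive")
        if self.centriole_length <= 0:
            raise ConfigError("centriole_length must be positive")
        if self.n_lumenal < 0 or self.n_pericentriolar < 0:
            raise ConfigError("particle counts must be >= 0")
        if not 0 <= self.background_fraction <= 1:
            raise ConfigError("background_fraction must lie in [0, 1]")
        if self.planted_distance_sd <= 0 or self.pericentriolar_sd <= 0:
            raise ConfigError("distance standard deviations must be positive")
        if self.planted_b_tubule_distance >= self.wall_radius:
            raise ConfigError(
                "planted lumenal B-tubule distance must be smaller than the wall radius"
            )
        if self.pericentriolar_mean <= self.wall_radius - self.planted_b_tubule_distance:
            # the mean must put the pool outside the wall
            if self.pericentriolar_mean <= 0:
                raise ConfigError("pericentriolar mean distance must be positive")
        self.minflux.validate()

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config key(s): {sorted(unknown)}")
        if "minflux" in d and isinstance(d["minflux"], dict):
            mf = d["minflux"]
            unknown_mf = set(mf) - set(MinfluxConfig.__dataclass_fields__)
            if unknown_mf:
                raise ConfigError(f"unknown minflux config key(s): {sorted(unknown_mf)}")
            d["minflux"] = MinfluxConfig(**mf)
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class CentrioleModel:
    """Centriole axis plus the nine MTT B-tubule centerline polylines."""

    axis: Axis
    length: float
    wall_radius: float
    mtt_b_tubule_lines: list  # 9 Polylines
    mtt_azimuths_deg: np.ndarray  # azimuth of each line at the proximal end

    def __post_init__(self):
        if len(self.mtt_b_tubule_lines) != 9:
            raise ConfigError("a centriole model carries exactly 9 MTT lines")

    @property
    def axial_extent(self) -> tuple:
        h = self.length / 2.0
        return (-h, h)


def _frame_to_world(direction) -> np.ndarray:
    """Rotation matrix mapping canonical +z to ``direction`` (minimal twist)."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, d)
    c = float(np.dot(z, d))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def simulate_centriole(config: SimulationConfig) -> CentrioleModel:
    """Construct the nine-fold MTT wall: straight (or helically twisted)
    B-tubule centerlines at ``wall_radius``, 40 degrees apart in azimuth,
    posed at the configured axis."""
    config.validate()
    rot = _frame_to_world(config.axis_direction)
    point = np.asarray(config.axis_point, dtype=float)
    s = np.linspace(-config.centriole_length / 2.0, config.centriole_length / 2.0, config.n_line_vertices)
    azimuths = np.arange(9) * 40.0
    lines = []
    for az in azimuths:
        phi = np.radians(az) + np.radians(config.mtt_twist_deg_per_nm) * (s - s[0])
        local = np.column_stack(
            [config.wall_radius * np.cos(phi), config.wall_radius * np.sin(phi), s]
        )
        lines.append(Polyline(local @ rot.T + point))
    axis = Axis(point, rot @ np.array([0.0, 0.0, 1.0]))
    return CentrioleModel(
        axis=axis,
        length=config.centriole_length,
        wall_radius=config.wall_radius,
        mtt_b_tubule_lines=lines,
        mtt_azimuths_deg=azimuths,
    )


def _mtt_frame_at(model: CentrioleModel, line_index: int, arc_fraction: float):
    """Local MTT frame at a fractional position along one B-tubule line:
    +z along the line tangent, +x pointing radially inward."""
    line: Polyline = model.mtt_b_tubule_lines[line_index]
    s = arc_fraction * line.total_length
    i = int(np.clip(np.searchsorted(line.arc_lengths, s) - 1, 0, len(line.vertices) - 2))
    seg = line.vertices[i + 1] - line.vertices[i]
    t = (s - line.arc_lengths[i]) / np.linalg.norm(seg)
    pos = line.vertices[i] + np.clip(t, 0.0, 1.0) * seg
    z = seg / np.linalg.norm(seg)
    to_axis = model.axis.point + np.dot(pos - model.axis.point, model.axis.direction) * model.axis.direction - pos
    x = to_axis - np.dot(to_axis, z) * z
    x = x / np.linalg.norm(x)
    y = np.cross(z, x)
    return pos, quat_from_matrix(np.column_stack([x, y, z]))


def _rotation_about(axis_vec, angle_rad) -> np.ndarray:
    a = np.asarray(axis_vec, dtype=float)
    a = a / np.linalg.norm(a)
    half = angle_rad / 2.0
    return quat_canonicalize(
        [math.cos(half), *(math.sin(half) * a)]
    )


def _small_random_rotation(rng, max_deg: float) -> np.ndarray:
    if max_deg <= 0:
        return np.array([1.0, 0.0, 0.0, 0.0])
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_deg))
    return _rotation_about(axis, angle)


def _particle_frame(df_rows) -> pd.DataFrame:
    return pd.DataFrame(
        df_rows,
        columns=["particle_id", "tomo_id", "x_nm", "y_nm", "z_nm", "qw", "qx", "qy", "qz", "pool"],
    )


def simulate_lumenal_turcs(
    model: CentrioleModel, config: SimulationConfig, tomo_id: str = "tomo_001"
) -> pd.DataFrame:
    """Condensed lumenal gamma-TuRC cluster.

    Each particle is placed at a Gaussian-planted center-to-center
    distance from one B-tubule line along a jittered inward ray, with
    axial positions in the central third of the centriole and best-effort
    minimum-separation rejection sampling.  A fraction
    ``1 - background_fraction`` of particles carries the planted
    orientation relative to the nearest MTT frame (perturbed by at most
    ``orientation_noise_deg``); the remainder is uniform on SO(3).
    """
    config.validate()
    if config.planted_b_tubule_distance + 4 * config.planted_distance_sd >= config.wall_radius * 1.6:
        raise ConfigError("planted lumenal distance infeasible for this wall radius")
    rng = np.random.default_rng(config.seed)
    planted_q = quat_canonicalize(config.planted_orientation)
    rows = []
    accepted = []
    for i in range(config.n_lumenal):
        best = None
        best_sep = -np.inf
        # one distance draw per particle: retries move only the placement
        # degrees of freedom, so rejection sampling cannot bias the law
        d = abs(rng.normal(config.planted_b_tubule_distance, config.planted_distance_sd))
        for _ in range(config.max_placement_tries):
            m = int(rng.integers(9))
            frac = rng.uniform(1.0 / 3.0, 2.0 / 3.0)  # central third
            zeta = math.radians(rng.uniform(-config.placement_jitter_deg, config.placement_jitter_deg))
            foot, q_mtt = _mtt_frame_at(model, m, frac)
            inward = rotate_vector(q_mtt, [1.0, 0.0, 0.0])
            tangent = rotate_vector(q_mtt, [0.0, 0.0, 1.0])
            ray = quat_to_matrix(_rotation_about(tangent, zeta)) @ inward
            pos = foot + d * ray
            sep = (
                min(np.linalg.norm(pos - p) for p in accepted) if accepted else np.inf
            )
            if sep > best_sep:
                best_sep = sep
                best = (pos, q_mtt)
            if sep >= config.min_separation:
                break
        pos, q_mtt = best
        accepted.append(pos)
        if rng.uniform() < config.background_fraction:
            q = random_rotation(rng)
        else:
            noise = _small_random_rotation(rng, config.orientation_noise_deg)
            # q_turc = q_mtt (x) planted^-1 so that relative_orientation(q_turc, q_mtt) = planted
            q = quat_canonicalize(
                quat_multiply(quat_multiply(q_mtt, quat_conjugate(planted_q)), noise)
            )
        rows.append((f"L{i + 1:04d}", tomo_id, *pos, *q, "unassigned"))
    return _particle_frame(rows)


def simulate_pericentriolar_turcs(
    model: CentrioleModel, config: SimulationConfig, tomo_id: str = "tomo_001"
) -> pd.DataFrame:
    """Broad pericentriolar pool: nearest-B-tubule distances from a
    truncated Gaussian (mean/sd/min from the config), outward placement,
    uniform orientations on SO(3)."""
    config.validate()
    from scipy.stats import truncnorm

    rng = np.random.default_rng(config.seed + 1)
    a = (config.pericentriolar_min - config.pericentriolar_mean) / config.pericentriolar_sd
    law = truncnorm(a, np.inf, loc=config.pericentriolar_mean, scale=config.pericentriolar_sd)
    rows = []
    for i in range(config.n_pericentriolar):
        m = int(rng.integers(9))
        frac = rng.uniform(0.0, 1.0)
        d = float(law.ppf(rng.uniform()))
        zeta = math.radians(rng.uniform(-config.placement_jitter_deg, config.placement_jitter_deg))
        foot, q_mtt = _mtt_frame_at(model, m, frac)
        outward = -rotate_vector(q_mtt, [1.0, 0.0, 0.0])
        tangent = rotate_vector(q_mtt, [0.0, 0.0, 1.0])
        ray = quat_to_matrix(_rotation_about(tangent, zeta)) @ outward
        pos = foot + d * ray
        q = random_rotation(rng)
        rows.append((f"P{i + 1:04d}", tomo_id, *pos, *q, "unassigned"))
    return _particle_frame(rows)


def simulate_minflux_structures(config: SimulationConfig, return_truth: bool = False):
    """MINFLUX localization table for ``n_structures`` randomly posed
    cylindrical shells.

    Emitters sit on a jittered lattice over the cylinder surface
    (uniform coverage, emulating the dense quasi-regular lumenal coat).
    Each emitter yields one trace; stored z-coordinates are divided by
    ``z_scale`` so the pipeline's 0.7 correction recovers true geometry,
    and the axial noise is sized so the *corrected* z error has
    ``sigma_z``.  A configured fraction of rows exceeds 100 kHz EFO, a
    configured fraction of traces is shorter than 4 localizations, and
    every trace carries wrong-iteration decoy rows.

    With ``return_truth`` the planted per-structure pose (axis direction,
    center, radius) is returned alongside the table for recovery checks.
    """
    config.validate()
    mf = config.minflux
    rng = np.random.default_rng(config.seed + 2)
    circumference = 2 * math.pi * mf.cylinder_radius
    n_azim = max(1, round(math.sqrt(mf.traces_per_structure * circumference / mf.cylinder_length)))
    n_axial = max(1, math.ceil(mf.traces_per_structure / n_azim))
    records = []
    truth = []
    for si in range(mf.n_structures):
        q_pose = random_rotation(rng)
        rot = quat_to_matrix(q_pose)
        center = np.array([si * 2000.0, 0.0, 0.0]) + rng.uniform(-100, 100, size=3)
        truth.append(
            {
                "structure_id": f"struct_{si:02d}",
                "axis_direction": rot @ np.array([0.0, 0.0, 1.0]),
                "center": center,
                "radius": mf.cylinder_radius,
            }
        )
        cells = [(ia, iz) for ia in range(n_azim) for iz in range(n_axial)]
        sel = rng.permutation(len(cells))[: mf.traces_per_structure]
        for ti, ci in enumerate(sel):
            ia, iz = cells[ci]
            phi = 2 * math.pi * (ia + rng.uniform()) / n_azim
            z0 = mf.cylinder_length * ((iz + rng.uniform()) / n_axial - 0.5)
            emitter_local = np.array(
                [mf.cylinder_radius * math.cos(phi), mf.cylinder_radius * math.sin(phi), z0]
            )
            emitter = rot @ emitter_local + center
            if rng.uniform() < mf.short_trace_fraction:
                n_locs = int(rng.integers(1, 4))
            else:
                n_locs = 4 + int(rng.poisson(max(mf.mean_locs_per_trace - 4.0, 0.0)))
            trace_id = f"s{si:02d}_t{ti:04d}"
            for it in range(n_locs):
                noise = np.array(
                    [
                        rng.normal(0.0, mf.sigma_xy),
                        rng.normal(0.0, mf.sigma_xy),
                        rng.normal(0.0, mf.sigma_z),
                    ]
                )
                p = emitter + noise
                if rng.uniform() < mf.efo_outlier_fraction:
                    efo = rng.uniform(100.0, 200.0)
                else:
                    efo = min(
                        mf.efo_median_khz * math.exp(rng.normal(0.0, 0.4)), 99.0
                    )
                records.append(
                    (
                        trace_id,
                        mf.valid_iteration,
                        p[0],
                        p[1],
                        p[2] / mf.z_scale,
                        efo,
                        f"struct_{si:02d}",
                    )
                )
            for _ in range(mf.decoys_per_trace):
                noise = rng.normal(0.0, 3 * mf.sigma_xy, size=3)
                p = emitter + noise
                records.append(
                    (
                        trace_id,
                        int(rng.integers(0, mf.valid_iteration)),
                        p[0],
                        p[1],
                        p[2] / mf.z_scale,
                        float(rng.uniform(10.0, 99.0)),
                        f"struct_{si:02d}",
                    )
                )
    table = pd.DataFrame(
        records,
        columns=["trace_id", "iteration", "x_nm", "y_nm", "z_nm", "efo_khz", "structure_id"],
    )
    return (table, truth) if return_truth else table


def simulate_pair_benchmark(
    n_pairs: int = 232,
    planted_fraction: float = 0.42,
    seed: int = 1,
    planted_shift_local=None,
    planted_orientation=None,
    shift_noise_nm: float = 3.0,
    orientation_noise_deg: float = 5.0,
    d_min: float = 60.0,
    d_max: float = 120.0,
):
    """Directly planted pair-configuration benchmark.

    Returns ``(shift_local_nm, q_rel, is_planted)`` arrays: a fraction
    ``planted_fraction`` of pairs sits at the planted local shift and
    relative orientation (small Gaussian shift noise, bounded rotation
    noise); the background is uniform on SO(3) and uniform in the
    admissible shift shell ``d_min..d_max`` nm.
    """
    rng = np.random.default_rng(seed)
    if planted_orientation is None:
        planted_orientation = default_planted_orientation()
    planted_q = quat_canonicalize(planted_orientation)
    if planted_shift_local is None:
        theta = math.radians(spoke_sector_azimuth_deg())
        planted_shift_local = 75.0 * np.array([math.cos(theta), math.sin(theta), 0.0])
    planted_shift_local = np.asarray(planted_shift_local, dtype=float)
    n_planted = int(round(planted_fraction * n_pairs))
    shifts, quats, flags = [], [], []
    for i in range(n_pairs):
        if i < n_planted:
            shift = planted_shift_local + rng.normal(0.0, shift_noise_nm, size=3)
            q = quat_canonicalize(
                quat_multiply(planted_q, _small_random_rotation(rng, orientation_noise_deg))
            )
            flags.append(True)
        else:
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            # uniform density over the admissible 3D shell (radius ~ r^2)
            r = (rng.uniform(d_min**3, d_max**3)) ** (1.0 / 3.0)
            shift = r * u
            q = random_rotation(rng)
            flags.append(False)
        shifts.append(shift)
        quats.append(q)
    return np.array(shifts), np.array(quats), np.array(flags)


def make_ring_model(
    model_id: str = "synthetic_ring",
    radius: float = 65.0,
    pitch: float = 120.0,
    spokes=range(1, 15),
    spokes_per_turn: int = 13,
    displacements: dict | None = None,
) -> "RingModel":
    """Synthetic 14-spoke ring model (Angstrom): gamma-tubulin centers on
    a one-start helix of the given radius and pitch.  ``displacements``
    maps spoke index -> 3-vector added to that center (to plant
    conformational deviations)."""
    from .io import RingModel

    centers = {}
    for k in spokes:
        a = 2 * math.pi * (k - 1) / spokes_per_turn
        c = np.array([radius * math.cos(a), radius * math.sin(a), pitch * (k - 1) / spokes_per_turn])
        if displacements and k in displacements:
            c = c + np.asarray(displacements[k], dtype=float)
        centers[int(k)] = c
    return RingModel(model_id, centers)
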