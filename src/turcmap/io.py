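"""Readers and writers for the tabular and structural formats the
pipeline touches.

Supported formats
-----------------
* canonical TSV particle tables (positions in nm, scalar-first unit
  quaternions, optional pool label),
* STAR particle loops (RELION-style ZYZ Euler triplets, converted to
  quaternions under a named convention),
* tabular MINFLUX localization exports (TSV/CSV),
* UCSF Chimera CMM marker XML,
* ring-model gamma-tubulin center tables (Angstrom),
* PDB ATOM records (selection centroids via gemmi).

All delimited files are UTF-8 with "." decimal separator.  Writers are
byte-deterministic given identical input; every read/write pair
round-trips to the stored precision (6 decimals).
"""

from __future__ import annotations

import io as _io
import warnings
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import quat_canonicalize

__all__ = [
    "FormatError",
    "PARTICLE_COLUMNS",
    "LOCALIZATION_COLUMNS",
    "POOL_LABELS",
    "RingModel",
    "read_particle_table",
    "write_particle_table",
    "read_localization_table",
    "write_localization_table",
    "write_marker_cmm",
    "read_ring_centers",
    "write_ring_centers",
    "pdb_group_centroid",
    "euler_zyz_to_quat",
    "quat_to_euler_zyz",
]


class FormatError(ValueError):
    """Raised when a file does not conform to the expected dialect."""


PARTICLE_COLUMNS = [
    "particle_id",
    "tomo_id",
    "x_nm",
    "y_nm",
    "z_nm",
    "qw",
    "qx",
    "qy",
    "qz",
    "pool",
]

LOCALIZATION_COLUMNS = ["trace_id", "iteration", "x_nm", "y_nm", "z_nm", "efo_khz", "structure_id"]

POOL_LABELS = ("lumenal", "pericentriolar", "unassigned")

_STAR_COLUMNS = {
    "particle_id": "_rlnImageName",
    "tomo_id": "_rlnMicrographName",
    "x": "_rlnCoordinateX",
    "y": "_rlnCoordinateY",
    "z": "_rlnCoordinateZ",
    "rot": "_rlnAngleRot",
    "tilt": "_rlnAngleTilt",
    "psi": "_rlnAnglePsi",
}


# ---------------------------------------------------------------------------
# Euler convention
# ---------------------------------------------------------------------------

def euler_zyz_to_quat(rot: float, tilt: float, psi: float, convention: str = "zyz_intrinsic") -> np.ndarray:
    """Convert a (rot, tilt, psi) Euler triplet in degrees to a canonical
    scalar-first unit quaternion.

    The default ``zyz_intrinsic`` convention composes intrinsic rotations
    Z(rot) * Y'(tilt) * Z''(psi); Euler (0, 0, 0) maps to the identity.
    The convention name is part of the file contract so that dialect
    disagreements between upstream packages stay explicit.
    """
    if convention != "zyz_intrinsic":
        raise FormatError(f"unknown Euler convention: {convention!r}")
    r = Rotation.from_euler("ZYZ", [rot, tilt, psi], degrees=True)
    x, y, z, w = r.as_quat()
    return quat_canonicalize([w, x, y, z])


def quat_to_euler_zyz(q, convention: str = "zyz_intrinsic"):
    """Inverse of :func:`euler_zyz_to_quat` (degrees; gimbal manifold at
    tilt 0/180 maps to a representative triplet)."""
    if convention != "zyz_intrinsic":
        raise FormatError(f"unknown Euler convention: {convention!r}")
    qq = quat_canonicalize(q)
    r = Rotation.from_quat([qq[1], qq[2], qq[3], qq[0]])
    with warnings.catch_warnings():
        # tilt = 0/180 has no unique triplet; the representative scipy
        # returns is a valid one and round-trips to the same rotation
        warnings.simplefilter("ignore", UserWarning)
        rot, tilt, psi = r.as_euler("ZYZ", degrees=True)
    return float(rot), float(tilt), float(psi)


# ---------------------------------------------------------------------------
# Particle tables
# ---------------------------------------------------------------------------

def _validate_particle_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PARTICLE_COLUMNS[:-1] if c not in df.columns]
    if missing:
        raise FormatError(f"particle table is missing mandatory column(s): {missing}")
    df = df.copy()
    if "pool" not in df.columns:
        df["pool"] = "unassigned"
    df["pool"] = df["pool"].fillna("unassigned")
    bad = set(df["pool"].unique()) - set(POOL_LABELS)
    if bad:
        raise FormatError(f"unknown pool label(s): {sorted(bad)}")
    q = df[["qw", "qx", "qy", "qz"]].to_numpy(dtype=float)
    norms = np.linalg.norm(q, axis=1)
    if np.any(norms <= 0):
        raise FormatError("particle table contains a zero-norm quaternion")
    dev = np.abs(norms - 1.0)
    if np.any(dev >= 1e-3):
        raise FormatError("particle orientation deviates from unit norm by >= 1e-3")
    if np.any(dev > 1e-6):
        warnings.warn(
            f"{int((dev > 1e-6).sum())} orientation(s) off unit norm by < 1e-3; normalized"
        )
    q = np.array([quat_canonicalize(row) for row in q])
    df[["qw", "qx", "qy", "qz"]] = q
    dup = df.duplicated(subset=["tomo_id", "particle_id"])
    if dup.any():
        raise FormatError("particle_id values must be unique within each tomo_id")
    return df[PARTICLE_COLUMNS]


def _read_star_loop(path) -> pd.DataFrame:
    """Minimal reader for a single STAR data block with one particles loop."""
    names: list[str] = []
    rows: list[list[str]] = []
    in_loop = False
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            s = line.strip()
            if not s or s.startswith("#") or s.startswith("data_"):
                continue
            if s == "loop_":
                in_loop = True
                names, rows = [], []
                continue
            if in_loop and s.startswith("_"):
                names.append(s.split()[0])
                continue
            if in_loop:
                parts = s.split()
                if len(parts) != len(names):
                    raise FormatError(
                        f"STAR row has {len(parts)} fields, expected {len(names)}: {s!r}"
                    )
                rows.append(parts)
    if not names:
        raise FormatError("no loop_ block found in STAR file")
    return pd.DataFrame(rows, columns=names)


def read_particle_table(
    path,
    dialect: str = "canonical_tsv",
    euler_convention: str = "zyz_intrinsic",
    pixel_size_nm: float = 1.0,
) -> pd.DataFrame:
    """Read an oriented-particle table.

    ``canonical_tsv`` expects the package's own column layout
    (positions already in nm, scalar-first quaternions).  ``star`` reads
    a particles loop with coordinate columns in pixels (scaled by
    ``pixel_size_nm``) and ZYZ Euler angles in degrees.
    """
    if dialect == "canonical_tsv":
        df = pd.read_csv(path, sep="\t", dtype={"particle_id": str, "tomo_id": str})
        return _validate_particle_table(df)
    if dialect == "star":
        raw = _read_star_loop(path)
        missing = [v for v in _STAR_COLUMNS.values() if v not in raw.columns]
        if missing:
            raise FormatError(f"STAR particles loop is missing column(s): {missing}")
        quats = np.array(
            [
                euler_zyz_to_quat(r, t, p, euler_convention)
                for r, t, p in zip(
                    raw[_STAR_COLUMNS["rot"]].astype(float),
                    raw[_STAR_COLUMNS["tilt"]].astype(float),
                    raw[_STAR_COLUMNS["psi"]].astype(float),
                )
            ]
        )
        df = pd.DataFrame(
            {
                "particle_id": raw[_STAR_COLUMNS["particle_id"]].astype(str),
                "tomo_id": raw[_STAR_COLUMNS["tomo_id"]].astype(str),
                "x_nm": raw[_STAR_COLUMNS["x"]].astype(float) * pixel_size_nm,
                "y_nm": raw[_STAR_COLUMNS["y"]].astype(float) * pixel_size_nm,
                "z_nm": raw[_STAR_COLUMNS["z"]].astype(float) * pixel_size_nm,
                "qw": quats[:, 0],
                "qx": quats[:, 1],
                "qy": quats[:, 2],
                "qz": quats[:, 3],
            }
        )
        return _validate_particle_table(df)
    raise FormatError(f"unknown particle-table dialect: {dialect!r}")


def write_particle_table(
    table: pd.DataFrame,
    path,
    dialect: str = "canonical_tsv",
    euler_convention: str = "zyz_intrinsic",
    pixel_size_nm: float = 1.0,
) -> None:
    """Write a particle table with deterministic column order and 6-decimal
    fixed formatting; round-trips via :func:`read_particle_table`."""
    df = table.copy()
    if "pool" not in df.columns:
        df["pool"] = "unassigned"
    df = df[PARTICLE_COLUMNS]
    if dialect == "canonical_tsv":
        df.to_csv(path, sep="\t", index=False, float_format="%.6f")
        return
    if dialect == "star":
        lines = ["data_particles", "", "loop_"]
        cols = [
            _STAR_COLUMNS["particle_id"],
            _STAR_COLUMNS["tomo_id"],
            _STAR_COLUMNS["x"],
            _STAR_COLUMNS["y"],
            _STAR_COLUMNS["z"],
            _STAR_COLUMNS["rot"],
            _STAR_COLUMNS["tilt"],
            _STAR_COLUMNS["psi"],
        ]
        lines += [f"{c} #{i + 1}" for i, c in enumerate(cols)]
        for _, row in df.iterrows():
            rot, tilt, psi = quat_to_euler_zyz(
                [row.qw, row.qx, row.qy, row.qz], euler_convention
            )
            lines.append(
                f"{row.particle_id} {row.tomo_id} "
                f"{row.x_nm / pixel_size_nm:.6f} {row.y_nm / pixel_size_nm:.6f} "
                f"{row.z_nm / pixel_size_nm:.6f} {rot:.6f} {tilt:.6f} {psi:.6f}"
            )
        Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
        return
    raise FormatError(f"unknown particle-table dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# MINFLUX localization tables
# ---------------------------------------------------------------------------

def read_localization_table(path, unit_scale: float = 1.0, efo_unit: str = "khz") -> pd.DataFrame:
    """Read a tabular MINFLUX export.

    ``unit_scale`` multiplies coordinates into nm (pass 1e9 for exports in
    meters).  ``efo_unit`` is ``"khz"`` or ``"hz"``; Hz inputs are divided
    by 1000.  The column ``itr`` is accepted as an alias for
    ``iteration``; missing ``structure_id`` defaults to ``"0"``.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    df = df.rename(columns={"itr": "iteration", "x": "x_nm", "y": "y_nm", "z": "z_nm", "efo": "efo_khz"})
    if "structure_id" not in df.columns:
        df["structure_id"] = "0"
    missing = [c for c in ("trace_id", "iteration", "x_nm", "y_nm", "z_nm", "efo_khz") if c not in df.columns]
    if missing:
        raise FormatError(f"localization table is missing column(s): {missing}")
    for c in ("x_nm", "y_nm", "z_nm", "efo_khz"):
        try:
            df[c] = df[c].astype(float)
        except (TypeError, ValueError) as exc:
            bad = pd.to_numeric(df[c], errors="coerce").isna()
            raise FormatError(
                f"non-numeric value in column {c!r} at row(s) {list(df.index[bad])}"
            ) from exc
    df[["x_nm", "y_nm", "z_nm"]] *= unit_scale
    if efo_unit == "hz":
        df["efo_khz"] /= 1000.0
    elif efo_unit != "khz":
        raise FormatError(f"unknown EFO unit: {efo_unit!r}")
    if (df["efo_khz"] < 0).any():
        raise FormatError("EFO values must be non-negative")
    if (df["iteration"].astype(int) < 0).any():
        raise FormatError("iteration indices must be non-negative")
    df["iteration"] = df["iteration"].astype(int)
    df["trace_id"] = df["trace_id"].astype(str)
    df["structure_id"] = df["structure_id"].astype(str)
    return df[LOCALIZATION_COLUMNS]


def write_localization_table(table: pd.DataFrame, path) -> None:
    table[LOCALIZATION_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# CMM markers
# ---------------------------------------------------------------------------

def write_marker_cmm(points, radius: float, path, name: str = "marker set 1") -> None:
    """Write points as a UCSF Chimera-compatible CMM marker_set XML file."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.size == 0:
        raise ValueError("marker export needs at least one point")
    root = ET.Element("marker_set", attrib={"name": name})
    for i, p in enumerate(pts, start=1):
        ET.SubElement(
            root,
            "marker",
            attrib={
                "id": str(i),
                "x": f"{p[0]:.6f}",
                "y": f"{p[1]:.6f}",
                "z": f"{p[2]:.6f}",
                "radius": f"{radius:.6f}",
            },
        )
    buf = _io.BytesIO()
    ET.ElementTree(root).write(buf, encoding="utf-8", xml_declaration=True)
    Path(path).write_bytes(buf.getvalue() + b"\n")


# ---------------------------------------------------------------------------
# Ring models
# ---------------------------------------------------------------------------

@dataclass
class RingModel:
    """Labeled gamma-tubulin center coordinates (Angstrom) of one
    gamma-TuRC conformational model.  A full ring has 14 spokes; partial
    models (e.g. a microtubule-capping reference without spoke 1) are
    flagged via :attr:`is_partial`."""

    model_id: str
    centers: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        fixed = {}
        for spoke, c in self.centers.items():
            spoke = int(spoke)
            if not 1 <= spoke <= 14:
                raise FormatError(f"spoke index {spoke} outside 1..14")
            fixed[spoke] = np.asarray(c, dtype=float).reshape(3)
        self.centers = dict(sorted(fixed.items()))

    @property
    def spokes(self) -> list[int]:
        return list(self.centers)

    @property
    def is_partial(self) -> bool:
        return len(self.centers) < 14

    def coords(self, spokes=None) -> np.ndarray:
        keys = self.spokes if spokes is None else list(spokes)
        missing = [k for k in keys if k not in self.centers]
        if missing:
            raise FormatError(f"model {self.model_id!r} lacks spoke(s) {missing}")
        return np.array([self.centers[k] for k in keys])

    def replace_coords(self, coords: np.ndarray, model_id: str | None = None) -> "RingModel":
        return RingModel(
            model_id if model_id is not None else self.model_id,
            dict(zip(self.spokes, np.asarray(coords, dtype=float))),
        )


def read_ring_centers(path, model_id: str | None = None) -> RingModel:
    """Read a spoke/x/y/z table (Angstrom) into a :class:`RingModel`."""
    df = pd.read_csv(path)
    missing = [c for c in ("spoke", "x", "y", "z") if c not in df.columns]
    if missing:
        raise FormatError(f"ring-center table is missing column(s): {missing}")
    if df["spoke"].duplicated().any():
        raise FormatError("duplicate spoke index in ring-center table")
    centers = {int(r.spoke): np.array([r.x, r.y, r.z], dtype=float) for r in df.itertuples()}
    return RingModel(model_id or Path(path).stem, centers)


def write_ring_centers(model: RingModel, path) -> None:
    df = pd.DataFrame(
        [(s, *model.centers[s]) for s in model.spokes], columns=["spoke", "x", "y", "z"]
    )
    df.to_csv(path, index=False, float_format="%.6f")


# ---------------------------------------------------------------------------
# PDB centroids
# ---------------------------------------------------------------------------

def pdb_group_centroid(path, chains, residue_range=None) -> np.ndarray:
    """Unweighted arithmetic mean of selected atom coordinates (Angstrom)
    from a PDB-format file.

    ``chains`` is an iterable of chain identifiers; ``residue_range`` an
    optional inclusive ``(first, last)`` sequence-number pair.  Mirrors
    the behaviour of an unweighted "measure center" on the selection.
    """
    import gemmi

    try:
        structure = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    chains = set(chains)
    coords = []
    for model in structure:
        for chain in model:
            if chain.name not in chains:
                continue
            for residue in chain:
                if residue_range is not None:
                    num = residue.seqid.num
                    if not residue_range[0] <= num <= residue_range[1]:
                        continue
                for atom in residue:
                    coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
        break  # first model only
    if not coords:
        raise FormatError(f"selection (chains={sorted(chains)}, residues={residue_range}) matches no atom")
    return np.asarray(coords, dtype=float).mean(axis=0)
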