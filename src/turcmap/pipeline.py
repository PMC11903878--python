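"""Config-driven orchestration of the analysis stages.

Each stage function consumes a :class:`turcmap.synth.SimulationConfig`
(or stage outputs) and returns a JSON-serializable report fragment that
records filter counts alongside the summaries, mirroring how retained
particle numbers are reported in tomographic spatial analyses.  Reports
contain no timestamps, so identical configs reproduce byte-identical
report files.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .conformation import ring_deviation_profile
from .io import write_localization_table, write_marker_cmm, write_particle_table
from .minflux import aggregate_traces, filter_localizations, fit_structure_axis, precision_summary
from .pairs import (
    cluster_pair_configurations,
    filter_pairs_by_distance,
    mtt_segments_from_model,
    pair_particles_to_mtts,
    wall_facing_angle,
)
from .spatial import (
    classify_pools,
    nearest_neighbor_distances,
    percentile_median_unbiased,
    signed_mtt_distances,
    summarize_distribution,
)
from .synth import (
    SimulationConfig,
    make_ring_model,
    simulate_centriole,
    simulate_lumenal_turcs,
    simulate_minflux_structures,
    simulate_pericentriolar_turcs,
)

__all__ = [
    "simulate_stage",
    "spatial_stage",
    "pairs_stage",
    "minflux_stage",
    "conformation_stage",
    "run_all",
    "write_report",
]


def _round_floats(obj, ndigits=6):
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (float, np.floating)):
        return round(float(obj), ndigits)
    if isinstance(obj, (int, np.integer)):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), ndigits)
    return obj


def write_report(report: dict, path) -> None:
    Path(path).write_text(
        json.dumps(_round_floats(report), indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def simulate_stage(config: SimulationConfig, out_dir: Path):
    """Generate the synthetic centrosome and MINFLUX recording; write the
    particle and localization tables."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = simulate_centriole(config)
    lumenal = simulate_lumenal_turcs(model, config)
    peri = simulate_pericentriolar_turcs(model, config)
    particles = pd.concat([lumenal, peri], ignore_index=True)
    locs = simulate_minflux_structures(config)
    write_particle_table(particles, out_dir / "particles.tsv")
    write_localization_table(locs, out_dir / "localizations.tsv")
    report = {
        "n_lumenal": len(lumenal),
        "n_pericentriolar": len(peri),
        "n_localization_rows": len(locs),
        "n_traces": int(locs["trace_id"].nunique()),
    }
    return model, particles, locs, report


def spatial_stage(particles, model, margin: float = 10.0):
    """Pool classification, signed B-tubule distances, and nearest-neighbor
    statistics per pool."""
    labeled = classify_pools(particles, model, margin=margin)
    signed, summary = signed_mtt_distances(labeled, model)
    nn = {}
    for pool in ("lumenal", "pericentriolar"):
        sub = labeled[labeled["pool"] == pool]
        if len(sub) >= 2:
            _, nn_summary = nearest_neighbor_distances(sub)
            nn[pool] = nn_summary.as_dict()
    report = {
        "pool_counts": labeled["pool"].value_counts().to_dict(),
        "signed_distance_nm": summary.as_dict(),
        "nearest_neighbor_nm": nn,
    }
    return labeled, signed, report


def pairs_stage(labeled, model, k: int = 8, seed: int = 0, restarts: int = 20,
                d_min: float = 60.0, d_max: float = 120.0, axis_tolerance_deg: float = 30.0):
    """Pairing, distance filtering, 7D k-means, and wall-facing angles."""
    segments = mtt_segments_from_model(model)
    pairs = pair_particles_to_mtts(labeled, segments, axis_tolerance_deg=axis_tolerance_deg)
    kept = filter_pairs_by_distance(pairs, d_min=d_min, d_max=d_max)
    result = cluster_pair_configurations(kept, k=k, seed=seed, restarts=restarts)
    members = [p for p, l in zip(kept, result.assignments) if l == result.main_cluster_index]
    angles = [wall_facing_angle(p) for p in members if np.linalg.norm(p.shift_local[:2]) > 1e-9]
    report = {
        "n_pairs_before_distance_filter": len(pairs),
        "n_pairs": len(kept),
        "k": result.k,
        "cluster_sizes": result.sizes.tolist(),
        "main_fraction_all": result.main_fraction_all,
        "main_fraction_lumenal": result.main_fraction_lumenal,
        "mean_shift_local_nm": result.mean_shift_local.tolist(),
        "mean_q_rel": result.mean_q_rel.tolist(),
        "angular_spread_deg": result.angular_spread_deg,
        "wall_facing_median_deg": (
            percentile_median_unbiased(angles, 0.5) if angles else None
        ),
    }
    return kept, result, report


def minflux_stage(locs, out_dir: Path | None = None, valid_iteration: int = 9,
                  efo_max_khz: float = 100.0, min_locs: int = 4, z_scale: float = 0.7):
    """Filtering, trace aggregation, precision summary, per-structure axis
    fits, and the pooled radial distribution."""
    filtered = filter_localizations(
        locs, valid_iteration=valid_iteration, efo_max_khz=efo_max_khz,
        min_locs=min_locs, z_scale=z_scale,
    )
    centers = aggregate_traces(filtered)
    precision = precision_summary(centers)
    radial_all = []
    axes = {}
    for sid in sorted({c.structure_id for c in centers}):
        struct = [c for c in centers if c.structure_id == sid]
        axis, profile = fit_structure_axis(struct)
        axes[sid] = {
            "direction": axis.direction.tolist(),
            "point": axis.point.tolist(),
            "n_traces": len(struct),
        }
        radial_all.append(profile.r)
    pooled = np.concatenate(radial_all)
    radial_summary = summarize_distribution(pooled)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_marker_cmm([c.center for c in centers], 6.0, out_dir / "trace_centers.cmm")
    report = {
        "rows_in": len(locs),
        "rows_kept": len(filtered),
        "n_traces": len(centers),
        "sigma_x_nm": precision.sigma_x,
        "sigma_y_nm": precision.sigma_y,
        "sigma_z_nm": precision.sigma_z,
        "sigma_xy_nm": precision.sigma_xy,
        "radial_nm": radial_summary.as_dict(),
        "axes": axes,
    }
    return centers, precision, report


def conformation_stage(displaced_spokes=(13, 14), displacement_A: float = 10.0):
    """Deviation profile of a synthetic ring with planted outward spoke
    displacements against its closed counterpart."""
    reference = make_ring_model("closed_reference_synthetic")
    displacements = {}
    for s in displaced_spokes:
        c = reference.centers[s]
        outward = np.array([c[0], c[1], 0.0])
        outward /= np.linalg.norm(outward)
        displacements[s] = displacement_A * outward
    query = make_ring_model("displaced_query_synthetic", displacements=displacements)
    profile = ring_deviation_profile(query, reference)
    report = {
        "subset": list(profile.subset),
        "rmsd_A": profile.rmsd,
        "deviations_A": {str(k): v for k, v in profile.deviations.items()},
    }
    return profile, report


def run_all(config: SimulationConfig, out_dir, k: int = 8, restarts: int = 20) -> dict:
    """End-to-end run on synthetic data; returns the full report dict and
    writes ``report.json`` plus stage outputs under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model, particles, locs, sim_report = simulate_stage(config, out_dir)
    labeled, _, spatial_report = spatial_stage(particles, model)
    _, _, pairs_report = pairs_stage(labeled, model, k=k, seed=config.seed, restarts=restarts)
    _, _, minflux_report = minflux_stage(locs, out_dir)
    _, conf_report = conformation_stage()
    report = {
        "turcmap_version": __version__,
        "config": config.to_dict(),
        "simulate": sim_report,
        "spatial": spatial_report,
        "pairs": pairs_report,
        "minflux": minflux_report,
        "conformation": conf_report,
    }
    write_report(report, out_dir / "report.json")
    return report
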