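# turcmap

Quantitative spatial-organization and conformational analyses for
γ-tubulin ring complexes (γ-TuRCs) at human centrosomes.

γ-TuRCs — the 14-spoke templates that nucleate microtubules — occupy two
centrosomal compartments: the pericentriolar material and the centriole
lumen. Subtomogram averaging of cryo-electron tomograms yields their
positions and orientations; MINFLUX nanoscopy maps interaction partners at
few-nm precision; atomic models describe the ring's conformational states.
`turcmap` implements the downstream quantitative analyses on top of such
data:

* **Distance-pool statistics** — classify particles into lumenal /
  pericentriolar pools, compute signed center-to-center distances to the
  nine microtubule-triplet (MTT) B-tubule centerlines, nearest-neighbor
  spacings, and median-unbiased (Hyndman–Fan type 8,
  `h = p(n + 1/3) + 1/3`) quantile summaries.
* **Pair-configuration clustering** — reduce each γ-TuRC–MTT pair to a
  rigid-motion-invariant 7D feature (local-frame shift ⊕ relative unit
  quaternion `q_rel = q_turc⁻¹ ⊗ q_mtt`), filter to 60–120 nm
  center-of-mass distance, k-means the features, and summarize the main
  cluster (fraction, mean pose, wall-facing spoke sector angle).
* **MINFLUX post-processing** — keep 9th-iteration localizations, correct
  z by 0.7, drop rows with EFO ≥ 100 kHz and traces with < 4
  localizations, average traces to emitter centers, fit per-structure
  cylinder axes by total least squares, and report radial distributions
  and localization precisions.
* **Ring-geometry deviations** — superpose γ-TuRC models on a spoke subset
  (Kabsch, proper rotations only; default spokes 2–8) and report
  per-spoke γ-tubulin-center deviations from a closed microtubule-capping
  reference.
* **Synthetic data** — generators for 9-fold centriole walls, lumenal
  clusters with planted distances and orientations, broad pericentriolar
  pools, and MINFLUX traces on cylindrical shells, so every stage is
  testable offline with recoverable ground truth.

See `docs/methods.md` for the underlying models, conventions, and
limitations.

## Worked example

Run the full pipeline on synthetic study-condition data:

```sh
turcmap all --seed 5 --out-dir run5
```

`run5/report.json` then contains (excerpt):

```json
{
  "pairs": {
    "main_fraction_lumenal": 0.648829,
    "wall_facing_median_deg": 3.807756,
    "n_pairs": 683
  },
  "minflux": {
    "sigma_xy_nm": 5.645482,
    "sigma_z_nm": 4.717666
  }
}
```

with `spatial.signed_distance_nm.per_pool.lumenal.median ≈ 75.7` (signed
values are negative on the lumenal side; pool summaries report
magnitudes) and
`minflux.radial_nm.median ≈ 35.06`. Reading: about 65% of lumenal
particles share one preferred arrangement relative to their nearest MTT,
with the spoke 9–12 sector facing the centriolar wall (median wall-facing
angle ~4°); the lumenal pool sits ~75 nm from the nearest B-tubule
centerline (negative sign = lumenal side); MINFLUX trace centers lie on a
~35 nm-radius cylinder with ~5.7 / 4.7 nm recovered lateral / axial
precision. Re-running with the same seed reproduces the report
byte-for-byte.

The same stages are available as library calls
(`turcmap.pipeline.run_all`, or the individual `turcmap.spatial`,
`turcmap.pairs`, `turcmap.minflux`, `turcmap.conformation` functions) and
as separate CLI commands (`simulate`, `spatial`, `pairs`, `minflux`,
`conformation`) driven by a YAML config:

```yaml
simulation:
  seed: 5
  n_lumenal: 300
  n_pericentriolar: 500
pairs:
  k: 8
  d_min: 60
  d_max: 120
```

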