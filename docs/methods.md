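# Methods

`turcmap` quantifies how γ-tubulin ring complexes (γ-TuRCs) are organized
at human centrosomes, from three kinds of evidence: oriented particle
tables produced by subtomogram averaging of cryo-electron tomograms,
MINFLUX single-molecule localization recordings, and atomic ring models of
γ-TuRC conformational states. This note describes the models and
procedures the package implements, the parameters that matter, and the
limits of what the bundled synthetic data can show.

## Coordinate and rotation conventions

Quaternions are scalar-first unit quaternions acting as local-frame →
world-frame maps, `v_world = R(q) v_local`. Because `q` and `−q` encode
the same rotation, every quaternion is canonicalized to `w ≥ 0` (for
`w = 0`, the first nonzero vector component is made non-negative) before
averaging or clustering; without this, one pose population would split
into two antipodal clusters. Orientation averages use the dominant
eigenvector of the accumulated outer-product matrix after sign-aligning
all inputs to the first sample; an eigenvalue tie (e.g. two orthogonal
180° rotations) has no meaningful mean and raises an error. Angles are
degrees at every interface. Spatial modules work in nm, the conformation
module in Å.

The γ-TuRC local frame puts +z along the ring's helical axis and +x
toward spoke 1's azimuth, with spoke *k* at azimuth `(k−1)·360/13°`
(14 spokes on a 13-fold helical lattice). MTT segment frames put +z along
the triplet axis and +x radially inward. Any fixed pair of conventions
works as long as generator and analyzer share them; these are the
package's.

## Distance-pool statistics

Particles are split into centriole-lumenal and pericentriolar pools by a
deterministic geometric rule replacing a visual split: lumenal iff the
radial coordinate about the centriole axis is below `wall_radius − margin`
and the axial coordinate falls inside the centriole extent widened by
`margin` (default 10 nm, absorbing wall thickness and axis-fit slack).
Each particle's distance is the minimum center-to-center distance to the
nine MTT B-tubule centerline polylines, signed negative for lumenal and
positive for pericentriolar particles. Nearest-neighbor distances are
computed per tomogram (and per pool), one value per particle, so mutually
closest pairs contribute twice. Distances are computed per tomogram;
pooling happens only at the summary stage.

All quantile summaries use the median-unbiased (Hyndman–Fan type 8)
estimator, `h = p(n + 1/3) + 1/3` with linear interpolation between order
statistics clamped to `[min, max]`; summaries report the median and the
central 90% and 95% intervals. Intervals are computed on pooled particles
by default (a per-centriole option exists), since per-centriole
aggregation is not uniquely defined for small per-tomogram counts.

## Pair-configuration clustering

Each γ-TuRC is paired with its closest MTT segment after rejecting
segments whose refined orientation deviates from the locally interpolated
MTT axis by more than `axis_tolerance_deg` (default 30°). Pairs outside a
60–120 nm center-of-mass distance window (inclusive) are discarded. A
pair is reduced to a 7D feature: the world shift rotated into the γ-TuRC
local frame and divided by `shift_scale` (default 60 nm, half the upper
distance cutoff, so positional and orientational coordinates span
comparable ranges), concatenated with the canonicalized relative
quaternion. Expressing the shift in the particle frame makes the feature
exactly invariant under global rigid motions — the property that makes
arrangements comparable across tomograms.

Features are grouped by Lloyd's k-means with k-means++ initialization and
`restarts` restarts (default 20, best inertia kept). Rows are sorted
lexicographically before clustering and assignments mapped back, so
results do not depend on input order. The main cluster is the largest;
its summary is the arithmetic mean local shift (nm) and the eigenvector
quaternion mean of member orientations.

The number of clusters is genuinely open (no value is published for this
analysis); it is exposed in config with default **k = 8**. The default was
chosen by a bias argument measured on the planted benchmark below: with a
uniform background, every background point falling in the main cluster's
Voronoi cell inflates the main-cluster fraction; at k = 5 this bias is
about +0.09 on a planted fraction of 0.42 and also drags the mean shift
several nm toward the background, while from k ≈ 8 the background cells
are small enough that the main-cluster share tracks the planted fraction
within ±0.05. Larger k mainly fragments the background further.

The wall-facing angle interprets the main cluster: it is the angle
between the mean azimuthal direction of a chosen spoke sector (default
spokes 9–12, the GCP4/5/4/6 side) in the γ-TuRC local frame and the
in-plane projection of the local shift toward the MTT; 0° means that
sector faces the triplet.

## MINFLUX post-processing

Filtering runs in a fixed order: keep final-iteration rows (default
iteration 9), multiply z by 0.7 (the optical-axis compression correction
for the instrument's z estimate), drop rows with EFO ≥ 100 kHz (strict
`<` keeps), then drop traces left with fewer than 4 localizations. Only
the EFO/trace-length interaction is order-sensitive; running the EFO cut
first is the stricter reading (traces that lose rows to the quality cut
must still have 4 good localizations). The corrected table is flagged so
a repeated pass is a no-op, making the filter idempotent.

Traces are averaged to emitter centers with per-axis sample standard
deviations (n−1). Localization precision is summarized as the
per-structure type-8 median of trace-wise standard deviations, averaged
across structures; σ_xy is the mean of the x and y values, matching the
convention of reporting one lateral precision.

The per-structure cylinder axis is the total-least-squares line through
the collective centroid, i.e. the direction minimizing summed squared
perpendicular distances (the dominant scatter direction). For points on a
cylindrical shell with uniform angular coverage this recovers the central
axis exactly; a literal unsquared-distance minimizer is not used because
the centroid anchoring matches the least-squares solution and is
deterministic. Degenerate (isotropic) clouds raise an error rather than
returning an arbitrary direction. Radial distributions of trace centers
about the fitted axes are pooled across structures and summarized with
type-8 quantiles.

## Ring-geometry deviations

Conformational models are compared as sets of labeled γ-tubulin centers
(Å), either read from spoke tables or extracted from PDB models as
unweighted selection centroids ("measure center" without mass weighting —
the weighting used originally is not documented, and the unweighted mean
is reproducible without element tables). A query ring is superposed onto
the closed microtubule-capping reference by proper Kabsch superposition
(reflections corrected) over a spoke subset; the deviation per spoke is
the Euclidean distance between the transformed query center and the
reference center. The default subset is spokes 2–8, with 3–8 selectable:
the two published descriptions of the superposition subset disagree, so
both are supported rather than silently resolving the conflict.
`align_ring_to_z` orients a ring with its normal (the minor scatter
direction of the near-planar centers) along +z, counter-clockwise spoke
order viewed from +z.

## Synthetic data: what it emulates and what it does not

The generators exist so every stage has planted, recoverable ground
truth; their defaults are the regimes observed in centrosomal tomograms
and MINFLUX recordings:

| parameter | default | role |
|---|---|---|
| wall radius | 115 nm | B-tubule centerline radius of the 9-fold wall |
| centriole length | 450 nm | axial extent; lumenal pool confined to the central third |
| lumenal B-tubule distance | 75 ± 6 nm | planted center-to-center law |
| lumenal background fraction | 0.37 | orientation-random lumenal particles |
| orientation noise | 5° | spread of the planted relative pose |
| pericentriolar law | 85 ± 26 nm, min 30 | truncated Gaussian stand-in |
| MINFLUX cylinder | r = 35 nm × 300 nm | 17 structures × 200 traces |
| localization noise | σ_xy = 6, σ_z = 5 nm | σ_z is post-correction; stored z is pre-divided by 0.7 |

Design notes:

* One planted-distance draw per particle; minimum-separation retries move
  only the placement degrees of freedom, so rejection sampling cannot
  bias the distance law. The placement ray tilts at most ±5° off the
  inward/outward normal so the chosen B-tubule provably stays the nearest
  line across the distance law.
* The preferred lumenal orientation default is constructed, not tuned: it
  is the unique z-twist that puts the spoke 9–12 sector on the
  wall-pointing direction when both frames share the centriole axis.
* MINFLUX emitters sit on a jittered lattice over the cylinder surface
  (uniform coverage emulating a dense quasi-regular lumenal coat);
  independent draws would tilt the fitted axis by 1–3° at 200 traces from
  sampling covariance alone, obscuring instrument-noise effects. Noise is
  applied in the world frame (instrument frame), structures are randomly
  posed, stored z is divided by 0.7 so the pipeline's correction recovers
  true geometry, and axial noise is sized so the *corrected* z error has
  σ_z. EFO values are a bounded log-normal with a configured outlier
  fraction above 100 kHz; decoy rows carry non-final iteration indices.
* The pair benchmark plants a configuration at fraction 0.42 among 232
  pairs; the background is uniform on SO(3) and uniform in *density* over
  the admissible 60–120 nm shift shell (radius sampled ∝ r²).

Known gaps between synthetic and real data: the generators produce one
centriole per table, so cross-centriole variability is absent; 300
lumenal particles forced into one lumen are volume-limited to ~11 nm
nearest-neighbor packing (real per-centriole occupancies are lower and
pack near 25 nm); the pericentriolar pool sits on a thin geometric shell
per distance draw rather than filling the pericentriolar material in 3D,
which compresses its nearest-neighbor distances; there is no missing
wedge, no localization drift, and no photophysics. Passing recovery tests
therefore demonstrates correctness of the estimators under the planted
laws, not robustness to every artifact of real recordings.

Per-trace sample standard deviations underestimate σ slightly at ~8
localizations per trace (the c₄ bias of the sample SD, ≈3.5% at n = 8),
so recovered precisions land near 5.7/4.7 nm for planted 6/5 nm; the
estimator is reported as-is rather than debiased because that matches
standard practice.

## Numerical choices

Unit-norm and identity checks at 1e-9; degeneracy (eigenvalue-tie) checks
at 1e-6 relative; superposition rejects subsets of rank < 2; quaternion
canonicalization resolves the w = 0 tie by the first nonzero vector
component; axis directions are signed toward +z (then +y, +x);
histogramming a constant radial coordinate pads a ±5% range instead of
failing. Reports round floats to 6 decimals and contain no timestamps, so
identical configs give byte-identical outputs.

## Problem sizes

Default runs use 300 + 500 particles, ~500 MTT segments, 232-pair
clustering benchmarks, and 17 × 200 MINFLUX traces (~30k localization
rows); a full pipeline run completes in seconds and the whole test suite
in about two minutes on one CPU.
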