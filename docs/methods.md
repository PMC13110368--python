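# Methods

This note documents the models, parameters and numerical choices behind
`pllpquant`.  Conventions used throughout: axis order (z, y, x), 0-based
indices, half-open crop intervals, all physical quantities in µm,
intensities on a nominal [0, 1] scale before noise.

## Synthetic primordium model

The generator is built for *exactness of ground truth*, not photorealism.
One primordium is an ellipsoidal epithelial plate:

* **Tissue ellipsoid.** Semi-axes derive from the cell count `n_cells`, the
  cell diameter `d` (default 7 µm) and the footprint elongation `E`
  (default 2.5): the ellipsoid volume is `n_cells × 0.95·d³` (mean cell
  volume ≈ 330 µm³, the epithelial range), with `rx = E·ry` and
  `rz = 0.8·ry` (the tissue is a flattened plate).  At the defaults this
  gives a ~90 × 32 × 25 µm tissue, i.e. a stack of roughly 30 × 90 × 220
  voxels at the default (1.0, 0.4, 0.4) µm confocal-like spacing.
* **Cell packing.** Centres are rejection-sampled inside 0.95× the
  ellipsoid with a minimum spacing of `0.8·d`; a bounded number of attempts
  guards against infeasible requests.  Rosette member cells are placed on
  rings (8 cells, radius 5 µm by default) around rosette centres staggered
  along the trailing half of the long axis.  The ellipsoid interior is then
  partitioned by **nearest-centre assignment in physical coordinates**, so
  per-cell volumes are exact by construction and sum to the labelled volume.
* **Membrane channel.** Voxels whose 6-neighbourhood crosses a label
  boundary are marked: weight 1 between cells, weight 2 on the outer tissue
  surface (the membrane label outlines the tissue surface most brightly in
  real stacks; without the brighter shell, the exterior watershed minimum
  floods into shell cells).  At each rosette centre a small apical focus of
  the same weight-2 intensity is added — the apical constriction where the
  ring cells' membranes converge, which is the salient rosette feature in
  membrane-labelled tissue.  The indicator is blurred with an
  anisotropy-corrected Gaussian of σ = `membrane_width/2` per axis and
  normalized to max 1.
* **Nuclei / EdU channels.** Gaussian blobs at cell centres; the EdU
  channel marks a random cell subset of the requested fraction and records
  it in the truth.
* **Noise.** Poisson at `photon_scale` (default 200 detected photons at
  intensity 1) followed by additive Gaussian `noise_sd` (default 0.02).
  `noise_sd = 0` together with `photon_scale = inf` is exactly noise-free,
  so the oracle examples hold to machine precision.

What the generator deliberately does **not** emulate: point-spread-function
anisotropy and diffraction, depth-dependent attenuation, migration dynamics
and deposition over time, irregular cell shapes (cells are convex
nearest-centre polytopes), and intensity heterogeneity along a single
membrane.  Passing tests therefore demonstrate that the measurement chain
is unbiased on geometrically clean tissue with realistic counts, sizes,
anisotropy and noise — not that it is robust to every optical artefact of
real confocal data.

### Genotype presets

Each preset scales the wild-type mean count of 120 cells
(`count_multiplier`), the Tead-reporter intensity (`reporter_multiplier`),
the per-embryo probability of the migration failure ("diving") phenotype,
and the EdU-positive fraction.  The multipliers carry the published cohort
effects: *yap1* 0.80, *vgll4b* 1.35, *vgll4b;vgll4l* 1.50 (1.14 at 19 hpf),
*vgll4b* overexpression 0.80, *yap1* overexpression in the double mutant
1.25 × 1.50, triple mutant 0.90; diving probabilities 0.0129 (WT), 0.16
(*yap1*), 0.68 / 0.25 (*yap1* + *vgll4b*/*vgll4l* mRNA); reporter
multipliers 1.70, 0.88, 1.27.  The cohort coefficient of variation of the
cell count is **not** a published number (dispersion appears only
graphically in the source plots); the default `count_cv = 0.08` was chosen
once as a realistic cohort CV that keeps n = 20/arm percent effects inside
±5 points.  Cell-count draws are rounded normals, resampled (bounded) if
non-positive.

## Registration

`project_and_mask` reproduces the projection-based pre-processing: maximum
Z-projection → Gaussian blur (default σ = 2 µm) → automatic threshold →
largest connected component.  The threshold is the classic bimodal
"Minimum" method: the 256-bin histogram is smoothed with a running mean of
three until exactly two local maxima remain (bounded at 10⁴ iterations),
and the threshold is the minimum between them.  A histogram that never
becomes bimodal raises an explicit error rather than guessing.

`fit_ellipse` uses second central moments of the foreground pixel
coordinates in physical units, with the +1/12-pixel² variance correction
for pixel extent; axis length = 4·√eigenvalue (the standard moment-ellipse
convention) and the angle of the principal eigenvector is folded to
(−90°, 90°], in image coordinates (y down).

`register_stack` rotates every slice in-plane by the fitted angle (linear
interpolation for intensities; ground-truth labels can be moved with the
same transform at nearest-neighbour order), crops Y/X to the rotated mask's
bounding box plus a 5 µm margin, and crops Z to the contiguous slice range
whose in-mask mean exceeds the out-of-mask background mean + 2 SD (padded
by one slice).  Thresholding happens before rotation; in-plane rotation
requires dy = dx (true for all supported acquisitions).  Round-trip
accuracy: re-fit angle 0° ± 2° on synthetic tissue at 35° orientation,
idempotent to ≤ 0.5°.

## 3D segmentation

The blurred membrane image (default σ = 0.75 µm, anisotropy-corrected per
axis) is treated as a topographic relief.  Regional minima shallower than
`h_depth` (default 0.05 on the [0, 1] scale) are suppressed (h-minima); the
surviving minima seed a marker-controlled watershed (scikit-image, region
growing — no zero-width watershed lines in the output).  Any region
touching the lateral (y/x) stack border is background.  The blur default of
0.75 µm matters: at σ = 1 µm the interiors of tightly packed cells fill in
and ~4 % of cells merge below the h = 0.05 depth; at 0.75 µm recovery on
default-noise synthetic tissue is exact (120/120 over multiple seeds)
while noise minima remain suppressed.

Per-label measurements are physical: volume = voxel count × dz·dy·dx;
surface area by **weighted exposed-face counting** (faces to a different
label or background, weighted dy·dx / dz·dx / dz·dy) — exact on rectilinear
oracles (a 10³ voxel cube at unit spacing reads 1000 µm³ / 600 µm²) and
biased high against smooth surfaces by up to ~1.5×, which is acceptable for
an outlier feature but should not be read as absolute membrane area.

Volume gates default to [30, 3000] µm³ (the source tool's thresholds are
not published; these bracket the ~330 µm³ cell scale by an order of
magnitude each way).  Blank Z-slices at either stack end are trimmed and
the trim recorded so aligned intensity stacks can be cropped identically.

Outlier fences: cells are flagged when volume or surface/volume ratio falls
outside median ± 3.5 × scaled MAD (1.4826·MAD); a degenerate zero MAD falls
back to Tukey 1.5·IQR fences, and a zero IQR skips the feature
(homogeneous cells → no removals).  Volume flags take precedence when both
features trip.  With fewer than 4 kept cells the step is a no-op.  On clean
synthetic cohorts the fence removes the natural high-sv tail of shell
cells (~2 % of cells), the dominant component of the pipeline's small
negative count bias (−0.5…−1 % per embryo).

**Oracle equivalence.** With one seed per true cell, the watershed
reproduces the ground-truth partition with mean per-cell Jaccard ≈ 0.99
(minimum > 0.96) on *cytoplasm* voxels.  The rendered membrane band itself
is excluded from the comparison: the physical membrane is shared by both
neighbours, so the generator's nearest-centre assignment of band voxels is
an arbitrary convention, and at the default anisotropic voxel size the
2-voxel band holds ~25 % of a 7 µm cell's voxels — flood-order tie-breaking
inside it caps the full-voxel Jaccard near 0.84 for any watershed,
including truth-seeded ones.

## Rosette detection and rosettiness

The published detector is a trained CNN whose weights are unavailable; the
replacement is a transparent geometric detector that preserves the
downstream statistic exactly.  The detector runs on a **mid-tissue optical
section** (central z-slice of the membrane channel): a maximum projection
through ~30 µm of membranes saturates and erases the rosette pattern.  The
template is **radially symmetric** — a bright apical hub (radius 1.5 µm)
surrounded by the dark interiors of the ring cells (annulus to half the
expected radius) — because normalized cross-correlation is
contrast-invariant and spoke patterns alone cannot separate rosettes from
ordinary 3-cell junctions; radial symmetry also removes any template-phase
search.  Detections are in-mask local maxima of the correlation above the
floor (default 0.8 on this template's score scale; measured margins on
synthetic tissue: 0.87–0.93 at true rosettes vs ≤ 0.74 elsewhere over ten
seeds), restricted to the mask eroded by ¾ of the expected radius (the
bright tissue shell is excluded; rosettes are interior structures), with
non-maximum suppression at 1.5× the radius.  Scores are clipped to [0, 1].

`rosettiness` = Σ detection scores / number of detections, and is
**undefined** (`None`), not zero, for an empty detection list.  It accepts
bare score lists, so scores from any external detector (including a CNN)
plug in unchanged.

## Intensity readouts

* `mean_gray`: whole-image mode is the mean of the average-intensity
  Z-projection (identical to the full-stack mean, asserted in tests);
  single-plane mode averages an ROI on one plane (default: central plane).
* Positive cells: "significantly higher fluorescence than surrounding
  tissue" is operationalized as cell mean > background mean + k·SD with
  k = 2 by default and a per-image background (the unlabelled region unless
  an explicit disjoint ROI is given).  The rule is invariant under global
  gain and monotone in k.
* Line profiles: 100 stations along the segment, each averaged over a
  3-pixel perpendicular band, positions expressed as relative distance in
  [0, 1], every channel normalized to its own maximum along the profile.
  The midpoint statistic interpolates each normalized channel at 0.5 and
  returns the target/reference ratio (undefined if the reference is 0).
* EdU: the same positivity rule on the EdU channel; the proliferative
  fraction is positives/total, undefined for zero cells.

## Statistics

* **ΔΔCt**: technical replicates are averaged per (gene, sample) *before*
  anything else (unbalanced well counts then cannot weight samples
  unequally); ΔCt = Ct(target) − Ct(reference) per sample; ΔΔCt is the
  group-mean difference against the control group; fold = 2^(−ΔΔCt).
  Invariant under any global Ct shift.  A sample missing the reference gene
  is an error that names the sample.
* **Mann–Whitney U** (the primary two-sample test; every comparison in the
  source figures uses it): U from midranks; exact two-tailed p by the
  standard count recurrence when the samples are untied and
  C(n_x+n_y, n_x) ≤ 10⁶, otherwise a normal approximation with
  tie-corrected variance and a 0.5 continuity correction.  Two-tailed
  p = min(1, 2·one-tail).  All-identical samples give p = 1.  The exact
  path is verified against an independent enumeration oracle for all
  n ≤ 6, and the approximation's type-I rate at α = 0.05 is calibrated to
  0.05 ± 0.01 over 10⁴ null simulations of rounded-normal cohorts at
  n = 20/arm.  A Welch t-test is provided as a sensitivity check
  (`welch_t`), not as the default.
* Significance labels: ns / * / ** / *** / **** at p > 0.05 and
  p ≤ 0.05, 0.01, 0.001, 0.0001, boundaries inclusive, most extreme
  bracket wins.
* Group summaries report n, mean, SD (n−1), SEM = SD/√n, with the
  dispersion mode (SD or SEM) recorded for plotting; n = 1 groups carry
  NaN dispersion.
* Diving-phenotype proportions use the Wilson score interval
  (statsmodels).

## Pipeline and reproducibility

`RunConfig` carries every stage parameter plus the seed, round-trips
through YAML exactly, and hashes to a run identifier; every output
directory receives the config copy and a JSON run log (seed, per-embryo
timings, failures).  Randomness flows exclusively through
`numpy.random.default_rng(seed)` / `SeedSequence` spawning, so identical
(config, seed) reproduce byte-identical cohort CSVs.  Per-embryo failures
are recorded and skipped; the CLI exits non-zero if any embryo failed.
Embryo identity is the generated name (or file stem); genotype travels in
the cohort table, never parsed from filenames.

## Problem sizes

The default test suite validates each recovery at reduced cohort sizes
(zero-variance arms of 4–6 embryos) so the whole suite runs in under two
minutes; `scripts/acceptance.py` runs the full desk-scale configuration —
seven cohorts of 20 embryos at default noise and count CV, with all arms
paired on one cohort seed (common random numbers, the same pairing used
for the reporter comparisons) so that arm contrasts estimate the preset
effect rather than draw noise; 10 paired reporter images per comparison;
50 simulated qPCR plates — in a few minutes on one CPU.

## Known limitations

* The surface-area estimator is voxel-faceted (high bias vs smooth
  surfaces); use it comparatively, not absolutely.
* The rosette detector's floor and template are calibrated to this
  generator's geometry; real micrographs will need a recalibrated floor or
  externally supplied scores (the rosettiness statistic is agnostic).
* The diving phenotype is a per-embryo annotation (or generator truth); no
  trajectory classifier is implemented.
* Rotation is strictly in-plane; stacks acquired with a tilted optical
  axis are out of scope, as are time-lapse registration and tracking.
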