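# pllpquant

Quantitative imaging and statistics for the zebrafish **posterior lateral
line primordium** (pLLP) — the migrating cluster of ~120 epithelial cells
that deposits the neuromasts of the lateral line.  The package reimplements,
as a tested and reusable Python pipeline, the measurement chain used to
compare pLLP size and composition across genotypes:

* **registration** — locate the primordium on a maximum Z-projection
  (Gaussian blur + bimodal-histogram "Minimum" auto-threshold), fit its
  second-moment ellipse, rotate the long axis horizontal, crop in X/Y/Z;
* **segmentation3d** — 3D single-cell segmentation of the membrane channel
  (anisotropy-corrected Gaussian blur → h-minima → marker-controlled
  watershed), physical per-cell measurements (volume, exposed-face surface
  area, centroids, channel means), volume gates, and robust
  median ± k·MAD outlier fences on volume and surface/volume ratio;
* **morphometrics** — cell count and total volume per embryo, ImageJ-style
  shape descriptors (AR, circularity, roundness, solidity), a geometric
  rosette detector with the *rosettiness* score (Σ detection scores /
  number of detections), neuromast-deposition patterns normalized to the
  ganglion, and stained-area measurement for in-situ images;
* **intensity** — mean gray values (whole-image average projection or
  single-plane ROI), reporter-positive cell counts (background mean + k·SD
  rule), band-averaged line profiles with the normalized midpoint ratio,
  and EdU-positive proliferation fractions;
* **stats** — ΔΔCt relative qPCR quantification
  (fold = 2^(−ΔΔCt), reference gene *rpl13*), two-tailed Mann–Whitney U
  (exact by enumeration for small untied samples, tie-corrected normal
  approximation otherwise), percent-change effect sizes, star significance
  labels, mean ± SD/SEM group summaries, and Wilson intervals for the
  migration ("diving") phenotype proportions;
* **synthetic** — a generator of membrane-labelled primordium stacks,
  reporter images, trunk overviews and qPCR plates with *exact* ground
  truth and genotype presets carrying the published effect sizes, so every
  stage of the pipeline can be validated without microscope data.

All imaging operations are anisotropy-aware: axis order is (z, y, x) and
every physical quantity is in micrometres.

## Worked example

Simulate a small wild-type vs *yap1* mutant cohort and push it through the
full pipeline (registration → watershed segmentation → volume filter →
outlier fences → per-embryo summary → Mann–Whitney):

```python
from pllpquant import RunConfig, run_pipeline

cfg = RunConfig(presets=[("wt", 5), ("yap1", 5)], seed=42,
                base_params={"orientation_deg": 20.0})
res = run_pipeline(cfg)
print(res["cohort"][["embryo", "genotype", "cell_count",
                     "aspect_ratio", "rosettiness"]].round(3))
print(res["stats"][["group", "mean_ref", "mean", "effect_percent",
                    "U", "p_two_tailed", "label"]].round(4))
```

which prints

```
  embryo genotype  cell_count  aspect_ratio  rosettiness
  wt_000       wt         123         2.531        0.929
  wt_001       wt         127         2.529        0.936
  wt_002       wt         100         2.551        0.944
  wt_003       wt         119         2.522        0.938
  wt_004       wt         120         2.518        0.927
yap1_000     yap1         101         2.530        0.926
...
group  mean_ref  mean  effect_percent    U  p_two_tailed label
 yap1     117.8  99.4        -15.6197 23.0        0.0345     *
```

The wild-type arm recovers ≈ 120 cells per embryo with the 2.5:1 footprint
the generator draws; the *yap1* preset (count multiplier 0.8) reads out as a
−16 % effect at n = 5/arm (−20 % is the injected effect; at this cohort
size the draw noise is still visible), significant by the two-tailed
Mann–Whitney test.  `rosettiness` near 0.93 reflects the two clean apical
rosettes the wild-type geometry contains.

The same stages are available from the shell:

```bash
pllpquant simulate --preset wt --n 5 --seed 1 --out-dir sim/
pllpquant register sim/wt_000.ome.tif --out reg.ome.tif
pllpquant segment reg.ome.tif --out-prefix wt_000
pllpquant run-all --preset wt:5 --preset vgll4b_vgll4l:5 --seed 1 --out-dir run/
pllpquant qpcr plate.csv --target-gene yap1 --control-group control
```

## Layout

```
src/pllpquant/
  types.py          shared containers (VoxelStack, LabelVolume, CellTable, ...)
  synthetic.py      ground-truth generator + genotype presets
  registration.py   projection mask, moment ellipse, rotate-and-crop
  segmentation.py   h-minima watershed, measurement, outlier fences
  morphometrics.py  shape descriptors, rosettes, deposition, stained area
  intensity.py      mean gray, positive cells, profiles, EdU
  stats.py          ΔΔCt, Mann–Whitney, effect sizes, summaries
  pipeline.py       RunConfig + end-to-end orchestration
  cli.py            pllpquant console script
  io.py             OME-TIFF / CSV / YAML / JSON I/O
docs/methods.md     model and parameter documentation
tests/              pytest suite (generated fixtures only)
```
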