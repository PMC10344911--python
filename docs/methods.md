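# Methods

`gliamorph` quantifies the morphology of cultured microglia from binary
silhouettes: the filled mask of one cell is reduced to sixteen parameters
spanning four classes — plain geometry, convex-hull shape, density and
roughness, and box-counting fractal statistics — and cohorts of cells
labelled by treatment are compared with nonparametric rank tests. This
note records the conventions, the defaults and why they were chosen, and
what the synthetic validation does and does not establish.

## Silhouette extraction

A two-channel micrograph (nuclear stain + cytoplasmic membrane marker) is
split into 8-bit grayscale channels (linear rescale from the source bit
depth), each channel is thresholded separately (Otsu by default — the
method is configurable and the applied threshold is logged), and the two
binary silhouettes are merged. The merge exists because cytoplasmic
markers are typically dim over the nucleus: thresholding the cytoplasm
channel alone leaves a perinuclear hole, which the nuclear silhouette
fills. A nuclear component is merged only when it overlaps the
hole-filled cytoplasm mask; isolated nuclear debris (free nuclei without
a cell body) is dropped.

Cleaning then fills interior holes, optionally separates touching cells
by watershed on the Euclidean distance transform (seeds = local maxima at
least `watershed_min_distance` = 10 px apart), removes particles below
`min_object_area` (default 200 px² — cultures differ, so this is a config
value, not a biological constant), and discards components touching the
image border (cells cut by the field of view would bias every size
measure downward). Each retained cell is centred in a square crop
(default 400 px) whose origin is recorded, so measurements can be mapped
back to the source field.

## Geometric parameters

* **area** — foreground pixel count × (μm/px)².
* **perimeter** — length of the sub-pixel boundary polygon traced at the
  0.5 iso-level (marching squares), with a staircase correction: along a
  straight digital edge at angle θ to the grid, the 0.5-level polygon is
  longer than the true edge by exactly cos θ + (√2−1)·sin θ (up to +8.2 %
  at 22.5°). Each contour segment is divided by that factor, with θ taken
  from the chord over ±3 contour vertices — but only where all window
  vertices stay within 0.8 px of the chord, the signature of a
  digitisation staircase. Genuine corners deviate far from their chord
  and keep their full length. On reference rasters this estimator is
  within 0.5 % for disks of radius 20–100 px, within 2 % for squares,
  plus-polyominoes and rotated ellipses. The residual scale-dependence of
  any such estimator is that block-upsampling a mask turns 1-px staircase
  artefacts into genuine 2-px geometry; perimeter then grows by ~10 %,
  which is a property of the mask, not a bug of the estimator.
* **circularity** = 4π·area/perimeter² (1 for a circle) and
  **transformation index** = its exact reciprocal, the classic
  ramification measure: both are reported because the source field uses
  both, and their product is unity to float precision by construction.

## Convex-hull parameters

The hull is built over the **outer corners** of the foreground pixels, so
the hull polygon contains the pixels' full area. This keeps the
invariants density = area/hull_area ≤ 1 and roughness =
perimeter/hull_perimeter ≥ 1 (up to perimeter discretisation, ~2 % for
small convex shapes) true by construction; a pixel-centre hull (available
as `points="centers"`) is smaller than the pixel area and breaks both.
From the hull polygon: area (shoelace), perimeter (edge sum), hull
circularity (4πA/P²), mean radius and max/min radii measured from the
polygon's **area centroid to its vertices** (vertices are the only
canonical "exterior points" of a polygon), maximum span (diameter over
vertex pairs), minimal bounding circle diameter (smallest enclosing
circle of the vertices), and span ratio = maximum span / minimal caliper
width (major/minor axis reading; an eigen-axis alternative would give
slightly different values and is intentionally not mixed in).

Degenerate masks (fewer than three non-collinear points under the chosen
point set) raise rather than return NaN.

## Box-counting parameters

Box sizes follow a power series with base 2 (2, 4, 8, … px) up to 45 % of
the larger side of the pattern's bounding box; for very small cells the
cap yields to a three-size minimum (a two-point log–log fit is not a
regression). Grids are anchored at the bounding box — never the crop —
so padding cannot change any count; besides the corner-anchored grid,
four seeded random grid origins are used.

* **Fractal dimension (Db)** is measured on the one-pixel outline
  (foreground pixels with a background 4-neighbour). The covering number
  N(ε) is taken as the *minimum* occupied-box count over the grid
  placements — the definition of box-counting dimension is via the
  minimal cover, and any single fixed grid overcounts for patterns not
  aligned with it (averaging per-grid slopes instead biases a
  depth-7 Sierpiński triangle from 1.585 down to ~1.50). Db is the
  least-squares slope of log N(ε) vs log(1/ε), with r² reported so poor
  fits can be filtered. Reference values: straight line 1.000, digital
  circle outline 0.967, Sierpiński depth 7 1.585 (theory log 3/log 2).
* **Lacunarity** is measured on the filled silhouette: for each box size
  and grid placement, boxes tile the foreground bounding box, each box's
  mass is its foreground fill fraction (clipped boxes are normalised by
  their clipped area), and λ = (σ/μ)² over all boxes including empty ones
  inside the bounding box. The reported lacunarity is the mean of λ over
  sizes and placements. Fill-fraction normalisation makes a solid block
  score exactly 0 under any grid offset, and bounding-box tiling makes
  the statistic independent of crop padding; background far from the
  cell carries no information about its gappiness.

## Group statistics

Per feature: Kruskal–Wallis omnibus H (tie-corrected, χ² p with k−1 df;
all-identical input returns H=0, p=1), then pairwise two-sided
Mann–Whitney U tests by normal approximation with mid-ranks,
tie-corrected variance and a 0.5 continuity correction toward the mean
(U reported as min(U₁, U₂)). The approximation is intended for both
groups above ~20 cells; smaller samples warn. Bonferroni adjustment uses
the number of pairs actually tested per feature (15 for six groups
all-vs-all) unless a family size is given. Summaries are mean ± SEM
(sd/√n, n−1 denominator; SEM of a singleton is reported missing).

Significance classes: `***` p < 0.005, `**` p < 0.01, `*` p < 0.05
(three-level default); a `two-level` rendering collapses `*` and `**`
into `**` (p < 0.05) for summary tables that use only two classes. The
shift report classifies each feature's treated-vs-reference change as
Up/Down by the sign of the mean difference, starred by the
Bonferroni-adjusted pairwise p.

Calibration of the omnibus test is checked empirically: over 1000 seeded
null replicates (six groups, n=30 each), the rejection rate at α=0.05
must land in 4–6 %.

## Synthetic data

The generator provides two tiers. *Reference shapes* (disk, square,
segment, plus-polyomino, Sierpiński triangle, spiky star) have
closed-form feature values and anchor the estimator tests. *Phenotype
silhouettes* compose a soma (radial-harmonic blob), tapered random-walk
processes grown from the soma rim (one optional secondary branch with
probability 0.3 — week-old cultures are only slightly ramified, deep
trees are unnecessary), and short filopodia-like spikes. Presets:

| preset | soma r (μm) | harmonics | processes | filopodia | emulates |
|---|---|---|---|---|---|
| ameboid | 9 ± 1.2 | 3 × 0.04 | 0 | 0 | round activated cells |
| slightly ramified | 8 ± 1.0 | 2 × 0.03 | ~2 × 7 μm | 1 | control cultures |
| hypertrophied | 11.5 ± 1.2 | 8 × 0.16 | ~0.5 | 12 × 6 μm | swollen treated cells |
| ramified | 5 ± 0.6 | 3 × 0.06 | ~5 × 25 μm | 2 | surveillant cells |

Cohort generation derives per-cell seeds as master + cell index, so every
cohort is a pure function of its seed. The six-arm study design assigns
these presets (with small per-arm modifications) to the treatment groups
at the study's cell counts (148/131/107/215/164/209; 974 in total). The
two-group design (control vs hypertrophied at ~1.4× soma radius) shifts
area, perimeter, transformation index, hull area/perimeter, roughness
and fractal dimension up and circularity and density down *by
construction*; the treated boundary complexity is set high enough that
the subtlest contrast (fractal dimension, within-group SD ~0.05) is
reliably detectable at 25 cells per group. The cost of that margin is a
treated transformation index (~5) somewhat above the range typical of
real cultures (~1.3–3.5); the control arm (TI ≈ 2.0, Db ≈ 1.08) sits
inside it.

Rendering back to two-channel pseudo-micrographs places a bright nuclear
disk at the deepest interior point of the cell and dims the cytoplasm
channel over it, reproducing the perinuclear-hole situation the merge
step exists for; Gaussian blur and additive noise are configurable. At
zero noise the extract pipeline recovers the ground-truth mask exactly
(IoU = 1), which validates the plumbing, not the segmentation: real
micrographs add uneven illumination, out-of-focus light, touching cells
and debris that the generator deliberately does not model (no PSF or
shot-noise calibration, no 3-D structure). Passing the synthetic suites
therefore establishes correctness of the measurements and statistics,
not segmentation performance on real data.

## Problem sizes and runtime

Validation runs at desk scale: direction recovery uses 100 independent
cohorts of 2×25 cells (0.5 μm/px, 256-px crops), the study-scale check
measures one 974-cell cohort, and the type-I calibration uses 1000 null
replicates. The full test suite runs in about two minutes on one core;
`scripts/acceptance.py` in about twenty seconds.

## Known limitations

* Absolute μm/μm² values depend entirely on the user-supplied pixel
  calibration (default 1 μm/px); dimensionless features are
  calibration-invariant to float precision.
* Perimeter-derived features are estimator-convention-bound at the ±2 %
  level on smooth shapes and are not invariant under block upsampling of
  masks (see above).
* The watershed split is automatic; heavily overlapping cells that a
  human would separate by hand may remain merged or be over-split —
  per-label exclusion lists are the supported remedy, not interactive
  editing.
* Lacunarity here is the grid-based CV² aggregate; sliding-box and
  rotational variants would give different absolute values.
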