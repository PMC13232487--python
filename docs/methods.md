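# Methods

## Quantification model

The pipeline treats one micrograph ("field") as the unit of measurement
and the animal as the biological replicate. Per field it produces a cell
table (area, centroid, border contact, artifact flags, stained-membrane
fraction, CLS call), a %CLS value and a size distribution; per animal it
averages fields; per group it reports mean ± SEM across animals and
compares groups by one-way ANOVA with Tukey's HSD.

### Segmentation

Grayscale conversion uses fixed ITU-R 601 weights (0.299, 0.587, 0.114);
the protocol this automates specifies only "grayscale", so the weights are
a stated convention, not a tuned choice. Binarization defaults to Otsu's
threshold; a fixed level can be supplied for exact reproducibility. The
adipocyte content (lipid lumen) is taken as the bright phase of a
brightfield section and membranes as the dark phase, so foreground is
`gray > threshold`. Components are 8-connected. Holes inside lumina
smaller than a quarter of the minimum cell area are filled before
labeling so intracellular speckle cannot fragment a cell, while genuine
membrane rings are never absorbed.

Manual artifact correction is replaced by two explicit rules, both
surfaced in the configuration and echoed in every output: an area band
(default 200–16,000 µm²; below it lie speckle and membrane fragments,
above it merged cells and tears) and exclusion of border-touching
components (default on). Cells are flagged, never deleted, so every
decision is auditable in `cells.csv`.

### CLS detection

Stain calling operates on the raw 8-bit channels with no white-balance or
deconvolution: stained ⇔ `R/B > 1.05`, strict. The comparison is computed
multiplicatively (`R > 1.05·B`), which also defines the degenerate blue=0
cases: pure red is stained, pure black is not.

"The area surrounding the membrane" is realized as the symmetric
morphological annulus `dilate(cell, disk(w)) \ erode(cell, disk(w))` with
`w = ring_width = 3` px by default; the width is configurable because the
original geometry is unstated. Ring pixels falling inside a neighboring
cell are retained — stain lying between two adjacent cells counts toward
both, the simplest faithful reading. A cell is a CLS iff the stained
fraction of its annulus strictly exceeds 0.30. Both boundaries are
covered by explicit boundary tests (ratio exactly 1.05 → unstained;
fraction exactly 0.30 → not CLS).

Per-field %CLS is computed as percent of filter-passing *cells* that are
CLS (not percent of fields containing one), so the CLS population matches
the morphometry population; a field with zero passing cells raises rather
than reporting 0 %. The alternative per-field-presence reading (percent of an
animal's fields containing at least one CLS) is reported alongside, as
`pct_fields_with_cls` in the per-animal table, without endorsement.

### Statistics

Aggregation order is fixed: field values are averaged within animal, then
group mean ± SEM (sd/√n, ddof = 1) is taken across animals. The 10-field
per-animal minimum of the acquisition protocol is enforced at aggregation
time (warning by default, hard failure with `strict_min_fields`). Group
comparison is textbook fixed-effects one-way ANOVA plus Tukey's HSD on
the studentized-range distribution (scipy implementations), flagged at
p < 0.05; the degenerate all-equal case is defined as F = 0, p = 1
rather than NaN. The two-group limit satisfies F = t² and the p-value is
cross-checked in the tests against an independent 10⁴-shuffle permutation
test.

## Synthetic-histology generator

The generator emulates the image class the detector assumes: circular
bright lumina (normal radii, truncated below), dark membrane annuli, a
bluish counterstain background, and reddish stain arcs around a
controllable fraction of cells. It does **not** emulate realistic tissue
texture, touching/merged adipocytes, stain bleed-through, chromatic
aberration or uneven illumination (an optional linear gradient exists but
defaults to flat). Passing tests therefore demonstrate correctness of the
*rules* — thresholds, geometry, aggregation, determinism — not robustness
to real-slide variability; on real data the Otsu threshold and artifact
band would need visual sanity checks.

Defaults (one 256 × 256 field at 1 µm/px): 12 cells, lumen radii
18 ± 4 µm truncated at 10 µm (mean planted area ≈ 1,000 µm², a lean-mouse
scale that sits comfortably inside the 200–16,000 µm² filter band),
membrane width 4 px, gray levels 210/60/180 (lumen/membrane/background)
with per-region Gaussian noise sd 2, counterstain R/B 0.85, stain R/B
1.20.

Channel values are solved in float from a target gray level `g` and
ratio `q` as `B = g/(0.299 q + 0.701)`, `R = qB`, `G = B`, so the 601
gray equals `g` and `R/B` equals `q` exactly before quantization. The
ratio pair (0.85, 1.20) keeps blue ≥ 50 everywhere and red un-clipped at
lumen brightness, so 8-bit rounding perturbs a ratio by at most
1/50 = 0.02 and can never carry a pixel across the 1.05 boundary.

Crowned cells receive an angular stain arc: membrane pixels are ranked by
angle from a seeded random start and exactly `round(f · n)` are stained,
so the planted fraction is exact to one pixel-arc. The stained band
extends 4 px into the lumen as well as across the membrane; this matters
because the detector's annulus is symmetric about the lumen boundary — a
membrane-only arc would cover only the outer half of the annulus and
halve every measured fraction. With the default geometry the measured
fraction tracks the planted one to well under 0.02 on noise-free fields.

Placement is dart throwing with pairwise clearance of two membrane widths
plus 2 px (so neighboring stain bands can never contaminate each other's
rings) and up to 30 restarts; an infeasible request fails loudly, naming
the achieved count. By default lumina are placed fully interior so planted
truth and filter-passing populations coincide; `allow_border_cells=True`
generates clipped cells for testing the border-exclusion rule. Cohort
seeds derive from a master seed via `SeedSequence([master, group, animal,
field])`, making whole cohorts reproducible bit-for-bit.

## Numerical and design choices

* Strict inequalities at both classifier boundaries, tested explicitly.
* Half-open histogram bins `[lo, hi)` (default 500 µm² width up to
  16,000 µm²); a value equal to the last edge is excluded.
* SEM of a single value is undefined and reported as null, never 0.
* %CLS of a field with no passing cells is an error, not 0.
* Tie-break in the stained-arc construction: the angular cutoff is the
  midpoint between the k-th and (k+1)-th membrane pixel angles.
* All tables are written with pandas' default float formatting, which is
  deterministic: identical config + seed ⇒ byte-identical CSVs.

## Problem sizes

The validation suite exercises cohorts of 2 groups × 3 animals × 10
fields (the per-protocol minimum design) at 256 × 256 px per field with
12 cells per field; this keeps the full test run around a minute while
every contract (exact truth recovery at zero noise, 100 % CLS accuracy at
noise sd 2 with planted fractions outside [0.25, 0.35], 5 % area
tolerance) is checked at full cohort structure. Larger fields and cell
counts only change packing density limits, which fail loudly.

## Known limitations

* No watershed splitting: adipocytes merged by a broken membrane segment
  as one component and are typically caught by the upper area filter, not
  recovered.
* The stain call is a per-pixel channel ratio; it will misbehave on
  images with strong color casts — no stain normalization is attempted.
* Tukey's HSD assumes balanced-ish group sizes and homoscedasticity; with
  n = 3 animals per group the test is valid but underpowered, as in the
  underlying experimental design.
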