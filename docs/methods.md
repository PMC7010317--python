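# Methods

`blebquant` quantifies two single-cell phenotypes from 3-channel
fluorescence micrographs of cultured fibroblasts — membrane blebbing and
focal-adhesion (FA) abundance — and runs the group-level statistics on those
readouts. Because suitable annotated micrographs are rarely shareable, the
package ships a seeded synthetic-scene generator with complete ground truth;
every stage is validated against it.

## Image model and segmentation

A field of view is a `ChannelStack`: co-registered 2-D images of a whole-cell
counterstain (cytoplasm channel), a DNA stain (nuclei channel), and an
adhesion marker such as vinculin or FAK (adhesion channel).

**Background threshold (cell bodies).** The cytoplasm channel is smoothed
with a Gaussian (`smooth_sigma`, default 2 px) and thresholded at
`threshold_factor` × the mean intensity of the dimmest `dim_fraction`
(default 20%) of pixels, which are taken to be background. The factor
(default 2.0) maps the background level to a threshold; it is configurable
because the mapping is a free choice of the operator. Selection of the
dimmest pixels uses a stable sort, so ties cannot reorder results.

**Nuclei and FAs: phase stretch transform (PST).** Both punctate targets are
segmented with the PST operator: the image spectrum is localized with a
Gaussian low-pass of width `lpf_sigma` (cycles/px) and multiplied by
`exp(-j·φ(r))`, where the radially symmetric warped-phase kernel is

    φ(r) ∝ W·r·arctan(W·r) − ½·ln(1 + (W·r)²),

normalized so max φ = `phase_strength`. The angle of the inverse transform
concentrates at intensity transitions: for a bright object it is negative
just inside the edge and positive just outside. Segmentation thresholds the
negative (interior-side) tail at a phase quantile — the phase of a positive
image is invariant under intensity scaling, so quantile thresholds transfer
across exposure settings — then applies morphological cleanup
(close → fill holes → open for nuclei; close → fill for FAs), labels
components with 8-connectivity, and drops components below
`min_region_area`. Two presets are shipped (`nuclei`: lpf_sigma 0.05,
min area 200 px; `fa`: lpf_sigma 0.25, min area 10 px). The preset values
were tuned on the synthetic fixtures: at a signal-to-noise ratio of 10 the
nuclei preset recovers disks with IoU ≥ 0.9, and the FA preset resolves all
ground-truth puncta of the default scenes one-to-one.

**Under-segmentation resolution.** Any cytoplasm component containing two or
more nuclei (a nucleus counts as contained when more than half its area lies
in the component — majority rather than any-overlap, so a 1-px graze cannot
claim a nucleus) is re-thresholded at `reseg_factor` × the original
threshold (default 1.5). Each surviving sub-component seeds the nucleus it
overlaps most; if the higher threshold fails to seed every nucleus the
nucleus masks themselves become the seeds (logged). Seeds then grow by
synchronized breadth-first geodesic dilation restricted to the component:
each iteration every frontier claims the unvisited 8-neighbors it reaches;
pixels claimed by several frontiers in the same iteration go to the seed
with the nearer nucleus centroid, remaining ties to the lower label. The
synchronous schedule makes the partition deterministic and metric-like (the
interface of a symmetric two-lobe region falls at the narrowest cut).
Components with zero or (after splitting) multiple nuclei are removed, and
cells touching the image border are dropped by default (`border_policy`).

## Morphometry and the blebbing rule

The outer boundary of each cell mask is traced at the 0.5 iso-level
(marching squares, sub-pixel, counter-clockwise) and smoothed with a
circular Savitzky–Golay filter (window 9, polyorder 3). Curvature at each
boundary point is the unsigned reciprocal circumradius 1/r of the circle
through the point and its two neighbors `curvature_step` samples away
(r = abc/4A; collinear triples give 0). The per-cell readout is the mean of
these values.

Two numerical choices matter here:

- *Unsigned curvature.* The 1/r definition admits no sign, so concave
  junctions between blebs also raise the mean — consistent with the intent
  of flagging rough boundaries.
- *Triplet spacing.* Marching-squares contours of binary masks carry
  pixel-quantization jitter at ~0.7 px point spacing. With the window-9
  filter, a spacing of 2 samples still measures that jitter (a rasterized
  r = 50 px circle reads 0.055 px⁻¹ instead of 0.020). At the default
  spacing of 8 samples (~5 px chords) the circle reads 0.0200 px⁻¹ and
  bead-scale protrusions (radius ≥ ~5 px) still register; this is the
  smallest spacing that stabilizes the circle fixture to ±5% at window 9.

A cell is called **blebbing** when all three of the following hold
(strict inequalities, matching the rule's "larger than"/"<" phrasing):
mean curvature > 0.029 px⁻¹, nuclear/cytoplasmic adhesion-marker intensity
ratio < 1.15, and cell/nucleus area ratio < 4.5. The intensity ratio is a
ratio of *mean* intensities (nucleus mean ÷ cytoplasm mean, cytoplasm =
cell − nucleus); means rather than integrated intensities keep the ratio
meaningful between compartments of very different areas. Before
classification, outlier cells are removed: DAPI-positive area < 1,000 px or
cell area > 150,000 px (each exclusion annotated with its rule name).
Curvature is computed on the smoothed trace at its native spacing, without
re-sampling.

## Focal-adhesion quantification

FA candidates from the PST `fa` preset are filtered by: majority of the
component inside some cell; not majority inside a nucleus; area ≥ 30 px;
mean adhesion-channel intensity strictly greater than the mean over the
assigned cell's whole mask (components at or below the cell mean are
removed). Components straddling two cells are assigned to the larger-overlap
cell, ties to the lower label. The area and intensity filters are
independent predicates, so their order cannot change the result. Cells then
receive integer counts (zero, not missing, when no adhesion survives).

Dataset-level cutoffs guard against segmentation artifacts: cells strictly
above the pooled 99th-percentile count (linear-interpolation percentile,
computed once over all groups and recorded in the run manifest) are removed
as probable blow-ups, and cells with four or fewer adhesions are removed as
probable out-of-focus cells. The realized cutoff is frozen, so re-applying
it removes nothing further.

## Group statistics

- **Blebbing frequencies.** Group × {blebbing, non-blebbing} counts; every
  unordered pair of groups is compared with a two-sided Fisher's exact test
  using the point-probability ("minlike") two-sided rule — the table
  probabilities ≤ the observed one are summed at fixed margins — and the
  family of pairwise p-values is adjusted by Benjamini–Hochberg FDR. All
  pairwise comparisons enter one family; the family size is the number of
  pairs.
- **FA counts.** Counts are right-skewed, so comparisons run on
  log₁₀(count) (defined because the lower cutoff guarantees counts ≥ 5):
  two-way fixed-effects ANOVA with interaction across the 2×2 design,
  Tukey HSD across the four group means, plus a distribution-free
  alternative (all-pairs Mann–Whitney U with BH adjustment). A response
  with zero variance is reported as a `no_variance` outcome with p = 1
  rather than a division-by-zero failure.
- **Spreading-assay arithmetic.** One spreading data point aggregates
  `cells_per_field × fields_per_plate × plates_per_point` cells
  (8 × 3 × 3 = 72 under the standard design).

Implementation uses scipy (`fisher_exact`, `mannwhitneyu`) and statsmodels
(`ols`/`anova_lm`, `pairwise_tukeyhsd`, `multipletests`); the test suite
cross-checks them against independent oracles: exhaustive hypergeometric
enumeration via log-factorials, the hand-written BH step-up recursion, and a
10,000-draw permutation distribution of the main-effect F statistic.

## Synthetic scenes

The generator emulates the geometric and intensity structure the pipeline
assumes, with one `numpy.random.Generator` threading all draws (identical
parameters + seed ⇒ byte-identical scenes):

- **Cells.** Equal-area elliptical bases (aspect ≤ 1.25), radius ~
  N(55, 6²) px clipped to [42, 70]. Smooth cells add a mild low-frequency
  radial wobble (≤ 3% of radius, harmonics 2–4). Blebby cells superpose
  8–14 semicircular bead protrusions of radius 0.15 × cell radius — beads on
  an ellipse is a modeling choice; real bleb morphometry is not
  parameterized anywhere we could copy, so amplitude and count were chosen
  so that the shipped classifier cutoffs sit between the two classes with
  a clear margin (smooth cells read ≤ ~0.023 px⁻¹, blebby ≥ ~0.067 px⁻¹).
  Outlines are radial functions of angle, hence always simple polygons;
  masks are filled on a pixel grid with centers at integer coordinates (one
  convention everywhere).
- **Nuclei.** One disk per cell at 0.55 × cell radius (cell/nucleus area
  ratio ≈ 3.3, under the 4.5 cutoff).
- **Adhesion channel.** Diffuse cytoplasmic signal (300) over background
  (150), FA disks at 2000 with areas 60–150 px and pairwise edge separation
  ≥ 10 px, placed inside the cell and clear of the nucleus. The nuclear
  level is a scene parameter because the nuc/cyto contrast is an observed
  property of real stains, not a constructed one: smooth cells render a
  nucleus-dominant marker (800, ratio ≈ 1.5 > 1.15) and blebby cells a
  cytoplasm-dominant one (250, ratio ≈ 0.5 < 1.15), so the intensity
  criterion is exercised in both directions.
- **Noise.** Gaussian (SD 25 by default, ≈ 3% of the cytoplasm foreground)
  plus optional Poisson shot noise, applied last and clipped to [0, 65535].
- **Touching pairs.** Optionally, cell pairs are placed at 92% of the sum of
  their radii (overlap assigned to the nearer center) so plain thresholding
  merges them — the fixture for the under-segmentation resolver. All other
  cells keep ≥ 2 px mask separation by construction.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: optics (PSF blur, depth of field,
out-of-focus cells), photobleaching, uneven illumination, textured
cytoplasm, apoptotic morphologies, overlapping cells beyond designed pairs,
and real bleb geometry. Recovery numbers on these scenes are upper bounds
on real-data performance; the value of the synthetic path is that every
stage's contract is checkable exactly.

## Problem sizes and determinism

Validation runs use 20 scenes × 10 cells (200 cells) for classifier and
segmentation recovery, 10 scenes for FA counting, 5 two-cell fixtures for
touching-pair resolution, and 500 replicates for the Fisher null
calibration; `scripts/acceptance.py` derives all scene seeds from its
`--seed` argument. Reruns with the same configuration and seed produce
byte-identical outputs end to end.

## Known limitations

- PST preset values are tuned on synthetic fixtures only; real micrographs
  will need the documented per-target re-tuning (the quantile thresholds
  transfer across intensity scales, but not across optics).
- FA components closer than ~10 px can merge; counts are only guaranteed at
  the fixture separation.
- The raw marching-squares trace carries a staircase length bias (~6% on a
  disk); length- and curvature-type measurements are therefore defined on
  the smoothed trace.
- The rank-based FA comparison is pairwise Mann–Whitney + BH, not a joint
  multiple-contrast pseudo-rank procedure; with heavy ties or very unequal
  group sizes the two can differ.
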