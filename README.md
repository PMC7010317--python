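# blebquant

Automated single-cell quantification of **membrane blebbing** and
**focal-adhesion (FA) abundance** from 3-channel fluorescence micrographs
(whole-cell counterstain, DNA stain, adhesion marker such as vinculin or
FAK), plus the group-level statistics for those readouts. It is aimed at
high-content imaging experiments on cultured cells — e.g. fibroblasts whose
boundary roughens into bead-like protrusions under energy stress — where
phenotype frequencies must be compared across genotypes and treatments over
thousands of cells.

The pipeline:

1. **Segmentation** — nuclei and FA puncta via the phase stretch transform
   (PST): the image spectrum is passed through a warped phase kernel
   φ(r) ∝ W·r·arctan(W·r) − ½·ln(1+(W·r)²) and the phase of the inverse
   transform is thresholded at a quantile. Cell bodies via a background
   threshold (2 × mean of the dimmest 20% of pixels after smoothing);
   regions holding ≥ 2 nuclei are re-thresholded higher and split by
   synchronized region growing from nucleus-assigned seeds; regions with 0
   or multiple nuclei are discarded.
2. **Morphometry** — each cell boundary is traced sub-pixel, smoothed with
   a circular Savitzky–Golay filter, and assigned per-point curvatures
   κᵢ = 1/rᵢ (circumradius of the circle through Pᵢ and two neighbors). A
   cell is called *blebbing* when mean κ > 0.029 px⁻¹, nuclear/cytoplasmic
   adhesion-marker intensity ratio < 1.15, and cell/nucleus area ratio
   < 4.5; outliers (nucleus < 1,000 px, cell > 150,000 px) are filtered
   first.
3. **FA counting** — puncta outside cells or inside nuclei, smaller than
   30 px, or not brighter than their cell's mean staining are removed;
   per-dataset cutoffs drop cells above the pooled 99th-percentile count or
   with ≤ 4 adhesions.
4. **Statistics** — pairwise two-sided Fisher's exact tests with
   Benjamini–Hochberg FDR on blebbing frequencies; two-way ANOVA + Tukey
   HSD on log₁₀ FA counts with a rank-based (Mann–Whitney + BH)
   alternative.

Real annotated micrographs are rarely available, so the package includes a
seeded **synthetic-scene generator** with complete ground truth (cell and
nucleus masks, blebbing labels, FA positions); all recovery claims are made
against it. See [docs/methods.md](docs/methods.md) for the model details
and the generator's limits.

## Worked example

Simulate a field of ten cells (half blebbing), segment it, and classify:

```python
import numpy as np
from blebquant import (SceneParams, generate_scene, segment_nuclei,
                       segment_cell_bodies, extract_features, features_to_frame)

channels, truth = generate_scene(SceneParams(seed=1))
nuclei = segment_nuclei(channels["nuclei"])
cells = segment_cell_bodies(channels["cytoplasm"], nuclei)
records = extract_features(cells, nuclei, channels["adhesion"])
df = features_to_frame(records)
cols = ["cell_id", "mean_curvature", "intensity_ratio_nuc_cyto",
        "area_ratio_cell_nuc", "blebbing"]
print(df[cols].round(3).head(4).to_string(index=False))

# segmentation labels are not in generator order: match each truth mask
labels = [int(np.bincount(cells[m][cells[m] > 0]).argmax()) for m in truth.cell_masks]
calls = df.set_index("cell_id")["blebbing"]
print("calls match truth:",
      np.mean([calls[l] == t for l, t in zip(labels, truth.blebbing_labels)]))
```

prints

```
 cell_id  mean_curvature  intensity_ratio_nuc_cyto  area_ratio_cell_nuc  blebbing
       1           0.017                     1.487                3.459     False
       2           0.076                     0.524                3.936      True
       3           0.016                     1.601                3.466     False
       4           0.018                     1.832                3.455     False
calls match truth: 1.0
```

Cell 1 is smooth (mean curvature 0.017 px⁻¹ < 0.029 and a nucleus-dominant
marker ratio 1.49 > 1.15 → non-blebbing); cell 2 carries bead protrusions
(0.076 px⁻¹) with a cytoplasm-dominant marker (0.52) and a compact spread
(3.9 < 4.5), so all three criteria fire and it is called blebbing. On this
seed every call matches the generator's ground truth.

The same stages are scriptable from the shell (`blebquant simulate`,
`segment`, `features`, `adhesions`, `stats`; see `--help` and
`configs/default.yaml`), and `analysis/01…05` run a complete simulated 2×2
experiment — generation, measurement, Fisher/FDR frequency comparisons, and
the log₁₀ ANOVA/Tukey FA analysis — writing tables under `results/`.

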