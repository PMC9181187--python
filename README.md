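# endomosaic

Synthetic corneal-endothelium image analysis: ground-truthed mosaic
generation, variable-frame center-method cell density (ECD), four-category
image-quality grading, nuclear-stain gold-standard counting, and the
paired statistics tying it all together.

The package simulates what an eye-bank specular-microscopy workflow
measures.  A field of endothelium is modelled as the Voronoi tessellation
of its cell centers over a 935 × 748 µm rectangle (1280 × 1024 px at
0.7305 µm/px).  A seeded generator produces jittered-hexagonal mosaics at
a target density, renders specular-style images (bright cells, dark
borders, dark fold bands that hide cells, locally blurred indistinct
patches, illumination falloff, sensor noise) and nuclear-stain images
(one Gaussian blob per cell), and simulates longitudinal cell loss
across storage sessions.  Every operation is a pure function of its
inputs and a seed.

## Modules

| module | contents |
| --- | --- |
| `endomosaic.geometry` | field-clipped Voronoi tessellation, adjacency, morphometry (area CV, hexagonality), contiguous groups |
| `endomosaic.synthesis` | mosaic generator, five-field layout planner, specular/nuclear renderers, storage-series simulation |
| `endomosaic.counting` | calibration, center-method frame counting, area-weighted pooling, per-cornea mean ± SD |
| `endomosaic.grading` | excellent/good/fair/unanalyzable classifier on per-cell flags; grade tabulation |
| `endomosaic.nuclei` | threshold + connected-component nucleus detection with merged-blob splitting; gold-standard density |
| `endomosaic.stats` | Shapiro–Wilk-gated paired t / exact signed-rank tests, repeated-measures ANOVA with step-down Šidák, field-of-view ratios |
| `endomosaic.pipeline` | the end-to-end simulated study (two arms: 50 corneas × 3 sessions, 12 corneas × 6 sessions, five fields each) |
| `endomosaic.cli` | `endomosaic` command with `simulate`, `grade`, `count`, `nuclei`, `compare`, `report`, `run` subcommands |

## CLI examples

```bash
# one synthetic field: images + ground-truth CSV + manifest
endomosaic simulate --seed 3 --target-ecd 2500 --out out/field

# grade an annotated image
endomosaic grade --centers centers.csv --flags flags.csv

# center-method density of one frame (pixel CSVs)
endomosaic count --centers pointed.csv --boundary frame.csv

# full simulated study arm
endomosaic run --arm three_month --seed 1 --out out/study
```

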