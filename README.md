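# trabfd

Box-counting fractal-dimension (FD) analysis of trabecular (cancellous)
alveolar bone on periapical radiographs, packaged as a reproducible
pipeline:

- **`trabfd.morphometry`** — radiograph I/O (PNG/TIFF/BMP, 8/16-bit, RGB),
  rectangular ROI cropping, and percent radiographic bone loss from the
  CEJ / defect-base / root-apex landmarks (`100 × d(CEJ, defect) / d(CEJ, apex)`).
- **`trabfd.segmentation`** — trabecular texture extraction: Gaussian blur
  (σ = kernel/6), subtraction from the original with a gray offset of 128,
  strict binarization, optional morphological opening, and thinning to a
  one-pixel-wide skeleton.
- **`trabfd.fractal`** — box counting over a configurable size ladder
  (default `2,3,4,6,8,12,16,32,64`, grid anchored top-left, partial edge
  boxes included) and FD as the least-squares slope of log N(s) vs log(1/s).
- **`trabfd.stats`** — Kruskal–Wallis with midranks and tie correction,
  Pearson correlation, chi-square independence, Shapiro–Wilk, pooled
  mean/SD summaries, and noncentral chi-square power / sample-size analysis.
- **`trabfd.roc`** — empirical ROC curves for "positive iff FD ≤ t" rules,
  Mann–Whitney AUC with Hanley–McNeil logit CIs, Youden-optimal criteria,
  exact Clopper–Pearson sensitivity/specificity intervals, and the FD
  staging classifier (healthy > 1.188; stage I/II ≤ 1.188; stage III
  ≤ 1.158; stage IV ≤ 1.102).
- **`trabfd.synthetic`** — seeded generators for everything the tests need:
  analytic fractal fixtures (Sierpinski carpet, filled square, line, point),
  power-law-spectrum radiograph phantoms with landmarks, and bivariate-normal
  cohort simulation from the per-stage FD / %bone-loss parameter table.

## CLI

```sh
trabfd simulate --seed 1 --outdir out            # phantoms + cohort.csv
trabfd process-images --image-dir out/images --outdir out
trabfd cohort-stats --cohort out/cohort.csv --outdir out
trabfd roc --cohort out/cohort.csv --outdir out  # 5 situations + staging calls
trabfd all --seed 1 --outdir out                 # the whole pipeline
```

Every command writes a `manifest_*.json` (config hash, seed, per-subject
status); rerunning with the same seed and config produces byte-identical
tables. Per-subject failures in `process-images` are recorded in
`failures.json` and signalled with exit code 3 rather than aborting the run.

ROI sidecar schema (one JSON per image):

```json
{"rect": [x, y, w, h],
 "landmarks": {"cej": [x, y], "defect": [x, y], "apex": [x, y]},
 "spacing_mm": 0.04}
```

Coordinates are 0-based with origin at the top-left; rectangles are
half-open `[x, x+w) × [y, y+h)`.

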