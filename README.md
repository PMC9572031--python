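# mlcquant

Quantification of **macrophage-like cells (MLCs)** on en face OCT slabs at
the vitreoretinal interface, with region-stratified densities relative to
retinal edema and nonparametric group statistics.

MLCs are hyperreflective, point-like cells visible in a thin en face OCT
slab 5–10 μm above the internal limiting membrane; their density changes in
retinal vascular disease such as retinal vein occlusion (RVO). This package
reimplements, as a tested and reusable Python library, the ImageJ-style
workflow used to count them:

1. **Enhance** — crop the screenshot border, apply successive white
   top-hats `f − (f ∘ B)` with five structuring elements (square r=5; 21-px
   lines at 0°, 90°, 45°, 135°), subtract a rolling-ball background
   (grayscale opening with a spherical-cap element, r=10), subtract a
   Gaussian blur (σ=10).
2. **Classify** — a trainable pixel classifier (extra-trees over an
   11-plane multi-scale feature stack) maps each pixel to P(cell); a
   deterministic Otsu fallback needs no training.
3. **Quantify** — 8-bit conversion, thresholding, connected-component
   particle analysis: count, area, percent area; density = count / analyzed
   area (33.66 mm² for the default 6×6 mm scan after cropping).
4. **Regions** — the edematous region is `thickness > 440 μm` on the
   matched retinal-thickness map; particle counts and areas partition
   exactly into edematous / non-edematous / whole.
5. **Stats** — Shapiro–Wilk-gated summaries (mean ± SD vs median (IQR)) and
   correlations (Pearson vs Spearman), Mann–Whitney U group comparisons
   (exact for small samples, tie-corrected otherwise), Friedman test across
   the three regions with Dunn's pairwise comparisons, Bonferroni-adjusted.

Because no clinical images of this kind are publicly deposited, the package
includes a first-class **synthetic-data generator**: en face images (bright
Gaussian-blob cells, curvilinear vessels, speckle), thickness maps with a
foveal pit and edema bumps, and whole cohorts whose group medians,
right-skewed density distributions and count–CFT rank correlations follow
the published cohort structure — with exact ground truth, so every stage is
testable. See `docs/methods.md` for the full model description.

## Worked example

`examples/02_train_and_segment.py` trains the pixel model on two synthetic
eyes labeled from their planted truth, then counts cells on a fresh eye:

```text
held-out pixel accuracy: 0.9939
planted 60 cells; recovered 60 (7.71 cells/mm² over 7.78 mm²)
```

The held-out accuracy is pixel-level classification accuracy on labeled
pixels; the recovered particle count matches the planted truth exactly here,
and stays within ±5% across the 20-seed benchmark in the test suite.

`examples/05_density_arithmetic.py` reproduces the headline density
arithmetic — median cell count over the 33.66 mm² analyzed area:

```text
     control eyes: median count  220.5 / 33.66 mm² =  6.55 cells/mm²
   acute RVO eyes: median count  388.0 / 33.66 mm² = 11.53 cells/mm²
 chronic RVO eyes: median count  422.0 / 33.66 mm² = 12.54 cells/mm²
     all RVO eyes: median count  391.0 / 33.66 mm² = 11.62 cells/mm²

non-edematous area = 33.66 − 9.14 = 24.52 mm²
```

The other examples cover the enhancement chain (`01`), the edema-region
partition with a planted density deficit (`03`), and an end-to-end
miniature cohort with report tables (`04`). A thin CLI wraps the same
functions (`mlcquant synthesize / preprocess-image / train / segment /
quantify / report / demo`).

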