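# Methods

`mlcquant` quantifies macrophage-like cells (MLCs) — hyperreflective,
point-like cells imaged in a thin en face OCT slab just above the internal
limiting membrane — and relates their density to retinal edema. Because
clinical en face OCT datasets of this kind are not publicly deposited, the
package pairs the analysis pipeline with a synthetic-data generator that
emulates the images and the cohort structure the analysis expects, with
exact ground truth. This note records the models, the parameters that
matter, the numerical choices, and what passing tests do and do not show.

## Image model and enhancement chain

An en face slab is an 8-bit grayscale image on a known grid (by default
512×512 px covering 6×6 mm, pixel pitch ≈ 11.7 μm). The slab arrives as a
device screenshot, so the first step crops a border margin (default 9 px per
side). Enhancement then runs, in order:

1. **White top-hat sequence.** `WTH(f, B) = f − (f ∘ B)` where `∘` is
   grayscale opening (erosion then dilation). Five flat structuring elements
   are applied successively, each stage feeding the next: a square of radius
   5 (11×11 px), then 1-px-thick digital lines of radius 10 (21 px long) at
   0°, 90°, 45° and 135°. A point-like cell is smaller than every element
   and passes each stage essentially unchanged; a curvilinear vessel
   contains at least one line element along its local direction and is
   suppressed. "Successively" is read as sequential composition (the way an
   ImageJ macro chains in-place operations); combining the five responses by
   maximum instead is possible by calling `white_top_hat` per element, but
   sequential is the default.
2. **Rolling-ball background subtraction** (radius 10). The background is
   the grayscale opening of the image with a *non-flat* spherical-cap
   element `g(δ) = √(r² − |δ|²)`: the surface swept by the top of a ball of
   radius r rolled under the intensity landscape. We implement the exact
   definition (scipy grey erosion + dilation with the cap heights) rather
   than the legacy ImageJ shrink/interpolate approximation, precisely so a
   brute-force sliding-window oracle can verify it bit-for-bit.
3. **Gaussian high-pass** (σ = 10): `clip(f − G_σ ∗ f, 0, 255)`, kernel
   truncated at 4σ.

All boundaries use edge-duplicating reflection, which avoids fabricating
bright border structure that would become spurious particles. Every stage is
anti-extensive and non-negative (`0 ≤ out ≤ in` pointwise); the suite
enforces this as a property test.

**Crop margin.** The published whole-image analyzed area is 33.66 mm². No
integer symmetric margin reproduces it exactly at 6 mm / 512 px (8 px →
33.79 mm², 9 px → 33.51 mm²); the margin is therefore configurable with a
default of 9 px, and the 33.66 mm² constant (`DEFAULT_ANALYZED_AREA_MM2`) is
used for the published-table arithmetic. A feasibility check in the
acceptance suite confirms that a single area value in [33.63, 33.69] mm² is
consistent with all five published count/density pairs at ±0.01 cells/mm²;
the feasible interval is ≈ [33.65, 33.68] mm².

## Pixel classification

The interactive trainable-segmentation step is recast as a reproducible fit:
an 11-plane feature stack per pixel (raw intensity; Gaussian blurs at
σ ∈ {1, 2, 4, 8}; gradient magnitude at σ ∈ {1, 2}; Laplacian at σ ∈ {1, 2};
differences of Gaussians (1,2) and (2,4)) feeds an extra-trees ensemble
(100 trees, seeded) that outputs P(cell). Labels are hand-painted images
(0 unlabeled / 1 cell / 2 background) or, for synthetic data, disks of
radius 2 px around planted centers. Background pixels are downsampled to at
most 5× the cell pixels; 25% of labeled pixels are held out to report
accuracy. The exact feature set and classifier of the original interactive
tool are not knowable; an ensemble of randomized trees over this stack is
the closest behavioral stand-in and is treated as the package's own design
choice.

A deterministic fallback needs no training: Otsu's threshold over the
256-bin histogram (ties broken toward the lower threshold). On the enhanced
images the histogram is strongly unimodal (cells occupy ~0.1% of pixels),
so Otsu tends to overcount speckle doublets; the trained classifier is the
default segmentation mode and the fallback is for quick, training-free runs.

## Particle analysis and regions

The probability map is scaled to 8-bit (`round(p·255)`) before thresholding
(≥ level·255, default level 0.5), mirroring the workflow's 8-bit conversion;
a map value of exactly 0.5 is kept. Connected components use 8-connectivity
by default (4 is available), with a size filter of min 2 px (no upper bound)
to suppress single-pixel noise — the original workflow states no filter, so
this is exposed in configuration because it directly moves the headline
count. Particle centroids are arithmetic pixel-coordinate means; particles
are ordered by the top-left corner of their bounding boxes.

The edematous region is `thickness > 440 μm` on the matched thickness map;
optional closing, hole filling and minimum-area cleanup replace the manual
boundary editing of the interactive workflow (off by default, so the mask is
a pure threshold). A particle belongs to the edematous region iff the pixel
under its centroid is in the mask — a particle straddling the boundary is
counted once, in one region — so counts and areas partition exactly:
edematous + non-edematous = whole. This preserves the additive structure of
the region table by construction.

## Statistics

- Shapiro–Wilk at α = 0.05 gates both the summary format (mean ± SD vs
  median (IQR), quartiles by linear interpolation) and the correlation
  method (Pearson vs Spearman with average ranks). Zero-range samples take
  the median path. An explicit method override exists because Shapiro–Wilk
  is underpowered at very small n.
- Mann–Whitney U, two-sided: exact enumeration of the permutation
  distribution of U (computed from midranks, so ties are handled) when both
  sides have ≤ 8 observations; tie-corrected normal approximation with
  continuity correction otherwise. The exact path is hand-written because
  scipy's exact method excludes ties.
- Friedman test across the three within-eye regions, with Dunn's pairwise
  rank comparisons: `z = (R̄_i − R̄_j) / √(k(k+1)/6n)` on within-eye mean
  ranks, each pairwise p multiplied by 3 (Bonferroni) and capped at 1 —
  the default post-hoc of the statistics package the analysis plan names.
  All-tied inputs are a degenerate no-effect case (χ² = 0, p = 1) rather
  than the 0/0 scipy produces. The chi-square p agrees with a
  10,000-permutation oracle to < 0.01 in the decision-relevant tail
  (verified at n = 12); at mid-range p the approximation is coarser.
- Count and density give identical rank-based results because the
  whole-image area is one constant; report tables emit both rows.

## Synthetic-data generator

The generator's defaults are the study conditions; they are not tuning
knobs.

**Cohort structure.** Three groups — 64 control, 43 acute, 29 chronic eyes.
Per-eye planted density is log-normal (right-skewed, as the reported
median/IQR summaries imply), with σ_log solved from
`IQR/median = 2·sinh(0.6745·σ)`: medians 6.55 / 11.53 / 12.53 cells/mm² and
σ_log 0.711 / 0.648 / 0.669 for control / acute / chronic. CFT is log-normal
the same way (medians 207.84 / 555.31 / 276.65 μm); vessel densities are
normal with the reported means ± SD; disease duration is log-normal
(medians 33 / 265 days). Cell count and CFT are coupled through a Gaussian
copula with latent correlation `ρ_l = 2·sin(π·ρ_s/6)` so the sample Spearman
correlation approaches the group target (−0.352 acute, +0.406 chronic)
without committing to a mechanistic model.

**Thickness maps.** Baseline (log-normal around 291.52 μm for controls,
305 μm for RVO eyes) minus a central foveal-pit Gaussian, plus non-negative
Gaussian edema bumps. The central bump amplitude is chosen so the map's
center value equals the eye's CFT draw (clipped to [80, 1200] μm for
rendering); RVO eyes add 0–3 satellite bumps (amplitude 50–150 μm, scale
40–90 px). A 2 μm smooth ripple keeps maps from being analytically flat.
The > 440 μm level set of a planted bump is known in closed form, which the
region tests exploit.

**Within-eye edema deficit.** The planted edematous density is the
non-edematous density times a group ratio (0.6 acute, 0.9 chronic — the
acute deficit is the pattern the region statistics must detect; the chronic
ratio is mild and non-significant by design). Cells are placed uniformly in
each region with a hard-core minimum separation (8 px), relaxed
progressively only if a region is too crowded to accommodate its count.

**Rendering.** Image = smooth background field (level 40, ±10) + bright
random-walk vessel streaks (8 per eye, amplitude 30) + isotropic Gaussian
cell blobs (σ uniform in [1, 2] px — the smallest resolvable bright feature
at this pitch — amplitude 120 ± 20%), multiplied by 15% speckle, plus
additive σ = 4 read noise and a bright border frame that the preprocessing
crop removes. Cell contrast is therefore ≈ 6× the local noise level.
Everything is driven by spawned child seeds of one root seed: identical spec
+ seed gives bit-identical images, maps and truth.

**What the generator does not emulate:** real MLC morphology (ameboid
shapes, clusters in chronic eyes), vessel shadowing and projection
artifacts, segmentation-line errors near strong edema, inter-device
intensity scales, or paired fellow-eye correlation. Passing the recovery
benchmarks therefore shows the chain is correct and well calibrated on
images matching its assumptions — not that it would hit ±5% on clinical
exports.

## Problem sizes and numerical choices

The default test suite exercises 256×256 px eyes for end-to-end runs and
the full 512×512 benchmark (200 cells, 20 seeds) for count recovery;
statistical calibration uses 2000 matched-null replicates (type-I error
bands 0.05 ± 0.02), 200 replicates for the edema-deficit power check and
500 for correlation recovery. Morphological operators are verified exactly
(not approximately) against brute-force sliding-window definitions on
random images up to 32×32, and connected components against a flood-fill
oracle. Probability maps round-trip through model serialization
bit-exactly.

Known limitations: the rolling-ball implementation is the exact opening
(deliberately not ImageJ's downsampled approximation, whose output differs
by a few gray levels); Otsu-mode counts are sensitive to the speckle level;
the Friedman chi-square p is approximate at very small n; and the generator's
amplitude/size distributions are calibration choices, since no per-cell
intensity statistics are published for this kind of data.
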