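# Methods

This note documents the model behind `choroviz`, the parameter choices
that matter, what the synthetic phantom generator does and does not
emulate, and the numerical conventions adopted where the design was
genuinely open.

## The measurement model

The object of study is the running pattern of the large veins of
Haller's layer in a macula-centred en-face OCT slab. The physiological
prior is hemodynamic: choroidal venous drainage divides at a horizontal
watershed through the macula and optic disc, the upper hemifield
draining toward the upper-temporal vortex vein and the lower hemifield
toward the lower-temporal one. In the right-eye frame (temporal on the
left) "conformant" vessels therefore run obliquely up-left above the
watershed and down-left below it. The pipeline quantifies how far an
eye departs from this pattern, and a binary classifier maps the
quantities to the clinical dichotomy symmetric/asymmetric.

All geometry assumes the right-eye frame; left eyes are mirrored
horizontally on ingestion (an involution-fixed normalization: applying
it twice equals applying it once). A strict mode that rejects left eyes
instead is available (`PipelineConfig.strict_od`).

### Binarization and denoising

Vessels are dark on a brighter background, so the mask is
`pixels <= t` with `t` the Otsu (maximum between-class variance)
threshold of the 8-bit histogram. Denoising removes 8-connected
foreground components and background holes smaller than
`min_component_px` (default 30 px at 512×512, rescaled by `(H/512)²`).
The size-based rule is this package's choice of denoising operator; it
is deliberately simple, scale-aware and parameter-light.

### Thinning

The centerline is obtained by Zhang–Suen parallel thinning (two
sub-iterations per pass, iterated to fixpoint), implemented in-package
and verified pixel-exactly against an independent per-pixel reference
implementation of the published algorithm in the test suite. Note that
`skimage.morphology.skeletonize(method="zhang")` is a lookup-table
variant whose output differs from the published parallel algorithm on
some inputs (it can retain corner spurs); it is therefore not used as
either the implementation or the oracle.

### Hemifield canonicalization (a deliberate design choice)

Per-hemifield quantities (area, skeleton length, mean diameter,
natural/unnatural percentages, ladder summaries) are computed by
splitting the mask at the watershed row `H/2` and processing the lower
half **flipped vertically**, with the upper-hemifield orientation band.
Flipping and applying the upper band is mathematically identical to
applying the mirrored lower band, so nothing changes semantically — but
it guarantees that both hemifields pass through *byte-identical*
algorithms. This matters because iterative thinning is not equivariant
under vertical mirroring (a mirror-symmetric mask can thin to an
asymmetric skeleton); with canonicalization, an exactly mirror-symmetric
image provably yields ratio features of exactly 1 and difference
features of exactly 0, which the test suite asserts with `==`.
The whole-image skeleton is still computed for the midline-crossing
features, which by definition need vessels spanning the watershed.
A consequence is that vessels crossing the midline are cut at the
boundary for hemifield statistics; their crossing behaviour is captured
by the dedicated crossing features instead.

### Segments and orientation

Bifurcations are skeleton pixels where three or more separate branches
meet, detected by the crossing number (count of distinct neighbour runs
around the 8-ring) rather than the raw neighbour count — the raw count
flags the four pixels adjacent to a junction as well. Segments are
maximal paths between bifurcations/free ends; orientation is the chord
angle between segment endpoints, mapped to [0°, 180°) with y up.
Segments shorter than `min_segment_px` (default 5) are excluded from
orientation statistics (they remain in the length totals, which count
skeleton pixels directly). Natural/unnatural percentages are
length-weighted; "neither" segments (within 5° of horizontal or
vertical, per the band definitions) are excluded from numerator and
denominator both.

### The ladder image

Horizontal lines every 25 px; each line pixel is white when the
majority of mask pixels in a 7-row window centred on the line is white
(window clipped at borders, majority over available rows). Maximal white
runs along a line are treated as vessel cross-sections: mean run length
is the diameter proxy, total white pixels the length proxy. For the
hemifield contrasts the ladder is built per canonical hemifield (lines
at 25, 50, … within each half), which keeps line placement
mirror-symmetric; temporal/nasal contrasts use the whole-image ladder
split at the vertical midline.

### The 28 features

Rows 1–6: area (mm²), length (mm), mean diameter (= area/length, mm)
per hemifield. 7–8: upper/lower ratio and signed difference of mean
diameter. 9–10: among segments crossing the watershed row, the
fractions oriented along the two diagonal axes. 11–14: natural and
unnatural percentages per hemifield. 15–18: natural:unnatural ratio per
hemifield, and the ratio/difference of those ratios. 19–20: upper:lower
ratio and difference of the natural percentage. 21–24 and 25–28:
ladder-image diameter/length differences then ratios, upper/lower and
temporal/nasal. Differences are signed (upper−lower, temporal−nasal; an
absolute-value mode exists). Ratios with a zero denominator are mapped
to a finite sentinel cap (default 100) and flagged, never NaN —
degenerate eyes (e.g. no unnatural vessels at all) must remain usable
by downstream classifiers.

Length here is a skeleton pixel count times the pixel pitch, the
convention the whole feature set is built on. Digital lengths of this
kind are orientation-biased: a thinned 45° line advances √2 per pixel,
while thinning renders shallow lines as rook-connected staircases, so
pixel count can under- or over-state Euclidean length by up to ~40%
depending on angle. This bias is a property of the metric, is shared by
both hemifields identically (canonicalization), and cancels from all
ratio/difference features; absolute lengths should be read as
calibrated instrument units rather than Euclidean millimetres.

## Classifiers

**GA-SVM.** Features are z-scored on training data; the SVM uses an RBF
kernel with Platt-scaled probabilities (calibration fitted on internal
training folds). C and γ are found by a small grid (C ∈ {0.1, 1, 10,
100}, γ ∈ {0.001, 0.01, 0.1, 1}) under internal stratified 5-fold
accuracy. Feature selection is a binary-mask genetic algorithm:
population 20, one-point crossover at 0.7, tournament size 2, up to
1000 generations with early stopping (default patience 100
improvement-free generations), elitism, all-zero masks repaired. The
stated mutation rate 0.2 is read as a per-individual mutation event
(each gene then flips with probability 1/28); a per-gene semantics is
exposed in `GAConfig.mutation_semantics`. Fitness is mean accuracy of
the wrapped SVM under internal stratified 5-fold CV on the training
partition, with fixed C = 1, γ = "scale" inside the GA to keep the
wrapper affordable; fitness evaluations are cached per mask.

**Embedding pathway.** Any object with `fit(images, y)`/`transform`
works. Built-ins: (a) `CNNEmbeddingExtractor`, a compact two-conv
network (8@5×5/stride 2 → ReLU → maxpool 2 → 16@3×3/stride 2 → ReLU)
trained in pure NumPy with SGD (lr 1e-4, momentum 0.9), batch 32,
binary cross-entropy through a global-average-pool logistic head, with
horizontal/vertical flips and ±15° rotations as augmentation; the
flattened final feature map is the embedding. (b) `PixelPCAExtractor`,
PCA of downsampled pixels — deterministic and fast, used by the
standing benchmark. The extractor and the PCA reduction (to
k' = min(100, n−1, d) components) are fitted inside each training fold
only.

**Fused random forest.** A random forest over the concatenation
[28 features | 100 embedding components]. The reference configuration is
100 000 trees; desk-scale runs use 500 (forest variance is tiny at this
sample size). CS is the fraction of trees voting symmetric.

CS orientation is fixed at 1 = confidently symmetric; classification
thresholds CS at 0.5 with asymmetry as the positive class, and a score
of exactly 0.5 is called symmetric (tie to the negative class,
documented rather than left to chance).

## Evaluation

Stratified 10-fold cross-validation (stratification is this package's
choice for near-balanced cohorts; an unstratified fallback engages when
a class has fewer members than folds). All models in a comparison share
the same fold assignment — a paired Wilcoxon test on per-fold metrics is
meaningless otherwise. AUC is the Mann–Whitney statistic with midrank
ties; κ is unweighted Cohen's kappa on the 2×2 table; fold SDs use the
n−1 denominator. The Wilcoxon signed-rank p-value is exact (full 2ⁿ
sign-pattern enumeration, zeros dropped, midranks) for n ≤ 15 and a
continuity-corrected normal approximation with tie-corrected variance
above.

## Confidence analysis

Strength = |CS − 0.5| ∈ [0, 0.5], binned into exact thirds with
half-open intervals: unconfident < 1/6 ≤ moderately confident < 1/3 ≤
confident. (Printed three-decimal bin bounds of the form 0.166/0.167
and 0.332/0.333 are truncations of these thirds; implementing the exact
thirds removes the 0.0005 gaps.) Agreement strata count how many of
three independent raters match the supervised label (3/2/1/0 →
agreement / partial agreement / partial disagreement / disagreement).
`simulate_raters` provides synthetic raters with per-rater error
probabilities so the stratified cross-tabulation can be exercised
without clinical readers. The module is model-agnostic about which
classifier supplies CS; the random forest is the default source as the
strongest model.

## The phantom generator

`SynthConfig`/`generate_image` render dark branching capsule strokes on
a brighter background with Gaussian pixel noise and 8-bit quantization.
In the symmetric regime (α = 0) strokes obey the drainage bands in both
hemifields with mirrored calibers. The asymmetry knob α ∈ [0, 1]
(a) flips a fraction α of upper-hemifield strokes into the opposite
band — concentrating the conformity loss in one hemifield, as in the
clinical pattern, which also makes the expected hemifield drainage
contrast monotone in α — (b) lets flipped strokes cross the watershed,
and (c) inflates lower-hemifield calibers by (1 + α). The label is
symmetric iff α < 0.5. Defaults: 256 px canvas (512 supported; 256
keeps the test suite fast), 5 trunks + 2 branches per hemifield,
caliber 5 ± 0.8 px, vessel/background intensities 70/200, noise SD 6.
Per-stroke ground truth (hemifield, orientation, rendered length,
caliber) is recorded with strokes clipped at the canvas border.

What the phantoms do **not** emulate: OCT speckle and shadowing,
vessel curvature and caliber taper, vortex-vein anatomy, the
choriocapillaris background texture, segmentation errors of the
upstream slab extraction. Passing benchmarks on phantoms therefore
demonstrates that the pipeline and classifiers recover the constructs
they were built to measure — not clinical-grade performance on real
eyes.

## Standing benchmark and problem sizes

The repository's standing end-to-end benchmark
(`choroviz.workflows.reference_benchmark`) uses n = 200 phantoms
(α = 0.1 vs 0.9, balanced), 10-fold shared-fold CV, the GA-SVM with a
desk-scale evolution budget (10 generations, patience 5), the fused
random forest with 500 trees and the pixel-PCA extractor, and a
label-shuffled null model. The GA feature-recovery simulation uses
n = 200 with two informative features and ten seeded runs. These sizes
are the package's own desk-scale choices; every knob accepts larger
values.

## Known limitations

- Digital skeleton length is orientation-biased (see above); absolute
  mm values are instrument units.
- The segment decomposition resolves junction ambiguities (diagonal
  shortcuts, staircase remnants) with deterministic tie-breaks; tiny
  residual fragments are kept as sub-threshold segments and excluded
  from orientation statistics.
- The midline-crossing features depend on a whole-image skeleton and
  are not exactly mirror-equivariant, unlike the hemifield features.
- The built-in CNN is a minimal embedding network, not a large
  pretrained backbone; with small cohorts the pixel-PCA pathway is
  often competitive and is the default in the benchmark.
- Image-quality and refraction exclusion criteria of a clinical cohort
  are acquisition-time metadata; the package filters on manifest fields
  but cannot compute them from pixels.
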