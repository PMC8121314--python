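# choroviz

Quantification and automated classification of the **choroidal vascular
running pattern** in OCT en-face images of Haller's layer.

In a normal eye the large choroidal veins of the posterior pole drain
symmetrically: a horizontal watershed line runs through the macula and
optic disc, vessels above it drain obliquely toward the upper-temporal
vortex vein and vessels below it toward the lower-temporal vortex vein.
In pachychoroid-spectrum disease this hemifield symmetry is frequently
lost, but grading it by eye is subjective and poorly reproducible.
`choroviz` turns an en-face slab image of Haller's layer (dark vessels
on a brighter background, right-eye frame, macula centred) into 28
engineered features describing that symmetry, and trains/evaluates
classifiers that label an eye **symmetric** or **asymmetric** with a
calibrated confidence score.

It is aimed at ophthalmic image-analysis researchers who want a fully
scripted, dependency-light reimplementation of this pipeline that can be
exercised end-to-end on synthetic phantoms (no clinical data required).

## Pipeline

For an image `I` (default 512×512 px ≙ 7×7 mm, scale `s` = 7/512 mm/px):

1. **Binarize** — Otsu's discriminant threshold; pixels darker than the
   threshold become the vessel mask. Small components/holes are removed.
2. **Thin** — Zhang–Suen iterative thinning to a 1-px centerline.
3. **Segment** — the skeleton is cut at bifurcation points into vessel
   segments; each segment gets a chord orientation θ ∈ [0°, 180°)
   (y-up, from horizontal). In the right-eye frame, upper-hemifield
   segments with θ ∈ [95°, 175°] and lower-hemifield segments with
   θ ∈ [5°, 85°] are *natural* oblique vessels (drainage-conformant);
   the opposite band is *unnatural*; ±5° of horizontal/vertical is
   neither.
4. **Ladder image** — horizontal sampling lines every 25 px, each line
   pixel set by a majority vote over a 7-px vertical strip; white runs
   act as coarse caliber/length probes.
5. **Features** — 28 quantities: per-hemifield vessel area (mm²),
   skeleton length (mm), mean diameter (area/length, mm); their
   upper/lower ratios and differences; length-weighted natural and
   unnatural percentages and derived contrasts; midline-crossing
   fractions; ladder-image length/diameter contrasts (upper/lower and
   temporal/nasal).
6. **Classifiers** — (a) an RBF-kernel SVM on the 28 features with
   genetic-algorithm feature selection (population 20, crossover 0.7,
   mutation 0.2, tournament 2, up to 1000 generations with early
   stopping); (b) a pluggable image-embedding pathway (built-ins: a
   compact CNN trained with SGD lr 1e-4 / momentum 0.9 / batch 32 /
   flip + ±15° rotation augmentation, and a pixel-PCA extractor); (c) a
   random forest fused over [28 features | 100 PCA components of the
   embedding]. All emit a confidence score CS ∈ [0, 1] (1 = confidently
   symmetric; threshold 0.5, asymmetry positive).
7. **Evaluation** — stratified 10-fold cross-validation with folds
   shared across models; AUC, accuracy, recall, precision, Cohen's κ;
   paired two-sided Wilcoxon signed-rank tests on per-fold metrics
   (exact for n ≤ 15).
8. **Confidence analysis** — strength |CS − 0.5| binned into thirds
   (unconfident / moderately confident / confident), cross-tabulated
   against agreement strata defined by how many of three raters match
   the supervised label.

Left (OS) eyes are mirrored into the right-eye frame on ingestion.

## Worked example

```python
import choroviz as cv

# a strongly asymmetric synthetic phantom (256 px, alpha = 0.9)
sample = cv.generate_image(cv.SynthConfig(alpha=0.9), seed=7)
f = cv.compute_features(sample.image)
print(f"label                 {sample.label}")
print(f"natural% upper        {f['natural_oblique_pct_upper']:.1f}")
print(f"natural% lower        {f['natural_oblique_pct_lower']:.1f}")
print(f"mean diameter diff    {f['upper_lower_diff_mean_diameter']:+.4f} mm")
```

prints

```
label                 asymmetric
natural% upper        24.7
natural% lower        97.1
mean diameter diff    -0.0939 mm
```

— in this phantom most upper-hemifield vessels run against the normal
drainage direction (natural share 24.7% vs 97.1% below the watershed),
and the lower vessels are on average 0.09 mm thicker, both hallmarks of
an asymmetric running pattern.

A full cross-validated comparison on a 200-eye phantom cohort:

```python
from choroviz.workflows import reference_benchmark
summary, table = reference_benchmark(n=200, seed=7)
print(summary.summary_table())
```

The CLI mirrors these steps (`choroviz simulate`, `choroviz features`,
`choroviz preprocess`, `choroviz ladder`, `choroviz evaluate`).

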