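# Methods

`pentadraw` studies automated scoring of the intersecting-pentagon copy item
of the Mini-Mental State Examination (MMSE). Because clinical drawing
archives are access-restricted, everything here runs on two synthetic
substrates that the package itself provides: a parametrized drawing
simulator (for images) and a cohort generator (for per-visit tabular data).
This note records the models, the defaults and why, the numerical choices,
and what the synthetic substrates do and do not establish.

## The drawing model

A drawing is two closed polygons on a 500x500 white canvas (dark ink),
described by eight attributes:

| attribute | meaning | ideal | units |
|---|---|---|---|
| `n_vertices_a/b` | vertex count of each figure | 5 | count, 3..10 |
| `distance` | center separation / (r_a + r_b) | 0.75 | dimensionless |
| `alignment` | rotation of figure B within one vertex spacing; 0 = vertex faces vertex, 0.5 = vertex faces side | 0 | fraction |
| `angle_distortion` | SD of vertex-angle jitter, in units of the nominal spacing 2*pi/n | 0 | dimensionless |
| `size_equality` | circumradius ratio r_b / r_a | 1 | dimensionless |
| `size` | r_a / (canvas half-width) | 0.35 | fraction |
| `line_width` | stroke width | 3 | px |
| `waviness` | RMS perpendicular edge displacement / edge length | 0 | dimensionless |

The ideal distance 0.75 gives the canonical small lens-shaped overlap of the
MMSE stimulus (overlap fraction ~= 0.07 of the smaller figure). Distortion
jitters vertex *angles* only (radii untouched), with jitter clamped to 45%
of the angular spacing so the polygon stays simple; this keeps "distortion"
orthogonal to "size". Waviness displaces each edge perpendicular to its
chord by a sum of three random-phase sinusoids windowed by `4t(1-t)` (so
vertices stay exact) and rescaled to the target RMS — smooth and
tremor-like, and zero at vertices so vertex counting remains well-posed.
Rendering draws the two closed strokes at 4x supersampling and
box-downsamples, giving deterministic anti-aliased images whose ink count
grows strictly with line width.

Sweep sets follow the explainability protocol: one attribute takes eight
levels while the others jitter uniformly in a small window around the ideal
drawing (distance ±0.05, alignment ±0.028, distortion +0.02, size ratio
±0.05, size ±0.03, width ±0.5, waviness +0.01), 20 replicates per level.
The per-attribute level grids (e.g. vertices 3..10, distance 0 to 1.5,
waviness 0 to 0.12) are package defaults chosen to span the pass and fail
regimes; no published grid exists for them. Per-image seeds derive from
`blake2b(base_seed | attribute | level | replicate)`, so every image set is
a pure function of one integer.

## Measurement

`extract_features` is deliberately blind to the generator. Ink is
thresholded by Otsu on the inverted image; stroke width is twice the median
medial-axis distance. Overlapping figures form one ink component whose
interior splits into faces; the two faces holding the horizontally extreme
interior pixels are the figure cores (the stimulus is a side-by-side pair),
and every other face lies inside both outlines, i.e. is overlap, and joins
both reconstructed regions. Strokes wider than 6 px are first thinned to
their skeleton, because thick ink otherwise swallows the interior faces
entirely. Regions are closed morphologically and dilated by half the stroke
width so areas refer to stroke centerlines; the measured overlap fraction is
intersection area over the smaller region.

Vertices are counted on the region outline by windowed turning angle: the
outline is resampled to 512 points, smoothed circularly (sigma = 2% of the
perimeter), and the tangent turning rate is integrated over a sliding window
of 8% of the perimeter. Local maxima above `max(0.3 rad, 0.5 * strongest
valid peak)` with at least 6% perimeter separation are vertices. The
rationale: a true corner contributes a *net* turn (2*pi/n >= 0.63 rad for
n <= 10), while wavy-but-straight-on-average edges integrate to ~0, so the
statistic separates tremor from geometry in a way plain polyline
simplification at a fixed tolerance cannot (a decagon's corner sagitta is
smaller than the simplification tolerance that tremor forces). The relative
threshold adapts to weak corners in distorted polygons. Two artifact guards
make the counter robust near tangencies, where sliver contacts stamp nubs
and notches onto a region: candidate peaks whose window also carries strong
negative turning (a notch-shoulder / wiggle signature that real convex
corners lack) are excluded — including from the strongest-peak reference —
and regions are morphologically opened with a stroke-width disk to shave
sliver spikes (skipped when that would erase a tiny figure). Detected
corners are finally snapped from the smoothed curve (biased inward) to the
nearby raw-contour apex. Edge straightness (path/chord − 1) uses a
separate, much lighter contour smoothing (0.4% of the perimeter) that
cancels the half-pixel raster staircase without absorbing genuine waviness;
its floor on clean renders is ~3e-4. Measured count accuracy on the
simulator: 100% for n = 3..10 at waviness <= 0.02 in the canonical overlap
regime, 96–98% on mixed corpora that include near-tangent contacts; beyond
waviness ~0.03 counts degrade gracefully (overcounting), which mimics how
heavy tremor genuinely obscures vertices.

How the figures cross is summarized by *crossing asymmetry*: at each
boundary crossing point, the distances to the nearest vertex of each figure
(in mean-edge units) are compared; their mean absolute difference is ~0
when the figures meet vertex-to-vertex (crossings sit symmetrically between
both figures' vertices) and ~0.3 when one figure's vertex pierces the
other's side. Thresholds at 0.12 / 0.22 give the categorical crossing type.

The conventional clinical rule passes a drawing iff exactly two figures are
found, both have five vertices, and an intersection is present; every
violated criterion is reported.

## The proxy cognition scorer

A deterministic, documented stand-in for a trained image-to-cognition
network — not a clinical instrument. It is an additive-penalty score on
measured features with ceiling 1.0: U-shaped in vertex count about 5 (0.22
per unit deviation per figure); unimodal in overlap with target 0.07 (the
canonical stimulus' own overlap) and a 1.2-point penalty for no
intersection that ramps in continuously below overlap 0.03 (a cliff at
exactly zero would make near-tangent drawings score bimodally); linear in
crossing asymmetry (0.8), edge-length CV (0.9 per figure), and size
inequality (0.6); hinged below size 0.22 (quadratic, 2.0) and below 2.6 px
measured stroke width (0.5); and linear in straightness (path/chord − 1)
above a 0.01 floor (14.0). The weights are
frozen in `PROXY_WEIGHTS` and were fixed once so that all eight qualitative
response shapes of the sweep catalogue hold; they have no clinical
calibration. All features are mirror-symmetric, so the score is invariant
to image flips.

## Imaging pipeline

Morphological opening (3x3 square, on the ink foreground) removes
digitization specks; by the same token it removes strokes thinner than the
kernel, so if opening erases the whole drawing (feather-thin ink) the
composed pipeline falls back to detecting on the un-denoised image rather
than failing the form. The reference region detector is the bounding box of
the large ink components (>= 5% of the largest, so disjoint pentagon pairs
are covered) plus a 5% margin — any detector with the same signature can be
swapped in. Standardization pads the crop onto a 500x500 white canvas
without rescaling; crops that cannot fit are isotropically downscaled with
a logged warning (erroring would kill batch runs). Model input is a 224x224
bilinear resize. The augmentation suite (flips, rotation ±15°, translation
±5%, contrast/brightness ±20%, sharpness 0.5–1.5, Gaussian noise sigma <=
10, salt-and-pepper <= 0.5%, each included with probability 0.5 except
flips at 0.25, applied in randomized order) uses mild, label-preserving
magnitudes; none are published, so they are configuration defaults.
Test-time augmentation averages a scorer over 30 such variants.

## Statistics

*Folds* are person-grouped: participants are shuffled and dealt round-robin,
so all visits of a participant share a fold and fold sizes are balanced
within one. *Out-of-fold prediction* audits leakage explicitly (train/test
participant sets must be disjoint) and guarantees exactly one prediction
per row.

*Variance decomposition* is LMG / hierarchical partitioning: a predictor's
share is its incremental R^2 averaged over all p! orders of entry, computed
exactly from the 2^p subset R^2 values with combinatorial weights and a
subset cache. Enumeration is restricted to p <= 10; no sampling
approximation is offered, so the permutation oracle equivalence is exact to
numerical precision.

*AUC* is the Mann–Whitney probability with ties counted half (midranks);
*DeLong's test* uses placement values through the same midranks, so the tie
convention is consistent, with the paired-AUC variance from the empirical
covariance of placements. *Calibration* fits per-fold logistic models of a
binary diagnosis on the continuous score, applied only to held-out folds;
an optional ridge penalty (off by default) handles separation in small
cohorts, and a constant score degenerates cleanly to the training
prevalence. *MMSE integration* adds the calibrated probability (of the
better cognitive state, so higher remains better) to the 29-item total
(replacing the pentagon item) or to the full 30-item total.

Diagnosis contrasts take the first visit at the impaired diagnosis and the
baseline visit for unimpaired participants; a participant who reaches the
more impaired group belongs to it alone.

## Synthetic cohort

Each participant gets a latent cognition trajectory (baseline ~ N(0,1)
minus 0.03 per year of age above 77.4, declining ~0.1 SD/visit), from which
are generated: a noisy global-cognition composite (SD 0.30), 29 MMSE items
through a logistic item-threshold model (difficulties ~ N(-2.0, 0.9), most
items easy for this population), a clinical diagnosis from a noisy read of
the latent level (NCI above -0.75, DM below -1.75), and one drawing per
visit whose waviness (+0.030 per unit impairment — the strongest effect),
distortion (+0.050), size (−0.040), placement variability and vertex-slip
probability (+0.15) drift with impairment. The drawing score is the proxy
scorer applied to the drawing's exact vector geometry (flag-selectable to
full rasterize-and-measure, which agrees up to measurement noise) plus
N(0, 0.15) model error; the binary rating is the conventional rule with a
2% flip rate for rater error. Demographics (age 77.4 ± 7, education
15.9 ± 3) follow the population the instrument is used in.

What the generator emulates: longitudinal person-grouped structure, a
continuous drawing score that carries more cognitive signal than the
pass/fail rating, MMSE items consistent with the same latent trait, and
diagnosis groups with realistic overlap. What it does not: real pen
trajectories, paper/scan artifacts beyond salt-and-pepper noise,
education/ethnicity effects on test performance, neuropathology, and any
population-calibrated effect size. Passing tests therefore establish the
*machinery* (leak-free evaluation, correct statistics, right directions of
effect under known generative signal), not clinical performance.

## Numerical choices and degenerate inputs

- All randomness flows through `numpy.random.Generator` seeded explicitly;
  child seeds come from a stable blake2b hash and stay below 2^31.
- Polygon intersection is exact (shapely); the rasterization estimator used
  to cross-check it counts filled pixels on a 2000x2000 grid and agrees
  within 1% for non-sliver intersections.
- Blank images raise a detection/no-figure error, mirroring the manual
  filter for forms without a drawing; in batch scoring the proxy assigns
  the maximal-penalty floor instead of raising.
- Drawings with fewer than two resolvable figures (including near-coincident
  pairs at distance ~0) report overlap as undefined and are scored with the
  maximal overlap penalty.
- Monotonicity/unimodality reports judge each level-to-level difference at
  the replicate noise floor: it must exceed both 1% of the median range and
  the larger of the two adjacent levels' MADs — the dispersion actually
  underlying those two medians (with 20 replicates the sampling noise of a
  median is of the order of the MAD). MAD is unscaled (no 1.4826 factor).
- Problem sizes in the verification scripts (100 geometry pairs, 200
  round-trip images, 8x20 sweep replicates, 1000 DeLong null replicates at
  n = 200, 500-participant cohorts, 50 cohort replicates at n = 300) are
  package defaults chosen to make each check statistically meaningful at
  interactive runtimes.

## Known limitations

- The figure-splitting heuristic assumes the side-by-side stimulus layout;
  heavily rotated scans should be deskewed upstream (rotation augmentation
  at ±15° is fine).
- Vertex counting degrades above waviness ~0.03; this matches the intended
  regime (the sweep explores beyond it only to show score degradation).
- The proxy scorer's weights are a design artifact; its absolute values are
  meaningless outside the package, only response *shapes* are.
- The learned object detector of deployed pipelines is replaced by a
  contour-based reference detector behind the same interface.
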