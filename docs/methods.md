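# Methods

## Problem and data model

Quantitative light-induced fluorescence (QLF) images the maxillary central
incisors under ~405 nm light through a long-pass filter; hypomineralized
enamel fluoresces less, so fluorosis appears as diffuse darkening of the
green channel. The analysis substrate is an 8-bit RGB capture plus a
per-tooth binary mask (labelled raster, 1 = UR1, 2 = UL1) drawn with a
region-of-interest tool; all analysis is restricted to the mask. Only the
green channel is used. Coordinates are 0-based, x = column rightward,
y = row downward (gingival side at the image top). Higher bit depths and
indexed images are rejected rather than silently rescaled.

No pixel pitch is attached to the data model by default; when
`mm_per_pixel` is absent the blur technique reports lesion area in pixels
and flags the unit rather than inventing a scale.

## Unsharp-mask technique

"Blur at 30 pixels" is interpreted as a square mean-filter window of
30×30 px — the most literal reading of averaging within a matrix of
pre-determined size — with the window side configurable
(`BlurParams.blur_size_px`). Even-sized windows anchor the extra
row/column down/right. The filter is **mask-aware** by default: windows
are renormalized by the in-mask pixel count, because including the dark
background in edge windows would manufacture spurious "loss" along the
entire tooth outline.

Loss is `max(0, blur − original)`: the blur is the sound-area control, and
brighter-than-blur pixels clamp to zero (no negative fluorosis). The
selection rule classes as lesion the in-mask pixels whose loss exceeds
`base_mean + k_sd × base_SD` (default `k_sd = 2`), where the base level is
the loss-map mean/SD over the automatically selected reference area. If
the base SD is exactly zero the rule degenerates to "above the base mean",
documented here as the deliberate limit behaviour.

ΔF_blur is the mean percentage loss relative to the **local** blurred
estimate. The original clinical software's internal ΔF scale (~2.3 in the
published descriptives) is not reconstructible from its description; this
implementation's percent-of-local-brightness definition is the package's
own, self-consistent scale. ΔQ_blur = ΔF_blur × Area_blur exactly, by
construction.

Known, intended behaviour: with lesions wider than the blur window the
blurred "sound" estimate sinks into the lesion, so ΔF/Area saturate and
under-read at high severity. This is a property of the technique, not a
defect, and is why area-monotonicity under growing injected lesions is
asserted only for the hull technique.

## Reference-area selection

The original operator-chosen reference area is replaced by an automatic
rule: a gingival anchor point is placed at the horizontal midpoint of the
two mask centroids, offset above the higher mask top edge by 0.25 of the
mean mask height (clamped to the frame); from it a ray is cast through
each tooth's centroid, and the 9×9 window centred on that ray, lying in
the incisal half of the mask and fully inside it, with the **brightest
median** green value becomes that tooth's reference patch (ties: smallest
y, then x). Brightest-median rather than brightest-pixel resists specular
highlights; preferring bright windows steers the patch away from lesions.
The offset fraction and patch size are configuration, since the source
description quantifies neither. Anchoring the blur technique's base level
to this patch is this package's interpretation of how the automatic
reference feeds the selection rule.

Exclusion rules mirror the clinical workflow: a capture is analyzable only
when both incisor masks exist and the horizontal bounding-box gap between
them (the diastema) is at most 5% of the image width by default — the
threshold is configurable because no numeric criterion was ever published.
Excluded subjects are kept in outputs with their reason, for audit.

## Convex-hull technique

After grayscale morphological opening (disk radius 1 by default; the
original structuring element is unstated) the in-mask pixels form the 3-D
point cloud {(x, y, g)}. Its convex hull is computed with
Quickhull (scipy/qhull). Only the **upper** facets — outward normal with
positive brightness component — are rendered: the upper envelope is what
fills dark areas by interpolation between surrounding sound areas, whereas
lower facets would reconstruct the lesions themselves. Each upper facet is
rasterized over its (x, y) projection by barycentric planar interpolation;
facets are visited in lexicographic vertex order so pixels on shared edges
deterministically take the first facet's value; any pixels missed by
floating-point cracks get the exact minimum over all upper-facet planes.
The result is clipped to the in-mask brightness range and floored at the
input (hard upper-envelope guarantee).

Degenerate inputs: a coplanar cloud (e.g. a planar brightness ramp)
returns the input exactly; collinear pixel sets use a 1-D upper concave
chain; fewer than three pixels is an error. For the opening step,
out-of-mask pixels are pre-filled with their nearest in-mask value so the
tooth outline does not erode toward the dark background.

Hulls are built **per tooth**, so a diastema gap can never become part of
a facet bridging the two incisors.

Thresholding is strictly-below: loss < 5 (of 255) is zeroed, loss = 5 is
retained. ΔF_ch and ΔQ_ch are fractional losses relative to the clean
surface (dimensionless), consistent with the ~0.05 / ~0.01 magnitudes of
the published descriptives; absolute 0–255 differences would be ~10×
larger. ΔQ_ch = Area_ch × ΔF_ch holds to machine precision because both
are computed from the same lesion-pixel sum.

## Synthetic phantoms

The generator emulates what the analysis needs, not photorealism:

* two superellipse (exponent-4) incisor outlines, default 130×90 px in a
  200×300 frame, 4 px apart;
* sound enamel at base brightness 180 plus a strictly concave dome of
  amplitude 18 (brightest mid-tooth) — concave so the upper hull of the
  sound surface is the surface itself;
* a diffuse lesion built by thresholding a Gaussian-filtered white-noise
  field (correlation length 8 px) at the quantile matching the target
  area fraction, then multiplying brightness by (1 − depth) inside;
  realized area/depth are recorded from the actual pixel counts;
* R = 0.32 G, B = 0.18 G (green-dominant fluorescence look), additive
  Gaussian noise of SD 2 (8-bit units), dark background at level 10;
* optional confounders: a deep circular stain patch, a sharp-edged
  demarcated opacity, and a missing tooth — off by default, and no
  classifier attempts to tell them from fluorosis (the methods cannot);
* repeat captures: integer translation, global illumination gain, fresh
  noise; masks translated identically.

What phantoms do **not** model: real enamel texture, specular highlights,
surface curvature/foreshortening, gingival fluorescence, plaque. Passing
tests therefore demonstrate algorithmic correctness and statistical
behaviour under controlled conditions, not clinical accuracy.

One numerical interaction worth recording: on a *curved* sound surface,
8-bit quantization leaves the upper hull fractionally above the integer
staircase, so at threshold 0 most sound pixels carry sub-1/255 "loss".
This is precisely the background noise the 5/255 threshold exists to
remove. Ground-truth-recovery checks at threshold 0 therefore use flat
(gradient-0), noiseless phantoms; all other checks keep the default
gradient and noise.

## Population generator and calibration

Five cooking-water fluoride intervals ([0, .20), [.20, .60), [.60, .90),
[.90, 1.60), 1.60+ ppm; the open top interval samples uniformly up to
3 ppm) with approximately equal subject counts. Per-interval TF scores
come from a discretized normal clipped to 0–7 with the published
per-interval (mean, SD); because rounding and clipping bias the realized
mean upward at low fluoride, the latent mean is root-solved so the
realized discretized mean matches the target exactly. The two incisors'
TF scores are drawn with correlation 0.8 — the true joint distribution is
unreported; this is a flagged assumption.

TF maps to lesion parameters through monotone anchors
TF 0 → (0.00, 0.00), 1 → (0.10, 0.04), 3 → (0.35, 0.08), 5+ → (0.70, 0.15)
(area fraction, depth fraction), linear between — a generator convention
whose magnitudes sit inside the observed metric ranges, exposed as
configuration.

Two rendering modes. `render="images"` writes phantom PNGs + masks and
leaves metrics to the analysis pipeline. `render="metrics"` draws
per-tooth metrics directly from the TF → lesion map plus a measurement
noise model (multiplicative lognormal CV 0.15 plus small additive floors);
this is the substrate for replicate-heavy statistical simulations
(hundreds of populations), where rendering and analyzing tens of
thousands of images would be pointless. The noise level was chosen to be
consistent with the very good repeatability of the imaging chain
(ICC ≈ 0.95 implies measurement SD ≈ 20–25% of between-subject SD), not
fitted to any test. 8% of subjects receive a repeat capture by default
(≈ the 44/553 of the validation study).

## Statistics

* Interval assignment rounds ppm to 2 dp first (the precision of the
  published interval labels), then uses lower-inclusive half-open bins.
* Subject level: TF = max of the two incisors (as published); the metric
  triple comes from the tooth with the larger ΔQ — the analogous max
  rule, an interpretation recorded here, keeping subject-level
  comparisons coherent.
* Spearman's rho with average ranks and the t-approximation p
  (scipy); zero-variance inputs report rho as undefined.
* Interval separation: all 10 unordered pairs by two-sided Mann-Whitney U
  with a simple ×10 Bonferroni correction (the 10-pair family was chosen;
  the published table is symmetric so per-row families are
  indistinguishable). Exact tie-aware enumeration of rank splits when
  both groups have ≤ 8 observations, tie-corrected continuity-corrected
  normal approximation otherwise. Median-centred Levene's test and
  one-way ANOVA are run alongside and the selected path reported — the
  nonparametric route is taken when Levene rejects at 0.05.
* ICC: two-way random-effects, absolute-agreement, single-measure
  (ICC(2,1), via pingouin) as the headline, with the consistency form
  ICC(3,1) alongside; ≥ 5 complete pairs required; zero between-subject
  variance reports NaN.
* ROC: thresholds sweep all observed values with a "metric ≥ threshold"
  rule, trapezoid AUC (equals tie-adjusted U/(n₁n₂) identically),
  operating point by Youden's J with ties resolved to the lower
  threshold. Positives are TF ≥ 3.

## Problem sizes

Default problem sizes were chosen so the whole suite exercises realistic
structure at desk scale: phantoms 200×300 (phantom ladders 140×200,
rendered populations 160×240 with 65%×30% teeth), populations of 30
subjects per interval, 200 replicates for type-I control and 100 for
power, oracle checks on ≤ 12×12 grids where brute force is exact. The
acceptance script renders 150 subjects (~45 repeat pairs, matching the
validation study's n = 44) and finishes in well under a minute.

## Known limitations

* The package cannot reproduce the published clinical coefficients — the
  553-subject image set was never deposited; synthetic correlations are
  higher than clinical ones because phantoms lack confounders by default.
* Differentiating fluorosis from caries, stain and demarcated opacities
  is out of scope (as it is for the source techniques); confounder
  phantoms exist to demonstrate the failure mode, not to fix it.
* The blur technique's metrics depend on the reference-area rule, which
  is an interpretation of an incompletely described automatic algorithm.
* Image capture, color calibration and automatic mask drawing are out of
  scope; masks are inputs.
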