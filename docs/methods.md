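# Methods

This note documents the models behind each stage, the tunable parameters
that matter, the numerical choices, and what the synthetic data does and
does not establish about real micrographs.

## Synthetic populations (`synthgen`)

**Size law.** Diameters are drawn from a lognormal distribution truncated to
[`diam_min`, `diam_max`] = [1, 50] µm, sampled exactly via a truncated normal
on log-diameter. Defaults µ = ln 6.5, σ = 0.6 place the *visible* population
mean (after sedimentation weighting) in the 6–11 µm range typical of
electroformed POPC:cholesterol GUV preparations. Real preparations vary
between electroformations, so these defaults are calibration choices, not
measured constants; the truncation at the defaults removes ≈ 0.2% of the
mass, which is why plain (untruncated) maximum-likelihood fits still recover
µ and σ to within 2% at n = 10 000.

**Contours.** Each vesicle outline is a radial harmonic perturbation
r(θ) = R·(1 + Σ_{k=2..6} a_k cos(kθ + φ_k)), discretized at 256 vertices.
Per-vesicle raw amplitudes decay as 1/k with random phases; a single global
scale on the amplitudes is found by bracketed root finding on the
*numerically evaluated* population mean IPQ (shoelace area, segment-sum
perimeter of the actual polygons), so the mean of `true_ipq` matches
`target_mean_ipq` (default 0.93) to well within ±0.01. The total relative
perturbation is capped at 0.42, keeping every contour star-shaped and
simple. After perturbation each polygon is rescaled so its area equals
π(d/2)² exactly, making `diameter_um` and the contour mutually consistent.

**Sedimentation.** Sucrose-filled vesicles settle into the focal plane with
a Stokes-law speed v(d) = c·d². The probability of being visible after t
minutes is p = 1 − exp(−t·v(d)/H), with chamber depth H = 0.5 mm and
settling coefficient c = 7.4·10⁻⁴ mm·min⁻¹·µm⁻², chosen once so that ≈ 75%
of a default population is visible at 30 min. This reproduces the observed
settling dynamics: visible counts grow by ≈ 3× between 3 and 30 min and by
≈ 1.16× between 30 and 60 min, and larger vesicles appear first (so early
samples are biased large). Per-vesicle settling times are exponential with
rate v(d)/H, the memoryless counterpart of the same model.

**Rendering.** Bright-field appearance: a dark membrane ring with a Gaussian
radial profile (scale `ring_width_px` = 1.5 px, contrast 90 of a background
of 200 on the 8-bit scale), a slightly offset interior (−8), and additive
Gaussian noise (σ = 3). The ring is drawn *interior-tangent*: its centerline
sits at R − `ring_width_px` so its outer edge coincides with the true
contour — a 10 µm vesicle at 0.25 µm/px spans 40 px in the ground-truth
mask. Crystallized-lipid distractors are filled irregular blobs with strong
high-order harmonics; they stay 0 in the ground-truth mask and their deeply
non-convex outlines are what the solidity flag downstream keys on.
Placement uses grid-hashed rejection sampling with ≥ 1 µm membrane
clearance (emulating the dilution used in practice precisely so that
automated segmentation works); populations too dense for clearance
placement (projected fill > 30%) fall back to uniform placement.

**Tracks.** The camera advances along one axis by N(2, 0.5²) px per frame
with N(0, 0.3²) transverse jitter, mirroring manually guided slide motion;
cumulative offsets are rounded to integer pixels and returned as ground
truth. Motion leaving less than 25% frame overlap is rejected.

**Not modeled** (by design): point-spread/defocus optics, Brownian motion
between frames, multilamellar or nested vesicles, membrane fluctuations in
time. Passing tests therefore demonstrate the pipeline's geometric and
statistical correctness, not robustness to optical artifacts of a specific
microscope.

## Stitching (`mosaic`)

Frames are related by pure translation (the rig permits no rotation or
scale). Shifts come from phase correlation: cross-power spectrum normalized
to unit magnitude with a regularization floor of 10⁻⁶ of the mean magnitude
so frequencies carrying negligible energy cannot inject random phase. The
integer peak is mapped to the signed shift of smallest magnitude (ties:
smaller |shift|, then smaller row, then smaller column) and refined per axis
by a quadratic fit through the peak's two neighbors, clamped to ±0.5 px.

Confidence is the correlation peak divided by the absolute sum of the
surface. For an unstructured pair this ratio concentrates around
√(π ln A)/A (A = pixels per frame; e.g. ≈ 1.5·10⁻⁵ at 570×762), which
matches seeded-noise nulls within ~10%; the default retention threshold is
2.5× that null. Below it, a frame inherits the previous per-frame shift
(smooth-motion assumption). Frames moving less than `min_motion_px` = 0.5
are dropped as duplicates — manual guidance produces many near-identical
frames, and dropping them avoids blur accumulation. Retained frames are
placed at integer-rounded cumulative offsets and blended with separable
triangular feather weights; canvas corners no frame reached are filled with
the median composited value so downstream stages see no artificial black
regions. On synthetic 100-frame tracks at default conditions the recovered
cumulative offsets agree with ground truth to ≪ 0.5 px RMS.

Backtracking motion is not special-cased: frames land wherever the
accumulated offsets say, and revisited regions blend by feathering.

## Segmentation (`segmentation`)

**Evidence.** The mosaic background is flattened by subtracting a
large-window median (window 800 px ≈ 4× the largest expected vesicle
diameter; computed on a strided subsample and bilinearly upsampled — the
approximation error is far below ring contrast). Ring evidence is the
gradient magnitude after σ = 1 px Gaussian smoothing, scaled to [0, 1].
This is deliberately insensitive to smooth illumination gradients.

**MRF.** Binary labeling x ∈ {bg, fg} minimizes
E(x) = Σ_i [(y_i − µ_{x_i})²/(2σ²_{x_i}) + ln σ_{x_i}] + β Σ_{i∼j} 1[x_i ≠ x_j]
with class statistics from an Otsu split of the evidence, β = 1.5,
4-connected neighbors, optimized by iterated conditional modes in fixed
row-major raster order from the threshold initialization (ties flip to
background) until no flips or 20 sweeps. The result is deterministic and
invariant to adding a constant to the evidence. β = 0 reduces exactly to the
pointwise maximum-likelihood rule. The inner loop is compiled with numba;
a 4800×762 mosaic segments in ~2 s.

**Closing and filling.** Vesicle interiors resemble background, so they are
claimed by morphology, not by the MRF: dilation by `ring_gap_px` = 2, hole
filling, erosion by the same disk, and a final hole fill. The interleaved
fill keeps a bridged gap closed where plain morphological closing would
re-open the thin bridge; solid regions pass through unchanged, and two
objects more than 2·`ring_gap_px` apart cannot merge.

**Band compensation.** The gradient band straddles the membrane ring and
extends roughly `ring half-width + smoothing` ≈ 3 px beyond the vesicle
boundary on every side, so filled objects are systematically inflated — for
1–4 µm vesicles enough to fail an IoU 0.5 match against ground truth.
A dedicated step erodes every filled object by `band_halfwidth_px` = 3
(objects that would vanish are kept at their uneroded extent). This restores
physical outlines (predicted/true area ratio ≈ 1.01 across sizes) and with
it unbiased diameters. Measured object-level detection F1 on default
synthetic mosaics with ≥ 200 vesicles and distractors: 0.97–0.99 across
seeds.

**Filtering.** Components are labeled 4-connected; effective diameters
outside [1, 50] µm are removed, border-touching components are removed (and
counted — whether such vesicles should count toward chamber quantities is
genuinely open; exclusion is the conservative choice and the rejection
report makes it auditable), and components with solidity < 0.85 are kept
but flagged `clump` — touching vesicles and crystallized lipids are left to
expert correction rather than automatic declumping, matching how the
workflow is used in practice. Survivors are renumbered 1..K in raster order
of centroids, making labeling stable and reproducible.

**Corrections.** Edits (delete, add_polygon, merge, split_polyline) are
applied in order from a JSON edit list; the result is renumbered and marked
`provenance = "corrected"`. A dangling label reference aborts with the edit
index.

## Morphometry (`morphometry`)

The central design decision: area and perimeter both come from the *same*
subpixel polygon, never from pixel counts or boundary-edge counts (which
would inflate a disk's perimeter by ≈ 4/π and cap circular IPQ near 0.785).

The contour is the 0.5 level set (marching squares, linear interpolation) of
the object's indicator after σ = 1 Gaussian smoothing; for objects too small
to survive that smoothing, σ backs off by halving (a 1-px object still
yields a closed polygon). The vertex chain is then smoothed along the
contour with a Gaussian of scale min(0.2·R_eq, 2.5) vertices (≈ px of arc),
which suppresses the pixel-lattice ripple that otherwise biases the
perimeter ≈ +0.5%. Vertex smoothing pulls a curved contour inward by the
curvature bias exp(−σ²/2R²); the polygon is rescaled about its centroid by
the exact inverse factor (exact for circles, conservative for near-circular
outlines). Anchors measured by the final estimator: disk r = 200 px →
IPQ 0.999; square → 0.792 (π/4 ≈ 0.785); 2:1 ellipse → 0.8405 (0.8412 by
elliptic-integral quadrature); disk diameters within 1% down to r = 5 px;
IPQ scale-invariant to < 0.005 for radii ≥ 20 px.

IPQ values marginally above 1 from discretization are reported as-is (the
isoperimetric inequality is asserted with ε = 0.01); clamping would bias
distributions. Objects below 4 px effective diameter are measured but
flagged `unreliable`. Raw pixel areas are kept alongside polygon areas for
audit.

## Population statistics (`popstats`)

One chamber sample pools its (typically two) tracks' records. Sample
summaries count accepted, non-flagged records (`clump`/`unreliable` objects
await review) and use sample (n − 1) standard deviations — chamber counts
are small (4–8). Population summaries aggregate *chamber means* (not pooled
vesicles), because the repeatability statistic explicitly measures
between-chamber variation; RSD = 100·σ/µ is rounded half-up to integer
percent, and settling ratios are reported to 1 decimal, both matching how
such tables are conventionally printed. Lognormal fitting is the exact ML
estimator on logs (mean, ddof = 0 std). Histograms use half-open bins
[e_i, e_{i+1}); box statistics use linear-interpolation quartiles.

`reference.py` carries the published chamber-repeatability benchmark for
electroformed GUV populations (three experiments, 4–8 chambers, 3–60 min).
Recomputing RSDs from its printed mean ± std cells reproduces the printed
integers for the self-consistent rows; two diameter rows and one quantity
row disagree by one point, presumably because the printed RSDs were derived
from unrounded chamber means. The bound claims hold as printed: the maximum
unrounded quantity RSD is 7.97 < 8%, and the maximum IPQ RSD at the table's
integer precision is 2%.

## Problem sizes in the tests

The test suite and acceptance checks run on deliberately desk-scale
problems: 4800×762 px synthetic mosaics with ~260 vesicles (a full-scale
20 000×762 mosaic is the same computation, ~4× longer), 100-frame tracks
for stitching accuracy, and 10 000-vesicle populations for parameter
recovery. These sizes make every check reproducible in seconds to minutes
on a single core while exercising identical code paths.

## Known limitations

- The MRF segmenter is a designed equivalent of the published approach (the
  original's exact energy and optimizer are not public); graph-cut
  optimization of the identical energy would be a valid drop-in.
- Touching vesicles are flagged, not split; quantities in heavily clumped
  scenes depend on expert edits.
- The renderer's idealized optics mean segmentation performance numbers on
  synthetic data are an upper bound for real micrographs with defocus and
  debris.
- Exact numerical agreement of IPQ with the original software is not
  claimable (its perimeter estimator is unspecified); the reported 0.92–0.99
  range is consistent with a subpixel estimator like this one.
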