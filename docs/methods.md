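# Methods

## Feature model

The descriptor of a region is the vector of higher-order local
autocorrelations (HLAC) of the preprocessed intensity field, up to second
order within a 3×3 window. A *mask* is a multiset of offsets containing
the window center; its raw feature over a region is the sum over centers
of the product of the pixel values at the offset positions. Masks that
are whole-pattern translations of each other measure the same
shift-invariant statistic and are identified; the canonical
representative is the lexicographically smallest in-window translation
that keeps the center in the multiset. Enumeration yields 35 classes for
orders 0–2; removing the 10 classes in which some pixel appears with
multiplicity ≥ 2 (squares and cubes in the product) leaves the 25-mask
working set, grouped 1 (order 0) / 4 (order 1) / 20 (order 2). The
order-1 group has exactly 4 members because the 8 neighbor offsets pair
up under translation equivalence ((0,0)–(1,0) ≡ (−1,0)–(0,0)); no
rotation or reflection reduction is applied, since that would not
reproduce the 35/25 counts. The mask-to-number assignment within a group
is this package's own stable ordering (ascending order, then
lexicographic canonical form); descriptors are only ever compared with
descriptors produced by the same ordering.

## Semantics and exactness

The per-center product map f(r) is defined where the full 3×3 window
fits inside the image — uniformly for all masks, including order 0 — and
is zero on the one-pixel border. A region sum counts every center inside
the region, with neighborhoods drawn from the full image. These
conventions make the direct path and the integral-table path bit
identical: each mask's f-map is accumulated into a summed-area table with
a zero guard row/column, and any rectangle's raw feature is four corner
reads per mask. Tables store exact int64; the largest possible cumulative
value (255³ per center) stays below 2⁶³ for images up to roughly
4.5 gigapixels, far beyond the intended frame sizes, so "equal" in tests
means strict integer equality, not a tolerance. Regions are half-open
[x, x+w) × [y, y+h) in 0-based x=column, y=row coordinates.

Normalization divides each raw feature by the region's pixel count
n = w·h (not by the count of valid centers). For a region flush with the
image boundary the border centers contribute zero but still enter n,
biasing the normalized features low — by a factor (w−2)(h−2)/(wh) on the
order-0 component, e.g. ≈5% for an 80×80 whole-frame query, which is the
same magnitude as the order-0 image-selection threshold (5). The
high-level query path therefore insets the query region by one pixel on
each edge that lies on the query image's boundary, so every counted
center has a valid neighborhood; interior regions are never modified, and
candidate regions in target images are left as enumerated (candidates
flush with a target border are rare and only mildly penalized).

## Preprocessing

Specular highlights are pixels whose value channel max(R,G,B) ≥ 240
(8-bit), dilated by a square of radius 2 to cover blob fringes; both
parameters are configurable. The marked pixels are filled by biharmonic
inpainting — a deterministic boundary-interpolating fill; unmasked pixels
pass through unchanged. Saturation is computed as
round(255·(max−min)/max), zero for black pixels, giving an 8-bit channel
on which the similarity thresholds below are meaningful. An optional
field-of-view mask can zero the black corners outside an endoscope's
circular image; the default is the full frame.

## Retrieval

Candidate sizes span ±10% (`scale_range_pct`) of the query size in 1 px
steps (`size_step_px`) on the query's longer axis; the shorter axis
follows by the same scale factor, so aspect ratio is preserved and the
size grid stays one-dimensional. Positions lie on a `position_stride_px`
(default 10) grid anchored at the origin. For a 400×300 target and a
100×100 query with 1 px position stride this enumerates exactly
Σ_{s=90..110}(401−s)(301−s) = 1,271,291 regions, which the test suite
checks both in closed form and by generation.

Selection runs in three stages on normalized features (all thresholds on
the 8-bit intensity scale):

- **Area selection** (per target image): a candidate survives if its
  |mean − query mean| is strictly below `area_sim_threshold` (20) *and*
  within the best `area_rank_fraction` (10%) of that image's candidates,
  ties at the rank cutoff kept. Requiring both is what makes the first
  stage aggressive; either alone would barely prune. Only the order-0
  table is touched, at four reads per candidate.
- **Image selection**: per image, the best candidate's distance on the
  order-0 component must be < `stage0_threshold` (5); for surviving
  images, the best distance over the four order-1 components must be
  < `stage1_threshold` (50); failing images are dropped with all their
  candidates.
- **Final ranking**: full 25-component Euclidean distance; each image is
  represented by its best candidate; images are ranked ascending by that
  distance. Ties break by (image id, y, x, w, h), so output is fully
  deterministic.

The stage partition (order-0 alone, then the order-1 quartet, then all
25) mirrors the coarse-to-fine narrative of the selection design; the
component subsets are configurable. Defaults reproduce the standard
operating point (±10%, 10 px shift, thresholds 20 / top-10% / 5 / 50).

Cost accounting: every table access in `region_features` and the staged
selectors increments a per-image read counter, so the claim "four reads
per mask regardless of region area" is asserted by counting, not timing.

## Synthetic scenes

The generator emulates a heterogeneous endoscopy image database in the
channel the method actually sees. Per-seed draws, at the default 800×600
frame:

- base saturation U(70, 130) — mild to severe inflammation differs
  grossly in mean saturation;
- band-limited noise: Gaussian-filtered white noise, σ U(8, 16) px,
  amplitude U(5, 9);
- haustral folds: a directional cosine ridge field, amplitude U(6, 14),
  wavelength U(25, 80) px, uniform random orientation, phase-warped by a
  smooth field (σ 30 px) — the dominant macro-texture signature that
  distinguishes frames;
- one soft-edged elliptical lesion, 260–380 px per axis, saturation
  contrast U(25, 55) (straddling the area-selection threshold of 20),
  fading over the outer 15% of its radius, placed uniformly with a 20 px
  margin;
- reddish hue (≈0.01–0.06) and high value (≈0.85) with mild jitter.

For smaller canvases, all length-type draws (σ, fold wavelength, object
size) shrink proportionally. Quasi-image queries crop the lesion's
bounding box and rescale it bilinearly, with a low-pass filter before
minification as camera optics would apply; scale 1 is an exact crop.

What the scenes deliberately reproduce: heterogeneous first moments,
scene-specific directional second/third-order texture statistics, soft
lesion boundaries, lesion size large relative to the 10 px position
stride (as in the intended clinical geometry, where query objects are a
few hundred pixels in an 800×600 frame). What they do not reproduce:
depth and perspective, vignetting and uneven illumination, wet-surface
specularity statistics, tilt/rotation of the lesion (the method is not
rotation invariant), or the long-tailed appearance variety of real
mucosa. Passing the synthetic experiments therefore demonstrates the
geometric/multiscale machinery, not clinical retrieval quality.

## Experiment sizes and measured behavior

- Multiscale recovery: 30 trials (10 seeded 3-frame databases × scales
  0.9/1.0/1.1), full 800×600 geometry; the test requires the source frame
  at rank 1 with IoU ≥ 0.7 in ≥ 90% of trials. The frame count and scale
  set follow the quasi-image experiment design; the trial count and IoU
  bar are the package's quantitative stand-in for a visual judgment.
- Database pruning: one 20-frame database, verbatim-crop query; survivor
  counts must be non-increasing stage to stage and area selection must
  remove > 50% of candidates (measured ≈93%).
- A 25-moment descriptor of smooth textures concentrates near a
  one-dimensional manifold parametrized by the region mean (the order-k
  components scale like meanᵏ⁺¹), so with millions of candidates a wrong
  frame can coincidentally approach a query about as closely as the true
  region's best grid-aligned candidate (offset ≤ 5 px at stride 10).
  Measured over seeded 21-frame databases the source frame ranked
  1,2,1,1,1,2 — reliably in the top 3 (which is the granularity at which
  many-image retrieval results are meaningfully read), not guaranteed
  rank 1. The suite asserts top-3 membership plus IoU ≥ 0.7 localization
  within the source frame; rank-1 is asserted only for the 3-frame
  recovery experiment above.

## Known limitations

- No rotation or tilt invariance: a rotated lesion is a different
  pattern to every order-1/2 mask.
- Euclidean distance over unwhitened components is dominated by the
  order-2 features (≈ mean³ in magnitude); the stage thresholds are
  calibrated for 8-bit saturation inputs and would need rescaling for
  any other intensity convention.
- The candidate grid is anchored at the origin; true regions are
  recovered up to the position stride and the ±10% size grid.
- Indexes store 25 int64 tables of (W+1)×(H+1) per image (≈96 MB for
  800×600), traded deliberately for exactness and O(1) lookups.
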