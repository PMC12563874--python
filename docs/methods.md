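# Methods

## Problem and model

Single-tooth implant planning on a dental panoramic radiograph (DPR)
starts from the two teeth adjacent to the edentulous gap.  Clinically,
the insertion direction is chosen relative to the angulation of those
neighbours: a pathway that splits the angle between them stays clear of
both roots and centers the implant in the mesiodistal corridor.

`implantpath` formalizes this.  Each adjacent tooth is an oriented
bounding box (OBB) — center `(cx, cy)`, side lengths `(w, h)`, rotation
`θ` — as produced by any oriented-box detector.  From each box we take
the *long axis* (the line through the center along the greater extent)
and the two *lateral edge lines* parallel to it at offset
`short_side/2`.  Auxiliary lines for the gap are the two gap-facing
lateral edges (default) or the two long axes.  Writing the auxiliary
lines in implicit form `A₁x + B₁y + C₁ = 0`, `A₂x + B₂y + C₂ = 0`, the
candidate pathways are the two solutions of the bisector equation

    (A₁x + B₁y + C₁)/√(A₁²+B₁²) = ± (A₂x + B₂y + C₂)/√(A₂²+B₂²)

which on canonical (unit-normal) lines are simply `n₁ − n₂` and
`n₁ + n₂`.  The two branches are mutually perpendicular; the **internal**
bisector is the one whose direction lies inside the wedge (span < 90°)
spanned by the two tooth axis directions.  Its direction angle and its
intersection with the crest segment (joining the coronal corners of the
gap-facing edges) are the pathway's angle and entry point.

### Conventions

- Image coordinates: 0-based, y-down, pixel centers at integer
  coordinates.  All modules share this.
- Angles: degrees, counter-clockwise from the image x-axis, reduced
  mod 180 wherever only a direction matters.  `θ ∈ [0, 180)`; at `θ = 0`
  the `w` side runs along x.
- Lines are canonical: `A² + B² = 1` and `A > 0` (or `A = 0, B > 0`).
  This makes `Ax + By + C` a true signed distance, makes equality
  testing deterministic, and fixes the ± branch bookkeeping.

### Choices where the procedure was genuinely open

- **Which lines feed the bisector.**  Both the long axes and the
  edge-hugging auxiliary segments are defensible readings of the
  clinical drawings.  The default is the gap-facing lateral edge lines,
  because they bound the corridor the implant must clear; a
  `use_edges=False` switch selects the central long axes.  Since every
  auxiliary line is parallel to its tooth's axis, the two readings give
  the *same direction* and differ only in the pathway's position.
- **Parallel teeth.**  Perfectly parallel neighbours make the bisector
  pair degenerate.  The midline between the auxiliary lines is returned
  instead, flagged as `parallel_fallback`, rather than failing — near-
  parallel neighbours are the common clinical case.
- **Square boxes.**  `w = h` makes "long axis" ill-defined; the h-side
  axis is used and a warning emitted.
- **90° wedge.**  Both bisector branches then touch the wedge boundary;
  the branch closer to vertical is taken (teeth are roughly vertical in
  a DPR crop), with a warning.
- **Entry point.**  Defined as the intersection of the pathway with the
  line through the two coronal corners of the gap-facing edges.  The
  coronal end defaults to the smaller-y end (`crest="up"`, crowns toward
  the top of the crop); `crest="down"` covers maxillary crops oriented
  the other way.

## Enhancement stack

DPR crops are low-contrast and noisy, which degrades oriented-box
detection; the package reproduces the enhancement pipeline used upstream
of the detector.

- **Bilateral filter.**  Each output pixel is the normalized
  double-Gaussian weighted mean of its window: spatial weight
  `exp(−d²/2σ_s²)`, intensity weight `exp(−Δf²/2σ_r²)`.  Discretized on
  a window of radius `ceil(3σ_s)` (>99% of the spatial kernel mass),
  mirror padding at borders.  Defaults `σ_s = 3 px`, `σ_r = 30` gray
  levels — mid-range values that smooth film grain without flattening
  enamel edges; both overridable.  The vectorized implementation is
  verified against a naive per-pixel double loop.
- **Histogram equalization.**  The plain CDF remap
  `s_k = (L−1)·CDF(r_k)` with `L = 256`, round-half-up.  Note this maps
  a constant image to 255 (its CDF is 1 at the single occupied level);
  no `cdf_min` rescaling is applied.
- **HE:BF compositing.**  The composite that works best for detection is
  3:7 (HE weight 0.3).  Two readings of "blending at varying degrees"
  are shipped: per-pixel convex combination (default) and dataset-
  proportion mixing (30% of images equalized, 70% bilateral-filtered),
  selectable via `--mode` on the CLI.
- **Augmentation.**  Brightness is a multiplicative scale `(1 + p/100)`
  with `p ∈ [−25, 25]`; exposure is a gamma-style power transform with
  exponent `(1 − p/100)`, `p ∈ [−15, 15]`; noise adds Gaussian noise
  with `σ = |p|% of 255`, `p ∈ [−15, 15]`.  The operator forms are this
  package's choices — only the percentage ranges are prescribed — and
  augmentation doubles a dataset (originals plus one randomized variant
  each), seeded for reproducibility.
- **Rounding.**  All intensity outputs use round-half-up then clip to
  [0, 255], so results are bit-reproducible across platforms.

## Evaluation

- **Rotated IoU** is the exact convex-polygon intersection-over-union
  (via polygon clipping); it reduces to the familiar axis-aligned IoU at
  `θ = 0`.  The test suite checks it against an independent
  Sutherland–Hodgman clipper.
- **Matching** is greedy one-to-one in descending confidence at an IoU
  threshold (default 0.5); IoU ties break by ground-truth index.  True
  negatives are undefined for open-image detection, so `TN = 0` and the
  reported "accuracy" `(TP+TN)/(TP+TN+FP+FN)` degenerates to
  `TP/(TP+FP+FN)`.
- **AP/mAP50** uses the all-points (continuous) precision-envelope
  integral by default; 11-point interpolation is available.  Metrics
  with empty denominators return `None` rather than raising.
- **Angular deviation** between a predicted pathway and a reference line
  is the unsigned angle in [0°, 90°]; the summary statistic is the plain
  arithmetic mean over images (the field sometimes labels this "MSE"
  even though the printed values are degrees, not squared degrees).

## Synthetic scenes

The generator emulates exactly the structure the pathway algorithm
consumes: two bright tooth-like shapes with known long-axis angles
flanking a darker gap, on a noisy low-contrast background.  Teeth are
rotated rounded rectangles with a mild root taper (root width 75% of
crown width, elliptical end caps) inside their labeled OBB.  Default
intensity model: background 60, teeth 160 with ±10% per-scene contrast
jitter, additive Gaussian noise σ = 5 (σ = 10 for the stress
conditions); default geometry 224×160 px, tooth 90×34 px, 40 px gap,
long-axis angles drawn uniformly from [70°, 110°].  Every scene carries
its exact OBB labels and the analytic pathway, so labels → pathway must
agree to machine precision and images → threshold → minimum-area-
rectangle fit → pathway can be scored against truth.

What the generator does **not** emulate: real root/crown morphology,
overlapping anatomy (sinus, canal, cervical spine shadow), intensity
gradients across the arch, blur, or detector-specific failure modes.
Passing the synthetic recovery tests therefore demonstrates the
geometric pipeline is correct and noise-tolerant, not that any detector
reaches clinical accuracy on real DPRs.

A note on the noise-degradation check: with the prescribed estimator
(midway threshold + minimum-area-rectangle fit), the binary mask is
essentially unchanged until the noise σ approaches the 50-level
threshold margin, so over σ ∈ {0, 5, 10, 20} the noise-induced error
(±0.02°) sits below the σ-independent rasterization bias of the
rectangle fit (≈0.4° mean).  The degradation test therefore uses a
paired design (same scene geometries at every σ) and asserts
non-decreasing means within one standard error, not a strict increase.

## Problem sizes

The test suite and the acceptance script use 200 synthetic scenes for
recovery statistics, 10,000 random line pairs for the bisector
properties, 10,000 random box pairs for the IoU cross-check, and
16×16 images for the brute-force bilateral comparisons (the naive oracle
is quadratic in window size); these sizes give stable statistics while
keeping a full run under a minute on one core.

## Known limitations

- Strictly 2-D: no buccolingual angulation, no bone depth/density — a
  DPR carries no volumetric information.
- Single-tooth gaps with two usable neighbours only; multi-tooth spans
  are out of scope.
- The detector is a pluggable boundary: the package consumes its label
  format and does not train or run one.  The threshold-and-fit
  "detector" used on synthetic scenes is a stand-in for pipeline
  testing, not a detection method.
- The entry point depends on the crest-side convention; crops oriented
  contrary to the `crest` setting will place it at the wrong end (the
  direction is unaffected).
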