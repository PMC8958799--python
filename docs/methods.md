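# Methods

## The measurement model

A plate time-lapse is a stack of co-registered grayscale frames of one
Petri dish, one frame per `frame_interval_h` (default 1 h), with a fixed
spatial calibration `scale_px_per_mm` (default 58.4 px/mm, a typical value
for a full-frame camera imaging a small square dish). Seeds are assumed
sown in a known `rows × cols` grid; the medium is dark (charcoal agar) so
seeds and roots are bright foreground on a dark background.

The pipeline is a chain of pure functions of (frames, configuration,
seeds):

1. **Seed segmentation** of the first frame, where only ungerminated seeds
   are present, gives one connected component per seed. Components are
   labelled `(row, col)` by sorting centroids row-major; a count mismatch
   falls back to snapping onto a lattice inferred from the centroid
   extremes, flagging unmatched cells `lost`.
2. **Root segmentation** of every frame feeds **bounding-box tracking**:
   each instance's box becomes the union of its previous box and the tight
   boxes of root components intersecting it (within a margin), so boxes
   expand monotonically with the root. Components claimed by two
   instances, or intersecting boxes, mark both instances *overlapped* —
   irreversibly, because from that hour pixel ownership is ambiguous.
3. **Length measurement**: inside each instance's box, the frame-0 seed
   body (dilated by `seed_dilate_px`) is masked out and the remaining root
   pixels are skeletonized; length is the geodesic step count (1 per
   4-neighbor step, √2 per diagonal) over all fragments, divided by the
   scale. Geodesic weights keep diagonal (curling, agravitropic) roots
   unbiased; raw pixel counting would underestimate a 45° root by ~29%.
4. **Germination** is estimated from the instance's foreground area in
   excess of its dry-seed baseline (see below).
5. **Growth rate** is the OLS slope of length vs time from the first frame
   with measurable length to `min(first overlap − 1 frame, last frame)`.
   Windows with fewer than 3 samples leave the rate undefined (recorded,
   not raised).
6. **Genotype comparison** pools per-seed rates by genotype: Shapiro-Wilk
   normality (warn-only at α = 0.05), one-way ANOVA, Tukey HSD, and a
   compact letter display by insertion-absorption, verified against the
   pairwise matrix.

## Germination timing from excess area

A length threshold (`detect_germination`: length ≥ 0.25 mm sustained for
2 frames) is provided and robust, but is structurally late by roughly
`0.25 mm / rate` — over 8 h for a root elongating at 0.03 mm/h — because
the radicle must first clear the masked seed body and then accumulate
threshold length. Timing germination to about one frame needs the earliest
available signal: the first foreground pixels in excess of the dry-seed
area. `estimate_germination_from_area` detects the first persistent excess
(≥ 3 px for 2 frames), fits a line to the next ~6 frames of excess area —
which grows at `width · rate · scale` px/h once the tip is clear — and
back-extrapolates to zero excess. That zero crossing dates *emergence*;
germination precedes it by the tip's traverse of the seed half-height,
`(seed_semi − width/2) · width / slope` hours, with `seed_semi` measured
from the instance's own first-frame box. The area series is trusted only
strictly before the overlap hour, since afterwards the box admits the
neighbor's pixels (otherwise a never-germinating seed would appear to
germinate when a neighbor's root reaches it). On synthetic plates this
estimator is unbiased to ~0.2 h across elongation rates 0.03–0.17 mm/h.

The growth-rate fit starts at the first frame with length above
`min_fit_length_mm` (default 0.2 mm) rather than at the germination hour:
measured length is exactly zero, then briefly sub-linear, while the
radicle is still partly hidden behind the masked seed body, and including
that transient biases the slope downward.

## Segmentation backends

*Classical* (default): Gaussian smoothing (σ = 0.5 px), then an isodata
threshold — iterate `t ← (mean_fg + mean_bg)/2` from the intensity-range
midpoint — followed by a ≥ 5 px component-size filter. Seeding isodata at
the range midpoint rather than a histogram-shape criterion matters when
foreground is a fraction of a percent of the frame: Otsu then splits the
background noise mode instead of separating foreground. A contrast guard
(< 40 gray levels between class means) returns an empty mask on blank
frames. Morphological opening is available (`open_radius`) but off by
default: with roots only ~3 px wide it clips tips and costs more accuracy
than it adds; at coarser root calibers it can be re-enabled.

*Learned*: a logistic pixel classifier (scikit-learn SGD, log loss) over
three per-pixel features (raw intensity, Gaussian σ = 1, σ = 2), trained
by seeded epochs on balanced pixel subsamples, thresholded at 0.5.
Inference follows the patch contract: 256 × 256 tiles (edge-reflection
padding, bit-exact stitch-back), and for the seed target an optional
block-average downsample (default factor 8, i.e. 256 → 32) with
nearest-neighbor upsampling — locating seeds does not need full
resolution, provided seeds span roughly 8 px or more at full scale; at the
reduced desk scale used in the tests the factor is left at 1. Training is
deterministic given `rng_seed` (hashable weights), records per-epoch log
loss, and takes seconds at desk scale. The classical backend doubles as an
independent oracle for the learned one; on synthetic frames their masks
agree to F1 ≥ 0.95.

## The synthetic plate generator

`synthetic.generate_plate_series` renders what the downstream stages
assume and nothing more: filled-ellipse seeds (~0.45 × 0.30 mm), roots as
constant-width round-capped tubes swept along an incrementally extended
polyline starting at the seed centroid. Heading starts straight down;
per-step Gaussian perturbations scaled by `curl` produce agravitropic
curling (`curl = 0` is exactly vertical). Intensities are 180 ± noise on
30 ± noise (8-bit), emulating bright tissue on charcoal agar. Drift, when
enabled, is a rigid per-seed translation along a random direction
(agar-shrinkage displacement). Truth records carry per-frame polylines,
arc lengths (exactly `rate · (t − germ_h)` until a root reaches the canvas
edge and stops), and the first hour at which two seeds' 1-px-dilated
footprints intersect (brute-force pixel test, pair-pruned by bounding
boxes). One seeded RNG drives everything: per-seed draws are consumed in
row-major order, per-seed path noise and per-frame intensity noise use
deterministically spawned substreams, so identical configs are
bit-identical.

Defaults are one plate of a germination assay under standard conditions:
8 × 8 seeds at 10 mm pitch, 96 hourly frames (four days), germination
probability 0.95 with delays uniform on 0–24 h, elongation rates uniform
on 0.10–0.17 mm/h (the wild-type range across the mutant-comparison
tables; mutant-like rates down to 0.03 mm/h are exercised explicitly in
the recovery tests), `curl = 0` (wild type is gravitropic), drift 0,
noise SD 8. What the generator does **not** model — photoreal agar
texture, condensation, cotyledons/hypocotyls, contamination, illumination
gradients — bounds what passing tests show: they validate the geometry and
statistics of the pipeline, not its robustness to real-world imaging
artifacts, which is what the learned backend and labeled real frames are
for.

## Problem sizes and numerical choices

Synthetic validation runs use 12 px/mm (a 64-seed plate is then
~1180 × 960 px; 96 frames analyze in well under a minute), root width
3 px, and the generator defaults above. At these conditions the pipeline
recovers per-seed growth rates with cohort MAPE below 1% (worst seed
< 5%), germination hours within ±1 frame for > 95% of seeds, exact
germination indices, and overlap hours within ±1 frame of truth.

Other fixed choices: boxes are 0-based half-open `(x0, y0, x1, y1)` with y
down; connectivity is 8-connected everywhere (roots are thin diagonal
structures); the tracking claim margin is expressed physically
(`margin_mm = 0.09`, ≈ 5 px at 58.4 px/mm) and converted per plate so
overlap timing does not degrade at reduced scales; a never-germinated
instance claiming nothing for 3 consecutive frames is `lost` (seed
drifted); ANOVA on all-equal data returns F = 0, p = 1 rather than NaN;
Tukey p-values come from `scipy.stats.tukey_hsd`; the letter display is
minimal (no letter deletable without breaking the sharing rule — checked
by brute force in the tests for up to 6 groups). CSVs carry a
schema-version header and write floats with `%.17g` so re-runs are
byte-identical and reads round-trip exactly.

For the focus-stack module, sharpness is the local variance (9 px window)
of the Laplacian response; any monotone sharpness functional with the
blur-ordering property would serve. Depth validity requires best
sharpness above `max(1e-6, P95 of a flat-field calibration)`; a
single-slice stack is all-valid at height 0. The surface mesh triangulates
each quad of four valid ROI pixels into two triangles ((w−1)(h−1)·2 for a
full grid), with vertices in mm stored as float32 so binary PLY output
round-trips bit-identically. Note the acquisition-rate caveat for
profilometry of living roots: surface dynamics must be slower than the
time needed to acquire one full stack, or the depth map mixes states.

## Known limitations

- Crossing roots are not disambiguated at the centerline level; once two
  roots overlap, both measurement windows close permanently.
- Lost seeds are not re-identified if they reappear.
- Skeleton length inherits ±1–2 px end effects from thinning; lengths are
  accurate to ~2 px/scale and slopes are essentially unaffected.
- The learned backend is a per-pixel classifier over intensity features;
  it has no shape prior and will not separate touching objects that a
  trained encoder-decoder might.
- Statistics pool seeds across replicate plates (no plate random effect);
  repeated-measures structure across hourly timepoints is not modelled.
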