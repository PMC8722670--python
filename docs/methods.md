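# Methods

This note documents the models and procedures implemented in `gazescan`,
the parameters that matter, the numerical choices, and what the
synthetic-data tests do and do not demonstrate.

## Velocity-encoded scanpath rendering

A gaze recording is a sequence of POG samples `(t_i, x_i, y_i, valid_i)`
with strictly increasing timestamps, coordinates in screen pixels with a
bottom-left origin, and a validity flag marking track loss (blinks,
missing or off-screen coordinates).  For each pair of *raw-adjacent*
valid samples the gaze speed is

    v_i = sqrt((x_{i+1} − x_i)² + (y_{i+1} − y_i)²) / (t_{i+1} − t_i)   [px/ms]

Transitions that span an invalid sample are omitted everywhere: a blink
must never be interpolated as a fast movement, so no stroke is drawn
and no speed is emitted across a gap.

**Clipping.**  The implied displacement per transition is capped at a
quarter of the screen diagonal (`sqrt(W² + H²)/4`, ≈ 409.8 px on a
1280×1024 screen); a transition exceeding the cap has its speed rescaled
as if the displacement were exactly the bound, with Δt unchanged.
Single-step movements beyond that bound are not physiological for
screen-viewing, so they are treated as tracker artefacts in the
*dynamics*; drawn positions are left as recorded.  Clipping is
idempotent.

**Segmentation.**  The valid samples of a recording are partitioned
into consecutive, non-overlapping runs of at most `max_points = 200`
samples; a trailing run shorter than `min_points = 20` is dropped.  Each
run becomes one image, so every image carries a comparable amount of
scanpath.  At 250 Hz a segment spans 0.8 s, typically two to four
fixation/saccade cycles.

**Gray mapping.**  Speeds are normalised by the largest speed the clip
bound allows at the nominal sampling interval, `v_max = clip_bound /
(1000/rate)` (≈ 102.45 px/ms at 250 Hz), and mapped linearly to
intensity `1 − 0.9·min(v/v_max, 1)`: still gaze renders white (1.0),
movement at or beyond the bound renders at the floor `g_min = 0.1`, so
every stroke stays visible on the black background.  Whether slow maps
to bright or dark is an arbitrary orientation; `invert_gray` flips it,
and the mapping is monotone either way.

**Rasterisation.**  Screen coordinates are scaled to the raster
(default 640×480), strokes are drawn with an integer Bresenham line
(1 px, no anti-aliasing), overlaps keep the maximum intensity, and the
raster is vertically mirrored exactly once (data space is bottom-up,
rasters are top-down).  Rendering is therefore bit-reproducible, which
the tests assert.

## Preprocessing

The black background is cropped to the strokes' bounding box plus a 2 px
margin (an all-black image is flagged, not dropped, so counts stay
conserved), and every crop is rescaled to one square target
(256×256 by default; 128×128 in the desk-scale benchmarks).  The resize
is bilinear and **not** aspect-preserving — one uniform target after
variable crops.  Downscaling applies a Gaussian anti-aliasing prefilter:
the strokes are one pixel wide, and plain bilinear subsampling would
skip most of them instead of averaging them into the output; with the
prefilter, the downscaled gray level is stroke intensity times local
stroke density, which preserves the velocity encoding.  Note that the
crop-and-resize normalises the spatial *scale* of a scanpath away; what
survives is stroke count, stroke density, curvature, and gray level.

Augmentation produces 5 variants per image by small affine jitter:
rotation uniform in ±10°, shift uniform in ±5 % of the side per axis,
zoom uniform in ±10 %, all from one seeded generator.  There is no
horizontal flip (gaze laterality may itself be diagnostic) and no
photometric transform (the gray level *is* the velocity signal).
Variants inherit their source's participant and label, so
participant-wise splits can keep variants with their participant.

## Classifier

The network is 4 × (3×3 same-padding convolution → ReLU → 2×2 max-pool
→ dropout 0.25) followed by flatten → dense → ReLU → dropout 0.5 →
dense(1) → sigmoid, trained with Adam on binary cross-entropy.  The
layer-type counts are fixed; filter widths, dense width, learning rate,
batch size and an optional per-epoch learning-rate decay are
configuration.  Defaults: filters (32, 32, 64, 64), dense 512 at
256×256 input; the desk-scale benchmark configuration is filters
(8, 8, 16, 16), dense 64 at 128×128, batch 8, learning rate 1.5e-3 —
sized so a full 3-fold cross-validation runs in minutes on one CPU.
Training runs for 3 epochs per fold with 20 % of the training images
held out for loss monitoring.  The implementation is a compact NumPy
engine (im2col convolutions, argmax-routed pooling, inverted dropout);
every random draw — weight initialisation, batch order, dropout masks —
comes from generators derived from one integer seed, so identical seeds
give bit-identical loss trajectories, which the tests assert.

Evaluation reports the ROC curve (threshold sweep over the unique
scores), AUC (trapezoidal, equal to the concordant-pair fraction with
ties counted ½ — asserted against a brute-force pair counter), and
accuracy/recall/precision at threshold 0.5, per fold with mean ± SD.
Two split modes exist because they answer different questions:
image-wise folds estimate how well images are separable when the model
may have seen other images of the same child (optimistic), while
participant-wise folds — class-stratified partitions over participant
IDs, with augmented variants following their participant — estimate
generalisation to unseen children, the clinically relevant number.

## MIC

The maximal information coefficient of `n` paired observations is

    MIC = max_{nx·ny ≤ B(n)}  I*(nx, ny) / log2(min(nx, ny)),   B(n) = n^0.6

where `I*(nx, ny)` is the largest mutual information of the 2-D
histogram induced by any nx-by-ny grid.  The implementation follows the
ApproxMaxMI strategy: one axis is mass-equipartitioned into rows (ties
never split), the other axis is optimised exactly by dynamic
programming over *clumps* — maximal runs of x-consecutive points lying
in the same row; the optimal cut points never fall inside a clump.
When there are more than `c·L` clumps (`c = 15`, `L` the column
budget), they are merged into mass-balanced superclumps to bound the
DP.  Both orientations are searched and the maximum taken, so the score
is exactly symmetric; only ranks enter the grids, so it is invariant
under strictly increasing transforms of either variable (both asserted
to 1e-9).  The DP maximises the additive decomposition
`H(P) − H(P,Q)` over bin boundaries, which for the full point set is
equivalent to maximising the mutual information; the tests verify the
DP against an exhaustive search over all cut placements given the same
rows, and verify a one-sided bound against an exhaustive *true* MIC
(which searches all row placements too, and therefore overfits noise at
small n — on independent data true MIC at n = 30 is ≈ 0.35 while the
estimator reports ≈ 0.17; both behaviours are expected).

**Velocity-severity pairs.**  Each image contributes one pair: its mean
clipped transition speed (consistent with what the image encodes; a
flag switches to raw speeds) and the CARS score of its participant, so
a child with several images is counted several times, damping outlier
images.  Non-ASD participants all sit at the CARS scale minimum of 15;
a constant-valued block inflates apparent grid dependence, so they are
excluded by default (`include_non_asd=True` restores them).  A
repeated-measures caveat applies to permutation checks: shuffling CARS
across *participants* preserves the block structure, and MIC correctly
detects the velocity-cluster → participant → permuted-score functional
map; only shuffling across *pairs* destroys the dependence.

## Synthetic gaze generator

The simulator emulates 250 Hz screen-based remote tracking on a
1280×1024 display as an alternating renewal process:

| parameter | non-ASD default | ASD default | unit |
| --- | --- | --- | --- |
| fixation duration (mean, SD) | 330, 80 | 150, 50 | ms |
| saccade duration (mean, SD) | 60, 15 | 60, 15 | ms |
| saccade amplitude (mean, SD) | 160, 60 | 400, 130 | px |
| fixation jitter (per-sample SD) | 3 | 7.5 | px |
| blink dropout rate | 0.05 | 0.08 | fraction |

Fixations are jittered stationary clusters; saccades are
constant-velocity straight-line displacements toward a uniformly drawn
on-screen target with the jump length drawn from the amplitude
distribution; blink bursts (~150 ms) mark contiguous samples invalid;
coordinates are clamped to the screen.  The fixation durations sit at
the long and short ends of the 150–550 ms range reported for
naturalistic viewing, and the group separation direction (more
frequent, larger saccades in ASD) follows one consistent strand of the
eye-movement literature; because that literature is not unanimous, the
profiles are configuration, not fact.

Each participant draws an individual **velocity scale** (log-normal,
σ = 0.5) multiplying both saccade amplitude and fixation jitter — i.e.
all sources of displacement, so the child's overall gaze speed is
proportional to it.  ASD participants receive
`CARS = 37.5 + 13·ln(scale) + ε`, `ε ~ N(0, 1.5)` (10 % of the 30–45
band), clipped to that band; non-ASD participants receive the constant
15.  A default cohort is 29 ASD / 30 non-ASD with 2 recordings of 4 s
per child, ≈ 590 images, ≈ 10 per child.

**What the simulator does and does not show.**  It reproduces the
*statistical structure* the pipeline assumes — alternating slow/fast
movement, track-loss gaps, per-child dynamics scales, a monotone
severity link — so passing tests show the pipeline can recover planted
group differences and severity links through the full
render→preprocess→train and velocity→MIC paths, with honest
participant-wise evaluation.  It does not model stimulus content,
saliency-driven or social gaze placement, main-sequence saccade
kinematics (velocity within a saccade is constant, not bell-shaped), or
measurement error structure of a real tracker.  Synthetic recovery
therefore says nothing about the *clinical* separability of real
cohorts; it validates the machinery, not the medicine.

## Numerical and design choices

- **One seed per run.**  Cohort generation, augmentation, splits,
  initial weights, batch order and dropout masks all derive from one
  integer; everything asserted deterministic is bit-deterministic.
- **Binocular exports** average the two eyes when both are usable, else
  take the usable one.
- **Degenerate inputs**: empty gaze files are format errors;
  non-monotone timestamps are data errors naming the row; a recording
  with fewer than `min_points` valid samples yields zero segments (not
  an error); an all-black rendered image is flagged and kept; evaluate
  refuses single-class label sets; MIC requires ≥ 30 finite pairs.
- **Max-compositing** on stroke overlap (brightest wins) keeps
  re-rendering bit-identical regardless of draw order.
- **Pooling ties** route gradients to the first maximum —
  deterministic, matters only on exactly-tied activations.
- **Class weighting** for the mild ASD/non-ASD imbalance exists but is
  off by default.
- **Desk-scale problem sizes.**  The benchmark suite uses the 59-child
  default cohort at 128×128 input for the CNN (≈ 2.5 min per 3-fold
  cross-validation), 5 recordings per child (≈ 725 pairs) for the noisy
  MIC recovery, and a 50-ASD cohort (≥ 1000 pairs) for the shuffle
  null.  These sizes were chosen so the whole validation runs on a
  single CPU in minutes while keeping the statistics stable across
  cohort draws.

## Known limitations

- The CNN training budget (3 epochs) and the crop-induced scale
  normalisation cap participant-wise AUC on the simulator at roughly
  0.86–0.92; most of the residual error is participant-level
  generalisation, not optimisation.
- MIC on repeated-measures pairs inherits the clustering caveat above;
  participant-level permutation is *not* a valid independence null for
  per-image pairs.
- The renderer clips only the colour-mapped dynamics; drawn positions
  are as recorded.  If a tracker emits wild position artefacts they
  will appear as strokes (with capped darkness).
- `read_gaze_records` trusts the user-supplied column map; vendor
  exports with event-coded rows need a pre-pass that maps them to the
  expected columns.
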