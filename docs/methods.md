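# Methods

This note documents the models, conventions and design choices behind
`gaitrep`: what each stage computes, which parameters matter, what the
synthetic walker does and does not emulate, and where the design was
genuinely open.

## Coordinate and data conventions

Arrays are row-major; `x` indexes columns, `y` indexes rows, both 0-based,
so S(x, y) lives at `array[y, x]`. Silhouettes are uint8 masks of {0, 1}.
Binarization thresholds at a fraction (default 0.5) of the per-image
maximum intensity, which is idempotent on masks and cuts antialiased 8-bit
input at mid-intensity. All-zero frames are dropped at load time: an empty
silhouette has no geometry and would poison cropping, centroids and
boundary tracing downstream.

## Preprocessing

Each frame is cropped to the bounding box of its foreground support — the
rows/columns between the first and last nonzero projection entries. The
alternative reading of projection-based cropping, deleting every interior
all-zero row/column, would translate detached segments (e.g. a separated
arm) toward the body and deform the shape, so the bounding-box span is
used; the 0-norm support sizes are still computed and recorded. All
cropped frames of a sequence are then zero-padded equally from both sides
to the sequence-wide maximum height and width; an odd remainder goes to
the right/bottom (any fixed convention works; this one is declared and
tested). No scaling is ever applied.

By default the bounding box is what centers a frame in the canvas. The
prose tradition for energy images centers on the silhouette centroid
instead; both are supported (`alignment="bbox" | "centroid"`), with
bounding-box padding as the default because it is what the cropping/padding
equations define and it requires no resampling decisions. Centroid
alignment translates by whole pixels and clips (with a warning) if content
would leave the canvas.

### Boundary tracing

The outer boundary is traced with Moore-Neighbor contour following:
start at the uppermost-leftmost foreground pixel (entered travelling
east), repeatedly scan the 8-neighborhood clockwise from just past the
backtrack pixel, and move to the first foreground neighbor. Two deliberate
modifications:

* **Termination.** Jacob's criterion (stop when the start pixel is
  re-entered from the initial direction) does not terminate on
  one-pixel-wide shapes, where the start is only ever re-entered from the
  opposite direction. The tracer instead stops when a (pixel, backtrack)
  state repeats — a strictly stronger condition that subsumes Jacob's rule
  and provably terminates, since the walk is a deterministic map on a
  finite state set.
* **Corner completion.** A foreground pixel whose only background contact
  is diagonal (the inside of a staircase corner) is skipped by the plain
  Moore walk although it is a boundary pixel in the 8-neighborhood sense.
  When the walk steps diagonally, the tracer additionally emits the
  foreground off-diagonal pixel of that step. The emitted pixel is always
  itself an 8-boundary pixel (it is diagonal to the background pixel the
  scan just passed) and is 4-adjacent to both endpoints of the step, so
  the trace remains an ordered, closed, 8-connected walk whose point set
  equals {p : mask(p) = 1 and some 8-neighbor is 0} for hole-free
  single-component shapes. This matters for tGBI (boundary images should
  contain every boundary pixel) and for cBIT invertibility.

Holes are ignored (outer contour only); with several components the
largest is traced and a warning is emitted, treating small extra
components as segmentation noise. A temporary one-pixel guard border makes
edge-touching foreground safe. A single-pixel silhouette yields the
degenerate length-1 trace.

## Gait-cycle detection

Each padded frame is compared to a fixed reference frame (default: frame
0) by the 2-D Pearson correlation, either of the silhouettes (`CorrI`) or
of their FFT magnitudes (`CorrF`, insensitive to residual translation).
Frames with zero variance correlate as 0 with a warning. Valleys of the
signal — local minima with topographic prominence at least a fraction
(default **0.1**) of the signal range — delimit cycles; prominence is the
depth below the lower of the two highest flanking peaks, computed with
`scipy.signal.find_peaks` on the negated signal, which matches the
textbook construction (nearest equal-value points or data ends bound the
flanking intervals). The range-relative threshold makes detection
invariant to affine rescaling of the signal; a flat signal has no valleys;
endpoints are never valleys. Consecutive valleys span one cycle
(inclusive); cycles shorter than `min_frames` (default 4) are discarded
with a warning, and `pair_valleys=2` merges alternate valleys for
similarity signals that dip twice per stride.

## The five maps

Definitions are in the README. Numerical choices:

* tGBI accumulates boundary images additively with 1-based time weights;
  the float map is unbounded and is rescaled only for PNG previews (the
  float TIFF is the canonical artifact).
* cGEI segment boundaries fall at ⌊N/3⌋ and ⌊2N/3⌋; remainder frames join
  the final (blue) segment. Channels keep the 1/N normalization, so the
  channel sum equals the GEI exactly when 3 | N and within one frame's
  weight otherwise.
* tGDI has N−1 difference images for an N-frame cycle; the accumulation
  runs over n = 1..N−1 with the 1/N normalization retained.
* cBIT resamples every trace to the maximum length N_B piecewise-linearly
  along the trace index with endpoints preserved, keeping real-valued
  coordinates; coordinates are normalized by (N_x−1, N_y−1) to [0, 1] so
  the map is resolution-independent, with the canvas recorded in metadata
  for exact inversion. Decoding rounds back to pixels, rasterizes and
  flood-fills (4-connected background, so the 8-connected boundary curve
  does not leak); reconstruction is exact for hole-free single-component
  silhouettes whose traces needed no resampling.

## Features and reduction

Color-shift augmentation produces the six channel orderings in the fixed
block order (R,G,B), (R,B,G), (G,R,B), (G,B,R), (B,R,G), (B,G,R);
grayscale maps replicate to three equal channels, making the six blocks
identical (harmless redundancy, kept for a uniform vector layout).

The descriptor backend is an interface. The reference backend is fc7 of an
ImageNet-pretrained AlexNet (4096 features per image; optional dependency,
bilinear resize to 224 × 224 without aspect preservation, standard ImageNet
channel normalization after per-image rescaling). The built-in backend is
a deterministic pooled-grid descriptor: per channel, a 16 × 16 mean-pooled
grid plus a 16-bin intensity histogram after per-image rescaling to
[0, 1] — 816 values per image, 4,896 per map after augmentation. The grid
resolution was chosen so that few-pixel left/right geometry differences on
a ~100-px-wide canvas survive pooling; an 8 × 8 grid would average them
away. The descriptor needs no weights or downloads and keeps every test
and the acceptance run fully reproducible offline.

Per-class PCA: for each class, the top P (default **15**) right-singular
vectors of the centered class matrix; P is clamped to class count − 1 with
a warning, and a warning fires when the retained variance falls below the
0.80 goal. A feature vector is reduced by projecting onto every class's
components after subtracting that class's mean — the mean handling is not
fixed by the R = Eᵀ·F formulation alone; per-class centering is adopted as
the consistent counterpart of per-class fitting. Reduced dimension is
n_classes × P (90 for six classes).

## Classification and evaluation

KNN with Euclidean distance; the neighbor count k is selected from
{1, 3, 5, 7, 9} by 3-fold validation inside each training fold. Vote ties
break by the smallest mean neighbor distance, then by class order. Scores
are vote fractions and feed the one-vs-rest AUC; multiclass AUC is
support-weighted over the defined classes. Evaluation is stratified 5-fold
cross-validation with the reducer fitted inside each training fold only —
fitting PCA on the full dataset before splitting would leak test
information into the projection, so the pipeline refuses to do it.
Undefined metrics (a never-predicted class's PPV, an absent class's AUC)
are reported as 0 / excluded with explicit flags rather than silently
averaged. Everything is deterministic given the seed.

## Synthetic walker

The generator renders a 2-D articulated stick figure (ellipse torso, disk
head, two-segment limbs rasterized with thickness) walking in place in
lateral view on a 200 × 100 canvas (height × width; a scaled-down frame
with the aspect ratio of typical 800 × 400 recordings, sized for fast
tests). Thigh angles are sinusoids of the cycle phase with contralateral
antiphase (base amplitude 0.45 rad, arms 0.30 rad); shanks amplify the
thigh angle and subtract a constant knee bend; sequences start at the
maximum-spread posture. Far-side limbs attach 8 px behind and 4 px above
the near-side ones and are drawn at 0.62 length and reduced width,
emulating the depth offset and partial occlusion of a lateral projection;
the arm swing lags the legs by 0.35 rad. Besides realism, these two
asymmetries are load-bearing: a perfectly bilateral walker's silhouette is
invariant under swapping left and right limbs half a period apart, which
makes left- and right-sided impairments indistinguishable and gives the
correlation signal two dips per stride; the far-side geometry and arm lag
break both degeneracies so one period produces one valley.

Class kinematics: NM uses full amplitudes; LL/RL suppress one leg's swing
(amplitude × 0.12) with a slightly shortened stride; LA/RA suppress one
arm (× 0.05); FB damps all amplitudes (× 0.45), halves the stride and
bends the knees (0.55 rad) — a shuffling, small-step gait. Datasets add
per-sequence nuisance variation (cycle length ± 2 frames, limb amplitudes
± 8%) and optional salt-and-pepper noise and boundary jitter, applied
inside a one-pixel guard border so tracing preconditions always hold.
Noise-free sequences are exactly periodic by construction.

What the generator does **not** emulate: clothing and carrying covariates,
camera-view changes, segmentation artifacts beyond pixel noise, realistic
joint trajectories (no double-support or stance/swing asymmetry), subject
identity variation, or the partial-impairment grades of real recordings.
Passing tests on this walker therefore demonstrate that the pipeline's
geometry, cycle detection, map construction and classification machinery
are correct and discriminative for limb-asymmetry cues — not that any
particular accuracy transfers to real clinical silhouettes.

## Problem sizes used by the shipped experiments

The acceptance script and end-to-end test use four classes (NM, LL, RL,
FB), 40 detected cycles per class (15 rendered sequences per class of 4
nominal cycles each), the built-in descriptor, P = 15 and 5-fold CV; the
cycle-detection benchmark uses all six classes at periods 8–24 frames.
These sizes keep a full run around half a minute on one CPU while leaving
every class with comfortably more samples per fold than P.

## Known limitations

* The reference-frame correlation signal assumes the subject stays
  roughly registered after cropping; for drifting silhouettes the Fourier
  magnitude variant is the fallback, and the choice is per-run, not
  automatic.
* cBIT invertibility is exact only without resampling and without holes;
  resampled traces reconstruct approximately.
* The AlexNet backend requires a weight download and is not exercised by
  the offline test suite; it shares the resize/normalization path with the
  built-in descriptor but its features are otherwise untested here.
* Per-class PCA assumes every class has at least P + 1 training samples
  per fold before clamping kicks in; very small classes silently reduce
  their block dimension (with a warning), changing the reduced layout.
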