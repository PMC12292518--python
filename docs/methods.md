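# Methods

`spinetrack` analyzes qualitative cervical-spine motion in dynamic X-ray
(videofluoroscopy) recordings.  The pipeline segments the eight vertebral
levels C0–C7 in every frame with a multi-class U-Net, enforces the
rigid-body property of vertebrae through a per-recording *mean shape*,
tracks each vertebra's orientation by rotationally fitting that mean
shape, and derives relative-rotation trajectories of vertebrae and of
adjacent-vertebra segments.  Agreement with ground truth is quantified by
overlap metrics (IoU, DSC) and by the intraclass correlation coefficient
of the trajectories.  Because clinical recordings are private, the package
ships a synthetic-recording generator with exact ground truth; every
result the tests and the acceptance script report is computed closed-loop
on that generator.

## Synthetic recordings

A recording is a stack of grayscale frames (default 52 frames at 15 fps,
256×256 px at desk scale; all sizes configurable).  Eight rigid
vertebra-like polygons are stacked in a curved column: C0 is an arc-like
skull-base region, C1 a wide flat arch, C2 a body with a dens, and C3–C7
are jittered copies of one base quadrilateral — deliberately
near-congruent, since the mutual resemblance of the lower cervical
vertebrae is the main source of label confusion in practice.

Kinematics: the global extension sweep rotates the column by
`total_rom_deg` (default 30°) from the first to the last frame, starting
at −ROM/2 so the column stays centered.  Each motion segment (C0–C1 …
C6–C7) contributes a smooth cubic ramp of configurable amplitude (default
2.5° each); ramp centers are placed so that the per-frame segmental
relative-rotation series peak in a configurable order — the sequence of
segmental contribution the motion analysis must recover.  Whatever
rotation the segments do not account for is carried by the base vertebra
C7 as a concentrated mid-recording burst.  Ramps are deliberately narrow
(auto half-width `max(2, 0.05·(T−1))` frames): clinically, individual
vertebrae rotate roughly 2–3.5° between frames during the active phase of
a sweep rather than drifting uniformly, and the trajectory statistics
(ICC in particular) are only meaningful when the relative-rotation series
has realistic variance.  Discrete peak uniqueness is guaranteed by
snapping ramp centers to half-integer frames.

Rendering: a low-frequency smoothed-noise background (so contrast
manipulation is visible), an additive intensity step per vertebra,
a per-recording multiplicative contrast factor drawn from
`contrast_range` (default 0.9–1.1), per-frame Gaussian noise (default SD
0.02 on a 0–1 intensity scale), and optional shading of C6/C7
(`occlusion_strength`, default 0.3) emulating the shoulders that obstruct
the lower vertebrae in real radiographs.  A pixel is foreground exactly
when its center lies inside the transformed polygon; masks and true
angles are exact by construction.  None of the noise/contrast defaults
are fitted to real recordings — the source studies do not quantify those
distributions — they are stated conventions chosen to be plainly visible
yet learnable.

What the generator does *not* emulate: 3D anatomy and overprojection,
X-ray attenuation physics, annotation error in the ground truth,
out-of-plane motion, and anatomical variability beyond polygon jitter.
Passing closed-loop tests therefore demonstrates the correctness and
internal consistency of the pipeline, not clinical-grade segmentation.

## Segmentation network

A five-level U-Net (desk scale: four levels, 8 base filters) with two 3×3
convolutions + ReLU per level, 2×2 max pooling, bilinear ×2 upsampling
followed by convolution in the decoder, skip concatenation, and a 1×1
convolution to nine channels (C0–C7 + background) with per-pixel softmax.
The 2D+t configuration stacks k ∈ {3,5,7,9} consecutive frames as input
channels and predicts only the middle frame; boundary frames without full
context are not predicted (and their relative rotation is defined as 0).

The network and its training loop are implemented directly in NumPy:
im2col + GEMM convolutions with hand-written backward passes, kept
channels-last internally so the only large memory copy per convolution is
the im2col gather.  Optimization is Adam (full-scale defaults: learning
rate 1e-4, batch size 8, up to 300 epochs; desk scale uses 2e-3 with a
45-epoch cap and a step decay — ×0.5 at 60 %, ×0.25 at 80 % of the cap —
to damp late-stage oscillation).  Training minimizes the class-weighted
Dice loss: weights W_c = 1/(Σ g)² are recomputed per batch from that
batch's ground truth, classes without foreground get weight 0, and the
total is Σ W_c L_c / Σ W_c so the loss stays in [0, 1].  The Dice terms
are computed per image (the loss formula's pixel index runs over one
network output) and averaged per class before the weighted combination;
batch pooling dilutes the per-sample gradients enough that the
near-congruent middle vertebrae can fail to acquire their identity at
all.

Three stabilizers, each answering a failure mode observed while
developing the trainer, complete the recipe.  (1) In the combination the
background participates at the weight of the rarest vertebra rather than
its own 1/N²: at 1/N² a mislabeled background is essentially free, which
opens a stable pathological optimum where one vertebra channel claims the
whole background and its own saturating Dice gradient can no longer undo
it.  (2) The final 1×1 convolution starts background-dominant (bias +2
for background, −2 for the vertebrae) and that bias stays frozen: a
learnable global offset is exactly the degree of freedom the leak
exploits, and per-class calibration is the threshold stage's job.  (3) A
small pixel-wise cross-entropy term is added to the training loss: pure
softmax-Dice training cannot revive a class whose softmax output has
underflowed — its logit gradient is proportional to the output itself —
while the cross-entropy logit gradient p − g never vanishes.  Dice + CE
is the standard remedy for this failure mode in medical segmentation;
the weighted Dice loss remains the objective and the stabilizer is
removable (``ce_weight = 0``).  The stabilizer weight is per model — 0.5
for the 2D model, 0.1 for the 2D+t model: the single-frame model
benefits from a strong classification signal during the early identity
race, while the temporal model, integrating evidence across misaligned
frames, needs the Dice term dominant to converge.  A tiny uniform floor
p′ = (1 − ε)p + ε/9 (ε = 1e-3) inside the training loss rounds this out;
the public loss function, validation monitoring and inference are all
untouched by the stabilizers.

Augmentation adds per-sample contrast jitter (shared across the temporal
channels of one input) and Gaussian noise.  Intensities are standardized
with the mean/SD of the training subset only.  Early stopping monitors
validation loss (patience 25 full scale; 8 with a 1e-3 minimum
improvement at desk scale) and the best-validation checkpoint is
restored.  Everything is float32 and seeded; identical configurations
reproduce identical histories.

## Thresholding

Each vertebra channel is binarized independently.  Candidate thresholds
0.1–0.9 in steps of 0.1; precision/recall/F1 are computed from pixel
counts pooled over all validation frames per vertebra (pooling, rather
than averaging per-frame F1, is scale-robust and the natural reading of a
PR curve).  Highest F1 wins; ties go to the lowest threshold; a pixel
exactly at the threshold is foreground.  Fragmented masks keep only the
largest 8-connected component for all shape/rotation analysis.

## Mean shape and rotation tracking

For each vertebra (C1–C7; C0 is excluded because the skull-base region
has no stable apparent shape) and each recording, the per-frame largest
components are translated to centroid-origin, rotationally aligned to the
median frame by an IoU-maximizing grid search, averaged as occupancy
maps, thresholded at 0.5 and recentered.  Construction fails — by design,
mirroring what happens on badly fragmented segmentations — when fewer
than 3 frames are usable or more than half cannot be aligned with
IoU ≥ 0.3.

Fitting pins the template to the target centroid and searches rotation
only (sub-pixel translation refinement is out of scope).  The overlap
objective is the IoU between the *bilinearly resampled* (continuous)
rotated template and the binary target; using the resampled values makes
the objective smooth in the angle.  Search: 1° grid over ±45° around 0
for the first frame and ±10° around the previous frame's angle afterwards
(inter-frame vertebral rotation is a few degrees, so ±10° is generous),
then a 0.1° grid over ±2° around the optimum.  The final angle is the
vertex of a quadratic fitted to the fine-grid overlap curve rather than
its argmax: the overlap of two rasterized shapes carries a grid-aliasing
ripple of up to ~0.5° when their orientations nearly coincide, and the
smooth-curve vertex averages that ripple out.  A guard keeps the argmax
instead when it stands far above the fitted curve (a genuine localized
optimum, e.g. an exact binary identity).  On noise-free synthetic
recordings with ≥40 px templates this tracks per-frame angles to within
0.5° and relative-rotation ICCs above 0.99; 1 px boundary corruption
degrades gracefully (≈1–1.5°).

## Motion analysis

dθ_C(t) = θ_C(t) − θ_C(t−1) with dθ = 0 on the first (predicted) frame
and on frames without a prediction; dθ_R = dθ_Ck − dθ_Cl for adjacent
pairs.  The sequence of segmental contribution orders the C4–C5, C5–C6
and C6–C7 segments by the cumulative C4–C7 rotation at which their
smoothed dθ_R peaks (centered moving average, window 5 frames — the
source method's peak definition leaves the smoothing unspecified, so the
window is this package's convention).  Within-series ties take the
earlier frame and are flagged ambiguous; segments that never contribute
(flat series) order last and are flagged.  Outlier frames are those whose
trajectory value leaves the [min, max] range of the gold-standard series
(margin configurable, default 0).  A recording is excluded at a given
level when its mean ICC is negative or any outlier frame is present.

## Evaluation

ICC is the two-way mixed-effects, consistency, single-measures
coefficient ICC(3,1) — frames are rows, the two raters (ground truth,
tracker) fixed columns; consistency is used because a constant angular
offset between tracker and ground truth (the mean shape's arbitrary
reference orientation) should not be penalized.  ICCs are computed per
recording and summarized as mean [min–max] with the number of retained
recordings, rather than pooling frames across recordings.  Model
comparisons use the two-sided Wilcoxon signed-rank test on paired scores:
exact up to n = 25 via dynamic programming over doubled midranks (exact
even with tied |differences|), normal approximation with tie correction
beyond (no continuity correction).  Zero differences are dropped.

## Problem sizes

The desk-scale study conditions used by the test suite and the acceptance
script: 12 recordings of 12 frames (40° ROM, so the per-frame vertebral
rotation averages ~3.3°, inside the clinically reported 2–3.5° band) at
128×128 px (6 individuals × 2, split 8/2/2 per individual), a 4-level
U-Net with 8 base filters trained for up to 45 epochs at learning rate
2e-3 for k = 1 and k = 3; rotation recovery on a 40-frame, 30°-ROM
recording with 48 px templates; and 100 seeded noise-free runs (20
frames, 22 px templates, 3.5° segment amplitudes, coarsened 2°/0.2°
search) for contribution-order recovery — at smaller template sizes the
segmental signal drops below the rasterization noise floor of binary-mask
tracking, so this is the smallest geometry at which the study measures
the method rather than the noise.  These sizes are the package's
own choices for a reproducible desk experiment; the full-scale settings
of the clinical problem (640×640 or 832×576 inputs, 5 levels, 300 epochs)
remain the configuration defaults.

## Known limitations

* The NumPy network trains small models quickly but is not suited to
  full-resolution clinical training.
* Centroid-pinned rotation fitting inherits any centroid bias of the
  segmentation; translation errors are not corrected.
* The synthetic column is strictly 2D and rigid; coupled translation
  along the spine, overprojection and annotation noise are absent, so
  closed-loop ICCs are optimistic relative to clinical data.
* Exact-rasterization angle recovery is limited by grid aliasing to about
  0.1–0.3° per frame at 40–50 px template height.
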