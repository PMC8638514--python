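# Methods

## The tracking problem

Long-axis cine cardiac images (two-chamber and four-chamber views) show the
mitral valve (MV) plane — the line through the two MV insertion points —
moving toward the apex in systole and back in diastole. Tracking those two
points in every frame yields the plane displacement curve, from which MAPSE
(mitral annular plane systolic excursion) and the annular velocity peaks
s′/e′/a′ are read. `mvtrack` implements a dual-stage coarse-to-fine
coordinate-regression pipeline for this task, together with the geometric
standardization between the stages, the clinical-metric derivation, an
agreement-evaluation suite, and a synthetic cine generator with analytic
ground truth so the whole pipeline is testable end to end without any
clinical data.

## Pipeline

1. **Coarse stage.** Every frame is resized to a fixed 160×160 grid with
   cubic interpolation (pixels become anisotropic; the resize is a pure
   per-axis scaling of pixel-center coordinates, so the associated
   `SimilarityTransform` is exactly invertible). A regression network
   predicts the two points per frame; predictions are mapped back to the
   original grid through the exact inverse.
2. **Standardization.** From the coarse annotation a single similarity
   transform per cine is estimated that (i) scales each axis by
   `pixel_spacing / 0.75` to a 0.75 mm isotropic grid, (ii) rotates about
   the frame-0 annulus midpoint so the frame-0 valve segment is horizontal,
   with the anterior (2ch) / lateral (4ch) point on the left and the apex
   down, and (iii) translates the frame-0 midpoint to the center of a
   118×162 crop (continuous crop center (x, y) = (80.5, 58.5)). The apex
   side is the side of the frame-0 plane toward which the mean of the
   remaining frames' annulus midpoints lies; when the left-point and
   apex-down constraints conflict (mirrored geometry), apex-down wins.
   Frames are resampled in **one** pass through the composed transform
   (cubic, zero fill outside the field of view).
3. **Refinement.** A second network predicts on the standardized frames;
   its outputs are mapped back through the exact inverse transform. The
   refinement is iterated once by default (`n_refine=2`, "stage 1+2+2"),
   each pass re-estimating the standardization from the latest annotation;
   beyond one iteration accuracy no longer improves, so no further passes
   are taken. Point mapping is exact affine arithmetic throughout — with
   ground-truth-lookup stand-ins for both networks the pipeline reproduces
   ground truth to < 1e-6 px, which separates plumbing errors from learning
   errors in every test.

**Conventions.** 0-based pixel coordinates, `x` = column, `y` = row, pixel
centers at integers, origin top-left. A positive rotation turns +x toward
+y. Annotations always store (x, y); spacing is carried as
(spacing_x, spacing_y) mm and never baked into coordinates.

## Regressor

Both stages use the same model family: a residual convolutional network
reading one grayscale frame and regressing (x1, y1, x2, y2) in pixels of
its input grid. The training recipe is per-image median/IQR intensity
normalization, an augmented training set precomputed up front (each
original plus `augmentation_factor − 1` jittered copies; each jitter draws
scale ±10 %, rotation ±10°, translation ±3 px uniformly, applied
consistently to image and targets), mean-squared-error loss, and Adam
(defaults: learning rate 1e-4, 20 epochs, mini-batches of 8).

Two backbones exist. `"full"` is the 50-layer bottleneck residual network
(7×7/2 stem, 3-4-6-3 bottleneck stages, global average pooling, 4-output
head). `"tiny"` is a reduced-depth residual network (stride-4 stem, two
strided basic residual blocks of 12/24/48 channels, small fully connected
head) that trains in minutes on one CPU; it is the first-class desk-scale
choice and the pipeline is backbone-agnostic by contract. Networks,
backpropagation and Adam are implemented in numpy (`mvtrack/_nn.py`);
training and prediction are bit-for-bit reproducible given the
configuration seed. Transfer-learning initialisation from natural-image
classification weights is not available in this build — no such weights
ship with the package — so `pretrained=True` raises and random (He)
initialisation is the supported path. Coordinate targets are in pixels of
the network grid (not normalized); batch-stack prediction processes frames
one at a time so it equals concatenated single-frame prediction exactly.

## Clinical metrics

Per view, plane displacement at frame *t* is the mean signed perpendicular
distance of the two points to the infinite line through the frame-0
(end-diastolic) points, in mm, positive toward the apex (apex side defined
as for standardization). The initial plane is fixed for the whole cycle.
The resultant curve is the frame-wise mean of the two views (the shorter
curve is linearly interpolated onto the longer's time base). Velocity is
the time-derivative in cm/s — central differences at interior samples,
one-sided at the endpoints. MAPSE = max displacement; s′ is the
apex-directed velocity peak before the MAPSE time; e′ the largest
return-directed peak after it; a′ the largest return-directed peak after
e′. Peak labels are resolved by time-order with phase gating rather than
global magnitude ranking so fused or unusual wave shapes cannot swap
labels; velocities are reported as positive magnitudes. A cine with no
late-diastolic peak (e.g. no atrial kick) reports a′ as NaN with
`complete=False`; a two-frame (ED/ES-only) annotation yields MAPSE only.
Frame times come from the data when present, else from RR/n_frames with
RR defaulting to 1.0 s with a warning.

## Synthetic phantoms

The generator emulates the variability of clinical long-axis cine
acquisitions: in-plane resolution 1.3–1.7 mm, 25–50 frames per cycle,
arbitrary in-plane orientation (0–360°), varying image sizes and
field-of-view placement, heart rates 50–90 bpm, MAPSE 8–18 mm, and two
annotation conventions — points at the valve/myocardium intersection, or
offset a fixed distance along the wall toward the apex (the
"basal myocardium" convention; offsetting both points identically shifts
the reference plane with them, so displacement curves and MAPSE are
invariant, which is exactly the decoupling the evaluation suite measures).

Motion model: the annulus plane translates rigidly along the long axis
following a piecewise cosine-ramp profile with four phases — systolic
descent to the peak excursion, early-diastolic recoil to a plateau at
`atrial_kick_fraction_of_mapse × MAPSE`, diastasis, and the atrial-kick
return to baseline. Cosine ramps make each velocity lobe a half-sine with
a closed-form peak (π·Δd / 2τ), giving an independent oracle for
s′/e′/a′. Phase boundaries snap to the frame grid so the sampled curve
attains MAPSE exactly at one frame and each velocity lobe spans a whole
number of frames; with the default phase split (recoil and kick sharing
active diastole equally, diastasis 15 % of diastole) every lobe spans ≥ 8
frames at 30 frames/cycle, keeping the central-difference peak error below
5 %. The fixed 50/50 recoil/kick split trades physiological timing (a real
a-wave is shorter than the e-wave) for resolvable peaks at clinical frame
rates; it is a deliberate schematic choice.

Appearance is schematic by design — bright blood pool, dark myocardial
shell, bright surrounding band, an atrium above the plane and, in the
four-chamber view, a neighbouring chamber: detectability, not realism, is
the goal. The phantoms contain none of the things that make real cines
hard (papillary muscles, valve leaflets, through-plane motion, banding or
coil-shading artifacts, non-rigid annular motion, observer disagreement),
so green end-to-end tests demonstrate that the pipeline's machinery —
transforms, training recipe, iteration, metric derivation, statistics — is
correct and learnable at desk scale; they do not certify clinical
accuracy. Ground-truth annotations are computed analytically from the same
plane position used to render, never read back from pixels. All
randomness flows from a single integer seed through spawned
`SeedSequence` children; identical seeds give bit-identical datasets.

## Evaluation suite

Spatial agreement: per-point Euclidean error in mm (anisotropic spacing
respected, labels matched one-to-one and never permuted), the acute angle
between the two annotated planes in degrees (folded to [0, 90]; degenerate
frames flagged NaN and excluded listwise with counts reported), and the
signed per-frame plane-displacement difference. Clinical agreement:
ICC(2,1) — two-way random effects, absolute agreement, single measures,
with a 95 % CI from F-distribution bounds with Satterthwaite degrees of
freedom (the variant is recorded in the output metadata) — plus
Bland-Altman bias with ±1.96·sd limits of agreement (sample sd of the
differences) and ordinary least-squares regression. The stage-wise report
pools both points and both views into one Euclidean summary per stage and
also derives per-cine MAPSE agreement.

## Desk-scale benchmark

`mvtrack.benchmark.run_benchmark` fixes the study conditions used by the
tests and the acceptance script: 240 subjects (200 train / 40 held-out)
sampled from the default ranges, 4 frames per cine for training, ×3
augmentation expansion, tiny backbones trained 8 epochs (coarse) and 6
epochs (refiner) with Adam at 1e-3 and mini-batches of 8, one model per
stage shared across views, and tracking with one refinement iteration.
These sizes were chosen so the whole study (simulate, train, track,
evaluate) completes in roughly ten minutes on a single CPU core while
leaving wide statistical margins. The refiner's translation augmentation
is widened to ±6 px because the tiny coarse model leaves a larger crop
misalignment than a full-scale coarse network would; the other draw ranges
keep their standard values.

## Numerical choices and edge cases

- Point mapping is exact affine algebra; image resampling (cubic spline,
  zero fill) never touches coordinates.
- Stage-2 resampling uses cubic interpolation like stage 1 (uniformity).
- Rotation pivot = frame-0 annulus midpoint; any pivot is equivalent given
  the free translation, this one keeps numbers small.
- Median/IQR normalization falls back to median-centering with a warning
  when the IQR is zero (constant image).
- Coincident frame-0 points raise `DegeneratePlaneError`; a single-frame
  annotation raises `AmbiguousApexError`; a refinement failure inside
  `track_mv` falls back to the previous stage's annotation with a warning
  so batch runs never abort on one cine.
- Bland-Altman limits use the sample standard deviation (ddof = 1).
- ICC is undefined (raises) on zero total variance.
- Velocity curves require ≥ 3 samples on a uniform, strictly increasing
  time base.

## Known limitations

- The phantom's rigid-plane motion cannot probe non-rigid annular
  dynamics, per-point asymmetries, or through-plane motion.
- Per-observer annotation noise is available as an optional jitter knob
  (`annotation_jitter_px`, default off) but has no empirically calibrated
  default.
- The full 50-layer backbone is implemented and smoke-tested but training
  it at scale on CPU is impractical; the tiny backbone carries all
  end-to-end results.
- Peak labelling assumes a single cardiac cycle starting at end-diastole;
  arrhythmic cycles without an a-wave report a′ absent rather than
  attempting rhythm-specific logic.
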