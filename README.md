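# mvtrack

Automated time-resolved tracking of the mitral valve (MV) plane in long-axis
cine cardiac images, and derivation of the clinical metrics that depend on
it: MAPSE (mitral annular plane systolic excursion) and the annular velocity
peaks LV s′, e′ and a′.

Manually annotating the two MV insertion points in every frame of the
two-chamber and four-chamber views is slow and error-prone, yet it is what
MAPSE and e′ — key systolic and diastolic function metrics — are computed
from. `mvtrack` implements a dual-stage coarse-to-fine coordinate-regression
pipeline for this task:

1. a **coarse** residual-network pass predicts both points on every frame of
   the cine resized to a fixed 160×160 grid;
2. an automated **linear standardization**, estimated from the coarse
   annotation alone, resamples the cine to 0.75 mm isotropic resolution with
   the valve horizontal, the apex down and a 118×162 crop centered on the
   annulus;
3. a **refinement** pass predicts on the standardized frames, and the
   predictions are mapped back to the original image through the exactly
   invertible transform. The refinement is iterated once by default
   ("stage 1+2+2").

From the tracked points the package derives per-view and resultant plane
displacement curves d(t) (mean signed perpendicular distance of the two
points to the end-diastolic plane, mm, positive toward the apex), the
velocity v(t) = d′(t) in cm/s, MAPSE = max d(t), and s′/e′/a′ as the first,
second and third global velocity peaks. An evaluation suite measures
spatial agreement (per-point Euclidean error, plane angular error,
per-frame displacement error) and clinical agreement (ICC(2,1) with 95 %
CI, Bland-Altman limits, regression).

Because clinical cine data cannot be bundled, the package ships a synthetic
long-axis cine generator with analytic ground truth that reproduces the
relevant variability axes (1.3–1.7 mm resolution, 25–50 frames/cycle,
arbitrary orientation and cropping, two annotation conventions). Every
stage of the pipeline is validated against it, from exact-transform
round trips to full train-and-track studies. See `docs/methods.md` for the
model and its assumptions.

## Worked example

```python
from mvtrack import (MotionProfileParams, RenderParams, render_cine,
                     metrics_from_annotations, OraclePredictor, track_mv,
                     euclidean_error)

motion = MotionProfileParams(mapse_mm=14.0, hr_bpm=72.0, n_frames=30,
                             noise_sd=0.03)
views = {}
for view, rot, seed in (("two_chamber", 25.0, 1), ("four_chamber", 210.0, 2)):
    views[view] = render_cine(
        motion,
        RenderParams(view=view, heart_rotation_deg=rot,
                     pixel_spacing_mm=(1.4, 1.4)),
        seed=seed,
    )

(c2, a2), (c4, a4) = views["two_chamber"], views["four_chamber"]
m, d, v = metrics_from_annotations(
    a2, a4, c2.pixel_spacing_mm, c4.pixel_spacing_mm,
    times_2ch=c2.frame_times_s, times_4ch=c4.frame_times_s)
print(f"MAPSE {m.mapse_mm:.2f} mm at t={m.mapse_time_s:.3f} s")
print(f"s' {m.s_prime_cm_s:.2f} cm/s   e' {m.e_prime_cm_s:.2f} cm/s   "
      f"a' {m.a_prime_cm_s:.2f} cm/s")

oracle = OraclePredictor(a2)          # ground-truth lookup stand-in
res = track_mv(c2, oracle, oracle, n_refine=2)
err = euclidean_error(res.final, a2, c2.pixel_spacing_mm)
print(f"oracle-pipeline max point error: {err.max():.2e} mm")
```

prints

```
MAPSE 14.00 mm at t=0.306 s
s' 7.03 cm/s   e' 6.75 cm/s   a' 2.89 cm/s
oracle-pipeline max point error: 2.81e-14 mm
```

The phantom was built with a 14 mm excursion, so MAPSE is recovered
exactly; the velocity peaks match the motion profile's closed-form values
to within the frame-rate discretization; and with ground-truth stand-ins
for both networks the whole resize → standardize → predict → invert chain
is loss-free (the `2.8e-14` mm is floating-point noise), which is the
property that separates pipeline plumbing from learning quality.

Training real (tiny-backbone) models end to end looks like:

```python
from mvtrack.benchmark import run_benchmark, mapse_agreement
bench = run_benchmark(seed=1)        # 200 train / 40 held-out subjects
print(bench.report)                  # stage-wise agreement table
print(mapse_agreement(bench).icc)    # held-out MAPSE ICC vs ground truth
```

## Command line

```bash
mvtrack simulate --n 24 --seed 7 --out data/
mvtrack train    --data data/ --out models/
mvtrack track    --data data/ --models models/ --out tracked/
mvtrack metrics  --data data/ --pred tracked/ --out metrics.csv
mvtrack evaluate --data data/ --pred tracked/ --out report
```

Cines are written as NIfTI with a JSON sidecar (DICOM and PNG/TIFF
directories are readable too); annotations travel as a plain CSV schema
(`subject_id, view, frame_index, point_label, x_px, y_px, source`).

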