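"""Clinical metric derivation from time-resolved annulus annotations.

The mitral valve plane displacement of a view is the average signed
perpendicular distance of the two insertion points to the *initial plane* —
the infinite line through the frame-0 (end-diastolic) points — converted to
millimetres and signed positive toward the apex.  The resultant displacement
averages the two chamber views; velocity is its time-derivative; MAPSE is
the maximal displacement; and s', e', a' are the first, second and third
global peaks of the velocity curve (apex-directed in systole, return-
directed in early and late diastole), reported as positive magnitudes.
"""

from __future__ import annotations

import warnings

import numpy as np

from .core import (
    ClinicalMetrics,
    DegeneratePlaneError,
    DisplacementCurve,
    MVAnnotation,
    VelocityCurve,
)

_DEFAULT_RR_S = 1.0


def _frame_times(n_frames: int, times, rr_interval_s: float | None) -> np.ndarray:
    if times is not None:
        t = np.asarray(times, dtype=float)
        if t.shape != (n_frames,):
            raise ValueError("times length must match the number of frames")
        return t
    if rr_interval_s is None:
        warnings.warn(
            "no frame timing available; assuming a 1.0 s RR interval",
            stacklevel=3,
        )
        rr_interval_s = _DEFAULT_RR_S
    return np.arange(n_frames) * (rr_interval_s / n_frames)


def plane_displacement(
    ann: MVAnnotation,
    pixel_spacing_mm: tuple[float, float],
    times=None,
    rr_interval_s: float | None = None,
) -> DisplacementCurve:
    """Signed MV plane displacement (mm) relative to the frame-0 plane.

    For every frame the perpendicular distances of both points to the line
    through the frame-0 points are averaged (in physical mm coordinates,
    honouring anisotropic spacing).  The sign is positive on the apex side,
    determined as the side toward which the mean of the later-frame annulus
    midpoints lies.  Frame times come from ``times`` if given, else from
    ``rr_interval_s / n_frames`` (defaulting to RR = 1.0 s with a warning).
    """
    if ann.n_frames < 2:
        raise ValueError("at least two annotated frames are required")
    spacing = np.asarray(pixel_spacing_mm, dtype=float)
    pts_mm = ann.points * spacing  # (T, 2, 2) in mm

    p0, p1 = pts_mm[0, 0], pts_mm[0, 1]
    seg = p1 - p0
    norm = np.linalg.norm(seg)
    if norm < 1e-12:
        raise DegeneratePlaneError("frame-0 annulus points coincide")
    normal = np.array([-seg[1], seg[0]]) / norm

    # signed offsets of every point from the initial plane
    offsets = (pts_mm - p0) @ normal  # (T, 2)
    per_frame = offsets.mean(axis=1)

    apex_side = per_frame[1:].mean()
    if apex_side < 0:
        per_frame = -per_frame
    t = _frame_times(ann.n_frames, times, rr_interval_s)
    return DisplacementCurve(times=t, values=per_frame, view=ann.view or "view")


def resultant_displacement(
    c2ch: DisplacementCurve, c4ch: DisplacementCurve
) -> DisplacementCurve:
    """Frame-wise mean displacement of the two chamber views.

    If the curves have different lengths the shorter one is linearly
    interpolated onto the longer one's time base before averaging.
    """
    for c in (c2ch, c4ch):
        if len(c) < 2:
            raise ValueError("each displacement curve needs at least two samples")
    longer, shorter = (c2ch, c4ch) if len(c2ch) >= len(c4ch) else (c4ch, c2ch)
    resampled = np.interp(longer.times, shorter.times, shorter.values)
    return DisplacementCurve(
        times=longer.times.copy(),
        values=0.5 * (longer.values + resampled),
        view="resultant",
    )


def velocity_curve(d: DisplacementCurve) -> VelocityCurve:
    """Time-derivative of a displacement curve, in cm/s.

    Central differences at interior samples, one-sided at the endpoints.
    Requires at least three samples on a uniform, strictly increasing time
    base.
    """
    if len(d) < 3:
        raise ValueError("at least three samples are required for a velocity curve")
    dt = np.diff(d.times)
    if np.any(dt <= 0):
        raise ValueError("times must be strictly increasing")
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
        raise ValueError("times must be uniformly spaced")
    v_mm_s = np.gradient(d.values, d.times)  # central interior, one-sided ends
    return VelocityCurve(times=d.times.copy(), values=v_mm_s / 10.0, view=d.view)


def _local_peaks(values: np.ndarray) -> list[int]:
    """Indices of local maxima of ``values`` (plateau-tolerant, ends included).

    Candidate maxima at adjacent samples (a flat-topped peak straddling two
    frames) are merged into the single larger one.
    """
    n = values.size
    idx = []
    for i in range(n):
        left = values[i - 1] if i > 0 else -np.inf
        right = values[i + 1] if i < n - 1 else -np.inf
        if values[i] >= left and values[i] >= right and (
            values[i] > left or values[i] > right or n == 1
        ):
            idx.append(i)
    merged: list[int] = []
    for i in idx:
        if merged and i - merged[-1] == 1:
            if values[i] > values[merged[-1]]:
                merged[-1] = i
        else:
            merged.append(i)
    return merged


def derive_metrics(d: DisplacementCurve, v: VelocityCurve | None = None) -> ClinicalMetrics:
    """Derive MAPSE and the s'/e'/a' velocity peaks from one cycle.

    MAPSE is the maximal displacement.  s' is the apex-directed (positive)
    velocity peak before the MAPSE time; e' the largest-magnitude
    return-directed (negative) velocity peak after it; a' the largest
    return-directed peak occurring after e' (the atrial kick).  Peaks are
    located by a local-extremum scan and reported as positive magnitudes;
    absent peaks are NaN with ``complete=False``.  A two-frame (ED/ES-only)
    annotation yields MAPSE only.
    """
    i_mapse = int(np.argmax(d.values))
    mapse = float(d.values[i_mapse])
    t_mapse = float(d.times[i_mapse])
    metrics = ClinicalMetrics(mapse_mm=mapse, mapse_time_s=t_mapse, complete=False)

    if v is None:
        if len(d) < 3:
            return metrics
        v = velocity_curve(d)
    if len(v) != len(d):
        raise ValueError("velocity curve length must match the displacement curve")

    vals = v.values
    # s': largest positive velocity peak strictly before the MAPSE time
    pre = [i for i in _local_peaks(vals) if i < i_mapse and vals[i] > 0]
    if not pre and i_mapse > 0:
        pre = [int(np.argmax(vals[:i_mapse]))]
    if pre:
        i_s = max(pre, key=lambda i: vals[i])
        metrics.s_prime_cm_s = float(vals[i_s])
        metrics.s_prime_time_s = float(v.times[i_s])

    # e', a': return-directed (negative) peaks after the MAPSE time
    post = [i for i in _local_peaks(-vals) if i > i_mapse and vals[i] < 0]
    if post:
        i_e = max(post, key=lambda i: -vals[i])
        metrics.e_prime_cm_s = float(-vals[i_e])
        metrics.e_prime_time_s = float(v.times[i_e])
        after = [i for i in post if i > i_e]
        if after:
            i_a = max(after, key=lambda i: -vals[i])
            metrics.a_prime_cm_s = float(-vals[i_a])
            metrics.a_prime_time_s = float(v.times[i_a])

    metrics.complete = bool(
        np.isfinite(metrics.s_prime_cm_s)
        and np.isfinite(metrics.e_prime_cm_s)
        and np.isfinite(metrics.a_prime_cm_s)
    )
    return metrics


def metrics_from_annotations(
    ann_2ch: MVAnnotation,
    ann_4ch: MVAnnotation,
    spacing_2ch: tuple[float, float],
    spacing_4ch: tuple[float, float],
    times_2ch=None,
    times_4ch=None,
    rr_interval_s: float | None = None,
) -> tuple[ClinicalMetrics, DisplacementCurve, VelocityCurve | None]:
    """Convenience chain: per-view displacement -> resultant -> metrics."""
    d2 = plane_displacement(ann_2ch, spacing_2ch, times_2ch, rr_interval_s)
    d4 = plane_displacement(ann_4ch, spacing_4ch, times_4ch, rr_interval_s)
    d = resultant_displacement(d2, d4)
    v = velocity_curve(d) if len(d) >= 3 else None
    return derive_metrics(d, v), d, v
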