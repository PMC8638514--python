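"""Synthetic long-axis cine phantoms with exact mitral-valve ground truth.

The generator emulates the variability axes of clinical long-axis cine CMR
without any real data: in-plane resolution 1.3-1.7 mm, 25-50 frames per
cycle, arbitrary in-plane heart orientation and field-of-view placement,
two- and four-chamber appearance, and two annotation conventions (points at
the valve/myocardium intersection, or offset toward the apex onto the most
basal compact myocardium).  The phantom is deliberately schematic — a bright
blood pool inside a dark myocardial shell with a bright surrounding band —
because detectability, not photorealism, is the goal.

Motion model: the annulus plane translates rigidly along the long axis
following a piecewise cosine-ramp profile with the four phases of annular
motion — systolic descent to peak excursion (MAPSE), early-diastolic recoil,
diastasis plateau, and the atrial-kick return to baseline.  Cosine ramps are
used so the velocity curve has well-defined s'/e'/a' peaks with closed-form
amplitudes.

Ground-truth annotations are computed analytically from the same plane
position used to render the images, never read back from pixels, so any
tracker evaluated against them has a well-defined error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .core import VIEW_LABELS, CineSeries, DisplacementCurve, MVAnnotation


class RenderError(ValueError):
    """Raised when a phantom cannot be rendered as parameterized."""


# --------------------------------------------------------------------------
# parameters
# --------------------------------------------------------------------------

@dataclass
class MotionProfileParams:
    """Parameters of the annular displacement profile.

    ``systole_fraction`` is the fraction of the cycle at which displacement
    peaks; ``diastasis_fraction`` the fraction of diastole spent on the
    plateau; ``atrial_kick_fraction_of_mapse`` the portion of the return
    completed by the atrial kick (the plateau sits at that height).
    ``noise_sd`` is the additive image noise standard deviation in intensity
    units (images are rendered on a 0-1 scale).
    """

    mapse_mm: float = 12.0
    hr_bpm: float = 70.0
    n_frames: int = 30
    systole_fraction: float = 0.35
    diastasis_fraction: float = 0.15
    atrial_kick_fraction_of_mapse: float = 0.30
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mapse_mm < 0:
            raise ValueError("mapse_mm must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if not 0.0 < self.systole_fraction < 1.0:
            raise ValueError("systole_fraction must be in (0, 1)")
        if not 0.0 <= self.diastasis_fraction < 1.0:
            raise ValueError("diastasis_fraction must be in [0, 1)")
        if not 0.0 <= self.atrial_kick_fraction_of_mapse <= 1.0:
            raise ValueError("atrial_kick_fraction_of_mapse must be in [0, 1]")
        if self.hr_bpm <= 0:
            raise ValueError("hr_bpm must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def rr_interval_s(self) -> float:
        return 60.0 / self.hr_bpm


#: fraction of the non-plateau diastole taken by the early recoil (e wave);
#: the remainder is the atrial kick.  Fixed split, not a study parameter.
_RECOIL_SHARE = 0.5

VALVE_INTERSECTION = "valve_intersection"
BASAL_MYOCARDIUM = "basal_myocardium"


@dataclass
class RenderParams:
    """Imaging and appearance parameters of one rendered view."""

    pixel_spacing_mm: tuple[float, float] = (1.5, 1.5)  # (x, y)
    image_size: tuple[int, int] = (180, 180)  # (rows, cols)
    heart_rotation_deg: float = 0.0
    heart_center_px: tuple[float, float] | None = None  # (x, y); None = image center
    annulus_width_mm: float = 30.0
    view: str = "two_chamber"
    annotation_convention: str = VALVE_INTERSECTION
    convention_offset_mm: float = 2.0
    annotation_jitter_px: float = 0.0

    def __post_init__(self) -> None:
        sx, sy = self.pixel_spacing_mm
        if not (0.5 <= sx <= 3.0 and 0.5 <= sy <= 3.0):
            raise ValueError("pixel spacing must lie in [0.5, 3.0] mm")
        if self.annulus_width_mm <= 0:
            raise ValueError("annulus_width_mm must be positive")
        if self.view not in VIEW_LABELS:
            raise ValueError(f"unknown view {self.view!r}")
        if self.annotation_convention not in (VALVE_INTERSECTION, BASAL_MYOCARDIUM):
            raise ValueError(
                f"unknown annotation convention {self.annotation_convention!r}"
            )
        self.heart_rotation_deg = float(self.heart_rotation_deg) % 360.0
        if self.annotation_jitter_px < 0:
            raise ValueError("annotation_jitter_px must be >= 0")

    @property
    def center_px(self) -> np.ndarray:
        if self.heart_center_px is not None:
            return np.asarray(self.heart_center_px, dtype=float)
        rows, cols = self.image_size
        return np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])


# --------------------------------------------------------------------------
# motion profile
# --------------------------------------------------------------------------

def _segment_bounds(params: MotionProfileParams) -> tuple[float, float, float, float]:
    """Phase boundaries (cycle fractions): peak, recoil end, plateau end, 1.

    All boundaries are snapped to the frame grid so the sampled curve
    attains ``mapse_mm`` exactly at one frame and every velocity lobe spans
    a whole number of frames (its sampled peak then sits at or next to the
    lobe midpoint, keeping the discretization error of the peak small).
    """
    n = params.n_frames

    def snap(frac: float, lo: int, hi: int) -> int:
        return int(np.clip(np.floor(frac * n + 0.5), lo, hi))

    i_ts = snap(params.systole_fraction, 1, n - 1)
    ts = i_ts / n
    diastole = 1.0 - ts
    plateau = params.diastasis_fraction * diastole
    active = diastole - plateau
    i_re = snap(ts + _RECOIL_SHARE * active, i_ts, n - 1)
    i_pe = snap(i_re / n + plateau, i_re, n - 1)
    return ts, i_re / n, i_pe / n, 1.0


def _cos_ramp(u: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Smooth monotone ramp from ``lo`` (u=0) to ``hi`` (u=1)."""
    return lo + (hi - lo) * 0.5 * (1.0 - np.cos(np.pi * np.clip(u, 0.0, 1.0)))


def displacement_function(params: MotionProfileParams):
    """The continuous displacement profile ``d(u)`` on cycle fraction u."""
    amp = params.mapse_mm
    level = amp * params.atrial_kick_fraction_of_mapse
    ts, t_re, t_pe, _ = _segment_bounds(params)

    def d(u):
        u = np.asarray(u, dtype=float)
        out = np.zeros_like(u)
        seg = u <= ts
        out[seg] = _cos_ramp(u[seg] / ts, 0.0, amp)
        seg = (u > ts) & (u <= t_re)
        if t_re > ts:
            out[seg] = _cos_ramp((u[seg] - ts) / (t_re - ts), amp, level)
        seg = (u > t_re) & (u <= t_pe)
        out[seg] = level
        seg = u > t_pe
        if 1.0 > t_pe:
            out[seg] = _cos_ramp((u[seg] - t_pe) / (1.0 - t_pe), level, 0.0)
        return out

    return d


def generate_displacement_profile(params: MotionProfileParams) -> DisplacementCurve:
    """Sample the annular displacement profile at the frame times.

    Returns a curve of ``n_frames`` samples at times ``i * RR / n_frames``;
    positive values are toward the apex, frame 0 is zero by construction and
    the single global maximum equals ``mapse_mm`` at the frame nearest
    ``systole_fraction``.
    """
    n = params.n_frames
    u = np.arange(n) / n
    values = displacement_function(params)(u)
    times = u * params.rr_interval_s
    return DisplacementCurve(times=times, values=values, view="profile")


def analytic_velocity_peaks(params: MotionProfileParams) -> dict[str, float]:
    """Closed-form s'/e'/a' magnitudes (cm/s) of the continuous profile.

    A cosine ramp covering an amplitude change ``dA`` (mm) in ``tau``
    seconds peaks at ``pi * dA / (2 * tau)`` mm/s.
    """
    ts, t_re, t_pe, _ = _segment_bounds(params)
    rr = params.rr_interval_s
    amp = params.mapse_mm
    level = amp * params.atrial_kick_fraction_of_mapse

    def ramp_peak(d_amp: float, frac: float) -> float:
        if frac <= 0:
            return math.nan
        return math.pi * d_amp / (2.0 * frac * rr) / 10.0  # mm/s -> cm/s

    return {
        "s_prime_cm_s": ramp_peak(amp, ts),
        "e_prime_cm_s": ramp_peak(amp - level, t_re - ts),
        "a_prime_cm_s": ramp_peak(level, 1.0 - t_pe),
    }


# --------------------------------------------------------------------------
# rendering
# --------------------------------------------------------------------------

# intensity levels of the schematic phantom (arbitrary units, 0-1 scale)
_I_BACKGROUND = 0.35
_I_BLOOD = 1.0
_I_MYO = 0.12
_I_FAT = 0.90
_I_ATRIUM = 0.80
_I_RV = 0.95

_MYO_THICKNESS_MM = 9.0
_FAT_BAND_MM = 6.0
_LV_LENGTH_FACTOR = 2.4  # LV long-axis length as a multiple of annulus width
_ATRIUM_DEPTH_MM = 45.0


def _axis_vectors(rotation_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit vectors (image x,y) along the annulus (e1) and toward apex (e2)."""
    phi = np.deg2rad(rotation_deg)
    e1 = np.array([np.cos(phi), np.sin(phi)])
    e2 = np.array([-np.sin(phi), np.cos(phi)])
    return e1, e2


def _render_frame(a: np.ndarray, b: np.ndarray, delta: float,
                  w2: float, view: str) -> np.ndarray:
    """Evaluate phantom intensity at canonical coordinates (a, b).

    ``a`` runs along the annulus (mm, positive toward the second point),
    ``b`` along the long axis toward the apex; the valve plane sits at
    ``b = delta``.
    """
    lv_len = _LV_LENGTH_FACTOR * 2.0 * w2
    apex_b = lv_len  # apex stays put; the base moves with delta
    tm = _MYO_THICKNESS_MM

    img = np.full(a.shape, _I_BACKGROUND)

    def half_ellipse(half_w: float, base: float, tip: float) -> np.ndarray:
        span = tip - base
        rel = (b - base) / span
        inside = (rel >= 0.0) & (rel <= 1.0)
        lim = np.zeros_like(a)
        lim[inside] = half_w * np.sqrt(np.clip(1.0 - rel[inside] ** 2, 0.0, 1.0))
        return inside & (np.abs(a) <= lim)

    # outer fat band, then myocardial shell, then blood pool (painted inward)
    img[half_ellipse(w2 + tm + _FAT_BAND_MM, delta, apex_b + tm + _FAT_BAND_MM)] = _I_FAT
    img[half_ellipse(w2 + tm, delta, apex_b + tm)] = _I_MYO
    img[half_ellipse(w2, delta, apex_b)] = _I_BLOOD

    # atrium above the plane (negative b side)
    atr = (b < delta) & (b > delta - _ATRIUM_DEPTH_MM) & (np.abs(a) <= 0.8 * w2)
    img[atr] = _I_ATRIUM

    if view == "four_chamber":
        # neighbouring (right-ventricular) chamber beside the septum
        ar = a + 2.1 * w2
        rel = (b - delta) / (0.8 * (apex_b - delta))
        inside = (rel >= 0.0) & (rel <= 1.0)
        lim = np.zeros_like(a)
        lim[inside] = 0.7 * w2 * np.sqrt(np.clip(1.0 - rel[inside] ** 2, 0.0, 1.0))
        img[inside & (np.abs(ar) <= lim)] = _I_RV
    return img


def render_cine(
    motion: MotionProfileParams, render: RenderParams, seed: int
) -> tuple[CineSeries, MVAnnotation]:
    """Render one view's cine phantom and its exact annotation.

    The annulus endpoints sit at the junctions where the bright blood pool,
    the dark myocardial shell and the atrium meet; both translate rigidly
    along the long axis following the displacement profile.  The returned
    annotation holds the analytic continuous coordinates of the two valve
    points at every frame (offset ``convention_offset_mm`` toward the apex
    under the basal-myocardium convention).  Identical seeds give
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    rows, cols = render.image_size
    sx, sy = render.pixel_spacing_mm
    center = render.center_px
    e1, e2 = _axis_vectors(render.heart_rotation_deg)
    w2 = render.annulus_width_mm / 2.0

    profile = generate_displacement_profile(motion)
    deltas = profile.values

    # analytic annotation (canonical (a, b) -> image pixels)
    offset_b = (
        render.convention_offset_mm
        if render.annotation_convention == BASAL_MYOCARDIUM
        else 0.0
    )
    points = np.empty((motion.n_frames, 2, 2))
    for i, delta in enumerate(deltas):
        for j, a_mm in enumerate((-w2, +w2)):
            v_mm = a_mm * e1 + (delta + offset_b) * e2
            points[i, j] = center + np.array([v_mm[0] / sx, v_mm[1] / sy])
    if render.annotation_jitter_px > 0:
        points = points + rng.normal(0.0, render.annotation_jitter_px, points.shape)

    bad = np.flatnonzero(
        (points[..., 0] < 0).any(axis=1)
        | (points[..., 0] > cols - 1).any(axis=1)
        | (points[..., 1] < 0).any(axis=1)
        | (points[..., 1] > rows - 1).any(axis=1)
    )
    if bad.size:
        raise RenderError(
            f"MV point outside the {rows}x{cols} image at frame {int(bad[0])}"
        )

    # canonical coordinates of every pixel (shared across frames)
    cgrid, rgrid = np.meshgrid(np.arange(cols), np.arange(rows))
    dx = (cgrid - center[0]) * sx
    dy = (rgrid - center[1]) * sy
    a = dx * e1[0] + dy * e1[1]
    b = dx * e2[0] + dy * e2[1]

    frames = np.empty((motion.n_frames, rows, cols))
    for i, delta in enumerate(deltas):
        frames[i] = _render_frame(a, b, float(delta), w2, render.view)
    if motion.noise_sd > 0:
        frames = frames + rng.normal(0.0, motion.noise_sd, frames.shape)

    cine = CineSeries(
        frames=frames,
        pixel_spacing_mm=render.pixel_spacing_mm,
        frame_times_s=profile.times.copy(),
        view=render.view,
    )
    ann = MVAnnotation.for_view(points, render.view)
    return cine, ann


# --------------------------------------------------------------------------
# dataset sampling
# --------------------------------------------------------------------------

#: Default per-subject sampling ranges, matching the variability of clinical
#: long-axis cine acquisitions: 1.3-1.7 mm resolution, 25-50 frames/cycle,
#: arbitrary orientation and modest field-of-view shifts.
DEFAULT_PARAM_RANGES: dict[str, tuple[float, float]] = {
    "mapse_mm": (8.0, 18.0),
    "hr_bpm": (50.0, 90.0),
    "n_frames": (25, 50),
    "systole_fraction": (0.30, 0.42),
    "diastasis_fraction": (0.15, 0.35),
    "atrial_kick_fraction_of_mapse": (0.20, 0.40),
    "noise_sd": (0.03, 0.03),
    "pixel_spacing_mm": (1.3, 1.7),
    "image_size": (150, 200),
    "heart_rotation_deg": (0.0, 360.0),
    "center_jitter_frac": (-0.08, 0.08),
    "annulus_width_mm": (25.0, 35.0),
}


@dataclass
class SubjectSpec:
    """Sampled generating parameters for one synthetic subject."""

    subject_id: str
    motion: MotionProfileParams
    render: dict[str, RenderParams]  # keyed by view
    seed: int
    split: str = ""

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "split": self.split,
            "seed": self.seed,
            "motion": asdict(self.motion),
            "render": {v: asdict(r) for v, r in self.render.items()},
        }


def _uniform(rng: np.random.Generator, ranges: dict, key: str) -> float:
    lo, hi = ranges[key]
    return float(lo) if lo == hi else float(rng.uniform(lo, hi))


def sample_subject(
    subject_id: str,
    rng: np.random.Generator,
    param_ranges: dict | None = None,
    annotation_convention: str = VALVE_INTERSECTION,
    convention_offset_mm: float = 2.0,
) -> SubjectSpec:
    """Draw one subject's motion and per-view render parameters."""
    ranges = dict(DEFAULT_PARAM_RANGES)
    if param_ranges:
        ranges.update(param_ranges)
    motion = MotionProfileParams(
        mapse_mm=_uniform(rng, ranges, "mapse_mm"),
        hr_bpm=_uniform(rng, ranges, "hr_bpm"),
        n_frames=int(rng.integers(ranges["n_frames"][0], ranges["n_frames"][1] + 1)),
        systole_fraction=_uniform(rng, ranges, "systole_fraction"),
        diastasis_fraction=_uniform(rng, ranges, "diastasis_fraction"),
        atrial_kick_fraction_of_mapse=_uniform(
            rng, ranges, "atrial_kick_fraction_of_mapse"
        ),
        noise_sd=_uniform(rng, ranges, "noise_sd"),
    )
    render: dict[str, RenderParams] = {}
    for view in ("two_chamber", "four_chamber"):
        spacing = _uniform(rng, ranges, "pixel_spacing_mm")
        lo, hi = ranges["image_size"]
        size = (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
        jx = _uniform(rng, ranges, "center_jitter_frac")
        jy = _uniform(rng, ranges, "center_jitter_frac")
        center = ((size[1] - 1) / 2.0 * (1 + jx), (size[0] - 1) / 2.0 * (1 + jy))
        render[view] = RenderParams(
            pixel_spacing_mm=(spacing, spacing),
            image_size=size,
            heart_rotation_deg=_uniform(rng, ranges, "heart_rotation_deg"),
            heart_center_px=center,
            annulus_width_mm=_uniform(rng, ranges, "annulus_width_mm"),
            view=view,
            annotation_convention=annotation_convention,
            convention_offset_mm=convention_offset_mm,
        )
    seed = int(rng.integers(0, 2**31 - 1))
    return SubjectSpec(subject_id=subject_id, motion=motion, render=render, seed=seed)


def render_subject(spec: SubjectSpec) -> dict[str, tuple[CineSeries, MVAnnotation]]:
    """Render both views of a subject; deterministic in the subject seed."""
    out = {}
    for k, view in enumerate(sorted(spec.render)):
        out[view] = render_cine(spec.motion, spec.render[view], spec.seed + k)
    return out


def sample_dataset(
    n_subjects: int,
    param_ranges: dict | None = None,
    split: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    **subject_kwargs,
) -> list[SubjectSpec]:
    """Sample subject parameter sets with a subject-disjoint train/test split."""
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    f_train, f_test = split
    if f_train + f_test > 1.0 + 1e-12:
        raise ValueError("split fractions must sum to <= 1")
    n_train = int(round(n_subjects * f_train))
    n_test = int(round(n_subjects * f_test))
    n_train = min(n_train, n_subjects)
    n_test = min(n_test, n_subjects - n_train)

    children = np.random.SeedSequence(seed).spawn(n_subjects)
    specs = []
    for i, child in enumerate(children):
        spec = sample_subject(
            f"s{i:04d}", np.random.default_rng(child), param_ranges, **subject_kwargs
        )
        spec.split = "train" if i < n_train else ("test" if i < n_train + n_test else "unused")
        specs.append(spec)
    return specs


def make_dataset(
    n_subjects: int,
    out_dir,
    param_ranges: dict | None = None,
    split: tuple[float, float] = (0.8, 0.2),
    seed: int = 0,
    **subject_kwargs,
) -> dict:
    """Render a dataset to disk and write its manifest.

    Writes one NIfTI cine and one annotation CSV per subject and view under
    ``out_dir`` plus a ``manifest.json`` listing paths, splits and the
    generating parameters.  Two calls with equal arguments produce identical
    manifests and data.
    """
    from pathlib import Path

    from . import io as mio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    specs = sample_dataset(n_subjects, param_ranges, split, seed, **subject_kwargs)

    manifest: dict = {"seed": int(seed), "n_subjects": int(n_subjects), "subjects": []}
    for spec in specs:
        entry = spec.to_dict()
        entry["views"] = {}
        for view, (cine, ann) in render_subject(spec).items():
            stem = f"{spec.subject_id}_{view}"
            cine_path = out_dir / f"{stem}.nii.gz"
            ann_path = out_dir / f"{stem}_gt.csv"
            mio.write_cine(cine, cine_path)
            mio.write_annotations(
                ann, ann_path, subject_id=spec.subject_id, source="ground_truth"
            )
            entry["views"][view] = {
                "cine": cine_path.name,
                "annotations": ann_path.name,
            }
        manifest["subjects"].append(entry)
    mio.write_json_atomic(manifest, out_dir / "manifest.json")
    return manifest
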