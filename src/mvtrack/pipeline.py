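"""Dual-stage coarse-to-fine tracking of the mitral valve plane.

Per cine and view: a coarse pass predicts the two valve points on every
frame of the 160x160-resized cine; the coarse annotation fixes an automated
standardization transform (0.75 mm isotropic, valve horizontal, apex down,
118x162 crop); a refinement pass predicts on the standardized frames and
maps the predictions back to the original grid through the exact inverse
transform.  The refinement can be iterated — each pass re-estimates the
standardization from the latest annotation — and the default of two passes
implements the "stage 1+2+2" configuration, past which accuracy no longer
improves.

Every reported point is the image of a network prediction under an exactly
invertible transform, so with ground-truth-lookup models the whole pipeline
reproduces ground truth to floating-point precision; this oracle route
(:class:`OraclePredictor`) isolates plumbing errors from learning errors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .core import CineSeries, DegeneratePlaneError, AmbiguousApexError, MVAnnotation
from .geometry import (
    SimilarityTransform,
    apply_transform,
    estimate_standardization,
    map_points,
    resize_to_network_grid,
)
from .regressor import RegressorConfig, TrainedRegressor, train_regressor


class OraclePredictor:
    """Ground-truth-lookup stand-in satisfying the predictor contract.

    Holds the exact annotation in original-image coordinates and answers
    predictions in any derived grid by mapping the truth through the
    transform the pipeline used to produce that grid.  Used to validate the
    pipeline's plumbing (resize, standardize, inverse map, iterate)
    independently of any trained network.
    """

    def __init__(self, gt: MVAnnotation, input_size: tuple[int, int] | None = None):
        self.gt = gt
        self.input_size = input_size

    def predict_stack(
        self, frames: np.ndarray, transform: SimilarityTransform | None = None
    ) -> np.ndarray:
        if frames.shape[0] != self.gt.n_frames:
            raise ValueError("frame count does not match the stored annotation")
        pts = self.gt.points
        return map_points(pts, transform, "forward") if transform is not None else pts.copy()


def _predict(model, frames: np.ndarray, transform: SimilarityTransform) -> np.ndarray:
    """Dispatch to a trained regressor or an oracle stand-in."""
    if isinstance(model, OraclePredictor):
        return model.predict_stack(frames, transform)
    return model.predict_stack(frames)


@dataclass
class TrackingResult:
    """Stage-wise annotations (original coordinates) for one cine and view."""

    annotations: dict[str, MVAnnotation]  # "stage1", "stage1+2", "stage1+2+2", ...
    transforms: list[SimilarityTransform] = field(default_factory=list)
    view: str | None = None

    @property
    def final(self) -> MVAnnotation:
        return self.annotations[list(self.annotations)[-1]]


def stage1_coarse(cine: CineSeries, model) -> MVAnnotation:
    """Coarse annotation of every frame via the fixed 160x160 grid.

    Resizes the cine (cubic), predicts per frame, and maps the points back
    to the original grid through the resize transform's inverse.
    """
    size = getattr(model, "input_size", None)
    if size is None:
        size = model.config.input_size if hasattr(model, "config") else (160, 160)
    resized, transform = resize_to_network_grid(cine, tuple(size))
    preds = _predict(model, resized.frames, transform)
    pts = map_points(preds, transform, "inverse")
    return MVAnnotation(pts, _labels_for(cine, model), cine.view)


def _labels_for(cine: CineSeries, model) -> tuple[str, str]:
    from .core import VIEW_LABELS

    if isinstance(model, OraclePredictor):
        return model.gt.labels
    return VIEW_LABELS.get(cine.view, ("point_a", "point_b"))


def stage2_refine(
    cine: CineSeries, current: MVAnnotation, model
) -> tuple[MVAnnotation, SimilarityTransform]:
    """One refinement pass: standardize from ``current``, predict, map back."""
    if current.n_frames < 2:
        raise AmbiguousApexError("refinement needs an annotation covering >= 2 frames")
    transform = estimate_standardization(current, cine)
    std = apply_transform(cine, transform)
    preds = _predict(model, std.cine.frames, transform)
    pts = map_points(preds, transform, "inverse")
    return MVAnnotation(pts, current.labels, cine.view), transform


def track_mv(
    cine: CineSeries, stage1_model, stage2_model, n_refine: int = 2
) -> TrackingResult:
    """Run the full dual-stage pipeline on one cine.

    ``n_refine`` successive refinement passes follow the coarse pass, each
    re-estimating the standardization from the most recent annotation;
    the default of 2 is the "stage 1+2+2" configuration.  A refinement that
    fails on a degenerate annotation falls back to the last successful
    stage's annotation with a warning, so batch runs never abort on one
    cine.
    """
    if n_refine < 0:
        raise ValueError("n_refine must be >= 0")
    ann = stage1_coarse(cine, stage1_model)
    result = TrackingResult(annotations={"stage1": ann}, view=cine.view)
    name = "stage1"
    for _ in range(n_refine):
        name += "+2"
        try:
            ann, transform = stage2_refine(cine, ann, stage2_model)
            result.transforms.append(transform)
        except (DegeneratePlaneError, AmbiguousApexError) as exc:
            warnings.warn(
                f"refinement failed ({exc}); keeping the previous stage's annotation",
                stacklevel=2,
            )
        result.annotations[name] = ann.copy()
    return result


# --------------------------------------------------------------------------
# training-set assembly
# --------------------------------------------------------------------------

def build_stage1_training_set(
    cines_and_gt, size: tuple[int, int] = (160, 160), frames_per_cine: int | None = None,
    seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble (resized frame, mapped points) pairs for the coarse network.

    ``cines_and_gt`` iterates over ``(CineSeries, MVAnnotation)``.  With
    ``frames_per_cine`` set, an evenly spread subset of frames is taken from
    each cine (deterministic in ``seed``) to keep desk-scale training sets
    small.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cine, gt in cines_and_gt:
        resized, transform = resize_to_network_grid(cine, size)
        pts = map_points(gt.points, transform, "forward")
        idx = _frame_subset(cine.n_frames, frames_per_cine, rng)
        xs.append(resized.frames[idx].astype(np.float32))
        ys.append(pts[idx])
    return np.concatenate(xs), np.concatenate(ys)


def build_stage2_training_set(
    cines_and_gt, frames_per_cine: int | None = None, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Assemble standardized (crop, mapped points) pairs for the refiner.

    Standardization is estimated from the ground-truth annotation itself,
    exactly as the published recipe trains the second network on images
    standardized from the reference points; train-time augmentation is what
    teaches the refiner to absorb residual stage-1 misalignment.
    """
    rng = np.random.default_rng(seed)
    xs, ys = [], []
    for cine, gt in cines_and_gt:
        transform = estimate_standardization(gt, cine)
        std = apply_transform(cine, transform)
        pts = map_points(gt.points, transform, "forward")
        idx = _frame_subset(cine.n_frames, frames_per_cine, rng)
        xs.append(std.cine.frames[idx].astype(np.float32))
        ys.append(pts[idx])
    return np.concatenate(xs), np.concatenate(ys)


def _frame_subset(n_frames: int, k: int | None, rng: np.random.Generator) -> np.ndarray:
    if k is None or k >= n_frames:
        return np.arange(n_frames)
    # evenly spread with a random phase so all cycle phases are seen
    base = np.linspace(0, n_frames - 1, k)
    jitter = rng.integers(0, max(1, n_frames // k), size=k)
    return np.unique(np.clip(np.round(base + jitter).astype(int), 0, n_frames - 1))


def build_training_sets(
    cines_and_gt,
    stage1_size: tuple[int, int] = (160, 160),
    frames_per_cine: int | None = None,
    seed: int = 0,
):
    """One-pass assembly of the coarse and refinement training sets.

    Iterates ``(CineSeries, MVAnnotation)`` once — cines can therefore come
    from a generator and be released immediately, which keeps memory flat
    for large synthetic datasets.  Returns float32 arrays
    ``(x1, y1, x2, y2)``.
    """
    rng = np.random.default_rng(seed)
    x1s, y1s, x2s, y2s = [], [], [], []
    for cine, gt in cines_and_gt:
        idx = _frame_subset(cine.n_frames, frames_per_cine, rng)
        resized, t1 = resize_to_network_grid(cine, stage1_size)
        x1s.append(resized.frames[idx].astype(np.float32))
        y1s.append(map_points(gt.points[idx], t1, "forward"))
        t2 = estimate_standardization(gt, cine)
        std = apply_transform(cine, t2)
        x2s.append(std.cine.frames[idx].astype(np.float32))
        y2s.append(map_points(gt.points[idx], t2, "forward"))
    return (
        np.concatenate(x1s), np.concatenate(y1s),
        np.concatenate(x2s), np.concatenate(y2s),
    )


def train_dual_stage(
    train_subjects,
    stage1_config: RegressorConfig,
    stage2_config: RegressorConfig,
    frames_per_cine: int | None = 3,
    progress: bool = False,
) -> tuple[TrainedRegressor, TrainedRegressor]:
    """Train the coarse and refinement regressors from rendered subjects.

    ``train_subjects`` iterates over ``(CineSeries, MVAnnotation)`` pairs
    pooled over views — one model per stage is shared between the chamber
    views, which the schematic phantoms support.
    """
    x1, y1, x2, y2 = build_training_sets(
        train_subjects, stage1_config.input_size, frames_per_cine,
        seed=stage1_config.seed,
    )
    m1 = train_regressor(x1, y1, stage1_config, progress=progress)
    del x1, y1
    m2 = train_regressor(x2, y2, stage2_config, progress=progress)
    return m1, m2
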