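"""Coordinate transforms for the dual-stage tracking pipeline.

Two linear resampling steps surround the landmark networks: the coarse stage
resizes arbitrary input frames to a fixed 160x160 grid, and the refinement
stage resamples the cine onto a *standardized* grid — 0.75 mm isotropic
spacing, the valve plane horizontal with the apex pointing down, cropped to
118x162 around the annulus midpoint.  Both steps are expressed as a single
:class:`SimilarityTransform` so that predicted points can be mapped back to
the original image exactly (to floating-point precision), independent of any
image interpolation error.

Point convention (see :mod:`mvtrack.core`): 0-based, ``(x, y)`` =
``(column, row)``, pixel centers at integer coordinates.  A positive
rotation angle turns the +x axis toward +y (i.e. clockwise on screen, since
rows grow downward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import (
    STANDARD_SIZE,
    STANDARD_SPACING_MM,
    AmbiguousApexError,
    CineSeries,
    DegeneratePlaneError,
    MVAnnotation,
)

_SWAP = np.array([[0.0, 1.0], [1.0, 0.0]])


@dataclass(frozen=True)
class SimilarityTransform:
    """Invertible affine map between two pixel grids.

    Forward mapping: ``p_out = matrix @ p_in + translation`` with ``p`` as
    ``(x, y)`` column vectors.  Constructed transforms are of the form
    ``matrix = R(rotation) @ diag(scale_x, scale_y)``, i.e. an (optionally
    anisotropic) axis-aligned scaling followed by a rotation; composition of
    two transforms multiplies the matrices and may leave that family, which
    is why the matrix itself is stored.
    """

    matrix: np.ndarray
    translation: np.ndarray
    output_size: tuple[int, int]  # (rows, cols)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        t = np.asarray(self.translation, dtype=float).reshape(2)
        if not np.all(np.isfinite(m)) or not np.all(np.isfinite(t)):
            raise ValueError("transform parameters must be finite")
        if abs(np.linalg.det(m)) < 1e-15:
            raise ValueError("transform matrix is singular")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "translation", t)
        object.__setattr__(self, "output_size", tuple(int(v) for v in self.output_size))

    # -- construction -----------------------------------------------------
    @classmethod
    def from_params(
        cls,
        scale: float | tuple[float, float],
        rotation_deg: float,
        translation_px: tuple[float, float],
        output_size: tuple[int, int],
    ) -> "SimilarityTransform":
        sx, sy = (scale, scale) if np.isscalar(scale) else scale
        if sx <= 0 or sy <= 0:
            raise ValueError("scale components must be positive")
        th = np.deg2rad(rotation_deg)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        return cls(rot @ np.diag([sx, sy]), np.asarray(translation_px, float), output_size)

    @classmethod
    def identity(cls, output_size: tuple[int, int]) -> "SimilarityTransform":
        return cls(np.eye(2), np.zeros(2), output_size)

    # -- parameter views --------------------------------------------------
    def _decompose(self) -> tuple[tuple[float, float], float]:
        """Recover (scale, rotation_deg) when the matrix is R @ diag(s)."""
        sx = float(np.linalg.norm(self.matrix[:, 0]))
        sy = float(np.linalg.norm(self.matrix[:, 1]))
        rot = self.matrix @ np.diag([1.0 / sx, 1.0 / sy])
        if not np.allclose(rot.T @ rot, np.eye(2), atol=1e-9) or np.linalg.det(rot) < 0:
            raise ValueError("transform is not a rotation-times-scaling")
        angle = float(np.rad2deg(np.arctan2(rot[1, 0], rot[0, 0])))
        return (sx, sy), angle

    @property
    def scale(self) -> tuple[float, float]:
        return self._decompose()[0]

    @property
    def rotation_deg(self) -> float:
        return self._decompose()[1]

    # -- point mapping ----------------------------------------------------
    def forward(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.matrix.T + self.translation

    def inverse(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return np.linalg.solve(self.matrix, (pts - self.translation).T).T

    def inv(self, output_size: tuple[int, int]) -> "SimilarityTransform":
        """The inverse transform, targeting the given output grid size."""
        minv = np.linalg.inv(self.matrix)
        return SimilarityTransform(minv, -minv @ self.translation, output_size)

    def compose(self, first: "SimilarityTransform") -> "SimilarityTransform":
        """The transform equivalent to applying ``first``, then ``self``."""
        return SimilarityTransform(
            self.matrix @ first.matrix,
            self.matrix @ first.translation + self.translation,
            self.output_size,
        )

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d: dict = {"output_size": list(self.output_size)}
        try:
            (sx, sy), rot = self._decompose()
            d.update(scale=[sx, sy], rotation_deg=rot)
        except ValueError:
            d["matrix"] = self.matrix.tolist()
        d["translation_px"] = self.translation.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimilarityTransform":
        size = tuple(d["output_size"])
        if "matrix" in d:
            return cls(np.asarray(d["matrix"]), np.asarray(d["translation_px"]), size)
        return cls.from_params(
            tuple(d["scale"]), d["rotation_deg"], tuple(d["translation_px"]), size
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "SimilarityTransform":
        return cls.from_dict(json.loads(s))


def map_points(
    points: np.ndarray, transform: SimilarityTransform, direction: str = "forward"
) -> np.ndarray:
    """Map continuous ``(x, y)`` coordinates through a transform.

    ``direction="forward"`` maps input-grid points to the output grid;
    ``"inverse"`` maps back.  Mapping is exact affine arithmetic and is the
    round-trip-safe path for annotations (images are resampled separately).
    Accepts any array whose last axis has length 2.
    """
    pts = np.asarray(points, dtype=float)
    if pts.shape[-1] != 2:
        raise ValueError("points must have a trailing axis of length 2")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    flat = pts.reshape(-1, 2)
    if direction == "forward":
        out = transform.forward(flat)
    elif direction == "inverse":
        out = transform.inverse(flat)
    else:
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    return out.reshape(pts.shape)


def _resample_stack(
    frames: np.ndarray, transform: SimilarityTransform, order: int = 3
) -> np.ndarray:
    """Resample every frame onto the transform's output grid (one pass).

    Uses the inverse mapping: for each output pixel the source location in
    the input grid is computed from the single composed transform, then
    sampled with an interpolating cubic spline.  Out-of-field samples are
    zero-filled.
    """
    minv = np.linalg.inv(transform.matrix)
    # ndimage works in (row, col) coordinates; ours are (x, y) = (col, row).
    matrix_rc = _SWAP @ minv @ _SWAP
    offset_rc = -_SWAP @ minv @ transform.translation
    out = np.empty((frames.shape[0], *transform.output_size), dtype=float)
    for i, frame in enumerate(frames):
        ndimage.affine_transform(
            np.asarray(frame, dtype=float),
            matrix_rc,
            offset=offset_rc,
            output_shape=transform.output_size,
            output=out[i],
            order=order,
            mode="constant",
            cval=0.0,
        )
    return out


def resize_to_network_grid(
    cine: CineSeries, size: tuple[int, int] = (160, 160)
) -> tuple[CineSeries, SimilarityTransform]:
    """Resize each frame to the coarse network's fixed grid.

    Frames are resampled with cubic interpolation to ``size`` (rows, cols)
    regardless of aspect ratio, so pixels generally become anisotropic.  The
    returned transform maps original-grid points to resized-grid points:
    pure per-axis scaling of pixel-center coordinates by
    ``cols_out / cols_in`` and ``rows_out / rows_in``.
    """
    rows_in, cols_in = cine.shape
    rows_out, cols_out = size
    if rows_in <= 1 or cols_in <= 1:
        raise ValueError(f"degenerate input image of shape {cine.shape}")
    scale = (cols_out / cols_in, rows_out / rows_in)
    transform = SimilarityTransform.from_params(scale, 0.0, (0.0, 0.0), size)
    if (rows_in, cols_in) == tuple(size):
        frames = cine.frames.astype(float, copy=True)
    else:
        frames = _resample_stack(cine.frames, transform, order=3)
    sx, sy = cine.pixel_spacing_mm
    resized = CineSeries(
        frames=frames,
        pixel_spacing_mm=(sx / scale[0], sy / scale[1]),
        frame_times_s=None if cine.frame_times_s is None else cine.frame_times_s.copy(),
        view=cine.view,
    )
    return resized, transform


def crop_center() -> np.ndarray:
    """Continuous coordinates of the standardized crop center, ``(x, y)``."""
    rows, cols = STANDARD_SIZE
    return np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])


def estimate_standardization(
    coarse: MVAnnotation, cine: CineSeries
) -> SimilarityTransform:
    """Estimate the stage-2 standardization transform from a coarse annotation.

    The transform (i) scales each axis by ``pixel_spacing / 0.75`` so the
    output grid is 0.75 mm isotropic, (ii) rotates about the frame-0 annulus
    midpoint so the frame-0 valve segment is horizontal — the anterior
    (2-chamber) or lateral (4-chamber) point on the left — with the apex
    side pointing down, and (iii) translates the frame-0 midpoint to the
    center of the 118x162 crop.

    The apex side is the side of the frame-0 plane toward which the mean of
    the remaining frames' annulus midpoints lies (the valve moves toward the
    apex during systole).  When the left-point and apex-down requirements
    conflict (a mirrored acquisition), apex-down wins: both candidate
    rotations that make the segment horizontal are tried and the one mapping
    the later midpoints to larger row values is kept.
    """
    if coarse.n_frames < 2:
        raise AmbiguousApexError(
            "at least two annotated frames are required to determine the apex side"
        )
    sx_mm, sy_mm = cine.pixel_spacing_mm
    scale = np.array([sx_mm / STANDARD_SPACING_MM, sy_mm / STANDARD_SPACING_MM])

    p_left, p_right = coarse.points[0, 0] * scale, coarse.points[0, 1] * scale
    seg = p_right - p_left
    if np.linalg.norm(seg) < 1e-12:
        raise DegeneratePlaneError("frame-0 annulus points coincide")
    theta0 = -np.degrees(np.arctan2(seg[1], seg[0]))

    mid0 = coarse.points[0].mean(axis=0) * scale
    later_mids = coarse.points[1:].mean(axis=1) * scale

    best = None
    for theta in (theta0, theta0 + 180.0):
        th = np.deg2rad(theta)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        offset = float(np.mean((later_mids - mid0) @ rot.T, axis=0)[1])
        if best is None or offset > best[1]:
            best = (theta, offset)
    theta, apex_offset = best
    if apex_offset <= 0.0:
        raise AmbiguousApexError(
            "later-frame midpoints do not separate from the frame-0 plane; "
            "apex side is undetermined"
        )

    th = np.deg2rad(theta)
    rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
    matrix = rot @ np.diag(scale)
    mid0_px = coarse.points[0].mean(axis=0)
    translation = crop_center() - matrix @ mid0_px
    return SimilarityTransform(matrix, translation, STANDARD_SIZE)


@dataclass
class StandardizedCine:
    """A cine resampled onto the standardized grid plus the transform used."""

    cine: CineSeries
    transform: SimilarityTransform

    def __post_init__(self) -> None:
        if self.cine.shape != STANDARD_SIZE:
            raise ValueError(
                f"standardized cine must be {STANDARD_SIZE}, got {self.cine.shape}"
            )


def apply_transform(cine: CineSeries, transform: SimilarityTransform) -> StandardizedCine:
    """Resample a cine onto the standardized grid in a single pass.

    All frames go through the one composed transform (no sequential
    resample-rotate-crop), with cubic interpolation and zero fill outside
    the original field of view.
    """
    frames = _resample_stack(cine.frames, transform, order=3)
    std = CineSeries(
        frames=frames,
        pixel_spacing_mm=(STANDARD_SPACING_MM, STANDARD_SPACING_MM),
        frame_times_s=None if cine.frame_times_s is None else cine.frame_times_s.copy(),
        view=cine.view,
    )
    return StandardizedCine(cine=std, transform=transform)
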