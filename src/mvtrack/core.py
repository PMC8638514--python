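"""Core data containers for mitral-valve plane tracking.

Coordinate convention used throughout the package: 0-based pixel indices,
``x`` = column, ``y`` = row, pixel centers at integer coordinates, origin at
the top-left of the image.  Points are stored as ``(x, y)`` pairs; pixel
spacing is stored as ``(spacing_x_mm, spacing_y_mm)`` in the same axis order.
The image *apex* direction corresponds to increasing row values once a cine
has been standardized.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

#: Isotropic pixel spacing of the standardized (stage-2) grid, in mm.
STANDARD_SPACING_MM = 0.75
#: Standardized crop size as (rows, cols); the wide axis spans the annulus.
STANDARD_SIZE = (118, 162)
#: Fixed input grid of the coarse (stage-1) network as (rows, cols).
NETWORK_SIZE = (160, 160)

#: Point labels per long-axis view; the first label is the point placed on
#: the left after standardization (anterior for 2-chamber, lateral for
#: 4-chamber).
VIEW_LABELS = {
    "two_chamber": ("anterior", "inferior"),
    "four_chamber": ("lateral", "septal"),
}


class DegeneratePlaneError(ValueError):
    """The two annulus points coincide and no valve plane is defined."""


class AmbiguousApexError(ValueError):
    """The apex side of the valve plane cannot be determined."""


@dataclass
class CineSeries:
    """One view's time-resolved grayscale image stack.

    Parameters
    ----------
    frames
        Array of shape ``(n_frames, rows, cols)``.
    pixel_spacing_mm
        In-plane spacing ``(spacing_x, spacing_y)``; may be anisotropic.
    frame_times_s
        Time of each frame from the start of the cycle, seconds.  ``None``
        means timing metadata is absent; consumers fall back to a 1.0 s
        RR interval with a warning.
    view
        ``"two_chamber"`` or ``"four_chamber"`` (optional, metadata only).
    """

    frames: np.ndarray
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0)
    frame_times_s: np.ndarray | None = None
    view: str | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError(
                f"frames must be (n_frames, rows, cols); got shape {self.frames.shape}"
            )
        sx, sy = self.pixel_spacing_mm
        if not (sx > 0 and sy > 0):
            raise ValueError("pixel spacing must be positive")
        if self.frame_times_s is not None:
            self.frame_times_s = np.asarray(self.frame_times_s, dtype=float)
            if self.frame_times_s.shape != (self.n_frames,):
                raise ValueError("frame_times_s length must match frame count")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of a single frame."""
        return self.frames.shape[1:]


@dataclass
class MVAnnotation:
    """Per-frame pair of mitral-valve insertion points.

    ``points`` has shape ``(n_frames, 2, 2)``: frame, point index, ``(x, y)``
    in continuous 0-based pixel coordinates of the image the annotation
    refers to.  Point index 0 carries ``labels[0]`` (the anterior/lateral
    point), index 1 carries ``labels[1]`` (inferior/septal).  Labels are
    never permuted by any operation in this package.
    """

    points: np.ndarray
    labels: tuple[str, str]
    view: str | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 3 or self.points.shape[1:] != (2, 2):
            raise ValueError(
                f"points must be (n_frames, 2, 2); got shape {self.points.shape}"
            )
        self.labels = tuple(self.labels)
        if len(self.labels) != 2:
            raise ValueError("exactly two point labels are required")

    @classmethod
    def for_view(cls, points: np.ndarray, view: str) -> "MVAnnotation":
        return cls(points=points, labels=VIEW_LABELS[view], view=view)

    @property
    def n_frames(self) -> int:
        return self.points.shape[0]

    def midpoints(self) -> np.ndarray:
        """Per-frame annulus midpoints, shape ``(n_frames, 2)``."""
        return self.points.mean(axis=1)

    def copy(self) -> "MVAnnotation":
        return MVAnnotation(self.points.copy(), self.labels, self.view)


@dataclass
class DisplacementCurve:
    """Signed MV plane displacement over the cycle.

    ``values`` are millimetres, positive toward the apex, zero at frame 0
    (the end-diastolic reference plane).  ``times`` are seconds from frame 0.
    """

    times: np.ndarray
    values: np.ndarray
    view: str = "resultant"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class VelocityCurve:
    """Time-derivative of a displacement curve, in cm/s (same sign rules)."""

    times: np.ndarray
    values: np.ndarray
    view: str = "resultant"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")

    def __len__(self) -> int:
        return self.values.size


@dataclass
class ClinicalMetrics:
    """MAPSE and the three global annular velocity peaks.

    Velocity peaks are reported as positive magnitudes (the field's
    convention); ``nan`` plus ``complete=False`` marks peaks that could not
    be derived (e.g. a two-frame ED/ES-only annotation, or an absent atrial
    kick).  Peak times in seconds from frame 0.
    """

    mapse_mm: float
    mapse_time_s: float
    s_prime_cm_s: float = float("nan")
    s_prime_time_s: float = float("nan")
    e_prime_cm_s: float = float("nan")
    e_prime_time_s: float = float("nan")
    a_prime_cm_s: float = float("nan")
    a_prime_time_s: float = float("nan")
    complete: bool = True

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
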