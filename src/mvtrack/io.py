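"""Readers and writers for cines, annotations, configs and manifests.

Cines travel as NIfTI (one file per cine, frames along the last axis, with
an optional JSON sidecar carrying view and exact frame times), as a
directory of single-frame DICOM files (read-only, ordered by instance
number), or as a directory of ordered PNG/TIFF frames with a JSON metadata
sidecar.  Annotations are plain CSV with one row per point:

    subject_id, view, frame_index, point_label, x_px, y_px, source

Coordinates are stored in original-image pixels at full precision with the
pixel spacing carried separately, so nothing is ever converted twice.  All
writes are atomic (temp file + rename).
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import VIEW_LABELS, CineSeries, MVAnnotation

VALID_SOURCES = {"manual", "stage1", "stage1+2", "stage1+2+2", "ground_truth"}
_VALID_LABELS = {lab for pair in VIEW_LABELS.values() for lab in pair}


# --------------------------------------------------------------------------
# atomic write helpers
# --------------------------------------------------------------------------

def _atomic_write_bytes(data: bytes, path: Path) -> None:
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_json_atomic(obj, path) -> None:
    _atomic_write_bytes(
        json.dumps(obj, indent=2, sort_keys=True).encode(), Path(path)
    )


# --------------------------------------------------------------------------
# cine I/O
# --------------------------------------------------------------------------

def write_cine(cine: CineSeries, path, png_debug_dir=None) -> None:
    """Write a cine as NIfTI (frames along the last axis) plus JSON sidecar.

    Optionally dumps one 8-bit PNG per frame into ``png_debug_dir``.
    """
    import nibabel as nib

    path = Path(path)
    data = np.moveaxis(cine.frames.astype(np.float32), 0, -1)  # (rows, cols, T)
    sx, sy = cine.pixel_spacing_mm
    affine = np.diag([sy, sx, 1.0, 1.0])
    img = nib.Nifti1Image(data, affine)
    dt = 0.0
    if cine.frame_times_s is not None and cine.n_frames > 1:
        dt = float(cine.frame_times_s[1] - cine.frame_times_s[0])
    img.header.set_zooms((sy, sx, dt))
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".nii.gz")
    os.close(fd)
    try:
        nib.save(img, tmp)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
    sidecar = {
        "pixel_spacing_mm": list(cine.pixel_spacing_mm),
        "view": cine.view,
        "frame_times_s": None
        if cine.frame_times_s is None
        else [float(t) for t in cine.frame_times_s],
    }
    write_json_atomic(sidecar, path.with_name(
        path.name.removesuffix(".nii.gz").removesuffix(".nii") + ".meta.json"
    ))
    if png_debug_dir is not None:
        import imageio.v3 as iio

        dbg = Path(png_debug_dir)
        dbg.mkdir(parents=True, exist_ok=True)
        lo, hi = cine.frames.min(), cine.frames.max()
        scale = 255.0 / (hi - lo) if hi > lo else 1.0
        for i, frame in enumerate(cine.frames):
            iio.imwrite(
                dbg / f"frame_{i:03d}.png",
                ((frame - lo) * scale).astype(np.uint8),
            )


def _read_nifti(path: Path) -> CineSeries:
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj, dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D (rows, cols, frames) NIfTI")
    frames = np.moveaxis(data, -1, 0)
    zooms = img.header.get_zooms()
    spacing = (float(zooms[1]), float(zooms[0]))  # (x, y)
    times = None
    meta_path = path.with_name(
        path.name.removesuffix(".nii.gz").removesuffix(".nii") + ".meta.json"
    )
    view = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        spacing = tuple(meta.get("pixel_spacing_mm", spacing))
        view = meta.get("view")
        if meta.get("frame_times_s") is not None:
            times = np.asarray(meta["frame_times_s"], dtype=float)
    if times is None and len(zooms) > 2 and zooms[2] > 0:
        times = np.arange(frames.shape[0]) * float(zooms[2])
    return CineSeries(frames, spacing, times, view)


def _read_dicom_dir(path: Path) -> CineSeries:
    import pydicom

    datasets = []
    for f in sorted(path.iterdir()):
        if f.is_file():
            try:
                datasets.append(pydicom.dcmread(str(f)))
            except Exception:
                continue
    if not datasets:
        raise ValueError(f"{path}: no readable DICOM files")
    datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))
    frames = np.stack([ds.pixel_array.astype(float) for ds in datasets])
    if len({f.shape for f in frames}) > 1:
        raise ValueError(f"{path}: inconsistent frame sizes across DICOM files")
    ds0 = datasets[0]
    if hasattr(ds0, "PixelSpacing"):
        # DICOM PixelSpacing is (row spacing, column spacing)
        spacing = (float(ds0.PixelSpacing[1]), float(ds0.PixelSpacing[0]))
    else:
        warnings.warn(f"{path}: no PixelSpacing tag; assuming 1.0 mm", stacklevel=3)
        spacing = (1.0, 1.0)
    times = None
    if hasattr(ds0, "CardiacNumberOfImages") and hasattr(ds0, "NominalInterval"):
        rr = float(ds0.NominalInterval) / 1000.0
        n = len(datasets)
        if rr > 0:
            times = np.arange(n) * rr / n
    if times is None:
        warnings.warn(
            f"{path}: no timing tags; assuming a 1.0 s RR interval", stacklevel=3
        )
        times = np.arange(len(datasets)) / len(datasets)
    return CineSeries(frames, spacing, times)


def _read_image_dir(path: Path) -> CineSeries:
    import imageio.v3 as iio

    files = sorted(
        f for f in path.iterdir() if f.suffix.lower() in (".png", ".tif", ".tiff")
    )
    if not files:
        raise ValueError(f"{path}: no PNG/TIFF frames found")
    frames = [np.asarray(iio.imread(f), dtype=float) for f in files]
    if len({f.shape for f in frames}) > 1:
        raise ValueError(f"{path}: inconsistent frame sizes")
    meta_path = path / "meta.json"
    spacing, times, view = (1.0, 1.0), None, None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        spacing = tuple(meta.get("pixel_spacing_mm", spacing))
        view = meta.get("view")
        if meta.get("frame_times_s") is not None:
            times = np.asarray(meta["frame_times_s"], dtype=float)
    else:
        warnings.warn(f"{path}: no metadata sidecar; assuming 1.0 mm spacing", stacklevel=3)
        warnings.warn(f"{path}: no timing metadata; assuming a 1.0 s RR interval", stacklevel=3)
        times = np.arange(len(frames)) / len(frames)
    return CineSeries(np.stack(frames), spacing, times, view)


def read_cine(path) -> CineSeries:
    """Read a cine from NIfTI, a DICOM directory, or a PNG/TIFF directory."""
    path = Path(path)
    if path.is_file():
        if path.name.endswith((".nii", ".nii.gz")):
            return _read_nifti(path)
        raise ValueError(f"unsupported cine container: {path}")
    if not path.exists():
        raise FileNotFoundError(f"no such cine: {path}")
    has_image = any(
        f.suffix.lower() in (".png", ".tif", ".tiff") for f in path.iterdir()
    )
    return _read_image_dir(path) if has_image else _read_dicom_dir(path)


# --------------------------------------------------------------------------
# annotation I/O
# --------------------------------------------------------------------------

def write_annotations(
    ann: MVAnnotation,
    path,
    subject_id: str = "subject",
    source: str = "ground_truth",
    append: bool = False,
) -> None:
    """Write an annotation to the CSV schema (lossless full precision)."""
    if source not in VALID_SOURCES:
        raise ValueError(f"unknown source {source!r}")
    view = ann.view or "two_chamber"
    rows = []
    for i in range(ann.n_frames):
        for j, label in enumerate(ann.labels):
            rows.append(
                {
                    "subject_id": subject_id,
                    "view": view,
                    "frame_index": i,
                    "point_label": label,
                    "x_px": repr(float(ann.points[i, j, 0])),
                    "y_px": repr(float(ann.points[i, j, 1])),
                    "source": source,
                }
            )
    df = pd.DataFrame(rows)
    path = Path(path)
    if append and path.exists():
        old = path.read_text()
        data = old + df.to_csv(index=False, header=False)
    else:
        data = df.to_csv(index=False)
    _atomic_write_bytes(data.encode(), path)


def read_annotation_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"subject_id": str})
    required = {
        "subject_id", "view", "frame_index", "point_label", "x_px", "y_px", "source"
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    unknown = set(df["point_label"]) - _VALID_LABELS
    if unknown:
        raise ValueError(f"{path}: unknown point labels {sorted(unknown)}")
    return df


def read_annotations(path) -> dict[tuple[str, str, str], MVAnnotation]:
    """Read annotations, partitioned by (subject_id, view, source).

    Each partition must carry exactly the two view-consistent labels per
    frame over a contiguous 0-based frame range.
    """
    df = read_annotation_table(path)
    out: dict[tuple[str, str, str], MVAnnotation] = {}
    for (subj, view, source), grp in df.groupby(
        ["subject_id", "view", "source"], sort=True
    ):
        if view not in VIEW_LABELS:
            raise ValueError(f"{path}: unknown view {view!r}")
        labels = VIEW_LABELS[view]
        if set(grp["point_label"]) - set(labels):
            raise ValueError(
                f"{path}: labels {sorted(set(grp['point_label']))} inconsistent "
                f"with view {view!r}"
            )
        dup = grp.duplicated(subset=["frame_index", "point_label"])
        if dup.any():
            raise ValueError(f"{path}: duplicate (frame, label) rows for {subj}/{view}")
        frames = np.sort(grp["frame_index"].unique())
        if not np.array_equal(frames, np.arange(frames.size)):
            raise ValueError(f"{path}: frame indices not contiguous from 0")
        counts = grp.groupby("frame_index").size()
        if not (counts == 2).all():
            raise ValueError(
                f"{path}: expected exactly two labelled points per frame for "
                f"{subj}/{view}"
            )
        pts = np.empty((frames.size, 2, 2))
        for j, label in enumerate(labels):
            sub = grp[grp["point_label"] == label].sort_values("frame_index")
            if len(sub) != frames.size:
                raise ValueError(
                    f"{path}: label {label!r} missing in some frames for {subj}/{view}"
                )
            pts[:, j, 0] = sub["x_px"].to_numpy(dtype=float)
            pts[:, j, 1] = sub["y_px"].to_numpy(dtype=float)
        out[(subj, view, source)] = MVAnnotation(pts, labels, view)
    return out


def read_single_annotation(path, source: str | None = None) -> MVAnnotation:
    """Read a file expected to contain exactly one annotation partition."""
    groups = read_annotations(path)
    if source is not None:
        groups = {k: v for k, v in groups.items() if k[2] == source}
    if len(groups) != 1:
        raise ValueError(
            f"{path}: expected one (subject, view, source) partition, found "
            f"{sorted(groups)}"
        )
    return next(iter(groups.values()))


# --------------------------------------------------------------------------
# run configuration
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    seed: int = 0
    backbone: str = "tiny"
    n_refine: int = 2
    frames_per_cine: int | None = 3
    n_subjects: int = 24
    split: tuple[float, float] = (0.8, 0.2)
    resultant_velocity: bool = True  # e' from the resultant curve derivative
    training: dict = field(default_factory=dict)  # RegressorConfig overrides

    def to_json(self) -> str:
        d = asdict(self)
        d["split"] = list(self.split)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "RunConfig":
        d = json.loads(s)
        d["split"] = tuple(d["split"])
        return cls(**d)

    def save(self, path) -> None:
        _atomic_write_bytes(self.to_json().encode(), Path(path))

    @classmethod
    def load(cls, path) -> "RunConfig":
        return cls.from_json(Path(path).read_text())
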