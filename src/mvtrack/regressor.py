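"""Trainable landmark regressor mapping one grayscale image to four coordinates.

Both pipeline stages use the same kind of model: a residual convolutional
network that reads a single normalized grayscale frame and regresses the two
valve points as ``(x1, y1, x2, y2)`` in pixels of its input grid.  The
training recipe is fixed: per-image median/IQR intensity normalization, a
precomputed augmented training set (random scaling ±10%, rotation ±10°,
translation ±3 px applied consistently to image and points), mean-squared
-error loss and the Adam optimizer (defaults: learning rate 1e-4, 20
epochs, mini-batches of 8, augmentation ×10).

Two backbones are available: ``"full"``, the 50-layer bottleneck residual
network, and ``"tiny"``, a reduced-depth residual network that trains in
minutes on one CPU and is the first-class choice for desk-scale work — the
pipeline is backbone-agnostic by contract.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import _nn
from .geometry import SimilarityTransform, _resample_stack


@dataclass
class RegressorConfig:
    backbone: str = "tiny"  # "full" (50-layer) | "tiny"
    input_size: tuple[int, int] = (160, 160)  # (rows, cols)
    learning_rate: float = 1e-4
    n_epochs: int = 20
    batch_size: int = 8
    augmentation_factor: int = 10
    pretrained: bool = False
    per_image_normalization: bool = True
    seed: int = 0
    # augmentation draw ranges (scale ±, rotation ± deg, translation ± px);
    # the defaults are the standard recipe.  A refiner trained behind a less
    # accurate coarse model can widen the translation range to absorb the
    # larger crop misalignment.
    aug_scale: float = 0.10
    aug_rotation_deg: float = 10.0
    aug_translation_px: float = 3.0

    def __post_init__(self) -> None:
        if self.backbone not in ("tiny", "full"):
            raise ValueError(f"unknown backbone {self.backbone!r}")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.n_epochs < 1:
            raise ValueError("n_epochs must be >= 1")
        if self.augmentation_factor < 1:
            raise ValueError("augmentation_factor must be >= 1")
        self.input_size = tuple(int(v) for v in self.input_size)


def normalize_intensity(image: np.ndarray) -> np.ndarray:
    """Normalize an image by its median and interquartile range.

    Returns ``(image - median) / IQR`` computed per image.  A constant
    (zero-IQR) image falls back to ``image - median`` with a warning.
    """
    image = np.asarray(image, dtype=float)
    med = np.median(image)
    q1, q3 = np.percentile(image, [25.0, 75.0])
    iqr = q3 - q1
    if iqr <= 0:
        warnings.warn(
            "image has zero interquartile range; returning median-centered values",
            stacklevel=2,
        )
        return image - med
    return (image - med) / iqr


def augment(
    image: np.ndarray,
    points: np.ndarray,
    factor: int,
    rng: np.random.Generator,
    scale_range: float = 0.10,
    rotation_range_deg: float = 10.0,
    translation_range_px: float = 3.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Jittered copies of an image/points pair for training.

    Each of the ``factor`` returned pairs applies one random similarity
    perturbation — scale in ±10%, rotation in ±10°, translation in ±3 px,
    all uniform — about the image center, consistently to the image (cubic
    resampling, zero fill) and the target coordinates.  The original pair is
    not included.  Coordinates pushed outside the frame are kept as-is:
    they remain valid regression targets; only the image is resampled.
    """
    image = np.asarray(image, dtype=float)
    points = np.asarray(points, dtype=float)
    rows, cols = image.shape
    center = np.array([(cols - 1) / 2.0, (rows - 1) / 2.0])
    out = []
    for _ in range(int(factor)):
        s = 1.0 + rng.uniform(-scale_range, scale_range)
        ang = rng.uniform(-rotation_range_deg, rotation_range_deg)
        t = rng.uniform(-translation_range_px, translation_range_px, size=2)
        th = np.deg2rad(ang)
        mat = s * np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        transform = SimilarityTransform(mat, center + t - mat @ center, (rows, cols))
        img_aug = _resample_stack(image[None], transform, order=3)[0]
        out.append((img_aug, transform.forward(points.reshape(-1, 2)).reshape(points.shape)))
    return out


@dataclass
class TrainedRegressor:
    """A fitted landmark regressor: weights, config and training history."""

    model: _nn.Sequential
    config: RegressorConfig
    loss_history: list[float] = field(default_factory=list)
    norm_stats: dict | None = None  # per-dataset (median, iqr) when enabled

    # -- prediction -------------------------------------------------------
    def _prepare(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image, dtype=float)
        if image.shape != self.config.input_size:
            raise ValueError(
                f"image shape {image.shape} does not match the model input size "
                f"{self.config.input_size}"
            )
        if self.norm_stats is not None:
            med, iqr = self.norm_stats["median"], self.norm_stats["iqr"]
            image = (image - med) / iqr if iqr > 0 else image - med
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                image = normalize_intensity(image)
        return image.astype(_nn.F32)

    def predict_points(self, image: np.ndarray) -> np.ndarray:
        """Predict the two valve points of one frame, shape (2, 2), in the
        input image's own pixel coordinates."""
        x = self._prepare(image)[None, None]
        out = self.model.forward(x, train=False)[0]
        return np.asarray(out, dtype=float).reshape(2, 2)

    def predict_stack(self, frames: np.ndarray) -> np.ndarray:
        """Per-frame prediction over a stack, shape (T, 2, 2).

        Frames are processed one at a time so stack prediction is exactly
        the concatenation of single-frame predictions.
        """
        return np.stack([self.predict_points(f) for f in frames])

    # -- persistence ------------------------------------------------------
    def save(self, path) -> None:
        """Save weights (npz) plus a JSON sidecar with config and history."""
        path = Path(path)
        arrays = _nn.get_parameters(self.model)
        np.savez_compressed(path, **{f"p{i}": a for i, a in enumerate(arrays)})
        sidecar = {
            "config": asdict(self.config),
            "loss_history": self.loss_history,
            "norm_stats": self.norm_stats,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path) -> "TrainedRegressor":
        path = Path(path)
        sidecar = json.loads(path.with_suffix(".json").read_text())
        cfg = RegressorConfig(**{
            **sidecar["config"],
            "input_size": tuple(sidecar["config"]["input_size"]),
        })
        model = _build_backbone(cfg, np.random.default_rng(cfg.seed))
        npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
        with np.load(npz_path) as data:
            arrays = [data[f"p{i}"] for i in range(len(data.files))]
        _nn.set_parameters(model, arrays)
        return cls(
            model=model,
            config=cfg,
            loss_history=list(sidecar["loss_history"]),
            norm_stats=sidecar["norm_stats"],
        )


def _build_backbone(config: RegressorConfig, rng: np.random.Generator) -> _nn.Sequential:
    if config.backbone == "tiny":
        return _nn.build_tiny(config.input_size, rng)
    return _nn.build_resnet50(config.input_size, rng)


def train_regressor(
    images: np.ndarray | list,
    points: np.ndarray | list,
    config: RegressorConfig,
    progress: bool = False,
) -> TrainedRegressor:
    """Fit a landmark regressor on (image, two-point) pairs.

    Minimizes the mean squared error between predicted and target coordinate
    quadruples with Adam.  The training set is expanded up front: each
    original pair plus ``augmentation_factor`` jittered copies.  A fixed
    ``config.seed`` makes the whole run reproducible.

    Raises on an empty dataset, on any image whose shape differs from
    ``config.input_size`` (the error names the offending item), and on
    ``pretrained=True`` — no natural-image classification weights ship with
    this package, so transfer-learning initialisation is unavailable and
    random (He) initialisation is the supported path.
    """
    if config.pretrained:
        raise RuntimeError(
            "pretrained initialisation is unavailable: this build ships no "
            "natural-image classification weights; use pretrained=False"
        )
    if len(images) == 0:
        raise ValueError("training dataset is empty")
    if len(images) != len(points):
        raise ValueError("images and points must have equal length")
    for i, img in enumerate(images):
        if np.shape(img) != tuple(config.input_size):
            raise ValueError(
                f"training item {i} has shape {np.shape(img)}, expected "
                f"{tuple(config.input_size)}"
            )

    ss = np.random.SeedSequence(config.seed)
    rng_init, rng_aug, rng_shuffle = (np.random.default_rng(s) for s in ss.spawn(3))
    model = _build_backbone(config, rng_init)

    # expanded training set (originals + augmented copies), assembled
    # directly into one float32 array to keep memory flat
    n_orig = len(images)
    factor = config.augmentation_factor
    n_total = n_orig * factor
    h, w = config.input_size
    x_arr = np.empty((n_total, 1, h, w), dtype=_nn.F32)
    y_arr = np.empty((n_total, 4), dtype=_nn.F32)
    pos = 0
    for img, pts in zip(images, points):
        img = np.asarray(img, dtype=float)
        pts = np.asarray(pts, dtype=float).reshape(2, 2)
        if not np.all(np.isfinite(pts)):
            raise ValueError("target coordinates must be finite")
        x_arr[pos, 0] = img
        y_arr[pos] = pts.ravel()
        pos += 1
        if factor > 1:
            for img_a, pts_a in augment(
                img, pts, factor - 1, rng_aug,
                scale_range=config.aug_scale,
                rotation_range_deg=config.aug_rotation_deg,
                translation_range_px=config.aug_translation_px,
            ):
                x_arr[pos, 0] = img_a
                y_arr[pos] = pts_a.ravel()
                pos += 1

    norm_stats = None
    if config.per_image_normalization:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(n_total):
                x_arr[i, 0] = normalize_intensity(x_arr[i, 0])
    else:
        med = float(np.median(x_arr))
        q1, q3 = np.percentile(x_arr, [25.0, 75.0])
        iqr = float(q3 - q1)
        norm_stats = {"median": med, "iqr": iqr}
        x_arr -= _nn.F32(med)
        if iqr > 0:
            x_arr /= _nn.F32(iqr)

    opt = _nn.Adam(model, lr=config.learning_rate)
    n = x_arr.shape[0]
    history: list[float] = []
    for epoch in range(config.n_epochs):
        order = rng_shuffle.permutation(n)
        losses = []
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            pred = model.forward(x_arr[idx], train=True)
            loss, grad = _nn.mse_loss(pred, y_arr[idx])
            model.backward(grad.astype(_nn.F32))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
        if progress:
            print(f"epoch {epoch + 1}/{config.n_epochs}: mse {history[-1]:.4f} px^2")

    return TrainedRegressor(
        model=model, config=config, loss_history=history, norm_stats=norm_stats
    )
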