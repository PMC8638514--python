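"""Agreement metrics between predicted and reference annotations.

Spatial agreement uses three complementary measures: the per-point Euclidean
distance error (mm), the angular error between the two valve planes
(degrees, folded to [0, 90]), and the signed per-frame plane-displacement
error (mm).  The displacement error deliberately decouples from the point
errors: offsets *along* the valve plane move the points but not the plane,
so a tracker (or observer) with a different placement convention can show a
large Euclidean error yet near-perfect displacement agreement.

Clinical agreement between paired measurements uses ICC(2,1) — two-way
random effects, absolute agreement, single measures — with a 95% CI from
the standard F-distribution bounds, Bland-Altman bias with ±1.96·sd limits
of agreement, and ordinary least-squares regression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import DisplacementCurve, MVAnnotation


# --------------------------------------------------------------------------
# spatial agreement
# --------------------------------------------------------------------------

def _check_matched(pred: MVAnnotation, gt: MVAnnotation) -> None:
    if pred.n_frames != gt.n_frames:
        missing = sorted(
            set(range(max(pred.n_frames, gt.n_frames)))
            - set(range(min(pred.n_frames, gt.n_frames)))
        )
        raise ValueError(f"annotations cover different frames; unmatched: {missing}")
    if pred.labels != gt.labels:
        raise ValueError(
            f"point labels differ ({pred.labels} vs {gt.labels}); refusing to permute"
        )


def euclidean_error(
    pred: MVAnnotation, gt: MVAnnotation, pixel_spacing_mm: tuple[float, float]
) -> np.ndarray:
    """Per-frame, per-point straight-line distance error in mm, shape (T, 2).

    Uses the anisotropic spacing ``(spacing_x, spacing_y)``; labels are
    matched one-to-one (anterior to anterior, etc.), never permuted.
    """
    _check_matched(pred, gt)
    spacing = np.asarray(pixel_spacing_mm, dtype=float)
    diff = (pred.points - gt.points) * spacing
    return np.linalg.norm(diff, axis=-1)


def angular_error(
    pred: MVAnnotation,
    gt: MVAnnotation,
    pixel_spacing_mm: tuple[float, float] = (1.0, 1.0),
) -> np.ndarray:
    """Per-frame acute angle (degrees) between the two annotated planes.

    Computed in physical (mm-scaled) coordinates; the result lies in
    [0, 90].  Frames where either annotation is degenerate (coincident
    points) are returned as NaN and should be excluded from summaries.
    """
    _check_matched(pred, gt)
    spacing = np.asarray(pixel_spacing_mm, dtype=float)
    v_pred = (pred.points[:, 1] - pred.points[:, 0]) * spacing
    v_gt = (gt.points[:, 1] - gt.points[:, 0]) * spacing
    n_pred = np.linalg.norm(v_pred, axis=1)
    n_gt = np.linalg.norm(v_gt, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.abs(np.einsum("ij,ij->i", v_pred, v_gt)) / (n_pred * n_gt)
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    ang[(n_pred < 1e-12) | (n_gt < 1e-12)] = np.nan
    return ang


def displacement_error(
    pred_curve: DisplacementCurve, gt_curve: DisplacementCurve
) -> np.ndarray:
    """Signed per-frame difference pred - gt, in mm (same time base required)."""
    if len(pred_curve) != len(gt_curve):
        raise ValueError("displacement curves have different lengths")
    if not np.allclose(pred_curve.times, gt_curve.times, rtol=1e-9, atol=1e-9):
        raise ValueError("displacement curves are on different time bases")
    return pred_curve.values - gt_curve.values


# --------------------------------------------------------------------------
# clinical agreement statistics
# --------------------------------------------------------------------------

@dataclass
class AgreementStats:
    """Paired-measurement agreement summary.

    ``icc`` is ICC(2,1) with its 95% CI; ``bias``/``loa`` follow
    Bland-Altman (limits = bias ± 1.96 · sd of the differences, sample sd);
    slope/intercept/r come from ordinary least squares of y on x.
    """

    n: int
    icc: float
    icc_ci95: tuple[float, float]
    bias: float
    loa: tuple[float, float]
    slope: float
    intercept: float
    r: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "icc": self.icc,
            "icc_ci95": list(self.icc_ci95),
            "bias": self.bias,
            "loa": list(self.loa),
            "slope": self.slope,
            "intercept": self.intercept,
            "r": self.r,
            **self.metadata,
        }


def icc(x, y, alpha: float = 0.05) -> AgreementStats:
    """ICC(2,1) (two-way random, absolute agreement, single measures).

    Computed from the two-way ANOVA mean squares of the n-by-2 table with
    rows = subjects and columns = raters/methods; the CI uses the standard
    F-distribution bounds with a Satterthwaite degrees-of-freedom
    approximation.  Raises on zero total variance (ICC undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if x.size < 3:
        raise ValueError("at least 3 pairs are required")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")

    table = np.column_stack([x, y])
    n, k = table.shape
    grand = table.mean()
    if np.allclose(table, grand, atol=1e-300) or np.var(table) < 1e-300:
        raise ValueError("zero total variance; ICC is undefined")

    row_means = table.mean(axis=1)
    col_means = table.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((table - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols

    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    icc_val = (msr - mse) / denom if denom != 0 else np.nan

    # Satterthwaite df for the CI of ICC(2,1)
    fj = msc / mse if mse > 0 else np.inf
    a = (k * icc_val) / (n * (1.0 - icc_val)) if icc_val < 1.0 else np.inf
    b = 1.0 + (k * icc_val * (n - 1.0)) / (n * (1.0 - icc_val)) if icc_val < 1.0 else np.inf
    if np.isfinite(a) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1.0) + (b * mse) ** 2 / ((n - 1.0) * (k - 1.0))
        v = v_num / v_den
        f1 = stats.f.ppf(1.0 - alpha / 2.0, n - 1.0, v)
        f2 = stats.f.ppf(1.0 - alpha / 2.0, v, n - 1.0)
        lower = n * (msr - f1 * mse) / (
            f1 * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        upper = n * (f2 * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f2 * msr
        )
    else:
        lower = upper = icc_val

    reg = stats.linregress(x, y)
    ba_bias, ba_loa = bland_altman(x, y)
    return AgreementStats(
        n=n,
        icc=float(icc_val),
        icc_ci95=(float(lower), float(upper)),
        bias=ba_bias,
        loa=ba_loa,
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r=float(reg.rvalue),
        metadata={"icc_variant": "ICC(2,1) absolute agreement, single measures"},
    )


def bland_altman(x, y) -> tuple[float, tuple[float, float]]:
    """Bland-Altman bias and ±1.96·sd limits of agreement of ``y - x``.

    Uses the sample standard deviation of the differences.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("x and y must be equal-length 1-D arrays with n >= 2")
    diff = y - x
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, (bias - 1.96 * sd, bias + 1.96 * sd)


# --------------------------------------------------------------------------
# stage-wise comparison harness
# --------------------------------------------------------------------------

def _nanmean_sd(a: np.ndarray) -> tuple[float, float]:
    a = np.asarray(a, dtype=float).ravel()
    good = a[np.isfinite(a)]
    if good.size == 0:
        return float("nan"), float("nan")
    return float(good.mean()), float(good.std(ddof=1)) if good.size > 1 else 0.0


def stagewise_report(results, gt_annotations, spacings, times=None) -> pd.DataFrame:
    """Spatial and clinical agreement per pipeline stage.

    Parameters
    ----------
    results
        List of :class:`mvtrack.pipeline.TrackingResult` (one per cine).
    gt_annotations
        Matching list of ground-truth :class:`MVAnnotation`.
    spacings
        Matching list of ``(spacing_x, spacing_y)`` mm tuples.
    times
        Optional matching list of frame-time arrays (seconds).

    Returns a tidy frame with one row per stage carrying pooled Euclidean,
    angular and displacement-error summaries plus the MAPSE ICC against
    ground truth, mirroring the stage-stratified comparison (stage 1,
    stage 1+2, stage 1+2+2).  Degenerate frames are excluded listwise from
    the means, with counts reported.
    """
    if not results:
        raise ValueError("no tracking results supplied")
    if times is None:
        times = [None] * len(results)
    from .metrics import derive_metrics, plane_displacement, velocity_curve

    stages = list(results[0].annotations.keys())
    rows = []
    for stage in stages:
        eucl, ang, disp = [], [], []
        mapse_pred, mapse_gt = [], []
        n_degenerate = 0
        for res, gt, spacing, t in zip(results, gt_annotations, spacings, times):
            pred = res.annotations[stage]
            eucl.append(euclidean_error(pred, gt, spacing).ravel())
            a = angular_error(pred, gt, spacing)
            n_degenerate += int(np.sum(~np.isfinite(a)))
            ang.append(a)
            d_pred = plane_displacement(pred, spacing, times=t, rr_interval_s=1.0)
            d_gt = plane_displacement(gt, spacing, times=t, rr_interval_s=1.0)
            disp.append(displacement_error(d_pred, d_gt))
            mapse_pred.append(derive_metrics(d_pred).mapse_mm)
            mapse_gt.append(derive_metrics(d_gt).mapse_mm)
        e_mean, e_sd = _nanmean_sd(np.concatenate(eucl))
        a_mean, a_sd = _nanmean_sd(np.concatenate(ang))
        d_mean, d_sd = _nanmean_sd(np.concatenate(disp))
        row = {
            "stage": stage,
            "n_cines": len(results),
            "euclidean_mm_mean": e_mean,
            "euclidean_mm_sd": e_sd,
            "angular_deg_mean": a_mean,
            "angular_deg_sd": a_sd,
            "displacement_mm_mean": d_mean,
            "displacement_mm_sd": d_sd,
            "n_degenerate_frames": n_degenerate,
        }
        if len(mapse_gt) >= 3 and np.var(mapse_gt) > 0:
            row["mapse_icc"] = icc(mapse_gt, mapse_pred).icc
        else:
            row["mapse_icc"] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
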