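"""Tests of spatial agreement metrics and the ICC / Bland-Altman statistics."""

import numpy as np
import pytest

from mvtrack import (
    DisplacementCurve,
    MVAnnotation,
    angular_error,
    bland_altman,
    displacement_error,
    euclidean_error,
    icc,
    plane_displacement,
)


def horizontal_ann(n_frames=4, offset=(0.0, 0.0)):
    pts = np.empty((n_frames, 2, 2))
    for i in range(n_frames):
        pts[i, 0] = (40.0 + offset[0], 50.0 + 2.0 * i + offset[1])
        pts[i, 1] = (60.0 + offset[0], 50.0 + 2.0 * i + offset[1])
    return MVAnnotation(pts, ("anterior", "inferior"), "two_chamber")


def brute_force_icc21(x, y):
    """Independent oracle: ICC(2,1) from explicitly summed ANOVA squares."""
    table = np.column_stack([np.asarray(x, float), np.asarray(y, float)])
    n, k = table.shape
    grand = table.sum() / (n * k)
    msr = msc = mse_acc = 0.0
    row_means = [table[i].sum() / k for i in range(n)]
    col_means = [table[:, j].sum() / n for j in range(k)]
    for i in range(n):
        msr += (row_means[i] - grand) ** 2
    msr = k * msr / (n - 1)
    for j in range(k):
        msc += (col_means[j] - grand) ** 2
    msc = n * msc / (k - 1)
    for i in range(n):
        for j in range(k):
            mse_acc += (table[i, j] - row_means[i] - col_means[j] + grand) ** 2
    mse = mse_acc / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestEuclideanError:
    def test_identical_annotations_zero(self):
        a = horizontal_ann()
        assert np.all(euclidean_error(a, a, (1.0, 1.0)) == 0.0)

    def test_three_four_five_triangle(self):
        gt = horizontal_ann()
        pred = horizontal_ann(offset=(3.0, 4.0))
        assert euclidean_error(pred, gt, (1.0, 1.0)) == pytest.approx(5.0)

    def test_anisotropic_spacing_pairing(self):
        gt = horizontal_ann()
        pred = horizontal_ann(offset=(3.0, 4.0))
        # x offset scaled by x spacing 2.0, y offset by y spacing 1.0
        assert euclidean_error(pred, gt, (2.0, 1.0)) == pytest.approx(np.sqrt(52.0))

    def test_rigid_transform_invariance(self):
        gt = horizontal_ann()
        pred = horizontal_ann(offset=(3.0, 4.0))
        th = np.deg2rad(31.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        gt_r = MVAnnotation(gt.points @ rot.T + [5.0, 6.0], gt.labels)
        pred_r = MVAnnotation(pred.points @ rot.T + [5.0, 6.0], pred.labels)
        assert np.abs(
            euclidean_error(pred_r, gt_r, (1.0, 1.0))
            - euclidean_error(pred, gt, (1.0, 1.0))
        ).max() < 1e-9

    def test_frame_mismatch_reported(self):
        with pytest.raises(ValueError, match="frames"):
            euclidean_error(horizontal_ann(3), horizontal_ann(5), (1.0, 1.0))


class TestAngularError:
    def test_identical_planes_zero(self):
        a = horizontal_ann()
        assert np.all(angular_error(a, a) == 0.0)

    def test_perpendicular_planes(self):
        gt = horizontal_ann(1)
        pts = np.array([[[50.0, 40.0], [50.0, 60.0]]])
        pred = MVAnnotation(pts, gt.labels)
        assert angular_error(pred, gt)[0] == pytest.approx(90.0)

    def test_constructed_rotation(self):
        gt = horizontal_ann(1)
        th = np.deg2rad(10.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        mid = gt.points[0].mean(axis=0)
        pred = MVAnnotation((gt.points - mid) @ rot.T + mid, gt.labels)
        assert angular_error(pred, gt)[0] == pytest.approx(10.0, abs=1e-9)

    def test_symmetry_and_point_swap_invariance(self):
        rng = np.random.default_rng(5)
        a = MVAnnotation(rng.uniform(0, 100, (6, 2, 2)), ("anterior", "inferior"))
        b = MVAnnotation(rng.uniform(0, 100, (6, 2, 2)), ("anterior", "inferior"))
        assert np.allclose(angular_error(a, b), angular_error(b, a))
        b_swapped = MVAnnotation(b.points[:, ::-1], b.labels)
        assert np.allclose(angular_error(a, b), angular_error(a, b_swapped))

    def test_degenerate_frame_flagged_nan(self):
        gt = horizontal_ann(2)
        pts = gt.points.copy()
        pts[1, 1] = pts[1, 0]  # coincident points in frame 1
        pred = MVAnnotation(pts, gt.labels)
        ang = angular_error(pred, gt)
        assert np.isfinite(ang[0]) and np.isnan(ang[1])


class TestDisplacementError:
    def test_identical_curves_zero(self):
        t = np.linspace(0, 0.9, 10)
        c = DisplacementCurve(t, np.arange(10.0))
        assert np.all(displacement_error(c, c) == 0.0)

    def test_constant_bias(self):
        t = np.linspace(0, 0.9, 10)
        gt = DisplacementCurve(t, np.arange(10.0))
        pred = DisplacementCurve(t, np.arange(10.0) + 0.5)
        err = displacement_error(pred, gt)
        assert err.mean() == pytest.approx(0.5)
        assert err.std() == pytest.approx(0.0)

    def test_in_plane_offset_decouples_from_euclidean(self):
        """Points shifted along the valve plane leave the displacement
        metric untouched although every point is wrong — plane motion is
        more reproducible than individual point placement."""
        gt = horizontal_ann()
        pred = horizontal_ann(offset=(4.0, 0.0))  # 4 px along the plane
        eucl = euclidean_error(pred, gt, (1.0, 1.0))
        assert np.all(eucl == pytest.approx(4.0))
        d_gt = plane_displacement(gt, (1.0, 1.0), rr_interval_s=1.0)
        d_pred = plane_displacement(pred, (1.0, 1.0), rr_interval_s=1.0)
        assert np.abs(displacement_error(d_pred, d_gt)).max() < 1e-12


class TestICC:
    def test_perfect_agreement(self):
        x = np.arange(10.0)
        stats = icc(x, x)
        assert stats.icc == pytest.approx(1.0)

    def test_heavy_noise_drives_icc_down(self):
        rng = np.random.default_rng(6)
        x = rng.normal(10.0, 1.0, 500)
        y = x + rng.normal(0.0, 10.0, 500)
        assert icc(x, y).icc < 0.2

    def test_matches_brute_force_anova_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(rng.uniform(-5, 5), rng.uniform(0.5, 3.0), 10)
            y = x + rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2.0), 10)
            assert abs(icc(x, y).icc - brute_force_icc21(x, y)) < 1e-10

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        x = rng.normal(12.0, 4.0, 40)
        y = x + rng.normal(-0.2, 1.3, 40)
        ours = icc(x, y)
        df = pd.DataFrame({
            "targets": np.r_[np.arange(40), np.arange(40)],
            "raters": ["a"] * 40 + ["b"] * 40,
            "scores": np.r_[x, y],
        })
        ref = pingouin.intraclass_corr(df, targets="targets", raters="raters",
                                       ratings="scores")
        # ICC(A,1): two-way random, absolute agreement, single measures
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        row = ref[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
        assert ours.icc == pytest.approx(row["ICC"], abs=1e-9)
        # pingouin reports the CI rounded to two decimals
        assert ours.icc_ci95[0] == pytest.approx(row[ci_col][0], abs=6e-3)
        assert ours.icc_ci95[1] == pytest.approx(row[ci_col][1], abs=6e-3)

    def test_zero_variance_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            icc([3.0] * 5, [3.0] * 5)


class TestBlandAltman:
    def test_equal_series(self):
        x = np.arange(5.0)
        bias, loa = bland_altman(x, x)
        assert bias == 0.0 and loa == (0.0, 0.0)

    def test_constant_shift(self):
        x = np.arange(5.0)
        bias, loa = bland_altman(x, x + 0.5)
        assert bias == pytest.approx(0.5)
        assert loa == pytest.approx((0.5, 0.5))

    def test_hand_computed_sd(self):
        x = np.zeros(3)
        y = np.array([-1.0, 0.0, 1.0])
        bias, loa = bland_altman(x, y)
        assert bias == 0.0
        assert loa == pytest.approx((-1.96, 1.96))


class TestStagewiseReport:
    def test_oracle_results_have_zero_errors(self, rendered_pair, rotated_pair):
        from mvtrack import OraclePredictor, stagewise_report, track_mv

        results, gts, spacings, times = [], [], [], []
        for cine, ann in (rendered_pair, rotated_pair):
            oracle = OraclePredictor(ann)
            results.append(track_mv(cine, oracle, oracle, n_refine=2))
            gts.append(ann)
            spacings.append(cine.pixel_spacing_mm)
            times.append(cine.frame_times_s)
        report = stagewise_report(results, gts, spacings, times)
        assert list(report["stage"]) == ["stage1", "stage1+2", "stage1+2+2"]
        assert report["euclidean_mm_mean"].abs().max() < 1e-9
        assert report["angular_deg_mean"].abs().max() < 1e-6
        assert report["displacement_mm_mean"].abs().max() < 1e-9
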