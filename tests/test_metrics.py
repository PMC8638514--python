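"""Tests of displacement/velocity curves and clinical-metric derivation."""

import numpy as np
import pytest

from mvtrack import (
    DegeneratePlaneError,
    DisplacementCurve,
    MVAnnotation,
    MotionProfileParams,
    analytic_velocity_peaks,
    derive_metrics,
    generate_displacement_profile,
    plane_displacement,
    resultant_displacement,
    velocity_curve,
)


def ann_from_offsets(offsets, along=0.0):
    """Horizontal 20-px annulus at row 50, shifted down by ``offsets[i]`` px
    (and optionally along the plane) per frame."""
    pts = np.empty((len(offsets), 2, 2))
    for i, off in enumerate(offsets):
        pts[i, 0] = (40.0 + along * i, 50.0 + off)
        pts[i, 1] = (60.0 + along * i, 50.0 + off)
    return MVAnnotation(pts, ("anterior", "inferior"), "two_chamber")


class TestPlaneDisplacement:
    def test_frame0_is_exactly_zero(self):
        d = plane_displacement(ann_from_offsets([0, 3, 5]), (1.0, 1.0),
                               rr_interval_s=1.0)
        assert d.values[0] == 0.0

    def test_rigid_perpendicular_translation(self):
        d = plane_displacement(ann_from_offsets([0, 5]), (1.0, 1.0),
                               rr_interval_s=1.0)
        assert d.values[1] == pytest.approx(5.0, abs=1e-12)

    def test_asymmetric_point_motion_averages(self):
        pts = np.array([
            [[40.0, 50.0], [60.0, 50.0]],
            [[40.0, 54.0], [60.0, 56.0]],  # 4 mm and 6 mm perpendicular
        ])
        ann = MVAnnotation(pts, ("anterior", "inferior"))
        d = plane_displacement(ann, (1.0, 1.0), rr_interval_s=1.0)
        assert d.values[1] == pytest.approx(5.0, abs=1e-12)

    def test_rotation_translation_invariance(self):
        base = ann_from_offsets([0, 2, 5, 3, 1])
        th = np.deg2rad(77.0)
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        moved = MVAnnotation(base.points @ rot.T + [13.0, -4.0], base.labels)
        d0 = plane_displacement(base, (1.0, 1.0), rr_interval_s=1.0)
        d1 = plane_displacement(moved, (1.0, 1.0), rr_interval_s=1.0)
        assert np.abs(d0.values - d1.values).max() < 1e-9

    def test_unit_discipline(self):
        # doubling the spacing with halved pixel displacement: same mm curve
        d1 = plane_displacement(ann_from_offsets([0, 4, 8]), (1.0, 1.0),
                                rr_interval_s=1.0)
        d2 = plane_displacement(ann_from_offsets([0, 2, 4]), (2.0, 2.0),
                                rr_interval_s=1.0)
        assert np.abs(d1.values - d2.values).max() < 1e-12

    def test_degenerate_frame0_raises(self):
        pts = np.zeros((3, 2, 2))
        with pytest.raises(DegeneratePlaneError):
            plane_displacement(MVAnnotation(pts, ("anterior", "inferior")),
                               (1.0, 1.0), rr_interval_s=1.0)

    def test_missing_timing_warns_and_defaults(self):
        with pytest.warns(UserWarning, match="RR"):
            d = plane_displacement(ann_from_offsets([0, 1, 2, 3]), (1.0, 1.0))
        assert d.times[-1] == pytest.approx(0.75)


class TestResultant:
    def test_identical_curves_unchanged(self):
        c = DisplacementCurve(np.linspace(0, 0.9, 10), np.arange(10.0))
        r = resultant_displacement(c, c)
        assert np.array_equal(r.values, c.values)

    def test_arithmetic_mean_of_constants(self):
        t = np.linspace(0, 0.9, 10)
        r = resultant_displacement(
            DisplacementCurve(t, np.full(10, 8.0)),
            DisplacementCurve(t, np.full(10, 12.0)),
        )
        assert np.all(r.values == 10.0)

    def test_interpolation_across_frame_counts(self):
        p = MotionProfileParams(mapse_mm=15.0, hr_bpm=60.0, n_frames=30)
        c30 = generate_displacement_profile(p)
        c25 = generate_displacement_profile(
            MotionProfileParams(mapse_mm=15.0, hr_bpm=60.0, n_frames=25)
        )
        r = resultant_displacement(c30, c25)
        assert len(r) == 30
        # both sample near-identical profiles; the mean stays within 2% of
        # MAPSE of the 30-frame profile
        assert np.abs(r.values - c30.values).max() < 0.02 * 15.0


class TestVelocityCurve:
    def test_constant_displacement_zero_velocity(self):
        d = DisplacementCurve(np.linspace(0, 0.4, 5), np.full(5, 7.0))
        assert np.abs(velocity_curve(d).values).max() < 1e-12

    def test_hand_computed_central_differences(self):
        d = DisplacementCurve(np.arange(5) * 0.1, [0.0, 5.0, 10.0, 5.0, 0.0])
        v = velocity_curve(d)
        assert v.values[1:4] == pytest.approx([5.0, 0.0, -5.0], abs=1e-12)

    def test_sine_derivative_peak(self):
        t = np.arange(30) / 30.0
        d = DisplacementCurve(t, 10.0 * np.sin(2 * np.pi * t))
        v = velocity_curve(d)
        analytic_peak = 2 * np.pi * 10.0 / 10.0  # cm/s
        assert np.abs(v.values).max() == pytest.approx(analytic_peak, rel=0.02)

    def test_bad_time_bases_rejected(self):
        with pytest.raises(ValueError):
            velocity_curve(DisplacementCurve([0.0, 0.1], [0.0, 1.0]))
        with pytest.raises(ValueError):
            velocity_curve(DisplacementCurve([0.0, 0.2, 0.1], [0.0, 1.0, 2.0]))
        with pytest.raises(ValueError):
            velocity_curve(DisplacementCurve([0.0, 0.1, 0.35], [0.0, 1.0, 2.0]))


class TestDeriveMetrics:
    def test_generator_round_trip(self):
        p = MotionProfileParams(mapse_mm=15.0, hr_bpm=60.0, n_frames=30)
        m = derive_metrics(generate_displacement_profile(p))
        assert m.mapse_mm == pytest.approx(15.0, rel=0.01)
        peaks = analytic_velocity_peaks(p)
        assert m.s_prime_cm_s == pytest.approx(peaks["s_prime_cm_s"], rel=0.05)
        assert m.e_prime_cm_s == pytest.approx(peaks["e_prime_cm_s"], rel=0.05)
        assert m.a_prime_cm_s == pytest.approx(peaks["a_prime_cm_s"], rel=0.05)
        assert m.complete

    def test_no_atrial_kick_flags_a_prime_absent(self):
        # single smooth descent and return: only one return-directed peak
        t = np.arange(30) / 30.0
        d = DisplacementCurve(t, 12.0 * np.sin(np.pi * t) ** 2)
        m = derive_metrics(d)
        assert np.isfinite(m.e_prime_cm_s)
        assert np.isnan(m.a_prime_cm_s)
        assert not m.complete

    def test_peak_time_ordering(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            p = MotionProfileParams(
                mapse_mm=float(rng.uniform(6, 20)),
                hr_bpm=float(rng.uniform(50, 90)),
                n_frames=int(rng.integers(25, 51)),
                systole_fraction=float(rng.uniform(0.3, 0.42)),
                diastasis_fraction=float(rng.uniform(0.15, 0.35)),
                atrial_kick_fraction_of_mapse=float(rng.uniform(0.2, 0.4)),
            )
            m = derive_metrics(generate_displacement_profile(p))
            if m.complete:
                assert m.s_prime_time_s < m.mapse_time_s
                assert m.mapse_time_s <= m.e_prime_time_s < m.a_prime_time_s

    def test_two_frame_annotation_gives_mapse_only(self):
        from mvtrack.metrics import metrics_from_annotations

        a2 = ann_from_offsets([0, 6])
        a4 = ann_from_offsets([0, 6])
        m, d, v = metrics_from_annotations(a2, a4, (1.0, 1.0), (1.0, 1.0),
                                           rr_interval_s=0.9)
        assert m.mapse_mm == pytest.approx(6.0)
        assert v is None
        assert not m.complete
        assert np.isnan(m.e_prime_cm_s)
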