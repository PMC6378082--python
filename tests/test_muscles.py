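"""Muscle stretch model: law-of-cosines lengths vs a 3-D rotation oracle."""

import math

import numpy as np
import pytest

from bpoplan import (
    MuscleAttachment,
    MuscleGeometry,
    Point2,
    baseline_geometry,
    classify_safety,
    stretch_ratio_curve,
    stretched_length,
)
from bpoplan.muscles import CRITICAL_STRETCH_RATIO, MuscleResult


def rotate_and_measure(att: MuscleAttachment, fulcrum: Point2, oa_deg: float) -> float:
    """Brute-force oracle: rotate the cranial point in-plane, take 3-D distance."""
    oa = math.radians(oa_deg)
    cx, cy, cz = att.cranial_point
    dx, dy = cx - fulcrum.x, cy - fulcrum.y
    rx = fulcrum.x + math.cos(oa) * dx - math.sin(oa) * dy
    ry = fulcrum.y + math.sin(oa) * dx + math.cos(oa) * dy
    ex, ey, ez = att.caudal_point
    return math.sqrt((rx - ex) ** 2 + (ry - ey) ** 2 + (cz - ez) ** 2)


class TestBaselineGeometry:
    def test_3_4_5_triangle(self):
        att = MuscleAttachment("seg", "TFL", "whole", (0.0, 3.0, 5.0), (4.0, 0.0, 5.0))
        g = baseline_geometry(att, Point2(0.0, 0.0))
        assert g.l1_mm == pytest.approx(3.0)
        assert g.l2_mm == pytest.approx(4.0)
        assert abs(math.degrees(g.beta_signed_rad)) == pytest.approx(90.0)
        assert g.l0_mm == pytest.approx(5.0)

    def test_out_of_plane_pythagoras(self):
        # in-plane chord 3, mediolateral offset 4 -> length 5
        att = MuscleAttachment("seg", "P", "whole", (0.0, 4.0, 4.0), (0.0, 7.0, 0.0))
        g = baseline_geometry(att, Point2(0.0, 0.0))
        assert g.delta_z_mm == pytest.approx(4.0)
        assert g.l0_mm == pytest.approx(5.0)

    def test_l0_matches_raw_3d_distance(self, muscle_fixture, fixture_fulcrum):
        for att in muscle_fixture:
            g = baseline_geometry(att, fixture_fulcrum)
            raw = math.dist(att.cranial_point, att.caudal_point)
            assert g.l0_mm == pytest.approx(raw, abs=1e-9)

    def test_attachment_on_fulcrum_rejected(self):
        att = MuscleAttachment("seg", "P", "whole", (0.0, 0.0, 5.0), (4.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="fulcrum"):
            baseline_geometry(att, Point2(0.0, 0.0))


class TestStretchedLength:
    def test_zero_angle_returns_baseline(self, muscle_fixture, fixture_fulcrum):
        for att in muscle_fixture:
            g = baseline_geometry(att, fixture_fulcrum)
            assert stretched_length(g, 0.0) == pytest.approx(g.l0_mm, abs=1e-12)

    def test_collinear_limit(self):
        g = MuscleGeometry("seg", 3.0, 4.0, math.radians(90.0), 0.0, 5.0)
        assert stretched_length(g, 90.0, cap_deg=90.0) == pytest.approx(7.0, abs=1e-12)

    def test_matches_rotation_oracle_on_random_segments(self):
        """1000 seeded random segments x random OA agree with rotate-and-measure."""
        rng = np.random.default_rng(424242)
        fulcrum = Point2(-31.5, 45.0)
        worst = 0.0
        for _ in range(1000):
            cr = (rng.uniform(-150, 150), rng.uniform(-150, 150), rng.uniform(-50, 50))
            ca = (rng.uniform(-150, 150), rng.uniform(-150, 150), rng.uniform(-50, 50))
            att = MuscleAttachment("seg", "P", "whole", cr, ca)
            oa = float(rng.uniform(0.0, 40.0))
            try:
                g = baseline_geometry(att, fulcrum)
            except ValueError:
                continue  # degenerate projection, rejected by design
            worst = max(worst, abs(stretched_length(g, oa) - rotate_and_measure(att, fulcrum, oa)))
        assert worst < 1e-9

    def test_small_angle_lengthening_iff_positive_beta(self):
        """Chord derivative is proportional to sin(beta): sign decides the fate."""
        rng = np.random.default_rng(77)
        for _ in range(200):
            beta = float(rng.uniform(-math.pi + 0.1, math.pi - 0.1))
            if abs(math.sin(beta)) < 1e-3:
                continue
            l1, l2 = float(rng.uniform(20, 120)), float(rng.uniform(20, 120))
            dz = float(rng.uniform(0, 40))
            l0 = math.sqrt(l1**2 + l2**2 - 2 * l1 * l2 * math.cos(beta) + dz**2)
            g = MuscleGeometry("seg", l1, l2, beta, dz, l0)
            d = stretched_length(g, 0.05)
            if math.sin(beta) > 0:
                assert d > g.l0_mm
            else:
                assert d < g.l0_mm

    def test_mirror_symmetry_in_beta(self):
        """Flipping the sign of beta mirrors the geometry: d(-beta, oa) = d(beta, -oa)."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            beta = float(rng.uniform(-2.5, 2.5))
            l1, l2 = float(rng.uniform(20, 120)), float(rng.uniform(20, 120))
            dz = float(rng.uniform(0, 40))
            oa = math.radians(float(rng.uniform(0, 40)))

            def chord(b, o):
                return math.sqrt(l1**2 + l2**2 - 2 * l1 * l2 * math.cos(b + o) + dz**2)

            l0_neg = chord(-beta, 0.0)
            g_neg = MuscleGeometry("seg", l1, l2, -beta, dz, l0_neg)
            assert stretched_length(g_neg, math.degrees(oa)) == pytest.approx(
                chord(beta, -oa), abs=1e-9
            )


class TestStretchRatioCurve:
    def test_all_segments_isometric_at_zero(self, muscle_fixture, fixture_fulcrum):
        results = stretch_ratio_curve(muscle_fixture, fixture_fulcrum, [0.0])
        assert all(r.classification == "isometric" for r in results)
        assert all(abs(r.stretch_ratio - 1.0) < 1e-12 for r in results)

    def test_fixture_pattern_at_20_degrees(self, muscle_fixture, fixture_fulcrum):
        """TFL and anterior GMed lengthen, middle GMed is isometric, the rest shorten."""
        results = {r.name: r for r in stretch_ratio_curve(muscle_fixture, fixture_fulcrum, [20.0])}
        assert results["TFL"].classification == "lengthening"
        assert results["GMed_anterior"].classification == "lengthening"
        assert results["GMed_middle"].classification == "isometric"
        for name in ("GMed_posterior", "GMax_anterior", "GMax_middle", "GMax_posterior", "P"):
            assert results[name].classification == "shortening", name
        # stretch magnitudes of the fixture: +8% aGMed, +4% TFL, -6/-5/-6/-8/-5%
        assert results["GMed_anterior"].stretch_ratio == pytest.approx(1.08, abs=1e-9)
        assert results["TFL"].stretch_ratio == pytest.approx(1.04, abs=1e-9)
        assert results["GMed_posterior"].stretch_ratio == pytest.approx(0.94, abs=1e-9)
        assert results["GMax_anterior"].stretch_ratio == pytest.approx(0.95, abs=1e-9)
        assert results["GMax_middle"].stretch_ratio == pytest.approx(0.94, abs=1e-9)
        assert results["GMax_posterior"].stretch_ratio == pytest.approx(0.92, abs=1e-9)
        assert results["P"].stretch_ratio == pytest.approx(0.95, abs=1e-9)

    def test_no_fixture_segment_exceeds_critical_in_planning_range(
        self, muscle_fixture, fixture_fulcrum
    ):
        grid = np.arange(0.0, 40.5, 0.5)
        results = stretch_ratio_curve(muscle_fixture, fixture_fulcrum, grid)
        assert not any(r.exceeds_critical for r in results)
        assert max(r.stretch_ratio for r in results) < 1.0 + CRITICAL_STRETCH_RATIO

    def test_monotone_lengthening_for_acute_positive_beta(self):
        g = MuscleGeometry(
            "seg", 50.0, 70.0, math.radians(45.0), 0.0,
            math.sqrt(50**2 + 70**2 - 2 * 50 * 70 * math.cos(math.radians(45))),
        )
        lengths = [stretched_length(g, oa) for oa in np.arange(0.0, 41.0)]
        assert np.all(np.diff(lengths) > 0)


class TestClassifySafety:
    def test_all_shortening_is_safe(self):
        results = [
            MuscleResult("a", 20.0, 50.0, 0.95, "shortening", False),
            MuscleResult("b", 20.0, 60.0, 0.90, "shortening", False),
        ]
        summary = classify_safety(results)
        assert summary.unsafe_segments == ()
        assert summary.n_shortening == 2

    def test_segment_beyond_critical_is_flagged(self):
        results = [MuscleResult("hot", 40.0, 90.0, 1.30, "lengthening", True)]
        summary = classify_safety(results)
        assert summary.unsafe_segments == ("hot",)
        assert summary.max_stretch_ratio == pytest.approx(1.30)
        assert summary.max_stretch_segment == "hot"
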