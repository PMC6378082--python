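"""Radiographic measurement, rigid osteotomy rotation, PT decompensation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bpoplan import (
    LandmarkSet,
    Point2,
    apply_osteotomy,
    decompensate_pt,
    make_patient,
    measure_parameters,
    oracle_predict,
)
from bpoplan.geometry import LANDMARK_NAMES
from bpoplan.synthetic import PatientSpec


def simple_landmarks(
    femoral_head=(0.0, 0.0),
    fulcrum=(-31.5, 45.0),
    s1_mid=(-48.6, 104.2),
    ss_deg=30.0,
    width=35.0,
    t1=(30.0, 400.0),
    c7=(40.0, 425.0),
):
    """Hand-built landmark set with an endplate of given slope about s1_mid."""
    ss = math.radians(ss_deg)
    ex, ey = math.cos(ss), -math.sin(ss)
    half = width / 2
    return LandmarkSet(
        femoral_head=Point2(*femoral_head),
        fulcrum=Point2(*fulcrum),
        s1_anterior=Point2(s1_mid[0] + half * ex, s1_mid[1] + half * ey),
        s1_posterior=Point2(s1_mid[0] - half * ex, s1_mid[1] - half * ey),
        t1_centroid=Point2(*t1),
        c7_centroid=Point2(*c7),
    )


class TestMeasureParameters:
    def test_pt_from_direct_construction(self):
        # S1 midpoint placed 400 mm away at 20 deg posterior of vertical
        mid = (-400 * math.sin(math.radians(20)), 400 * math.cos(math.radians(20)))
        lm = simple_landmarks(s1_mid=mid, ss_deg=0.0)
        assert measure_parameters(lm, 0.0).pt_deg == pytest.approx(20.0, abs=1e-9)

    def test_horizontal_endplate_makes_pi_equal_pt(self):
        lm = simple_landmarks(ss_deg=0.0)
        p = measure_parameters(lm, 0.0)
        assert p.ss_deg == pytest.approx(0.0, abs=1e-12)
        assert p.pi_deg == pytest.approx(p.pt_deg, abs=1e-9)

    def test_sva_is_plumb_offset_from_posterior_corner(self):
        lm = simple_landmarks(s1_mid=(-10 + 17.5, 100.0), ss_deg=0.0, c7=(150.0, 425.0))
        # posterior corner at x = -10, C7 at x = 150
        assert lm.s1_posterior.x == pytest.approx(-10.0)
        assert measure_parameters(lm, 0.0).sva_mm == pytest.approx(160.0, abs=1e-12)

    def test_t1_plumbline_switch(self):
        lm = simple_landmarks()
        c7_based = measure_parameters(lm, 0.0, plumbline="c7").sva_mm
        t1_based = measure_parameters(lm, 0.0, plumbline="t1").sva_mm
        assert c7_based - t1_based == pytest.approx(lm.c7_centroid.x - lm.t1_centroid.x)

    def test_pi_equals_pt_plus_ss_on_random_patients(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            pt = float(rng.uniform(-5, 45))
            pi = float(np.clip(pt + rng.uniform(-20, 80), 25, 95))
            spec = PatientSpec(
                pi_deg=pi,
                pt_deg=pt,
                sva_mm=float(rng.uniform(-100, 350)),
                ll_deg=float(rng.uniform(0, 60)),
            )
            p = measure_parameters(make_patient(spec), spec.ll_deg)
            assert p.pi_deg == pytest.approx(p.pt_deg + p.ss_deg, abs=1e-9)

    def test_degenerate_midpoint_rejected(self):
        lm = simple_landmarks(femoral_head=(-48.6, 104.2))
        with pytest.raises(ValueError, match="midpoint"):
            measure_parameters(lm, 0.0)

    def test_coincident_landmarks_rejected_at_construction(self):
        with pytest.raises(ValueError, match="fulcrum"):
            simple_landmarks(fulcrum=(0.0, 0.0))


class TestApplyOsteotomy:
    def test_zero_angle_is_identity(self):
        lm = simple_landmarks()
        out = apply_osteotomy(lm, 0.0)
        for name in LANDMARK_NAMES:
            assert out.point(name) == lm.point(name)

    def test_quarter_turn_about_origin_fulcrum(self):
        # endplate sloped 45 deg so the rotated set still satisfies the
        # anterior-corner invariant after a quarter turn
        lm = simple_landmarks(femoral_head=(30.0, -40.0), fulcrum=(0.0, 0.0),
                              s1_mid=(0.0, 100.0), ss_deg=45.0)
        out = apply_osteotomy(lm, 90.0, cap_deg=90.0)
        mid = out.s1_midpoint
        assert (mid.x, mid.y) == pytest.approx((-100.0, 0.0), abs=1e-9)
        # caudal landmark untouched
        assert out.femoral_head == lm.femoral_head

    @given(oa=st.floats(0.0, 60.0), pt=st.floats(0.0, 40.0))
    @settings(max_examples=40, deadline=None)
    def test_rigid_motion_preserves_cranial_distances(self, oa, pt):
        lm = make_patient(PatientSpec(pi_deg=60.0, pt_deg=pt, sva_mm=150.0, ll_deg=30.0))
        out = apply_osteotomy(lm, oa)
        cranial = [n for n in LANDMARK_NAMES if lm.fragment_map[n] == "cranial"]
        for i, a in enumerate(cranial):
            assert abs(
                out.point(a).distance_to(out.fulcrum) - lm.point(a).distance_to(lm.fulcrum)
            ) < 1e-9
            for b in cranial[i + 1:]:
                assert abs(
                    out.point(a).distance_to(out.point(b))
                    - lm.point(a).distance_to(lm.point(b))
                ) < 1e-9

    @given(a=st.floats(0.0, 25.0), b=st.floats(0.0, 25.0))
    @settings(max_examples=40, deadline=None)
    def test_rotations_compose_additively(self, a, b):
        lm = simple_landmarks()
        two_step = apply_osteotomy(apply_osteotomy(lm, a), b)
        one_step = apply_osteotomy(lm, a + b)
        for name in LANDMARK_NAMES:
            assert two_step.point(name).x == pytest.approx(one_step.point(name).x, abs=1e-9)
            assert two_step.point(name).y == pytest.approx(one_step.point(name).y, abs=1e-9)


class TestOraclePredict:
    def test_single_zero_row_equals_baseline(self, deformity_landmarks):
        base = measure_parameters(deformity_landmarks, 26.2)
        tab = oracle_predict(deformity_landmarks, 26.2, [0.0])
        assert len(tab) == 1
        assert tab.loc[0, "pi_deg"] == base.pi_deg
        assert tab.loc[0, "sva_mm"] == base.sva_mm

    def test_sacral_slope_falls_exactly_one_for_one(self, deformity_landmarks, oa_grid):
        tab = oracle_predict(deformity_landmarks, 26.2, oa_grid)
        expected = tab.loc[0, "ss_deg"] - tab["oa_deg"]
        assert np.max(np.abs(tab["ss_deg"] - expected)) < 1e-9

    def test_correlation_signs_on_cohort(self, cohort_specs, oa_grid):
        """SVA, PI, TPA strictly fall and PT strictly rises with the opening angle."""
        for spec in cohort_specs:
            tab = oracle_predict(make_patient(spec), spec.ll_deg, oa_grid)
            assert np.all(np.diff(tab["sva_mm"]) < 0)
            assert np.all(np.diff(tab["pi_deg"]) < 0)
            assert np.all(np.diff(tab["tpa_deg"]) < 0)
            assert np.all(np.diff(tab["pt_deg"]) > 0)

    def test_grid_must_be_sorted_and_nonempty(self, deformity_landmarks):
        with pytest.raises(ValueError, match="nonempty"):
            oracle_predict(deformity_landmarks, 26.2, [])
        with pytest.raises(ValueError, match="ascending"):
            oracle_predict(deformity_landmarks, 26.2, [10.0, 5.0])


class TestDecompensatePt:
    def test_current_target_is_identity(self):
        lm = simple_landmarks()
        pt = measure_parameters(lm, 0.0).pt_deg
        out = decompensate_pt(lm, pt)
        for name in LANDMARK_NAMES:
            assert out.point(name).x == pytest.approx(lm.point(name).x, abs=1e-9)

    @pytest.mark.parametrize("target", [5.0, 15.0, 28.0])
    def test_target_pt_is_reached_and_pi_preserved(self, target):
        lm = make_patient(PatientSpec(pi_deg=58.0, pt_deg=30.0, sva_mm=120.0, ll_deg=30.0))
        before = measure_parameters(lm, 0.0)
        after = measure_parameters(decompensate_pt(lm, target), 0.0)
        assert after.pt_deg == pytest.approx(target, abs=1e-9)
        assert after.pi_deg == pytest.approx(before.pi_deg, abs=1e-9)

    def test_unmasking_retroversion_increases_sva(self):
        """Rotating a PT=30 deg compensated image anteriorly to PT=15 deg raises SVA."""
        lm = make_patient(PatientSpec(pi_deg=58.0, pt_deg=30.0, sva_mm=120.0, ll_deg=30.0))
        before = measure_parameters(lm, 0.0).sva_mm
        after = measure_parameters(decompensate_pt(lm, 15.0), 0.0).sva_mm
        assert after > before
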