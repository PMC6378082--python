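"""Landmark geometry, radiographic parameter measurement, and the rigid-rotation
osteotomy oracle.

Coordinate frame
----------------
Sagittal plane, millimetres, ``x`` anterior-positive, ``y`` cranial-positive,
origin arbitrary.  A positive opening angle (OA) rotates the cranial fragment
counterclockwise about the fulcrum in this frame, i.e. displaces the trunk
posteriorly — the correction an anterior opening wedge at the sciatic notch
produces.

Sign conventions (all angles reported in degrees)
-------------------------------------------------
PT   signed angle from vertical of the femoral-head → S1-midpoint line,
     positive when the midpoint lies posterior to the vertical through the
     femoral head (pelvic retroversion).
SS   signed inclination of the S1 endplate from horizontal, positive when the
     endplate slopes downward anteriorly (the normal standing posture);
     with this convention PI = PT + SS holds identically.
PI   unsigned angle at the S1 midpoint between the endplate perpendicular and
     the line to the femoral head.
SVA  horizontal offset of the cranial plumb landmark (C7 centroid by default,
     T1 optionally) from the posterosuperior S1 corner.
TPA  unsigned angle at the femoral head between the rays to the T1 centroid
     and to the S1 midpoint.
T1SPi  signed angle from vertical of the T1-centroid → femoral-head line,
     positive when T1 lies anterior to the femoral head.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Point2",
    "LandmarkSet",
    "SpinopelvicParameters",
    "PREDICTION_COLUMNS",
    "DEFAULT_OA_CAP_DEG",
    "LANDMARK_NAMES",
    "measure_parameters",
    "apply_osteotomy",
    "oracle_predict",
    "decompensate_pt",
]

#: Hard cap on the opening angle accepted by the model, degrees.
DEFAULT_OA_CAP_DEG = 60.0

#: Fixed column order of every prediction table the package writes.
PREDICTION_COLUMNS = [
    "oa_deg",
    "pi_deg",
    "pt_deg",
    "ss_deg",
    "sva_mm",
    "tpa_deg",
    "t1spi_deg",
    "pi_minus_ll_deg",
]

LANDMARK_NAMES = (
    "femoral_head",
    "fulcrum",
    "s1_anterior",
    "s1_posterior",
    "t1_centroid",
    "c7_centroid",
)

#: Which fragment each landmark belongs to.  The fulcrum is shared by both
#: fragments and the femoral head stays with the caudal (fixed) fragment.
DEFAULT_FRAGMENT_MAP: Mapping[str, str] = {
    "femoral_head": "caudal",
    "fulcrum": "fulcrum",
    "s1_anterior": "cranial",
    "s1_posterior": "cranial",
    "t1_centroid": "cranial",
    "c7_centroid": "cranial",
}


@dataclass(frozen=True)
class Point2:
    """A sagittal-plane point (mm): ``x`` anterior-positive, ``y`` cranial-positive."""

    x: float
    y: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x) and math.isfinite(self.y)):
            raise ValueError(f"non-finite coordinates ({self.x}, {self.y})")

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)

    def distance_to(self, other: "Point2") -> float:
        return math.hypot(self.x - other.x, self.y - other.y)


def _rotate_about(p: Point2, center: Point2, angle_rad: float) -> Point2:
    """Rotate ``p`` about ``center`` by ``angle_rad`` counterclockwise."""
    c, s = math.cos(angle_rad), math.sin(angle_rad)
    dx, dy = p.x - center.x, p.y - center.y
    return Point2(center.x + c * dx - s * dy, center.y + s * dx + c * dy)


@dataclass(frozen=True)
class LandmarkSet:
    """The six named sagittal landmarks driving the osteotomy model.

    The fulcrum is the posterior cortex at the sciatic notch — the hinge of
    the opening wedge.  ``fragment_map`` records which side of the osteotomy
    each landmark moves with; by construction the femoral head is caudal and
    the sacrum/spine landmarks cranial.
    """

    femoral_head: Point2
    fulcrum: Point2
    s1_anterior: Point2
    s1_posterior: Point2
    t1_centroid: Point2
    c7_centroid: Point2
    fragment_map: Mapping[str, str] = field(default_factory=lambda: dict(DEFAULT_FRAGMENT_MAP))

    def __post_init__(self) -> None:
        if self.fulcrum.distance_to(self.femoral_head) == 0.0:
            raise ValueError("degenerate geometry: fulcrum coincides with femoral_head")
        if self.s1_anterior.distance_to(self.s1_posterior) == 0.0:
            raise ValueError("degenerate geometry: s1_anterior coincides with s1_posterior")
        if not self.s1_anterior.x > self.s1_posterior.x:
            raise ValueError(
                "s1_anterior must lie anterior to (greater x than) s1_posterior"
            )
        missing = set(LANDMARK_NAMES) - set(self.fragment_map)
        if missing:
            raise ValueError(f"fragment_map missing landmarks: {sorted(missing)}")
        bad = {n: f for n, f in self.fragment_map.items() if f not in ("cranial", "caudal", "fulcrum")}
        if bad:
            raise ValueError(f"fragment_map has unknown fragments: {bad}")

    @property
    def s1_midpoint(self) -> Point2:
        return Point2(
            0.5 * (self.s1_anterior.x + self.s1_posterior.x),
            0.5 * (self.s1_anterior.y + self.s1_posterior.y),
        )

    def point(self, name: str) -> Point2:
        return getattr(self, name)

    def as_dict(self) -> dict[str, Point2]:
        return {name: getattr(self, name) for name in LANDMARK_NAMES}


@dataclass(frozen=True)
class SpinopelvicParameters:
    """One measurement of the sagittal alignment state.

    ``ll_deg`` is carried through as an input constant: the spine (hence the
    lumbar lordosis) is treated as rigid, so only PI − LL changes, via PI.
    """

    pi_deg: float
    pt_deg: float
    ss_deg: float
    sva_mm: float
    tpa_deg: float
    t1spi_deg: float
    ll_deg: float

    def __post_init__(self) -> None:
        if abs(self.pi_deg - (self.pt_deg + self.ss_deg)) > 1e-9:
            raise ValueError(
                f"PI = PT + SS violated: {self.pi_deg} != {self.pt_deg} + {self.ss_deg}"
            )
        if not math.isfinite(self.sva_mm):
            raise ValueError("SVA must be finite")

    @property
    def pi_minus_ll_deg(self) -> float:
        return self.pi_deg - self.ll_deg

    def as_row(self, oa_deg: float) -> dict[str, float]:
        return {
            "oa_deg": oa_deg,
            "pi_deg": self.pi_deg,
            "pt_deg": self.pt_deg,
            "ss_deg": self.ss_deg,
            "sva_mm": self.sva_mm,
            "tpa_deg": self.tpa_deg,
            "t1spi_deg": self.t1spi_deg,
            "pi_minus_ll_deg": self.pi_minus_ll_deg,
        }


def _unsigned_angle(u: np.ndarray, v: np.ndarray) -> float:
    """Unsigned angle between vectors, radians, robust near 0 and pi."""
    cross = u[0] * v[1] - u[1] * v[0]
    dot = float(np.dot(u, v))
    return math.atan2(abs(cross), dot)


def validate_oa(oa_deg: float, cap_deg: float = DEFAULT_OA_CAP_DEG) -> float:
    """Validate an opening angle in degrees against ``[0, cap]``."""
    if not math.isfinite(oa_deg):
        raise ValueError("opening angle must be finite")
    if not (0.0 <= oa_deg <= cap_deg):
        raise ValueError(f"opening angle {oa_deg}° outside [0, {cap_deg}]°")
    return float(oa_deg)


def measure_parameters(
    landmarks: LandmarkSet, ll_deg: float, plumbline: str = "c7"
) -> SpinopelvicParameters:
    """Measure PI, PT, SS, SVA, TPA and T1SPi directly from the landmarks.

    Parameters
    ----------
    landmarks
        Validated landmark set.
    ll_deg
        Lumbar lordosis in degrees; carried through unchanged (rigid spine).
    plumbline
        ``"c7"`` (default) or ``"t1"`` — which centroid drops the plumbline
        for the SVA measurement.
    """
    if plumbline not in ("c7", "t1"):
        raise ValueError(f"plumbline must be 'c7' or 't1', got {plumbline!r}")
    f = landmarks.femoral_head
    m = landmarks.s1_midpoint
    if m.distance_to(f) == 0.0:
        raise ValueError(
            "degenerate geometry: S1 endplate midpoint coincides with femoral_head"
        )
    t = landmarks.t1_centroid

    # PT: femoral_head -> S1 midpoint from vertical, posterior positive.
    v = m.as_array() - f.as_array()
    pt = math.atan2(-v[0], v[1])

    # SS: endplate inclination from horizontal, positive sloping down anteriorly.
    e = landmarks.s1_anterior.as_array() - landmarks.s1_posterior.as_array()
    ss = math.atan2(-e[1], e[0])

    # PI: angle between the caudally directed endplate perpendicular and the
    # midpoint -> femoral head ray, signed counterclockwise from the normal so
    # that PI = PT + SS holds identically (positive, hence equal to the
    # unsigned angle, for plausible anatomy).
    n_caudal = np.array([e[1], -e[0]])
    u = f.as_array() - m.as_array()
    pi = math.atan2(n_caudal[0] * u[1] - n_caudal[1] * u[0], float(np.dot(n_caudal, u)))
    if abs(pi - (pt + ss)) > math.radians(1e-9):
        raise AssertionError("internal: PI = PT + SS identity violated")
    pi = pt + ss  # exact identity, removes residual atan2 rounding

    tpa = _unsigned_angle(t.as_array() - f.as_array(), m.as_array() - f.as_array())
    t1spi = math.atan2(t.x - f.x, t.y - f.y)

    plumb = landmarks.c7_centroid if plumbline == "c7" else landmarks.t1_centroid
    sva = plumb.x - landmarks.s1_posterior.x

    return SpinopelvicParameters(
        pi_deg=math.degrees(pi),
        pt_deg=math.degrees(pt),
        ss_deg=math.degrees(ss),
        sva_mm=sva,
        tpa_deg=math.degrees(tpa),
        t1spi_deg=math.degrees(t1spi),
        ll_deg=float(ll_deg),
    )


def apply_osteotomy(
    landmarks: LandmarkSet, oa_deg: float, cap_deg: float = DEFAULT_OA_CAP_DEG
) -> LandmarkSet:
    """Simulate the opening wedge: rotate the cranial fragment about the fulcrum.

    Every landmark mapped to the cranial fragment rotates counterclockwise by
    ``oa_deg`` about the fulcrum (trunk displaces posteriorly); caudal
    landmarks and the fulcrum itself are unchanged.  Returns a new set.
    """
    oa = math.radians(validate_oa(oa_deg, cap_deg))
    if oa == 0.0:
        return replace(landmarks)  # exact identity, no rounding through the pivot
    fulcrum = landmarks.fulcrum
    moved = {}
    for name in LANDMARK_NAMES:
        p = landmarks.point(name)
        if landmarks.fragment_map[name] == "cranial":
            p = _rotate_about(p, fulcrum, oa)
        moved[name] = p
    return replace(landmarks, **moved)


def oracle_predict(
    landmarks: LandmarkSet,
    ll_deg: float,
    oa_grid_deg: Iterable[float],
    plumbline: str = "c7",
    cap_deg: float = DEFAULT_OA_CAP_DEG,
) -> pd.DataFrame:
    """Direct geometric prediction: rotate, then measure, per grid angle.

    This is the normative model — a rigid rotation of the cranial fragment
    followed by the standard radiographic measurements — against which the
    closed-form equations are validated.

    Returns a :class:`pandas.DataFrame` with columns :data:`PREDICTION_COLUMNS`.
    """
    grid = [float(oa) for oa in oa_grid_deg]
    if not grid:
        raise ValueError("oa_grid must be nonempty")
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("oa_grid must be sorted ascending")
    rows = []
    for oa in grid:
        rotated = apply_osteotomy(landmarks, oa, cap_deg=cap_deg)
        params = measure_parameters(rotated, ll_deg, plumbline=plumbline)
        rows.append(params.as_row(oa))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def decompensate_pt(landmarks: LandmarkSet, target_pt_deg: float) -> LandmarkSet:
    """Rotate the whole image about the femoral head so PT equals the target.

    Compensatory pelvic retroversion (high PT) masks part of the sagittal
    deformity; planning on the compensated image under-corrects.  Rotating the
    entire landmark set (both fragments) anteriorly about the femoral head to
    a normal PT unmasks the full deformity.  PI is invariant under this
    whole-image rotation.
    """
    current = measure_parameters(landmarks, 0.0)
    delta = math.radians(target_pt_deg - current.pt_deg)
    center = landmarks.femoral_head
    moved = {name: _rotate_about(landmarks.point(name), center, delta) for name in LANDMARK_NAMES}
    return replace(landmarks, **moved)
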