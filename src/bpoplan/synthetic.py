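"""Synthetic patients and the packaged muscle fixture.

``make_patient`` inverts the radiographic measurements: given target baseline
PI, PT and SVA it places the six landmarks so that measuring them returns
exactly the prescribed values (femoral head at the origin, S1 midpoint on the
PT direction, endplate tilted to SS = PI − PT, plumb landmark offset by SVA).
The trunk is rigid in this model, so only the endpoint landmarks matter; T1
is dropped onto a gently lordotic arc between the S1 midpoint and C7 purely
for visual plausibility.

``make_cohort`` samples patient specs uniformly from deformity-like ranges —
no claim of epidemiological realism, just coverage of the plausible space on
which the model's monotonicity properties must hold.

``default_muscle_fixture`` loads the packaged synthetic attachment geometry
standing in for a musculoskeletal-model export (see
``scripts/build_muscle_fixture.py`` for its construction).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

from .geometry import LandmarkSet, Point2
from .muscles import MuscleAttachment

__all__ = [
    "PatientSpec",
    "CohortSpec",
    "DEFAULT_COHORT_RANGES",
    "make_patient",
    "make_cohort",
    "sample_patient_specs",
    "default_muscle_fixture",
    "default_fixture_fulcrum",
]


@dataclass(frozen=True)
class PatientSpec:
    """Prescribed baseline alignment plus body-scale constants (mm, deg)."""

    pi_deg: float
    pt_deg: float
    sva_mm: float
    ll_deg: float
    trunk_height_mm: float = 420.0        # femoral head -> T1 vertical scale
    fulcrum_offset_mm: float = 55.0       # femoral head -> sciatic-notch fulcrum
    fulcrum_angle_deg: float = 35.0       # posterior-cranial, from vertical
    endplate_width_mm: float = 35.0
    s1_distance_mm: float = 115.0         # femoral head -> S1 midpoint
    seed: int = 0

    def __post_init__(self) -> None:
        checks = [
            (20.0 <= self.pi_deg <= 100.0, "pi_deg must lie in [20, 100]"),
            (-10.0 <= self.pt_deg <= 50.0, "pt_deg must lie in [-10, 50]"),
            (abs(self.sva_mm) <= 400.0, "|sva_mm| must be <= 400"),
            (self.trunk_height_mm > 0, "trunk_height_mm must be positive"),
            (self.fulcrum_offset_mm > 0, "fulcrum_offset_mm must be positive"),
            (self.endplate_width_mm > 0, "endplate_width_mm must be positive"),
            (self.s1_distance_mm > 0, "s1_distance_mm must be positive"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(f"unconstructible patient spec: {msg}")
        ss = self.pi_deg - self.pt_deg
        if not -89.0 < ss < 89.0:
            raise ValueError(
                f"unconstructible patient spec: SS = PI - PT = {ss}° "
                "must lie in (-89°, 89°) for a valid endplate"
            )


#: Uniform sampling ranges for deformity-like cohorts.
DEFAULT_COHORT_RANGES: dict[str, tuple[float, float]] = {
    "pi_deg": (45.0, 85.0),
    "pt_deg": (15.0, 35.0),
    "sva_mm": (80.0, 250.0),
    "ll_deg": (10.0, 40.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """A cohort: n patients drawn uniformly from per-parameter ranges."""

    n: int
    ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COHORT_RANGES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("cohort size n must be >= 1")
        merged = dict(DEFAULT_COHORT_RANGES) | dict(self.ranges)
        unknown = set(merged) - set(DEFAULT_COHORT_RANGES)
        if unknown:
            raise ValueError(f"unknown cohort range keys: {sorted(unknown)}")
        for k, (lo, hi) in merged.items():
            if not lo <= hi:
                raise ValueError(f"empty range for {k}: ({lo}, {hi})")
        object.__setattr__(self, "ranges", merged)


def make_patient(spec: PatientSpec) -> LandmarkSet:
    """Construct a landmark set whose measured (PI, PT, SVA) equal the spec.

    Deterministic (the construction has no randomness; the spec's seed only
    tags provenance).  SVA is realised against the C7 plumbline, the package
    default.
    """
    pt = math.radians(spec.pt_deg)
    ss = math.radians(spec.pi_deg - spec.pt_deg)

    f = Point2(0.0, 0.0)
    th = math.radians(spec.fulcrum_angle_deg)
    fulcrum = Point2(-spec.fulcrum_offset_mm * math.sin(th),
                     spec.fulcrum_offset_mm * math.cos(th))
    m = Point2(-spec.s1_distance_mm * math.sin(pt),
               spec.s1_distance_mm * math.cos(pt))
    # endplate direction, posterior -> anterior, sloping down anteriorly for SS > 0
    ex, ey = math.cos(ss), -math.sin(ss)
    half = 0.5 * spec.endplate_width_mm
    s1_anterior = Point2(m.x + half * ex, m.y + half * ey)
    s1_posterior = Point2(m.x - half * ex, m.y - half * ey)

    c7 = Point2(s1_posterior.x + spec.sva_mm, spec.trunk_height_mm + 25.0)
    t1 = _t1_on_arc(m, c7, spec.trunk_height_mm, spec.ll_deg)

    return LandmarkSet(
        femoral_head=f,
        fulcrum=fulcrum,
        s1_anterior=s1_anterior,
        s1_posterior=s1_posterior,
        t1_centroid=t1,
        c7_centroid=c7,
    )


def _t1_on_arc(m: Point2, c7: Point2, t1_height: float, ll_deg: float) -> Point2:
    """Place T1 at the given height on a lordosis-scaled arc from S1 to C7.

    The arc is cosmetic — the rigid-trunk model only uses endpoint positions —
    but keeps generated images anatomically plausible.
    """
    chord = c7.as_array() - m.as_array()
    length = float(np.hypot(*chord))
    if c7.y <= m.y or length == 0.0:
        raise ValueError("unconstructible patient spec: C7 must lie cranial to S1")
    t = (t1_height - m.y) / (c7.y - m.y)
    t = min(max(t, 0.05), 0.98)  # keep T1 strictly between S1 and C7
    u = chord / length
    anterior_normal = np.array([u[1], -u[0]])
    bulge = math.sin(math.pi * t) * math.radians(ll_deg) * 0.12 * length
    p = m.as_array() + t * chord + bulge * anterior_normal
    return Point2(float(p[0]), float(p[1]))


def sample_patient_specs(spec: CohortSpec) -> list[PatientSpec]:
    """Draw the cohort's patient specs (uniform per parameter, seeded)."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for i in range(spec.n):
        draw = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in sorted(spec.ranges.items())}
        out.append(PatientSpec(seed=int(spec.seed) + i, **draw))
    return out


def make_cohort(spec: CohortSpec) -> list[LandmarkSet]:
    """Generate the cohort's landmark sets (reproducible for a given seed)."""
    return [make_patient(ps) for ps in sample_patient_specs(spec)]


def default_fixture_fulcrum() -> Point2:
    """Fulcrum position paired with the packaged muscle fixture.

    Matches the default ``PatientSpec`` fulcrum: 55 mm from the femoral head
    (origin) at 35° posterior-cranial.
    """
    th = math.radians(35.0)
    return Point2(-55.0 * math.sin(th), 55.0 * math.cos(th))


def default_muscle_fixture() -> list[MuscleAttachment]:
    """Load the packaged synthetic muscle attachment fixture (8 segments).

    Gluteus medius and maximus are split into anterior/middle/posterior
    one-dimensional segments; tensor fasciae latae and piriformis are single
    segments.  The coordinates are a synthetic stand-in constructed so the
    stretch-ratio pattern at a 20° opening matches the published behaviour of
    muscles crossing the osteotomy site (see scripts/build_muscle_fixture.py).
    """
    ref = resources.files("bpoplan").joinpath("data/muscle_attachments.json")
    try:
        payload = json.loads(ref.read_text())
    except FileNotFoundError as exc:  # pragma: no cover
        raise FileNotFoundError("packaged muscle fixture data file is missing") from exc
    return [
        MuscleAttachment(
            name=seg["name"],
            group=seg["group"],
            section=seg["section"],
            cranial_point=tuple(seg["cranial"]),
            caudal_point=tuple(seg["caudal"]),
        )
        for seg in payload["segments"]
    ]
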