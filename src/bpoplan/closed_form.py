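"""Closed-form predictive equations for the opening-wedge osteotomy.

The osteotomy is a rigid rotation of the cranial fragment about the sciatic
notch fulcrum, so every post-correction parameter is a trigonometric function
of the opening angle OA and a handful of patient-specific constants derived
once from the baseline landmarks:

========  ======================================================
``a``     fulcrum → femoral-head distance
``b``     fulcrum → S1-midpoint distance
``L``     fulcrum → T1-centroid distance
``L'``    fulcrum → posterosuperior S1 corner distance
``k``     b/a,  ``k' = a/b``,  ``k'' = a/L``
``α1–α6`` baseline angles fixing the relative orientation of the
          fulcrum–femoral-head, fulcrum–S1 and fulcrum–T1 rays, the
          endplate perpendicular, and the vertical
========  ======================================================

With γ = α2 + OA the included fulcrum angle of the triangle
(fulcrum, femoral head, S1 midpoint), the law of sines gives

    PI(OA)  = asin[ sin γ / sqrt(1 + k² − 2k cos γ) ] + α1
    PT(OA)  = PI(OA) + π/2 − α1 − α3 + OA
    β(OA)   = asin[ sin γ / sqrt(1 + k'² − 2k' cos γ) ]
    T1SPi(OA) = asin[ sin(α6+OA) / sqrt(1 + k''² − 2k'' cos(α6+OA)) ] + α5 − π/2
    TPA(OA) = T1SPi(OA) − α5 − β(OA) + π/2
    SVA(OA) = L_p sin(ψ0 − OA) + L' cos(α4 − OA)

Here β is the angle at the femoral head between the rays to the fulcrum and
to the S1 midpoint (unrelated to the muscle model's β).  The arcsine terms
are the far angles of law-of-sines triangles; they are evaluated with the
two-argument arctangent, which coincides with the arcsine on its acute branch
and remains exact when the triangle angle passes 90° or the fulcrum angle
passes 180°.

Two trunk inclinations appear and must not be conflated.  The reported T1
spinopelvic inclination (T1SPi) is referenced at the femoral head.  The trunk
inclination driving SVA, ψ = ψ0 − OA, is referenced at the *fulcrum* (the
plumb landmark rotates about the fulcrum, so its inclination there falls
exactly 1° per degree of OA); its lever arm L_p is the fulcrum → plumb-landmark
distance, consistent with k'' = a/L.  Both are exact under rigid rotation;
using the femoral-head inclination inside the SVA expression is not.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import (
    DEFAULT_OA_CAP_DEG,
    PREDICTION_COLUMNS,
    LandmarkSet,
    SpinopelvicParameters,
    measure_parameters,
    validate_oa,
)

__all__ = [
    "DerivedGeometry",
    "LinearModel",
    "EXAMPLE_PATIENT_MODELS",
    "derive_geometry",
    "closed_form_predict",
    "closed_form_table",
    "fit_linear",
    "evaluate_linear",
]


@dataclass(frozen=True)
class DerivedGeometry:
    """Patient-specific scalars of the closed-form equations (lengths mm, angles rad)."""

    a_mm: float
    b_mm: float
    l_mm: float
    l_prime_mm: float
    k: float
    k_prime: float
    k_dprime: float
    alpha1: float
    alpha2: float
    alpha3: float
    alpha4: float
    alpha5: float
    alpha6: float
    #: plumbline choice ('c7' or 't1') baked into the SVA constants below
    plumbline: str
    #: fulcrum → plumb-landmark distance L_p (equals l_mm when plumbline='t1')
    l_plumb_mm: float
    #: baseline fulcrum-referenced inclination ψ0 of the plumb landmark (rad)
    plumb_incl_rad: float

    def __post_init__(self) -> None:
        for name in ("a_mm", "b_mm", "l_mm", "l_prime_mm", "l_plumb_mm"):
            if not getattr(self, name) > 0.0:
                raise ValueError(f"{name} must be positive")
        if abs(self.k * self.k_prime - 1.0) > 1e-12:
            raise ValueError("k * k' must equal 1")
        if abs(self.k_dprime - self.a_mm / self.l_mm) > 1e-12:
            raise ValueError("k'' must equal a / L")


def _polar(dx: float, dy: float) -> float:
    return math.atan2(dy, dx)


def _ccw(from_angle: float, to_angle: float) -> float:
    """Counterclockwise angle from one ray direction to another, in [0, 2π)."""
    return (to_angle - from_angle) % (2.0 * math.pi)


def derive_geometry(landmarks: LandmarkSet, plumbline: str = "c7") -> DerivedGeometry:
    """Extract the patient-specific constants from a baseline landmark set.

    The α angles are fixed by the baseline configuration:

    - α2, α6: counterclockwise angle at the fulcrum from the ray to the
      femoral head to the ray to the S1 midpoint (α2) / T1 centroid (α6);
    - α5: π/2 plus the anterior-positive inclination from vertical of the
      femoral-head → fulcrum ray;
    - α1: baseline PI minus the baseline S1-midpoint triangle angle (the
      rigid-invariant angle between the endplate perpendicular and the
      midpoint → fulcrum ray);
    - α3: π/2 − α1 + SS(0), making the PT relation an identity;
    - α4: π minus the polar angle of the fulcrum → S1-posterior-corner ray,
      so that L' cos(α4 − OA) is that corner's anterior offset from the
      fulcrum at every OA.
    """
    if plumbline not in ("c7", "t1"):
        raise ValueError(f"plumbline must be 'c7' or 't1', got {plumbline!r}")
    f = landmarks.femoral_head
    o = landmarks.fulcrum
    m = landmarks.s1_midpoint
    t = landmarks.t1_centroid
    sp = landmarks.s1_posterior
    plumb = landmarks.c7_centroid if plumbline == "c7" else t

    a = o.distance_to(f)
    b = o.distance_to(m)
    l = o.distance_to(t)
    l_prime = o.distance_to(sp)
    l_plumb = o.distance_to(plumb)
    for val, pair in ((a, "fulcrum-femoral_head"), (b, "fulcrum-S1 midpoint"),
                      (l, "fulcrum-t1_centroid"), (l_prime, "fulcrum-s1_posterior"),
                      (l_plumb, f"fulcrum-{plumbline} plumb landmark")):
        if val == 0.0:
            raise ValueError(f"zero-length segment: {pair}")

    th_of = _polar(f.x - o.x, f.y - o.y)   # fulcrum -> femoral head
    th_om = _polar(m.x - o.x, m.y - o.y)
    th_ot = _polar(t.x - o.x, t.y - o.y)
    th_osp = _polar(sp.x - o.x, sp.y - o.y)

    alpha2 = _ccw(th_of, th_om)
    alpha6 = _ccw(th_of, th_ot)
    alpha4 = math.pi - th_osp
    alpha5 = 0.5 * math.pi + math.atan2(o.x - f.x, o.y - f.y)

    base = measure_parameters(landmarks, 0.0, plumbline=plumbline)
    angle_m0 = _triangle_far_angle(a, b, alpha2)
    alpha1 = math.radians(base.pi_deg) - angle_m0
    alpha3 = 0.5 * math.pi - alpha1 + math.radians(base.ss_deg)

    psi0 = math.atan2(plumb.x - o.x, plumb.y - o.y)

    return DerivedGeometry(
        a_mm=a, b_mm=b, l_mm=l, l_prime_mm=l_prime,
        k=b / a, k_prime=a / b, k_dprime=a / l,
        alpha1=alpha1, alpha2=alpha2, alpha3=alpha3,
        alpha4=alpha4, alpha5=alpha5, alpha6=alpha6,
        plumbline=plumbline, l_plumb_mm=l_plumb, plumb_incl_rad=psi0,
    )


def _triangle_far_angle(near: float, far: float, gamma: float) -> float:
    """Angle opposite ``near`` in a triangle with sides ``near``, ``far`` and
    included angle ``gamma`` between them.

    Equals asin(sin γ / sqrt(1 + r² − 2r cos γ)) with r = near/far on the acute
    branch, but stays exact for obtuse results and for γ beyond π.
    """
    return math.atan2(near * math.sin(gamma), far - near * math.cos(gamma))


def printed_arcsine_form(ratio: float, gamma: float) -> float:
    """asin(sin γ / sqrt(1 + r² − 2 r cos γ)) — the textbook arcsine form.

    Valid only while the resulting triangle angle is acute; kept for
    cross-checking :func:`_triangle_far_angle` on its branch.
    """
    denom = math.sqrt(1.0 + ratio * ratio - 2.0 * ratio * math.cos(gamma))
    arg = math.sin(gamma) / denom
    if abs(arg) > 1.0 + 1e-12:
        raise ValueError(f"arcsine argument {arg} out of range at gamma={gamma}")
    return math.asin(max(-1.0, min(1.0, arg)))


def closed_form_predict(
    geom: DerivedGeometry,
    ll_deg: float,
    oa_deg: float,
    cap_deg: float = DEFAULT_OA_CAP_DEG,
) -> SpinopelvicParameters:
    """Evaluate the closed-form equations at one opening angle."""
    oa = math.radians(validate_oa(oa_deg, cap_deg))
    g = geom

    gamma2 = g.alpha2 + oa
    gamma6 = g.alpha6 + oa

    angle_m = _triangle_far_angle(g.a_mm, g.b_mm, gamma2)      # at S1 midpoint
    beta = _triangle_far_angle(g.b_mm, g.a_mm, gamma2)         # at femoral head
    angle_t = _triangle_far_angle(g.l_mm, g.a_mm, gamma6)      # at femoral head, T1 ray

    pi = angle_m + g.alpha1
    pt = pi + 0.5 * math.pi - g.alpha1 - g.alpha3 + oa
    ss = pi - pt
    t1spi = angle_t + g.alpha5 - 0.5 * math.pi
    tpa = t1spi - g.alpha5 - beta + 0.5 * math.pi
    sva = g.l_plumb_mm * math.sin(g.plumb_incl_rad - oa) + g.l_prime_mm * math.cos(g.alpha4 - oa)

    return SpinopelvicParameters(
        pi_deg=math.degrees(pi),
        pt_deg=math.degrees(pt),
        ss_deg=math.degrees(ss),
        sva_mm=sva,
        tpa_deg=math.degrees(tpa),
        t1spi_deg=math.degrees(t1spi),
        ll_deg=float(ll_deg),
    )


def closed_form_table(
    geom: DerivedGeometry,
    ll_deg: float,
    oa_grid_deg,
    cap_deg: float = DEFAULT_OA_CAP_DEG,
) -> pd.DataFrame:
    """Closed-form counterpart of :func:`bpoplan.geometry.oracle_predict`."""
    grid = [float(oa) for oa in oa_grid_deg]
    if not grid:
        raise ValueError("oa_grid must be nonempty")
    if any(y < x for x, y in zip(grid, grid[1:])):
        raise ValueError("oa_grid must be sorted ascending")
    rows = [closed_form_predict(geom, ll_deg, oa, cap_deg).as_row(oa) for oa in grid]
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


@dataclass(frozen=True)
class LinearModel:
    """Least-squares line for one parameter against the opening angle."""

    parameter_name: str
    slope: float          # units per degree of OA
    intercept: float      # units at OA = 0
    r_squared: float
    oa_range_deg: tuple[float, float]

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0 + 1e-12):
            raise ValueError("r_squared must lie in [0, 1]")
        if not self.oa_range_deg[1] >= self.oa_range_deg[0]:
            raise ValueError("oa_range must be nonempty")


#: Linear coefficients for the package's reference example patient — a severe
#: rigid sagittal deformity with baseline SVA ≈ 224 mm — used in the worked
#: examples and tests.  SVA in mm; OA, PI, PT, TPA in degrees.
EXAMPLE_PATIENT_MODELS: Mapping[str, LinearModel] = {
    "sva_mm": LinearModel("sva_mm", -8.3, 223.8, 1.0, (0.0, 40.0)),
    "pi_deg": LinearModel("pi_deg", -0.7, 54.4, 1.0, (0.0, 40.0)),
    "pt_deg": LinearModel("pt_deg", 0.3, 10.4, 1.0, (0.0, 40.0)),
    "tpa_deg": LinearModel("tpa_deg", -0.6, 27.0, 1.0, (0.0, 40.0)),
}


def fit_linear(table: pd.DataFrame, parameters: tuple[str, ...] | None = None) -> dict[str, LinearModel]:
    """Ordinary least squares of each parameter column against ``oa_deg``.

    The exact parameter–OA relations are trigonometric, but over the practical
    range of opening angles they are nearly linear; the fitted slopes are the
    clinically quotable degrees-per-degree (or mm-per-degree) rates.
    """
    if "oa_deg" not in table.columns:
        raise ValueError("table must have an oa_deg column")
    oa = table["oa_deg"].to_numpy(dtype=float)
    if len(np.unique(oa)) < 3:
        raise ValueError("need at least 3 distinct OA values to fit")
    if parameters is None:
        parameters = tuple(c for c in table.columns if c != "oa_deg")
    models: dict[str, LinearModel] = {}
    for name in parameters:
        y = table[name].to_numpy(dtype=float)
        res = stats.linregress(oa, y)
        models[name] = LinearModel(
            parameter_name=name,
            slope=float(res.slope),
            intercept=float(res.intercept),
            r_squared=float(res.rvalue) ** 2,
            oa_range_deg=(float(oa.min()), float(oa.max())),
        )
    return models


def evaluate_linear(model: LinearModel, oa_deg: float) -> float:
    """Evaluate ``slope * oa + intercept`` in the model's units."""
    return model.slope * float(oa_deg) + model.intercept
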