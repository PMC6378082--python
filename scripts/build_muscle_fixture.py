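"""Construct the packaged synthetic muscle attachment fixture.

The real attachment geometry of the muscles crossing the osteotomy site
(gluteus medius/maximus sections, tensor fasciae latae, piriformis) comes
from a musculoskeletal model and is not publicly tabulated, so the package
ships a synthetic stand-in built here.  For each segment we fix plausible
in-plane lever arms l1 (fulcrum → iliac attachment), l2 (fulcrum → femoral
attachment) and a mediolateral offset Δz, then solve the signed fulcrum angle
β so that the stretch ratio at a 20° opening angle equals the target value:

    anterior GMed +8%, TFL +4%, posterior GMed −6%, anterior GMax −5%,
    middle GMax −6%, posterior GMax −8%, piriformis −5%, middle GMed isometric
    (β = −10° makes λ(20°) = 1 exactly by chord symmetry).

3-D coordinates are then laid out around the default fixture fulcrum with
anatomically sensible caudal ray directions.  Run from the repository root:

    python scripts/build_muscle_fixture.py
"""

from __future__ import annotations

import json
import math
import pathlib
import sys

from scipy.optimize import brentq

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from bpoplan.geometry import Point2  # noqa: E402
from bpoplan.muscles import MuscleGeometry, baseline_geometry, stretched_length  # noqa: E402
from bpoplan.synthetic import default_fixture_fulcrum  # noqa: E402

OUT = pathlib.Path(__file__).resolve().parents[1] / "src/bpoplan/data/muscle_attachments.json"

# name, group, section, l1, l2, dz, cranial-ray polar angle (deg), target λ(20°)
SEGMENTS = [
    ("GMed_anterior", "GMed", "anterior", 75.0, 85.0, 15.0, 55.0, 1.08),
    ("GMed_middle", "GMed", "middle", 55.0, 120.0, 35.0, 95.0, None),  # β = −10°
    ("GMed_posterior", "GMed", "posterior", 65.0, 80.0, 15.0, 115.0, 0.94),
    ("GMax_anterior", "GMax", "anterior", 80.0, 95.0, 25.0, 120.0, 0.95),
    ("GMax_middle", "GMax", "middle", 85.0, 100.0, 25.0, 128.0, 0.94),
    ("GMax_posterior", "GMax", "posterior", 90.0, 105.0, 25.0, 135.0, 0.92),
    ("TFL", "TFL", "whole", 70.0, 110.0, 20.0, 45.0, 1.04),
    ("P", "P", "whole", 60.0, 95.0, 30.0, 165.0, 0.95),
]


def lam20(l1: float, l2: float, dz: float, beta_deg: float) -> float:
    g = _geom(l1, l2, dz, beta_deg)
    return stretched_length(g, 20.0) / g.l0_mm


def _geom(l1: float, l2: float, dz: float, beta_deg: float) -> MuscleGeometry:
    b = math.radians(beta_deg)
    l0 = math.sqrt(l1 * l1 + l2 * l2 - 2 * l1 * l2 * math.cos(b) + dz * dz)
    return MuscleGeometry("tmp", l1, l2, b, dz, l0)


def solve_beta(l1: float, l2: float, dz: float, target: float) -> float:
    """Signed β (deg) achieving the target λ(20°)."""
    if target is None:
        return -10.0
    f = lambda beta: lam20(l1, l2, dz, beta) - target
    if target > 1.0:
        lo, hi = 15.0, 175.0
    else:
        lo, hi = -165.0, -25.0
    return float(brentq(f, lo, hi, xtol=1e-12))


def main() -> None:
    fulcrum = default_fixture_fulcrum()
    segments = []
    for name, group, section, l1, l2, dz, theta1_deg, target in SEGMENTS:
        beta = solve_beta(l1, l2, dz, target)
        th1 = math.radians(theta1_deg)
        th2 = th1 - math.radians(beta)
        caudal = (fulcrum.x + l2 * math.cos(th2), fulcrum.y + l2 * math.sin(th2), 0.0)
        cranial = (fulcrum.x + l1 * math.cos(th1), fulcrum.y + l1 * math.sin(th1), dz)
        segments.append(
            {"name": name, "group": group, "section": section,
             "cranial": list(cranial), "caudal": list(caudal)}
        )
        # verification: reduce back and report the realised stretch curve
        att_geom = baseline_geometry(
            __import__("bpoplan.muscles", fromlist=["MuscleAttachment"]).MuscleAttachment(
                name, group, section, cranial, caudal
            ),
            fulcrum,
        )
        realised = stretched_length(att_geom, 20.0) / att_geom.l0_mm
        lam40 = stretched_length(att_geom, 40.0) / att_geom.l0_mm
        tgt = 1.0 if target is None else target
        print(f"{name:15s} beta={beta:9.4f} deg  lambda(20)={realised:.6f} "
              f"(target {tgt:.2f})  lambda(40)={lam40:.6f}")
        assert abs(realised - tgt) < 1e-9, name
        assert lam40 < 1.254, f"{name} exceeds critical stretch inside the OA cap"

    OUT.parent.mkdir(parents=True, exist_ok=True)
    payload = {"units": "mm", "segments": segments}
    OUT.write_text(json.dumps(payload, indent=2) + "\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
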