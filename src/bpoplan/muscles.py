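"""Stretch of muscle segments crossing the osteotomy site.

Each segment is a straight line from a cranial-fragment attachment (ilium) to
a caudal attachment (femur / greater trochanter).  The opening wedge rotates
the cranial attachment in the sagittal plane about the fulcrum while the
caudal attachment stays put, so with

    l1  in-plane fulcrum → cranial-attachment distance
    l2  in-plane fulcrum → caudal-attachment distance
    β   signed baseline angle at the fulcrum, counterclockwise from the
        caudal ray to the cranial ray
    Δz  out-of-plane (mediolateral) offset between the attachments

the post-osteotomy length is the law-of-cosines chord lifted by Δz:

    l(OA) = sqrt(l1² + l2² − 2 l1 l2 cos(β + OA)),   d(OA) = sqrt(l(OA)² + Δz²)

and the stretch ratio is λ(OA) = d(OA) / L0 with L0 = d(0).  The sign of β
decides the fate of a segment: the chord derivative is proportional to
l1·l2·sin(β + OA), so segments whose cranial attachment sits counterclockwise
(anteriorly, for plausible geometry) of the caudal ray lengthen and the rest
shorten — anterior muscles (TFL, anterior gluteus medius) stretch, posterior
ones (gluteus maximus, piriformis, posterior gluteus medius) slacken.

Shortening segments are considered safe (a slack muscle carries no stress);
lengthening segments are flagged when λ reaches the critical stretch ratio
beyond which muscle function is impaired (default 25.4% strain).

This β at the fulcrum is unrelated to the spinopelvic β of the closed-form
alignment equations; they never mix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .geometry import DEFAULT_OA_CAP_DEG, Point2, validate_oa

__all__ = [
    "MuscleAttachment",
    "MuscleGeometry",
    "MuscleResult",
    "SafetySummary",
    "MUSCLE_GROUPS",
    "CRITICAL_STRETCH_RATIO",
    "ISOMETRIC_TOL",
    "baseline_geometry",
    "stretched_length",
    "stretch_ratio_curve",
    "classify_safety",
    "muscle_results_table",
]

#: group name -> required sections
MUSCLE_GROUPS = {
    "GMed": ("anterior", "middle", "posterior"),
    "GMax": ("anterior", "middle", "posterior"),
    "TFL": ("whole",),
    "P": ("whole",),
}

#: Critical stretch ratio (strain) beyond which function is impaired.
CRITICAL_STRETCH_RATIO = 0.254

#: |λ − 1| at or below this is classified isometric.
ISOMETRIC_TOL = 1e-6


@dataclass(frozen=True)
class MuscleAttachment:
    """One straight-line muscle segment in 3-D (mm).

    Coordinates: x anterior, y cranial, z mediolateral (out of the sagittal
    plane).  The cranial point rides the rotated fragment; the caudal point
    is femoral and fixed.
    """

    name: str
    group: str
    section: str
    cranial_point: tuple[float, float, float]
    caudal_point: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.group not in MUSCLE_GROUPS:
            raise ValueError(f"unknown muscle group {self.group!r}")
        if self.section not in MUSCLE_GROUPS[self.group]:
            raise ValueError(
                f"section {self.section!r} invalid for group {self.group!r}"
            )
        if tuple(self.cranial_point) == tuple(self.caudal_point):
            raise ValueError(f"segment {self.name!r}: attachment points coincide")
        for p in (self.cranial_point, self.caudal_point):
            if len(p) != 3 or not all(math.isfinite(c) for c in p):
                raise ValueError(f"segment {self.name!r}: bad 3-D coordinate {p}")


@dataclass(frozen=True)
class MuscleGeometry:
    """Per-segment scalars of the stretch equation (lengths mm, β rad, signed)."""

    name: str
    l1_mm: float
    l2_mm: float
    beta_signed_rad: float
    delta_z_mm: float
    l0_mm: float

    def __post_init__(self) -> None:
        if not (self.l1_mm > 0 and self.l2_mm > 0):
            raise ValueError(f"segment {self.name!r}: l1 and l2 must be positive")
        expected = math.sqrt(
            self.l1_mm**2 + self.l2_mm**2
            - 2 * self.l1_mm * self.l2_mm * math.cos(self.beta_signed_rad)
            + self.delta_z_mm**2
        )
        if abs(expected - self.l0_mm) > 1e-9:
            raise ValueError(f"segment {self.name!r}: L0 inconsistent with (l1, l2, beta, dz)")


@dataclass(frozen=True)
class MuscleResult:
    """Stretch state of one segment at one opening angle."""

    name: str
    oa_deg: float
    length_mm: float
    stretch_ratio: float
    classification: str  # lengthening | shortening | isometric
    exceeds_critical: bool

    def __post_init__(self) -> None:
        if not self.stretch_ratio > 0:
            raise ValueError("stretch ratio must be positive")
        iso = abs(self.stretch_ratio - 1.0) <= ISOMETRIC_TOL
        if iso != (self.classification == "isometric"):
            raise ValueError("classification inconsistent with stretch ratio")


def baseline_geometry(attachment: MuscleAttachment, fulcrum: Point2) -> MuscleGeometry:
    """Reduce a 3-D segment to the (l1, l2, β, Δz) scalars about the fulcrum."""
    cx, cy, cz = attachment.cranial_point
    dx, dy, dz = attachment.caudal_point
    v1 = (cx - fulcrum.x, cy - fulcrum.y)
    v2 = (dx - fulcrum.x, dy - fulcrum.y)
    l1 = math.hypot(*v1)
    l2 = math.hypot(*v2)
    if l1 == 0.0 or l2 == 0.0:
        raise ValueError(
            f"segment {attachment.name!r}: attachment projects onto the fulcrum"
        )
    beta = math.atan2(v1[1], v1[0]) - math.atan2(v2[1], v2[0])
    beta = math.atan2(math.sin(beta), math.cos(beta))  # wrap to (-pi, pi]
    delta_z = abs(cz - dz)
    l0 = math.sqrt(l1 * l1 + l2 * l2 - 2 * l1 * l2 * math.cos(beta) + delta_z * delta_z)
    return MuscleGeometry(attachment.name, l1, l2, beta, delta_z, l0)


def stretched_length(
    geom: MuscleGeometry, oa_deg: float, cap_deg: float = DEFAULT_OA_CAP_DEG
) -> float:
    """Post-osteotomy segment length d(OA) in mm."""
    oa = math.radians(validate_oa(oa_deg, cap_deg))
    chord_sq = (
        geom.l1_mm**2 + geom.l2_mm**2
        - 2 * geom.l1_mm * geom.l2_mm * math.cos(geom.beta_signed_rad + oa)
    )
    return math.sqrt(chord_sq + geom.delta_z_mm**2)


def stretch_ratio_curve(
    attachments: Sequence[MuscleAttachment],
    fulcrum: Point2,
    oa_grid_deg: Iterable[float],
    critical_sr: float = CRITICAL_STRETCH_RATIO,
    cap_deg: float = DEFAULT_OA_CAP_DEG,
) -> list[MuscleResult]:
    """λ(OA) = d(OA)/L0 for every segment over the grid, with classification."""
    attachments = list(attachments)
    grid = [float(oa) for oa in oa_grid_deg]
    if not attachments or not grid:
        raise ValueError("attachments and oa_grid must be nonempty")
    if not 0.0 < critical_sr < 1.0:
        raise ValueError("critical_sr must lie in (0, 1)")
    results = []
    for att in attachments:
        geom = baseline_geometry(att, fulcrum)
        for oa in grid:
            d = stretched_length(geom, oa, cap_deg)
            lam = d / geom.l0_mm
            if abs(lam - 1.0) <= ISOMETRIC_TOL:
                cls = "isometric"
            elif lam > 1.0:
                cls = "lengthening"
            else:
                cls = "shortening"
            results.append(
                MuscleResult(att.name, oa, d, lam, cls, lam >= 1.0 + critical_sr)
            )
    return results


@dataclass(frozen=True)
class SafetySummary:
    """Roll-up of stretch results: what lengthens, what exceeds critical."""

    n_segments: int
    n_lengthening: int
    n_shortening: int
    n_isometric: int
    unsafe_segments: tuple[str, ...]
    max_stretch_ratio: float
    max_stretch_segment: str
    max_stretch_oa_deg: float


def classify_safety(results: Sequence[MuscleResult]) -> SafetySummary:
    """Summarise a batch of results.

    Shortening segments are safe by assumption (no stress when slack);
    lengthening segments are unsafe only beyond the critical stretch ratio.
    """
    if not results:
        return SafetySummary(0, 0, 0, 0, (), 0.0, "", 0.0)
    names = sorted({r.name for r in results})
    unsafe = tuple(sorted({r.name for r in results if r.exceeds_critical}))
    best = max(results, key=lambda r: r.stretch_ratio)
    counts = {"lengthening": set(), "shortening": set(), "isometric": set()}
    for r in results:
        counts[r.classification].add((r.name, r.oa_deg))
    return SafetySummary(
        n_segments=len(names),
        n_lengthening=len({n for n, _ in counts["lengthening"]}),
        n_shortening=len({n for n, _ in counts["shortening"]}),
        n_isometric=len({n for n, _ in counts["isometric"]}),
        unsafe_segments=unsafe,
        max_stretch_ratio=best.stretch_ratio,
        max_stretch_segment=best.name,
        max_stretch_oa_deg=best.oa_deg,
    )


def muscle_results_table(results: Sequence[MuscleResult]) -> pd.DataFrame:
    """Results as a DataFrame with the package's fixed muscle-CSV columns."""
    return pd.DataFrame(
        [
            {
                "segment": r.name,
                "oa_deg": r.oa_deg,
                "length_mm": r.length_mm,
                "stretch_ratio": r.stretch_ratio,
                "classification": r.classification,
                "exceeds_critical": r.exceeds_critical,
            }
            for r in results
        ],
        columns=["segment", "oa_deg", "length_mm", "stretch_ratio",
                 "classification", "exceeds_critical"],
    )
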