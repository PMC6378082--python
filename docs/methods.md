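# Methods

## Model

The osteotomy is modelled in the sagittal plane (x anterior-positive,
y cranial-positive, millimetres).  Bilateral anterior opening wedges from the
anterior inferior iliac spine to the sciatic notch hinge at the posterior
sciatic-notch cortex; creating an anterior wedge of opening angle OA rotates
everything cranial to the cut — upper pelvis, sacrum, and the spine assumed
rigid on top of it — counterclockwise (posteriorly) about that fulcrum, while
the femoral heads and lower pelvis stay fixed.  Six landmarks carry the whole
state: femoral head centre, fulcrum, the two S1-endplate corners, and the T1
and C7 centroids.  The rigid-spine assumption restricts validity to fused,
ankylosed or otherwise stiff deformities; lumbar lordosis is carried as a
constant so only PI − LL changes, via PI.

### Measurement conventions

- **PT**: signed angle from vertical of the femoral-head → S1-midpoint line,
  positive with the midpoint posterior (retroversion).
- **SS**: signed endplate inclination from horizontal, positive when the
  plate slopes downward anteriorly — the normal standing configuration.
  (The opposite sign choice is sometimes seen; it breaks both PI = PT + SS
  and the degree-for-degree SS drop below, so it is not used here.)
- **PI**: angle at the S1 midpoint between the endplate perpendicular and
  the line to the femoral head, evaluated as the signed angle from the
  caudal normal so that PI = PT + SS is an identity (it coincides with the
  unsigned textbook definition for any plausible anatomy).
- **SVA**: horizontal offset of the cranial plumb landmark from the
  posterosuperior S1 corner.  The C7 centroid is the default plumbline
  (standard SVA); T1 is available as a config switch since both centroids
  are carried.
- **TPA**: angle at the femoral head between the rays to T1 and to the S1
  midpoint.  **T1SPi**: signed vertical inclination of the T1 → femoral-head
  line, positive with T1 anterior.

Angles are degrees at every interface and radians internally.  Degenerate
landmark sets (coincident points, endplate reversed) are rejected at
construction.

### Exact consequences of the rigid rotation

With the cranial fragment rotating as one body: SS(OA) = SS(0) − OA exactly;
hence PT(OA) − PI(OA) = OA − SS(0), so the fitted PT and PI slopes differ by
exactly 1 °/°.  PI falls (the fulcrum lies between femoral head and sacrum),
PT rises but by less than a degree per degree, and SVA and TPA fall — the
signature sign pattern asserted on every synthetic patient.  Whole-image
rotation about the femoral head (PT decompensation) changes PT at will but
leaves PI untouched, because PI is internal to the pelvis.

### Closed form

All quantities are law-of-sines decompositions over two triangles with a
common vertex at the fulcrum O: (O, femoral head F, S1 midpoint M) with
sides a = |OF|, b = |OM| and included angle α₂ + OA, and (O, F, T1) with
sides a, L = |OT1| and included angle α₆ + OA.  The angle opposite a "far"
side is written as asin(sin γ/√(1 + r² − 2r cos γ)) with the side ratio
r ∈ {k, k′, k″}; the implementation evaluates the equivalent two-argument
arctangent atan2(near·sin γ, far − near·cos γ), which equals the arcsine on
its acute branch (asserted in tests) and remains exact when the triangle
angle turns obtuse or γ passes 180°.  The baseline constants α₁…α₆ are fixed
from the landmark rays at OA = 0 (their reconstruction is round-tripped in
the tests); rigid invariance then makes every relation exact at all OA, and
the suite verifies closed form ≡ oracle to ~1e−14 (criterion: 1e−6 ° /
1e−3 mm) over 20 seeded patients × 0–40°.

One subtlety: two distinct trunk inclinations appear.  The *reported* T1
spinopelvic inclination is referenced at the femoral head (angle-at-F term
plus α₅ − π/2).  The inclination inside the SVA expression must instead be
referenced at the fulcrum (ψ = ψ₀ − OA, falling exactly 1 °/°, lever arm
L_p = |O → plumb landmark|, consistent with k″ = a/L); substituting the
femoral-head inclination there is not exact, because |F → T1| is not
invariant under rotation about O.  Both readings are implemented where each
is exact, and the geometric oracle remains normative throughout (the planner
defaults to it).

### Linear approximations and planning

Over the practical 0–40° range the trigonometric curves are almost perfectly
linear (r² > 0.99 on every generated patient); `fit_linear` produces the
clinically quotable mm/° and °/° rates.  A transcribed example-patient model
set (SVA = −8.3·OA + 223.8, PI = −0.7·OA + 54.4, PT = 0.3·OA + 10.4,
TPA = −0.6·OA + 27.0) is packaged for worked examples and tests; its PT/PI
slopes differ by the forced 1.0.

The planner treats each goal as a closed inequality (the strict/closed
distinction is below solver tolerance).  Falling parameters (SVA, TPA,
PI − LL) contribute minimum angles; PT and the SVA floor contribute maximum
angles.  Monotonicity is verified on a 0.5° grid and each crossing is found
by bisection to 1e−6°, the same solver path for oracle, closed-form and
linear engines; the returned interval is re-verified on a 0.1° grid.  An
empty intersection is reported as an infeasible result with the most
restrictive constraint pair, not as an error.  Published per-patient
thresholds (e.g. a 26–30° window for one example radiograph) are
patient-specific: whether a given criteria set is reachable inside the OA
cap depends entirely on the individual geometry, as the planner makes
explicit.  Note also that threshold sets can be internally tight — a PI − LL
goal of < 9° may bind later than the SVA and TPA goals and thus dictate the
lower end of the interval.

## Muscle stretch model

Muscle segments crossing the osteotomy are one-dimensional straight lines
from a cranial (iliac) to a caudal (femoral) attachment.  The cranial point
rotates in-plane with the fragment, so the in-plane chord follows the law of
cosines in β + OA, where β is the *signed* counterclockwise angle at the
fulcrum from the caudal to the cranial ray, and the mediolateral offset Δz
adds in quadrature.  The signed β (the printed form of the law of cosines is
sign-agnostic) is what makes anterior segments (sin β > 0) lengthen and
posterior segments shorten under one common +OA — matching the observed
mixed pattern.  Broad muscles (gluteus medius and maximus) are split into
anterior/middle/posterior segments.  Shortening segments are safe by
assumption (no stress when slack); lengthening segments are flagged against
a critical stretch ratio, default 0.254 (a commonly quoted 0.25 is one
config value away).  |λ − 1| ≤ 1e−6 classifies as isometric.

The packaged 8-segment attachment fixture is **synthetic**: real
musculoskeletal-model attachment coordinates for this construct are not
publicly tabulated, so `scripts/build_muscle_fixture.py` chooses plausible
lever arms (l₁ 55–90 mm, l₂ 80–120 mm, Δz 15–35 mm) and solves each β so
that the stretch ratio at a 20° opening equals the intended pattern
(anterior GMed +8 %, TFL +4 %, posterior GMed −6 %, GMax −5/−6/−8 %,
piriformis −5 %, middle GMed isometric — β = −10° gives λ(20°) = 1 by chord
symmetry).  Consequently the fixture's percentages at 20° are reproduced by
construction, not independently derived; the model equations themselves are
validated against a brute-force 3-D rotate-and-measure oracle (1000 seeded
random segments, agreement ≲1e−13 mm, criterion 1e−9).

## Synthetic patients

`make_patient` inverts the measurement: femoral head at the origin, S1
midpoint at distance 115 mm (default) along the prescribed PT direction,
endplate of width 35 mm tilted to SS = PI − PT, C7 placed so SVA comes out
exactly, fulcrum 55 mm from the femoral head at 35° posterior-cranial, T1 on
a lordosis-scaled arc between S1 and C7 (cosmetic — the rigid model uses
only endpoints).  Round-trip recovery of (PI, PT, SVA) is exact to ~1e−13
(criterion 1e−9) on 200 seeded random specs.  Specs are validated
(PI ∈ [20°, 100°], PT ∈ [−10°, 50°], |SVA| ≤ 400 mm, SS constructible);
violations name the offending bound.  Cohorts sample uniformly from
deformity-like ranges (PI 45–85°, PT 15–35°, SVA 80–250 mm, LL 10–40°) —
coverage of the plausible space, not an epidemiological model.

## What the synthetic tests do and do not show

All quantitative guarantees (oracle equivalence, identities, sign patterns,
round-trips) are statements about the rigid-rotation geometry and hold for
any landmark set in the plausible domain.  What synthetic data cannot show:
landmark-digitisation error, true patient trunk proportions (the SVA lever
arm — hence the mm/° rate — depends on them), spinal flexibility, hip-driven
PT compensation after surgery, and real muscle paths with wrapping.  The
default cohort's SVA slopes (≈ −5 to −7 mm/°) are gentler than the steepest
published example patient (−8.3 mm/°), which is consistent with that
patient's longer trunk lever arm.

## Problem sizes and numerical choices

The suite and the acceptance script use 10–20-patient cohorts on a 41-point
OA grid, 200-spec round-trips and 1000-segment muscle oracles — ample for
machine-precision identities, and everything runs in seconds.  Bisection
tolerance 1e−6°, planner verification slack 1e−3 in each threshold's unit,
isometric tie-break 1e−6, opening-angle hard cap 60° (planning default 40°).
CSV output is fixed at six significant digits for diff-stability.
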