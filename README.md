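# bpoplan

Geometric planning of **bilateral opening-wedge pelvic osteotomy (BPO)** for
rigid sagittal spinal deformity.

Instead of a three-column spinal osteotomy, sagittal malalignment can in
principle be corrected more caudally: bilateral anterior opening-wedge cuts
from the anterior inferior iliac spine to the sciatic notch hinge the cranial
pelvis (and the rigid spine riding on it) backwards about a fulcrum at the
posterior sciatic-notch cortex.  Because the fulcrum sits low, a small
opening angle (OA) produces a large change in the sagittal vertical axis.
Uniquely, this osteotomy corrects *pelvic incidence* rather than lumbar
lordosis, so PI–LL matching is achieved by lowering PI.

`bpoplan` is for spine/pelvis surgeons and biomechanics researchers who want
to explore this correction strategy quantitatively.  It provides:

- **measurement** of the standard sagittal parameters (PI, PT, SS, SVA, TPA,
  T1SPi) from six landmark coordinates (femoral head centre, osteotomy
  fulcrum, S1 endplate corners, T1 and C7 centroids);
- a **geometric oracle** that simulates the osteotomy as a rigid 2-D rotation
  of the cranial fragment and re-measures;
- exact **closed-form predictive equations** — each parameter as a
  trigonometric function of OA and patient-specific constants
  (a, b, L, L′, k = b/a, k′ = a/b, k″ = a/L, α₁…α₆), e.g.

  ```
  PI(OA) = asin[ sin(α₂+OA) / √(1 + k² − 2k·cos(α₂+OA)) ] + α₁
  PT(OA) = PI(OA) + π/2 − α₁ − α₃ + OA
  SVA(OA) = L_p·sin(ψ₀ − OA) + L′·cos(α₄ − OA)
  ```

  plus least-squares **linear approximations** (the curves are almost
  perfectly linear over the practical range, r² > 0.99);
- a **planner** that intersects the correction goals
  (−50 mm < SVA < 50 mm, TPA < 14°, PT < 20°, PI − LL < 9°) into a feasible
  OA interval with named binding constraints;
- a **muscle stretch model** for the segments crossing the osteotomy
  (gluteus medius/maximus ×3 sections each, TFL, piriformis):
  d(OA) = √(l₁² + l₂² − 2l₁l₂cos(β+OA) + Δz²), stretch ratio λ = d/L₀,
  checked against a critical stretch of 25.4 %;
- a **synthetic patient generator** that inverts the measurements, so any
  prescribed baseline (PI, PT, SVA) becomes a testable landmark set;
- **PT decompensation**: whole-image anterior rotation about the femoral head
  that removes compensatory pelvic retroversion before planning (PI is
  invariant under it).

The spine is treated as rigid throughout — the intended use case is prior
multilevel fusion, ankylosis, or iatrogenic flatback.

## Worked example

Generate a synthetic patient with a severe rigid deformity (PI 60°, PT 15°,
SVA 180 mm, LL 25°), predict the parameters over 0–40° of opening, and plan:

```sh
bpoplan synth --out patient.json --pi 60 --pt 15 --sva 180 --ll 25
bpoplan predict --landmarks patient.json --ll 25 --out pred.csv --oa-max 40 --step 10
```

`pred.csv`:

```
oa_deg,pi_deg,pt_deg,ss_deg,sva_mm,tpa_deg,t1spi_deg,pi_minus_ll_deg
0,60,15,45,180,32.2009,17.2009,35
10,55.493,20.493,35,121.43,28.5334,8.04039,30.493
20,50.9662,25.9662,25,59.1701,24.9668,-0.999421,25.9662
30,46.4276,31.4276,15,-4.88751,21.4835,-9.94418,21.4276
40,41.8845,36.8845,5,-68.7966,18.0654,-18.8191,16.8845
```

SVA, PI and TPA fall with the opening angle and PT rises; the sacral slope
falls exactly 1° per degree because the endplate rotates with the fragment.
Planning against thresholds this geometry can reach
(`tpa_max_deg: 25`, `pt_max_deg: 30`, `pi_minus_ll_max_deg: 25`):

```
$ bpoplan plan --landmarks patient.json --ll 25 --criteria crit.yaml
...
Constraint crossings (deg):
  pi_minus_ll_max         22.1305
  pt_max                  27.3846
  sva_max                 21.4418
  sva_min                 37.0383
  tpa_max                 19.9057
Feasible opening angle: 22.1305 deg (pi_minus_ll_max) to 27.3846 deg (pt_max)
```

PI − LL is the last parameter to reach its goal (22.1°) and the rising PT
caps the correction at 27.4°.  The muscle model on the packaged attachment
fixture:

```
$ bpoplan muscles --out sr.csv
8 segments; max stretch ratio 1.1303 (GMed_middle at 40 deg); 0 exceed critical
```

At a 20° opening, TFL (+4 %) and anterior gluteus medius (+8 %) lengthen,
the middle gluteus medius is isometric, and the five posterior segments
shorten — anterior muscles stretch, posterior ones slacken — with every
stretch ratio well below the 25.4 % critical value.

Library use mirrors the CLI: `make_patient`, `measure_parameters`,
`apply_osteotomy`, `oracle_predict`, `derive_geometry`,
`closed_form_predict`, `fit_linear`, `feasible_oa_range`,
`stretch_ratio_curve`.

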