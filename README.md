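# isopoint

Motion-informed, patient-specific femoral attachment localization for
medial patellofemoral ligament (MPFL) reconstruction.

## What it does

The femoral tunnel position in MPFL reconstruction largely determines
how the graft's length changes as the knee flexes; the standard
radiographic landmark (the Schöttle point, *S-point*) is static and
ignores subject-specific patellar tracking. Given a dynamic-imaging
sequence of per-frame femoral and patellar geometry, `isopoint` finds
the *individualized* femoral point (*I-point*): the point on the femoral
surface, within a 5–15 mm annulus of the S-point, that minimizes the
variability of the modeled ligament length across flexion.

With `C_i` the patellar articular-surface centroid in frame *i* and *N*
frames, the objective is the variance of the frame-wise lengths

```
f(P) = (1/N) Σᵢ ( ‖P − Cᵢ‖ − L̄(P) )²,    L̄(P) = (1/N) Σᵢ ‖P − Cᵢ‖
```

minimized subject to `r_min ≤ ‖P − S‖ ≤ r_max` and a femoral-surface
constraint, by sequential quadratic programming (damped-BFGS curvature,
ℓ1-merit line search, exact active-set QP subproblems) with multi-start
seeding from the best annulus vertices and an exhaustive vertex search
as an independent oracle. The package also provides:

* anatomical coordinate frames from condylar landmarks (origin at the
  MFC/LFC midpoint; X medial–lateral, Y anterior–posterior, Z
  proximal–distal; left knees mirrored into the right-knee convention),
* alpha-complex surface reconstruction from point clouds and fast exact
  closest-point queries,
* patellar trajectory fitting over flexion and MPFL% length-change
  profiles per 10° bin,
* cohort statistics: two-group PERMANOVA with Monte-Carlo permutations,
  per-axis variance partitioning, exact paired Wilcoxon signed-rank,
  classical MDS and KDEs,
* a synthetic-data module that generates condyle-like femurs with
  analytic landmarks and flexion sequences with a planted best-isometry
  point, so the whole pipeline is testable against known truth.

See `docs/methods.md` for the model, conventions and limitations.

## Worked example

Simulate a knee (25 frames, 0–90° flexion, 0.3 mm radial noise on the
planted isometric point) and run the full pipeline:

```sh
isopoint run-all --simulate default --seed 3 --noise 0.3 --out demo/
```

prints

```
I-point length SD 0.3201 mm vs S-point 4.0702 mm
```

and writes `demo/result.json` containing, among other fields,

```json
"i_point": [36.086, -12.365, 5.003],
"length_sd_mm": 0.3201,
"mean_length_mm": 55.123,
"converged": true
```

Read: at the conventional landmark the modeled ligament length varies by
4.07 mm (SD) over the motion; at the optimized attachment it varies by
0.32 mm — matching the 0.3 mm noise floor planted by the simulation, so
the optimizer recovered essentially all recoverable isometry. The
I-point coordinates are millimetres in the anatomical frame (X medial,
Y anterior, Z proximal).

The same stages are available piecewise (`isopoint simulate / frame /
optimize / profile / stats`) and as library calls (`isopoint.make_knee`,
`isopoint.build_problem`, `isopoint.optimize_ipoint`,
`isopoint.cohort_summary`, …).

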