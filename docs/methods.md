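# Methods

## Problem and model

In medial patellofemoral ligament reconstruction (MPFLR) the femoral
tunnel position largely determines how the graft's length changes as the
knee flexes. The conventional femoral landmark (the Schöttle point,
S-point) is defined on static radiographs and ignores subject-specific
patellar tracking. `isopoint` implements a motion-informed alternative:
given a sequence of per-frame femoral and patellar surfaces from dynamic
imaging, it searches the femoral surface near the S-point for the point
whose straight-line distance to the patellar reference varies least over
the motion.

The modeled ligament is the segment from a femoral attachment candidate
`P` to the patellar reference `C_i` (the geometric centroid of the
patellar cloud in frame `i`). The objective is the population variance of
the frame-wise lengths,

    f(P) = (1/N) Σ_i ( ‖P − C_i‖ − L̄(P) )²,   L̄(P) = (1/N) Σ_i ‖P − C_i‖,

in mm²; its square root is the length SD reported alongside. The search
is constrained to

* the annulus  r_min ≤ ‖P − S‖ ≤ r_max  around the S-point
  (defaults 5 and 15 mm — the clinically interpretable neighborhood), and
* the femoral surface, relaxed to an inequality
  dist(P, surface) ≤ ε_surf  with ε_surf = 0.1 mm, followed by an exact
  projection of the final iterate onto the surface. The relaxation keeps
  the constraint differentiable almost everywhere while the projection
  restores the literal "on the surface" requirement.

The straight-line model deliberately ignores graft wrapping, soft-tissue
contact, and load; its output is a geometric isometry surrogate, not a
biomechanical prediction.

## Anatomical frame

The local frame has its origin at the midpoint of the medial and lateral
femoral condyle landmarks (MFC, LFC). X runs from LFC to MFC (flipped for
left knees so +X is always medial and cohorts pool both sides), Z is the
component of the shaft-axis point (RA) offset orthogonal to X (proximal),
and Y = Z × X completes a right-handed triad. The plane containing MFC,
LFC and RA is therefore the XZ plane; this keeps Z proximal–distal, which
is the axis convention all coordinate statistics use. RA is accepted as a
point; only its offset from the origin matters.

## Surface reconstruction

Point clouds are triangulated through the 3-D Delaunay tetrahedralization
filtered into an alpha complex: tetrahedra with circumradius ≤ α are
kept, and the surface consists of the boundary faces of that complex plus
faces outside it that are Gabriel (their diametral ball contains no other
point) with triangle circumradius ≤ α. The Gabriel completion is what
makes thin-shell clouds (points sampled on a surface rather than
throughout a solid) reconstruct correctly — for such clouds every
tetrahedron has a circumradius on the order of the local feature size and
is discarded, so the tetrahedron-only rule would return nothing, while
unrestricted small faces would add spurious chords through the interior.
On a 500-point sphere sample the result is the exact 2V−4 closed
triangulation with area within ~1% of the analytic value.

Defaults: α = 2× the median nearest-neighbour spacing (scale-free);
triangles with area < 1e−6 mm² are dropped and unreferenced vertices
pruned. Triangle meshes supplied directly bypass reconstruction and only
get the degeneracy cleanup.

Closest-point queries prune candidate triangles with a KD-tree on
triangle centroids (the distance to the nearest vertex is an upper bound)
and evaluate the exact region-based point–triangle projection on the
survivors; tests verify equality with an exhaustive per-triangle scan.

## Trajectory fitting and flexion angles

Per-frame centroids are fitted with an independent least-squares
polynomial per local coordinate (degree 3 by default — smooth monotone
patellar paths over 0–90° with 20–30 frames, without oscillation),
parameterized by the measured flexion angle when each frame carries one
and by normalized frame index otherwise. The fit is computed in a
parameter scaled to [−1, 1] for conditioning. The raw centroids, not the
fitted curve, are the optimizer targets; the curve serves angle-grid
evaluation and the filling of empty bins.

When flexion angles are absent, frames are assigned angles by normalized
arc length along the fitted path scaled onto 0–90°. This is a convention
of this package (dynamic-imaging protocols rarely export per-frame
angles), and is flagged as such in outputs.

## SQP solver

The constrained program is solved by sequential quadratic programming in
the three spatial coordinates:

* each iteration solves the QP  min ½ΔᵀHΔ + ∇fᵀΔ  subject to the
  linearized constraints ∇g_iᵀΔ + g_i ≤ 0. With at most three
  constraints the QP is solved exactly by enumerating the 2³ active sets
  and checking multiplier signs and feasibility;
* steps are accepted through an ℓ1-merit backtracking (Armijo) line
  search with penalty weight kept above twice the largest multiplier;
* H is a damped (Powell) BFGS approximation started from the identity,
  keeping it positive definite;
* the gradient of the surface distance is (P − closest)/dist away from
  the surface and a central finite difference (h = 1e−5 mm) within 1e−8 mm
  of it, where the unsigned distance is non-smooth;
* convergence requires the KKT residual below 1e−6 and the objective
  change below 1e−10 mm², with a 200-iteration cap; if the linearization
  becomes infeasible the iterate is restored by alternating surface
  projection and radial clamping and the curvature model reset.

Because f is non-convex over the surface, the solver is multi-started
(default 10 starts) from the lowest-objective annulus vertices plus the
surface projection of the S-point when feasible; the best feasible point
seen anywhere is returned, so the result can never be worse than the
best seed. An exhaustive evaluation over all annulus vertices
(`brute_force_ipoint`) is kept as an independent oracle: on every tested
mesh the solver's objective is ≤ the vertex minimum. Ties are broken by
distance to the S-point, then lexicographically, for determinism.

## Length profiles

Per-frame lengths are normalized as MPFL% = 100·(L_i − L_ref)/L_ref. The
reference length L_ref defaults to the per-knee mean over frames (so
MPFL% averages to zero per knee); a length-at-angle reference is
available for sensitivity analyses. Profiles are summarized per 10° bin
centred on 0°,…,90° (half-open [θ−5°, θ+5°), end bins clamped), with
empty bins filled from the fitted trajectory. Positive MPFL% means
elongation.

## Cohort statistics

Coordinates are compared with a two-group PERMANOVA on raw Euclidean
distances in mm (no standardization — all axes share units). The
permutation p-value uses the bias-avoiding convention
p = (1 + #{F_perm ≥ F_obs})/(1 + n_perm) with 999 permutations by
default; an exhaustive enumeration mode exists for tiny inputs. The
per-axis share of the between-group separation is Δ_axis²/Σ Δ², with
Δ the difference of group means — for equal group sizes this equals each
axis's share of the between-group sum of squares.

Paired per-axis and per-angle-bin comparisons use a Wilcoxon signed-rank
test: zeros dropped, tied magnitudes mid-ranked, the exact null obtained
by rank-sum counting over all 2ⁿ sign assignments for n ≤ 25 (doubled
ranks keep mid-ranks integral) and a normal approximation with continuity
and tie corrections above. No multiple-testing correction is applied
across the ten angle bins by default (per-angle reporting); Holm
correction can be applied by the caller. Shapiro–Wilk (delegated to
scipy) gates whether parametric summaries are worth reporting; it never
alters the pipeline.

Visualization coordinates come from classical (Torgerson) MDS — exact for
Euclidean input at full dimension — and Gaussian KDEs with the Silverman
bandwidth rule.

## Synthetic data

The generator provides every fixture the tests need, with planted truth:

* **Femur** — two condylar spheres (radius 22 mm) whose extreme ±X points
  are the MFC/LFC landmarks, 81 mm apart (a typical adult intercondylar
  width), bridged by a 14 mm shaft cylinder with a hemispheric cap.
  Spheres are sampled on Fibonacci lattices and the shaft on a triangular
  lattice, allocated by component area so spacing is globally uniform
  (~1100 points by default, giving meshes comfortably under 2000
  vertices). The S-point and the planted optimum P* are inserted as exact
  surface samples on the medial condyle, a 10 mm chord apart (inside the
  5–15 mm annulus). A random rigid pose stands in for scanner
  coordinates.
* **Motion** — the patellar cloud is a rigid ±-paired ellipsoid point set
  (so its centroid is exact to rounding), swept along a flexion arc of
  0–90° in 25 frames; the centroid of frame i sits at distance
  L* + ε_i from P*, with L* = 55 mm (the scale of adult MPFL lengths) and
  ε_i ~ N(0, σ). At σ = 0 the planted point is exactly isometric, which
  is what makes recovery testable; σ > 0 plants a known length SD.
* **Cohort** — paired S/I coordinate tables: S per subject from a
  diagonal Gaussian around (39.15, −1.29, 9.32) mm with SDs (3.1, 2.1,
  2.2) mm (spreads consistent with published cohort confidence
  intervals), I = S + δ + noise with δ = (−0.38, −0.19, 1.88) mm by
  default — a ~1.9 mm proximal shift. Because a group-exchange
  permutation test assumes exchangeable independent rows, its type-I
  calibration uses `paired=False`, which draws I independently with the
  same marginal; the paired default feeds the paired statistics.

What the generator does **not** emulate: real trochlear morphology,
cartilage, segmentation noise, articular-surface delineation of the
patella, or frame-to-frame registration error. Passing tests demonstrate
the correctness of the geometry, optimization and statistics machinery
under known truth — not the clinical validity of the attachment point on
real anatomy.

## Problem sizes and determinism

Default test/validation sizes: ~1100-point femurs (≈1000 vertices after
reconstruction), 25 frames, 50-geometry recovery and dominance batches,
100-knee isometry-ordering batches at σ = 0.3 mm with 800-point femurs,
500-simulation permutation calibration at n = 20/20 with 999
permutations. All randomness flows from explicit seeds through
`numpy.random.default_rng`; identical seeds reproduce identical datasets
bit for bit, and iterative solver outputs are deterministic given the
seed and configuration.

## Known limitations

* The unsigned surface distance is non-smooth exactly on the surface;
  the finite-difference subgradient used there is adequate because the
  constraint is inactive inside the ε_surf band, but a signed distance
  would be cleaner for closed meshes.
* Alpha-complex reconstruction can leave small non-manifold patches near
  component junctions; distance queries are unaffected, but area
  estimates on such regions carry a few percent of bias at coarse
  sampling.
* Flexion-angle assignment without measured angles is a stated
  convention (arc length), not a measurement.
* The reference length choice (mean vs length-at-angle) shifts MPFL%
  curves vertically; both are exposed, the mean is the default.
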