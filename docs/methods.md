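# Methods

This note documents the mechanical model, the numerical choices behind it,
and what the synthetic-data studies do and do not demonstrate.

## Face model: single-layer flat-shell FE

The face surface is treated as a thin linear-elastic shell of uniform
thickness rather than a layered solid (skin/fat/muscle/bone). This is the
decisive simplification for design-loop use: the FE model follows directly
from a surface mesh, with no volumetric meshing or per-layer property
assignment. Material constants default to soft-tissue values commonly used
for skin-scale indentation: elastic modulus E = 0.03 MPa, Poisson ratio
ν = 0.49 (nearly incompressible), thickness h = 2 mm. All six DOFs of
every vertex on the mesh's open boundary edge are clamped — the scan
boundary is where the face "attaches" to the rest of the head, which is
taken as rigid.

Each triangle is a flat facet element assembled from independent local
blocks:

- **Membrane**: constant-strain triangle (CST), stiffness
  h·A·BᵀD_pB with D_p = E/(1−ν²)·[[1,ν,0],[ν,1,0],[0,0,(1−ν)/2]].
- **Bending**: discrete-Kirchhoff triangle (DKT) with
  D_b = Eh³/12(1−ν²) times the same pattern. We initially implemented the
  simplest Mindlin/Reissner triangle (linear w and rotations, reduced or
  relaxed shear integration, D_s = κGh with κ = 5/6,
  G = E/2(1+ν)); it locks severely at the thinness ratios of interest
  (h/L < 1 on the benchmark below, 34% error at a 32×32 mesh) and was
  replaced by DKT, the standard CST companion for facet shells. DKT
  enforces zero transverse shear along element edges, so the shear block
  is absorbed into the bending formulation; the Mindlin path is retained
  behind `element_stiffness(..., formulation="mindlin")` for comparison.
- **Drilling stabilization**: the rotation about the shell normal has no
  physical stiffness in a 5-DOF/node formulation. We carry 6 DOFs/node
  globally and add an artificial zero-row-sum drilling block scaled to
  `drilling_factor` (default 1e-6) times the largest plate-block diagonal,
  making the assembled stiffness positive definite on near-coplanar
  patches without measurably polluting the response.

The local frame is e₁ along the first edge, e₃ the unit normal,
e₂ = e₃×e₁ — deterministic and orientation-stable.

Verification: the element reproduces constant-curvature and twist patch
states exactly, has exact zero energy for all six rigid-body modes, its
membrane block matches an independently integrated CST oracle to 1e-10,
and the clamped-square-plate benchmark (side 100 mm, ν = 0.3, central
point load) converges monotonically to the series solution
w_c = 0.00560·P·a²/D with 0.45% error at a 32×32 grid.

## Parametric mask: periodic cubic spline reference line

A mask design is an ordered closed loop of n ≥ 4 reference points. Each
coordinate axis is interpolated by a periodic cubic spline in the
cumulative-chord-length parameter (chord length is the standard
shape-preserving choice when the parameterization is free). The knot
second derivatives solve the cyclic tridiagonal continuity system

    l₍ₖ₋₁₎g″₍ₖ₋₁₎ + 2(l₍ₖ₋₁₎+l₍ₖ₎)g″₍ₖ₎ + l₍ₖ₎g″₍ₖ₊₁₎ =
        6[(g₍ₖ₊₁₎−g₍ₖ₎)/l₍ₖ₎ − (g₍ₖ₎−g₍ₖ₋₁₎)/l₍ₖ₋₁₎]

with periodic closure of value, slope and curvature at the seam. The
corner entries are handled by a Sherman–Morrison update around two banded
tridiagonal solves; tests check the solution against a dense solve of the
full cyclic matrix (1e-10) and against an independent library
implementation of periodic cubic splines.

Contact nodes are sampled at equal arc-length intervals (default spacing
1.0 mm, section count = round(L/spacing), minimum 8). Arc length uses
adaptive quadrature per spline piece (rel. err < 1e-8); the inverse
mapping target-arc-length → parameter uses a 32-point per-piece trapezoid
grid anchored to the quadrature piece lengths — parameter error is far
below the millimetre node spacing. The cross-section profile placed in
the plane normal to the curve is configurable (default: a single node on
the reference line, i.e. line contact; optionally a flat strip). Profile
frames use the double-reflection rotation-minimizing frame, which is
defined at inflections where the Frenet frame is not.

## Static condensation

Master nodes are the face vertices that can touch the mask under *any*
design variant of a study: for every mask node of every variant, the
nearest face triangle (exact point-to-triangle distance, KD-tree
prefiltered) contributes its three vertices; clamped boundary vertices
are excluded. All 6 DOFs of each master node are retained, leaving the
contact direction choice to the solver.

The reduced stiffness is the Schur complement
K_r = K_m − K_cᵀK_slave⁻¹K_c, computed with one sparse LU factorization
of the slave block and multi-RHS solves (K_slave⁻¹ is never formed); K_r
is stored dense (its dimension is a few hundred to a few thousand). The
factorization is kept so the slave field u_s = −K_slave⁻¹K_c u_m can be
recovered, which reproduces the unreduced solution *exactly* (to solver
precision) whenever slave loads vanish — the property the tests verify at
1e-8 relative against full sparse solves on faces of 200–2000 nodes.

## Contact model

Assumptions: two-body, static, frictionless, no detachment during a
solve; the mask is rigid; contact acts along a single push direction
(default −Z for a face looking along +Z). Pairing is node-to-node:
each mask node takes its nearest master vertex (constraints attach to
DOFs, so nearest-vertex, not nearest-point-on-triangle); when several
mask nodes claim one vertex the closest wins.

With push depth δ and clearance c (signed distance from face vertex to
mask node along the push direction), the prescribed penetration is
d_f = δ − c. Pairs with d_f ≤ 0 never touch and are dropped — these
produce the zero-pressure regions reported by the pressure summary. The
remaining constraints Cᵀu = d_f enter a saddle-point system

    [K_r  C] [u]   [f_r]        (sign convention chosen so contact
    [Cᵀ   0] [Λ] = [d_f]         forces on the face are Λ ≥ 0)

solved by block elimination: Cholesky of K_r, Schur complement
S = CᵀK_r⁻¹C on the multipliers. An active-set loop removes tensile
pairs (λ < 0) and re-solves until all retained multipliers are
compressive; complementarity is spot-checked in tests by re-adding a
released pair and observing a negative multiplier. The external load f_r
defaults to zero — the only loading is the prescribed mask displacement
entering through d_f. A diagnostic reaction −ΣΛ is available as the force
transmitted to the rigid mask; no mask stiffness matrix is built.

Verified invariants: constraint residual < 1e-8 mm; monotone total force
in push depth; total contact force balances the clamped-boundary reaction
to 1e-6 relative; the reduced solve equals the full unreduced augmented
solve (same active set, displacements and multipliers to 1e-8 relative).

## Nodal pressures

Pressure at a contact vertex is λ/A with A one third of the summed areas
of its incident triangles; tributary areas tile the surface exactly
(Σ_j A_j = total mesh area), so Σ pressure·area recovers the total
contact force identically. Summary statistics (mean, max, SD with the
population divisor N) are taken over *all* paired vertices including
zero-pressure ones, because uncontacted area is part of fit quality; an
excluding-zeros variant is exported alongside for sensitivity.

## Design sweep and ranking

Candidates form the full Cartesian grid of per-point offsets
{−k·m, …, 0, …, +k·m} (defaults: five steps of 3 mm along X, matching the
cheek-point adjustment study; 4 points × 5 steps = 625 candidates). The
sweep solves every candidate against one shared condensed model (the
master set must cover all candidates — violations raise a coverage
error naming the candidate) and equals per-candidate no-reuse pipelines
to 1e-8 on every statistic. Ranking scalarizes the stated criterion
"lower mean and lower SD" as z(mean) + z(SD) with population z-scores
across candidates — symmetric, scale-free (invariant under affine
pressure rescaling); ties break by lower mean, then enumeration
(lexicographic-offset) order.

## Synthetic face generator

The generator emulates a template-registered face scan: a structured
polar UV grid (centre vertex + rings) mapped to an ellipse, height field
= flattened half-ellipsoid dome + Gaussian nose ridge (σₓ tied to nose
width, ridge centred slightly above mid-face) + Gaussian chin bump, with
a small seeded uniform in-plane jitter (25% of the local cell size, so
triangles cannot invert) emulating scan irregularity. Landmarks
(sellion, pronasale, promentale, cheeks) are the vertices nearest the
mid-line extrema of the generating height field. Generation is
bit-identical per (spec, seed); vertex count lands within ±2% of the
target (the default target is 5,303 nodes, i.e. 31,818 DOFs at 6
DOFs/node).

The default study loop (`reference_loop_on_face`) places 8 reference
points on an ellipse crossing the nose ridge and chin at phase 0 — like a
medical mask resting on the nose bridge — at the local surface height
plus 0.5 mm clearance. Between the widely spaced points the spline cuts
corners across the steep nose flanks, losing contact at the sides of the
nasal root and lip; the 12-point variant adds reference points there
(loop angles 72°/108°/252°/288°), which consistently reduces the
zero-pressure node count across generator seeds. Study resolution is
2,000 nodes: coarse enough to assemble in seconds, fine enough that
node-to-node pairing noise does not drown the loop-geometry signal (on
faces below ≈1,000 nodes it does).

What the synthetic studies do **not** show: absolute pressure magnitudes
for real faces. The synthetic dome is smoother and the line-contact mask
thinner than reality, so computed mean pressures (≈1e-4 MPa at 3 mm push)
sit below the 1e-2 MPa scale typical of instrumented mask measurements;
the pipeline's correctness claims are the exactness, conservation and
invariance properties above, which are resolution- and geometry-robust.

## Numerical choices and degenerate inputs

- Zero-area triangles (< 1e-9 mm²), repeated vertex indices, non-finite
  coordinates and out-of-range landmarks are rejected at mesh
  construction.
- STL input merges duplicate corner records by exact coordinate hashing
  after a 1e-6 mm snap (STL stores no shared topology).
- OBJ/ascii-PLY readers are strict: non-triangular faces raise a format
  error naming the offending face rather than silently triangulating.
- ν = 0.5 exactly is rejected (singular constitutive matrix); ν up to
  0.49 is routine.
- Meshes with no open boundary cannot be clamped; solves raise a rank
  error advising boundary conditions instead of returning garbage.
- The active-set loop is capped (default 50 iterations; typical runs use
  3–6) and raises if all pairs release.
- Contact Schur complements with duplicate constraints (two pairs on one
  DOF) raise a constraint-rank error listing the offending pairs.

## Known limitations

- Homogeneous material: one (E, ν, h) for the whole face; bone-dominant
  vs tissue-dominant regions are not distinguished.
- Linear statics: no large deformation, no friction/sliding/detachment,
  no strap-force load path; the mask is perfectly rigid.
- Contact constrains only the translation along the push direction;
  tangential compliance is ignored.
- Node-to-node pairing quantizes the contact footprint to the face mesh;
  pressure fields on coarse meshes are spiky, and zero-pressure counts
  carry discretization noise of a few nodes.
- The rigid-line mask has no width by default; a flat-strip profile is
  available but the default studies use line contact.
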