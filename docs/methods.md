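# Methods

## Model

The segmenting surface is a 2-simplex mesh: a closed 2-manifold mesh in
which every vertex has exactly three neighbors, the topological dual of a
triangulation. One simplex vertex corresponds to one (virtual) dual
triangle; one polygonal simplex face corresponds to one dual-triangulation
vertex, placed at the face's gravity center. Constant degree-3 connectivity
gives every vertex a well-defined neighbor plane, circumcircle, and simplex
angle, which is what makes the force model uniform across the surface.

The seed surface is the dual of an icosphere (20·4^level triangles; level 2,
i.e. 320 simplex vertices, by default), radially projected so all vertices
lie exactly on the seed sphere.

### Per-vertex geometry

For vertex `P` with neighbor triangle `(P1, P2, P3)`:

* `n`: unit normal of the neighbor triangle, from the cyclic cross-product
  sum `P1×P2 + P2×P3 + P3×P1` (translation invariant); neighbor triples are
  stored counterclockwise viewed from outside, so `n` points outward.
* `P*`: orthogonal projection of `P` onto the neighbor plane; barycentric
  weights `ω` of `P*` sum to one.
* `(C, r)`: circumcircle of the neighbor triangle; `d = |C − P*|`.
* `(O, R)`: circumsphere of the tetrahedron `(P, P1, P2, P3)`.
* simplex angle `θ ∈ [−π, π]`: `sin θ = (r/R)·s`, `cos θ = (|OC|/R)·σ·s`
  with `s = sign((P − P1)·n)` and `σ = sign((C − O)·n)`, recovered by
  two-argument arctangent. Referencing the cosine sign to the side of `P`
  (the extra factor `s`) is required: without it the angle is not odd under
  mirror reflection through the neighbor plane and contradicts the triangle
  identity `tan θ = 2 r L / ((r² − d²) − L²)`. The implementation
  cross-checks itself through the identity `sin²θ + cos²θ = 1`, which ties
  `r`, `R`, `O`, `C` together.
* elevation `L(r, d, θ)`: the height above the neighbor plane that realizes
  a prescribed simplex angle,
  `L = (r² − d²) tan θ / (ω √(r² + (r² − d²) tan²θ) + r)`,
  `ω = sign(π/2 − |θ|)`. For `|θ| > π/2` the algebraically equivalent
  conjugate form `−(r + √(r² + (r²−d²) tan²θ))/tan θ` avoids catastrophic
  cancellation; at `θ = ±π/2` the finite circular-arc limit `±√(r² − d²)`
  is used. Round trip (place at prescribed `θ`, re-measure) is exact to
  ~1e-14 over random configurations; this property arbitrates every sign
  and grouping choice above.

### Forces

Internal: `F_int = α_t (C − P*) + α_n ((P* + L(r,d,θ_ref)·n) − P)` with
`α_n = 1/(1 + g²)`, `g` the Gaussian-gradient magnitude of the smoothed
image at the vertex, `α_t = 1 − α_n`. The tangential term regularizes
vertex spacing; its pull is clamped to the local mean edge length because
the circumcenter diverges for near-collinear neighbor triples. The normal
term restores the elevation prescribed by a reference angle `θ_ref`
(default 0: a locally flattening prior; `theta_ref="keep"` instead tracks
the per-vertex time-averaged measured angle). In flat image regions
(`g ≈ 0`) curvature smoothing dominates; on strong edges it switches off so
image-driven curvature survives.

External: `F_ext = B(I) · (β_g F_gradient + β_e F_edge + q·n)`.

* `F_gradient = ((argmax − P)·n)·n`, the normal-projected displacement to
  the gradient-magnitude arg-max sampled along `P ± t·n` (trilinear, step
  0.5 voxel, extent `max(r, 2)` capped at `search_cap` voxels; ties break
  toward the smallest |t|, then toward +n).
* `F_edge = argmax − P` on the edge map
  `f = |∇(G_σ' * I_binary)|²` of the intensity-windowed binary image. The
  arg-max is taken on `f`, not on the binary plateau, so the boundary locus
  is unique.
* `β_g = 1 − exp(−f(P)/K)`, `β_e = exp(−f(P)/K)`: near the boundary the
  gradient term takes over, far away the edge term. `K` defaults to the
  median of the edge map over its significant voxels (above 1e-6 of the
  maximum — the Gaussian blur leaves sub-epsilon tails everywhere, so a
  strict positivity test would return the tail median instead of the ridge
  scale).
* `q·n`: balloon inflation (default q = 1.5 voxels/iteration), which drives
  the expansion from the small seed.
* `B(I)` gates on the smoothed intensity at the vertex: 1 iff
  `I_min ≤ I ≤ I_max` (inclusive), else 0.

Gate semantics: gate closure is implemented as a **full stop** — a vertex
whose local intensity has left the window holds its position entirely (no
internal force, no inertia) while it remains out-of-window. If only the
external force were zeroed, the settled surface would never become static:
tangential smoothing keeps kneading the frozen boundary, producing a slow
outward ratchet, and at larger balloon weights a bump → split → re-inflate
feedback that crumples the surface. With the full stop the converged state
is exactly static, which is also what makes runs bitwise reproducible in
their tails.

### Evolution and refinement

`P(t+1) = P(t) + (1−γ)(P(t) − P(t−1)) + α F_int + β F_ext`, displacement
clamped to `step_max` per iteration. Defaults: γ = 0.65, α = β = 0.4,
`step_max` = 1 voxel, 30 iterations, convergence when the mean displacement
drops below 0.01 voxel. Non-finite forces freeze the affected vertex for
the iteration with a logged warning.

After each iteration (full model), every dual triangle with area above
`area_threshold` is split 1→3 at its gravity center against the snapshot
taken at pass start, and the simplex mesh is rebuilt from the refined
triangulation. A split conserves the triangulation's surface exactly:
children each take one third of the parent's area, and new simplex vertices
inherit the parent vertex's offset from its dual triangle (placing them at
dual barycenters, which lie inside the surface, would dent the mesh inward
at every split and re-trigger inflation). The threshold default is
8 voxel² (~4-voxel facet edges): facets must stay at or below the scale of
the narrowest feature the model is meant to track (the reference narrow
lobe has tube radius 4 voxels); the earlier-considered 25 voxel² never
fires on such features. Degree-3 regularity, adjacency symmetry, and the
Euler characteristic (V − E + F = 2) are re-validated continuously in the
test suite; each split adds (+1 vertex, +3 edges, +2 faces) to the dual
triangulation.

Dual-triangulation winding is fixed combinatorially from the ordered
neighbor triples (the face between neighbors j1 and j2, then j2–j3, then
j3–j1), not by per-triangle geometric flips, so orientation stays globally
consistent on arbitrarily contorted meshes.

### Ablation variants

A: internal smoothing only (the bare simplex-mesh model). B: + gradient
force. C: + everything derived from the binarized image (edge force, β
weighting, `B(I)` gate). D: + balloon. E: + adaptive decomposition (the
full model). A `gate_enabled` switch additionally turns `B(I)` off inside
any gated variant for the leakage experiment, and `external_unweighted`
drops the β weights.

## Preprocessing

Perona–Malik anisotropic diffusion (conductance `exp(−(s/κ)²)`, explicit
6-neighbor scheme, reflective boundaries; defaults 10 iterations, κ = 30,
dt = 1/7, inside the 1/6 stability bound; flux antisymmetry conserves total
intensity), Gaussian-derivative gradient magnitude (σ = 1 voxel),
binarization between manually set window thresholds (defaults −250/500),
and the edge map at σ' = 1.5 voxels. The pooled intensity histogram is a
diagnostic only — thresholds are user parameters.

## Coordinates and spacing

All computation runs in continuous 0-based voxel-index coordinates, axes
ordered (x, y, z), voxel centers at integers; `world = origin + index ·
spacing`. Conversion to mm happens only at mesh export and in the metrics.
Forces are therefore computed in index space; with anisotropic spacing the
effective force weights differ per axis. This is a documented limitation:
the surface evaluation honors spacing, the dynamics do not.

## Metrics

VOE = 100(1 − |A∩B|/|A∪B|); RVD = 100(|A| − |B|)/|B| reported signed
(over-segmentation positive; the CLI also prints |RVD|). Surfaces are
border voxels (mask minus its 6-connected erosion); ASSD/RMSSSD/MSSD are
the mean/RMS/max of the pooled symmetric set of nearest-surface-voxel
distances (distance transforms with anisotropic sampling), verified against
a brute-force all-pairs oracle to 1e-9 on small grids. SADE is the mean
distance from mesh vertices to the nearest truth-surface voxel center
(trilinear lookup in the surface distance transform), tracked per
iteration. SADE is one-sided: it measures where the vertices are, not
whether the truth surface is covered — a mesh that never enters a narrow
protrusion is not penalized for it (see Limitations).

Note that border-voxel centers lie about half a voxel inside the analytic
surface, so e.g. a radius-10 mesh inside a radius-12 voxelized sphere
measures SADE ≈ 1.5 voxel-mm, not the naive 2.0.

## Voxelization

A mask voxel is 1 iff its center lies inside the dual-triangulation
surface, computed by axis-aligned ray parity per (y, z) column with a tiny
fixed ray offset against exact-hit degeneracies; a generalized
winding-number implementation provides an independent second route, and the
two agree voxel-for-voxel in the tests. Because dual vertices are face
barycenters (chords of the simplex surface), the dual surface of a
320-vertex sphere encloses ~8% less volume than the ideal sphere; the
voxelizer reproduces the dual surface's exact volume to under 1%.

## Phantoms

The generator emulates the imaging situation the model targets: a bright
body (100 HU, inside the [−250, 500] window) in dark background (−1000 HU),
boundary blurred with a 1-voxel Gaussian (partial-volume proxy), plus
additive Gaussian noise (σ = 10) seeded from a single integer. Shapes:
sphere (radius 20 in a 64³ grid), ellipsoid, and a lobed sphere (radius 18
with a cylinder-capped protrusion of radius 4 extending 14 voxels beyond
the surface; a 72³ grid so the lobe keeps a margin). The distractor variant
attaches an out-of-window structure (700 HU sphere, radius 10, one-voxel
overlap with the body; 80³ grid) that the intensity gate must exclude.
Ground truth is the exact analytic region, unaffected by blur or noise.

What the phantoms do not emulate: soft-tissue contrast as low as real
abdominal CT (liver vs. adjacent organs can differ by tens of HU, not
1100), anisotropic slice spacing, beam hardening, and anatomical shape
variability. Passing the phantom suite therefore demonstrates the mechanics
of the model — expansion, boundary locking, gating, refinement, evaluation —
not clinical-grade accuracy.

## Study conditions and problem sizes

The shipped experiments use: sphere recovery at 64³ (seeded noise, variant
E, defaults); the five-variant ablation on the 72³ lobed phantom at 30
iterations with the displacement-tolerance stop disabled so all variants
run the same horizon; the distractor experiment at 80³ with the gate on
and off. Each run takes seconds on one CPU; the solver contains no
randomness, so identical inputs give bitwise-identical traces, meshes, and
masks.

## Known limitations

* The balloon weight needed to push a front into a tube narrower than
  ~2× the facet scale against the flattening prior (roughly
  `q > (α/β)·α_n·tube radius`) also destabilizes the settled boundary
  (bump/split feedback), so the default configuration enters the reference
  narrow lobe only partially. Consequently the full model's one-sided SADE
  on the lobed phantom is not below the unrefined variant's: the unrefined
  mesh never attempts the lobe and keeps all vertices on the well-fit
  convex shell, while the refined mesh is charged for its in-transit front
  vertices. Volumetric overlap (VOE) does favor the refined model.
* A sparse mesh's vertices settle individually into the voxel-staircase
  dips of the truth-surface distance field, which flatters SADE for coarse
  meshes relative to dense, spacing-regularized ones.
* Self-intersection is not detected or repaired; topology changes other
  than the 1→3 split (holes, merges, coarsening) are out of scope.
* The settled surface sits at the intensity-window contour plus up to one
  discrete overshoot step, i.e. within about a voxel of the true boundary;
  sub-voxel boundary placement is limited by the 0.5-voxel line-search step
  and the trilinear interpolant.
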