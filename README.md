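# simplexseg

Deformable **2-simplex mesh** segmentation of 3-D volumes with balloon-driven
expansion, an intensity-window gate, and adaptive facet decomposition.

The package targets the classic interactive-segmentation workflow for
CT-like volumes: a user places a seed point with a small radius inside a
bright organ-like structure; a closed spherical mesh expands from the seed
under image-derived forces until it settles on the structure's boundary, and
the result is returned both as a surface mesh and as a binary mask, together
with the standard volumetric/surface evaluation criteria. Synthetic phantoms
with exact analytic ground truth make every stage testable without any
external data.

## The model

The surface is a **2-simplex mesh**: a closed mesh in which every vertex has
exactly three neighbors — the topological dual of a triangulation. Each
vertex `P_i` with neighbors `(P_i1, P_i2, P_i3)` carries a local frame: the
neighbor-plane projection `P*_i` with barycentric weights `ω`, the
circumcircle `(C_i, r_i)` of the neighbor triangle, the circumsphere of the
tetrahedron `(P_i, P_i1, P_i2, P_i3)`, and the **simplex angle**
`θ_i ∈ [−π, π]`, a scaled mean-curvature descriptor with

    P_i = ω_i1 P_i1 + ω_i2 P_i2 + ω_i3 P_i3 + L(r_i, d_i, θ_i) · n_i ,

where `L` is the elevation realizing a prescribed angle and `n_i` the
outward neighbor-plane normal.

Vertices move by damped Newtonian dynamics,

    P(t+1) = P(t) + (1−γ)(P(t) − P(t−1)) + α F_internal + β F_external ,

with

* `F_internal = α_tangent (C_i − P*_i) + α_normal (P*_i + L(r,d,θ_ref) n − P_i)`,
  where `α_normal = 1/(1 + |∇(G_σ * I)|²)` — curvature smoothing switches
  itself off on strong image edges;
* `F_external = B(I) · (β_grad F_gradient + β_edge F_edge + q·n)`, combining
  attraction to the gradient-magnitude arg-max along the vertex normal,
  attraction to the edge map `f = |∇(G_σ' * I_binary)|²` of the
  intensity-windowed binary image (`β_grad = 1 − e^{−f/K}`,
  `β_edge = e^{−f/K}`), and a balloon inflation term `q·n`;
* `B(I)`: a Boolean gate that stops a vertex completely once the local
  intensity leaves the organ window `[I_min, I_max]` (default [−250, 500],
  the CT soft-tissue range) — this is what prevents leakage into adjacent
  out-of-window structures.

After every iteration, any dual (virtual) triangle whose area exceeds a
threshold is split 1→3 at its gravity center and the simplex mesh is rebuilt
from the refined triangulation, so facets stay small enough to follow narrow
protrusions.

Evaluation criteria: VOE, signed RVD, ASSD, RMSSSD, MSSD (pooled symmetric
border-voxel surface distances, mm) and the per-iteration SADE (mean
vertex-to-truth-surface distance, mm).

## Worked example

```
$ simplexseg phantom --shape lobed --size 72 --radius 18 --seed 7 \
      --out vol.nii.gz --truth gt.nii.gz
phantom written to vol.nii.gz; ground truth to gt.nii.gz

$ simplexseg segment --input vol.nii.gz --seed 35.5,35.5,35.5 --radius 10 \
      --variant E --out mask.nii.gz --mesh mesh.ply --truth gt.nii.gz --trace trace.csv
done after 11 iterations (tol); 960 vertices; mask volume 23456 voxels -> mask.nii.gz

$ simplexseg evaluate --pred mask.nii.gz --truth gt.nii.gz
VOE [%]               6.793
RVD [%] (signed)     -6.639
|RVD| [%]             6.639
ASSD [mm]             0.584
RMSSSD [mm]           1.606
MSSD [mm]            13.000
```

The phantom is a bright sphere (100 HU, radius 18 voxels) with a narrow
protruding lobe, embedded in air-like background (−1000 HU) with Gaussian
noise. The mesh expands from a radius-10 seed sphere, converges in 11
iterations (mean displacement below tolerance), and has been refined from
320 to 960 vertices on the way. The overlap error of 6.8% is dominated by
the sub-voxel offset between the intensity-window contour and the true
surface plus the unreached distal part of the narrow lobe (visible as the
13 mm maximum surface distance); the average surface error is 0.58 mm at
1 mm voxel spacing. `trace.csv` records per-iteration mean displacement,
vertex counts, split counts, and SADE; a `*.config.json` echo of every
parameter is written next to each output for reproducibility.

The same pipeline is available as a library:

```python
import simplexseg as S

spec = S.PhantomSpec(shape="lobed", size=72, radius=18.0, rng_seed=7)
vol, truth = S.make_phantom(spec)
res = S.run_segmentation(vol, seed=spec.center, radius=10.0, ground_truth=truth)
print(S.evaluate_masks(res.mask, truth, mesh=res.mesh))
```

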