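"""Newtonian mesh evolution, ablation variants, and mesh voxelization.

The damped second-order dynamics m P'' = -gamma P' + F_int + F_ext are
discretized per vertex as

    P(t+1) = P(t) + (1 - gamma)(P(t) - P(t-1)) + alpha F_int + beta F_ext,

with the per-iteration displacement clamped to ``step_max`` voxels.  The
mass is absorbed in the discretization; gamma in [0, 1] trades inertia
(gamma=0: full momentum) against overdamping (gamma=1: memoryless).

Ablation variants (cumulative):
  A - plain simplex-mesh model: internal smoothing only;
  B - adds the gradient force (attraction to the gradient-magnitude arg-max
      along the normal);
  C - adds the binary-image machinery: the edge force, the beta weighting of
      the gradient/edge pair, and the Boolean intensity gate B(I);
  D - adds the balloon inflation force;
  E - adds per-iteration adaptive facet decomposition (the full model).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .forces import ForceParams, external_force_bulk, internal_force_bulk
from .geometry import vertex_geometry_bulk
from .preprocess import DerivedImages, PreprocessParams, compute_derived_images
from .refine import RefineParams, decompose_pass
from .simplex_mesh import SimplexMesh, dual_triangulation, init_simplex_sphere, validate
from .volume_io import BinaryMask, Volume

__all__ = [
    "EvolutionParams",
    "EvolutionState",
    "SegmentationResult",
    "VARIANTS",
    "step",
    "run_segmentation",
    "mesh_to_mask",
]

log = logging.getLogger(__name__)

#: variant -> (use_gradient, use_binary, use_balloon, refine)
VARIANTS = {
    "A": (False, False, False, False),
    "B": (True, False, False, False),
    "C": (True, True, False, False),
    "D": (True, True, True, False),
    "E": (True, True, True, True),
}


@dataclass
class EvolutionParams:
    """gamma: damping in [0,1]; alpha/beta: internal/external force weights;
    iters: iteration budget; step_max: per-iteration displacement cap
    (voxels); tol: convergence threshold on mean displacement (voxels);
    variant: ablation configuration A-E."""

    gamma: float = 0.65
    alpha: float = 0.4
    beta: float = 0.4
    iters: int = 30
    step_max: float = 1.0
    tol: float = 0.01
    variant: str = "E"
    init_level: int = 2

    def __post_init__(self) -> None:
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if self.iters < 1:
            raise ValueError("iters must be >= 1")
        if self.step_max <= 0:
            raise ValueError("step_max must be > 0")
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {sorted(VARIANTS)}")


@dataclass
class EvolutionState:
    mesh: SimplexMesh
    prev_positions: np.ndarray
    iteration: int = 0
    theta_avg: np.ndarray | None = None  # running mean measured angle ('keep' mode)
    trace: list = field(default_factory=list)


@dataclass
class SegmentationResult:
    mesh: SimplexMesh
    mask: BinaryMask
    trace: list
    images: DerivedImages
    stop_reason: str


def step(state: EvolutionState, images: DerivedImages, fparams: ForceParams,
         eparams: EvolutionParams) -> EvolutionState:
    """One explicit evolution step; returns a new state (input untouched)."""
    use_gradient, use_binary, use_balloon, _ = VARIANTS[eparams.variant]
    mesh = state.mesh
    P = mesh.positions
    bulk = vertex_geometry_bulk(P, mesh.neighbors)

    if fparams.theta_ref == "keep":
        k = state.iteration + 1
        avg = state.theta_avg if state.theta_avg is not None else bulk["theta"].copy()
        avg = avg + (bulk["theta"] - avg) / k
        theta_ref = avg
    else:
        avg = state.theta_avg
        theta_ref = float(fparams.theta_ref)

    from .forces import _sample  # trilinear sampler

    grad_at_p = _sample(images.grad_mag.data, P)
    f_int = internal_force_bulk(bulk, grad_at_p, theta_ref)
    ext = external_force_bulk(P, bulk["n"], images, fparams, bulk["r"],
                              use_gradient=use_gradient, use_binary=use_binary,
                              use_balloon=use_balloon)
    disp = ((1.0 - eparams.gamma) * (P - state.prev_positions)
            + eparams.alpha * f_int + eparams.beta * ext["f_external"])
    bad = ~np.isfinite(disp).all(axis=1)
    if np.any(bad):
        log.warning("%d vertices with non-finite force frozen this iteration",
                    int(bad.sum()))
        disp[bad] = 0.0
    norms = np.linalg.norm(disp, axis=1)
    over = norms > eparams.step_max
    if np.any(over):
        disp[over] *= (eparams.step_max / norms[over])[:, None]

    if use_binary and fparams.gate_enabled:
        # Gate closure is a full stop: a vertex whose local intensity has
        # left the organ window holds its position entirely.  Letting the
        # internal force keep kneading a region whose image evidence says
        # "stop" would slowly re-inflate or shrink the settled boundary, so
        # the converged state would never be static.
        disp[ext["gate"] == 0] = 0.0

    new_mesh = SimplexMesh(positions=P + disp, neighbors=mesh.neighbors.copy(),
                           faces=[list(f) for f in mesh.faces])
    return EvolutionState(mesh=new_mesh, prev_positions=P.copy(),
                          iteration=state.iteration + 1, theta_avg=avg,
                          trace=state.trace)


def run_segmentation(vol: Volume, seed, radius: float,
                     pparams: PreprocessParams | None = None,
                     fparams: ForceParams | None = None,
                     eparams: EvolutionParams | None = None,
                     rparams: RefineParams | None = None,
                     ground_truth: BinaryMask | None = None,
                     images: DerivedImages | None = None,
                     on_iteration=None) -> SegmentationResult:
    """Full pipeline: preprocess, seed a spherical mesh, evolve, voxelize.

    ``seed`` is a voxel-index coordinate strictly inside the volume and
    inside the intensity window; ``radius`` the initial sphere radius in
    voxels.  Pass precomputed ``images`` to reuse preprocessing across runs.
    ``on_iteration(state, n_splits)`` is called after each iteration.
    """
    pparams = pparams or PreprocessParams()
    fparams = fparams or ForceParams(i_min=pparams.i_min, i_max=pparams.i_max)
    eparams = eparams or EvolutionParams()
    rparams = rparams or RefineParams()
    seed = np.asarray(seed, np.float64)

    shape = vol.shape
    if not np.all((seed > 0) & (seed < np.asarray(shape) - 1)):
        raise ValueError(f"seed {seed.tolist()} is not strictly inside the volume {shape}")
    if images is None:
        images = compute_derived_images(vol, pparams)
    from .forces import _sample

    seed_intensity = float(_sample(images.smoothed.data, seed))
    if not (fparams.i_min <= seed_intensity <= fparams.i_max):
        raise ValueError(
            f"seed intensity {seed_intensity:.1f} outside the window "
            f"[{fparams.i_min}, {fparams.i_max}]"
        )

    refine_on = VARIANTS[eparams.variant][3]
    mesh = init_simplex_sphere(seed, radius, level=eparams.init_level)
    state = EvolutionState(mesh=mesh, prev_positions=mesh.positions.copy())

    truth_dist = None
    if ground_truth is not None:
        from .metrics import _surface_distance_field

        truth_dist = _surface_distance_field(ground_truth)

    stop_reason = "iters"
    for _ in range(eparams.iters):
        prev = state.mesh.positions
        state = step(state, images, fparams, eparams)
        mean_disp = float(np.mean(np.linalg.norm(state.mesh.positions - prev, axis=1)))
        n_splits = 0
        if refine_on:
            res = decompose_pass(state.mesh, rparams)
            if res.n_splits:
                n_splits = res.n_splits
                # remap inertia: children inherit their parent vertex's velocity
                velocity = state.mesh.positions - state.prev_positions
                state = EvolutionState(
                    mesh=res.mesh,
                    prev_positions=res.mesh.positions - velocity[res.vertex_parent],
                    iteration=state.iteration,
                    theta_avg=(state.theta_avg[res.vertex_parent]
                               if state.theta_avg is not None else None),
                    trace=state.trace,
                )
        rec = {
            "iteration": state.iteration,
            "mean_displacement": mean_disp,
            "n_vertices": state.mesh.n_vertices,
            "n_triangles": state.mesh.n_vertices,  # one dual triangle per vertex
            "n_splits": n_splits,
        }
        if truth_dist is not None:
            from .metrics import _sade_from_field

            rec["sade_mm"] = _sade_from_field(state.mesh, truth_dist, ground_truth.spacing)
        state.trace.append(rec)
        if on_iteration is not None:
            on_iteration(state, n_splits)
        if n_splits == 0 and mean_disp < eparams.tol:
            stop_reason = "tol"
            break

    report = validate(state.mesh)
    if not report.ok:
        raise RuntimeError(f"evolved mesh failed validation: {report.violations[:3]}")
    mask = mesh_to_mask(state.mesh, shape, vol.spacing)
    for r in state.trace:
        r.setdefault("stop_reason", "")
    state.trace[-1]["stop_reason"] = stop_reason
    return SegmentationResult(mesh=state.mesh, mask=mask, trace=state.trace,
                              images=images, stop_reason=stop_reason)


# ---------------------------------------------------------------------------
# voxelization
# ---------------------------------------------------------------------------


def mesh_to_mask(mesh: SimplexMesh, shape, spacing=(1.0, 1.0, 1.0),
                 method: str = "parity") -> BinaryMask:
    """Voxelize the dual-triangulation surface: voxel = 1 iff its center is
    inside the closed surface.

    ``method="parity"`` casts an axis-aligned ray per (y, z) column and fills
    between crossings; ``method="winding"`` thresholds the generalized
    winding number at 1/2 (slower; used as an independent cross-check).
    """
    report = validate(mesh)
    if not report.ok:
        raise ValueError(f"cannot voxelize an invalid mesh: {report.violations[:3]}")
    tri = dual_triangulation(mesh)
    verts = tri.tri_vertices
    faces = tri.triangles
    shape = tuple(int(s) for s in shape)
    if method == "parity":
        data = _voxelize_parity(verts, faces, shape)
    elif method == "winding":
        data = _voxelize_winding(verts, faces, shape)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BinaryMask(data=data, spacing=spacing)


# tiny deterministic ray offset pushes voxel centers off any plane/edge that
# happens to contain them exactly
_RAY_EPS = (2.0**-20, 2.0**-21)


def _voxelize_parity(verts: np.ndarray, faces: np.ndarray, shape) -> np.ndarray:
    nx, ny, nz = shape
    crossings: dict = {}
    v = verts[faces]  # (F, 3, 3)
    ey, ez = _RAY_EPS
    for a, b, c in v:
        ys = np.array([a[1], b[1], c[1]]) - ey
        zs = np.array([a[2], b[2], c[2]]) - ez
        y0 = max(int(np.ceil(ys.min())), 0)
        y1 = min(int(np.floor(ys.max())), ny - 1)
        z0 = max(int(np.ceil(zs.min())), 0)
        z1 = min(int(np.floor(zs.max())), nz - 1)
        if y0 > y1 or z0 > z1:
            continue
        yy, zz = np.meshgrid(np.arange(y0, y1 + 1), np.arange(z0, z1 + 1), indexing="ij")
        py = yy.ravel() + ey
        pz = zz.ravel() + ez
        # 2-D barycentric test in the (y, z) projection
        d00 = (b[1] - a[1], b[2] - a[2])
        d01 = (c[1] - a[1], c[2] - a[2])
        det = d00[0] * d01[1] - d00[1] * d01[0]
        if det == 0.0:
            continue  # triangle edge-on to the ray: adjacent faces cover it
        w1 = ((py - a[1]) * d01[1] - (pz - a[2]) * d01[0]) / det
        w2 = ((pz - a[2]) * d00[0] - (py - a[1]) * d00[1]) / det
        inside = (w1 >= 0) & (w2 >= 0) & (w1 + w2 <= 1)
        if not np.any(inside):
            continue
        xs = a[0] + w1[inside] * (b[0] - a[0]) + w2[inside] * (c[0] - a[0])
        for yi, zi, xc in zip(yy.ravel()[inside], zz.ravel()[inside], xs):
            crossings.setdefault((int(yi), int(zi)), []).append(xc)
    data = np.zeros(shape, dtype=np.uint8)
    for (yi, zi), xs in crossings.items():
        xs = sorted(xs)
        if len(xs) % 2:  # grazing contact: drop the unpaired crossing
            continue
        for lo, hi in zip(xs[0::2], xs[1::2]):
            x0 = max(int(np.ceil(lo)), 0)
            x1 = min(int(np.floor(hi)), nx - 1)
            if x0 <= x1:
                data[x0:x1 + 1, yi, zi] = 1
    return data


def _voxelize_winding(verts: np.ndarray, faces: np.ndarray, shape) -> np.ndarray:
    grid = np.stack(np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"),
                    axis=-1).reshape(-1, 3).astype(np.float64)
    tri = verts[faces]  # (F, 3, 3)
    wn = np.zeros(len(grid))
    chunk = 2048
    for s in range(0, len(grid), chunk):
        pts = grid[s:s + chunk]
        a = tri[None, :, 0, :] - pts[:, None, :]
        b = tri[None, :, 1, :] - pts[:, None, :]
        c = tri[None, :, 2, :] - pts[:, None, :]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.sum(np.cross(a, b) * c, axis=-1)  # scalar triple product
        den = (la * lb * lc + np.sum(a * b, axis=-1) * lc
               + np.sum(b * c, axis=-1) * la + np.sum(c * a, axis=-1) * lb)
        wn[s:s + chunk] = np.sum(2.0 * np.arctan2(num, den), axis=-1)
    inside = (wn / (4.0 * np.pi)) > 0.5
    return inside.reshape(shape).astype(np.uint8)
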