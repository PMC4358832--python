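"""Internal (smoothing) and external (image-driven) forces per mesh vertex.

Internal force
--------------
F_int = alpha_tangent * F_tangent + alpha_normal * F_normal with

* F_tangent = C - P*: moves the in-plane projection of the vertex toward the
  circumcenter of its neighbor triangle (even spacing among neighbors);
* F_normal = (P* + L(r, d, theta_ref) n) - P: restores the vertex to the
  elevation prescribed by a reference simplex angle theta_ref (default 0, a
  locally flattening prior);
* alpha_normal = 1 / (1 + g^2) where g is the Gaussian-gradient magnitude of
  the smoothed image at the vertex, alpha_tangent = 1 - alpha_normal.  In
  flat image regions the normal (curvature) smoothing dominates; on strong
  edges it switches off so the surface can keep image-driven curvature.

External force
--------------
F_ext = B(I) * (beta_grad * F_gradient + beta_edge * F_edge + F_balloon) with

* F_gradient: displacement along the normal to the gradient-magnitude
  arg-max sampled on the line P +- t n;
* F_edge: displacement to the edge-map arg-max on the same line;
* F_balloon = q n: outward inflation;
* beta_grad = 1 - exp(-f(P)/K), beta_edge = exp(-f(P)/K) where f is the
  edge map, so beta_grad + beta_edge = 1: near the boundary the gradient
  term takes over, far away the edge term;
* B(I): Boolean gate, 1 iff the smoothed intensity at P lies in the organ
  window [i_min, i_max]; zeroes the entire external force elsewhere to stop
  leakage into out-of-window tissue.

All image sampling is trilinear; samples outside the grid clamp to border
values.  A vertex outside the volume receives zero external force.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import elevation_L, vertex_geometry, vertex_geometry_bulk
from .preprocess import DerivedImages
from .volume_io import BinaryMask, Volume

__all__ = [
    "ForceParams",
    "VertexForces",
    "internal_force",
    "gradient_force",
    "edge_force",
    "balloon_force",
    "boolean_gate",
    "external_force",
    "resolve_K",
]

log = logging.getLogger(__name__)


@dataclass
class ForceParams:
    """Scalar knobs of the force model.

    K: edge-map scale of the beta weights; ``None`` resolves to the median of
    the nonzero edge-map voxels (scale-adaptive).  q: balloon weight in
    voxels/iteration.  i_min/i_max: intensity window of the gate.
    search_len: extent (voxels) of the normal-line arg-max search; ``None``
    uses max(r_i, 2) per vertex, r_i the neighbor-triangle circumradius.
    step: sampling step along the normal.  theta_ref: reference simplex angle
    of the normal force — a float (0 = flattening prior) or ``"keep"`` to use
    the per-vertex time-averaged measured angle.  gate_enabled=False disables
    B(I) (ablation); external_unweighted drops the beta weights.
    """

    K: float | None = None
    q: float = 1.5
    i_min: float = -250.0
    i_max: float = 500.0
    search_len: float | None = None
    search_cap: float = 6.0
    step: float = 0.5
    theta_ref: float | str = 0.0
    gate_enabled: bool = True
    external_unweighted: bool = False

    def __post_init__(self) -> None:
        if self.K is not None and self.K <= 0:
            raise ValueError("K must be a positive constant greater than zero")
        if not (0 < self.step <= 1):
            raise ValueError("step must be in (0, 1]")
        if self.search_len is not None and self.search_len <= 0:
            raise ValueError("search_len must be > 0")
        if self.search_cap <= 0:
            raise ValueError("search_cap must be > 0")
        if self.i_min >= self.i_max:
            raise ValueError("i_min must be < i_max")
        if isinstance(self.theta_ref, str) and self.theta_ref != "keep":
            raise ValueError("theta_ref must be a float or 'keep'")


@dataclass
class VertexForces:
    """Decomposed per-vertex forces and their weights."""

    f_internal: np.ndarray
    f_external: np.ndarray
    f_tangent: np.ndarray
    f_normal: np.ndarray
    f_gradient: np.ndarray
    f_edge: np.ndarray
    f_balloon: np.ndarray
    alpha_tangent: float
    alpha_normal: float
    beta_grad: float
    beta_edge: float
    gate: int


def resolve_K(params: ForceParams, edge_map: Volume) -> float:
    """K default: median of the edge map over its significant voxels.

    "Significant" means above 1e-6 of the map's maximum: the Gaussian blur
    that builds the edge map leaves sub-epsilon tails everywhere, so a strict
    positivity test would return the tail median instead of the boundary
    ridge scale.
    """
    if params.K is not None:
        return float(params.K)
    data = edge_map.data
    mx = float(data.max())
    if mx <= 0:
        return 1.0
    nz = data[data > 1e-6 * mx]
    return float(np.median(nz))


def _sample(volume_data: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Trilinear sampling at (..., 3) index coordinates, border-clamped."""
    pts = np.asarray(coords, np.float64).reshape(-1, 3).T
    out = ndimage.map_coordinates(
        np.asarray(volume_data, np.float64), pts, order=1, mode="nearest"
    )
    return out.reshape(np.shape(coords)[:-1])


def _inside(shape, p) -> np.ndarray:
    p = np.asarray(p, np.float64)
    ok = np.ones(p.shape[:-1], dtype=bool)
    for ax in range(3):
        ok &= (p[..., ax] >= 0) & (p[..., ax] <= shape[ax] - 1)
    return ok


def _line_offsets(search_len: float, step: float) -> np.ndarray:
    """Sampling offsets ordered by |t| with +t before -t (the tie rule)."""
    k = int(np.floor(search_len / step + 1e-9))
    ts = [0.0]
    for i in range(1, k + 1):
        ts.extend((i * step, -i * step))
    return np.array(ts)


# ---------------------------------------------------------------------------
# scalar per-vertex operations; vectorized mesh-wide versions below
# ---------------------------------------------------------------------------


def internal_force(geom, grad_at_p: float, theta_ref: float | None = 0.0):
    """(f_internal, alpha_tangent, alpha_normal) for one vertex.

    ``geom`` is a :class:`~simplexseg.geometry.VertexGeometry`.  ``theta_ref``
    of ``None`` means "use the measured angle" (zero normal restoring force).
    """
    g = float(grad_at_p)
    if g < 0:
        raise ValueError("gradient magnitude must be >= 0")
    a_n = 1.0 / (1.0 + g * g)
    a_t = 1.0 - a_n
    f_tan = geom.circle_center - geom.p_star
    ref = geom.theta if theta_ref is None else float(theta_ref)
    if geom.d < geom.r and abs(ref) < np.pi:
        L_ref = elevation_L(geom.r, geom.d, ref)
    else:  # projection outside the circumcircle: fall back to the flat target
        L_ref = 0.0
    # restoring displacement toward the reference configuration on the normal
    f_norm = (L_ref - _current_h(geom)) * geom.n
    return a_t * f_tan + a_n * f_norm, a_t, a_n


def _current_h(geom) -> float:
    """Signed elevation of the vertex implied by theta (h = L(r,d,theta))."""
    if geom.d < geom.r and abs(geom.theta) < np.pi:
        return elevation_L(geom.r, geom.d, geom.theta)
    return 0.0


def gradient_force(p, n, grad_mag: Volume, edge_map: Volume, params: ForceParams,
                   r_i: float = 2.0):
    """(f_gradient, beta_grad): pull along the normal to the gradient arg-max.

    The search line is P +- t n, t up to search_len (default max(r_i, 2)),
    sampled every ``step`` voxels; ties break toward the smallest |t|, then
    toward +n.  The displacement is projected on the normal:
    f = ((Max_grad - P) . n) n.
    """
    p = np.asarray(p, np.float64)
    n = np.asarray(n, np.float64)
    K = resolve_K(params, edge_map)
    beta = 1.0 - np.exp(-float(_sample(edge_map.data, p)) / K)
    if not bool(_inside(grad_mag.shape, p)):
        return np.zeros(3), float(beta)
    sl = params.search_len if params.search_len is not None else max(float(r_i), 2.0)
    sl = min(sl, params.search_cap)
    ts = _line_offsets(sl, params.step)
    samples = _sample(grad_mag.data, p[None, :] + ts[:, None] * n[None, :])
    t_star = ts[int(np.argmax(samples))]  # argmax takes the first max: the tie rule
    return t_star * n, float(beta)


def edge_force(p, n, binary: BinaryMask, edge_map: Volume, params: ForceParams,
               r_i: float = 2.0):
    """(f_edge, beta_edge): displacement to the edge-map arg-max on the line.

    The arg-max is taken on the edge map f (the smoothed binary image's
    squared gradient), not the raw binary plateau, so the boundary locus is
    unique; the displacement is the full vector Max_edge - P.
    """
    p = np.asarray(p, np.float64)
    n = np.asarray(n, np.float64)
    K = resolve_K(params, edge_map)
    beta = np.exp(-float(_sample(edge_map.data, p)) / K)
    if not bool(_inside(edge_map.shape, p)):
        return np.zeros(3), float(beta)
    sl = params.search_len if params.search_len is not None else max(float(r_i), 2.0)
    sl = min(sl, params.search_cap)
    ts = _line_offsets(sl, params.step)
    samples = _sample(edge_map.data, p[None, :] + ts[:, None] * n[None, :])
    t_star = ts[int(np.argmax(samples))]
    return t_star * n, float(beta)


def balloon_force(n, q: float) -> np.ndarray:
    """Outward inflation q * n along the unit vertex normal."""
    return float(q) * np.asarray(n, np.float64)


def boolean_gate(intensity_at_p: float, i_min: float, i_max: float) -> int:
    """B(I) = 1 iff i_min <= I <= i_max (inclusive), else 0."""
    if i_min >= i_max:
        raise ValueError("i_min must be < i_max")
    return int(i_min <= float(intensity_at_p) <= i_max)


def external_force(p, n, images: DerivedImages, params: ForceParams,
                   r_i: float = 2.0) -> VertexForces:
    """Full external force for one vertex (gate applied); internal fields zero."""
    p = np.asarray(p, np.float64)
    n = np.asarray(n, np.float64)
    f_grad, b_grad = gradient_force(p, n, images.grad_mag, images.edge_map, params, r_i)
    f_edge_, b_edge = edge_force(p, n, images.binary, images.edge_map, params, r_i)
    f_bal = balloon_force(n, params.q)
    intensity = float(_sample(images.smoothed.data, p))
    gate = boolean_gate(intensity, params.i_min, params.i_max) if params.gate_enabled else 1
    if params.external_unweighted:
        f_ext = gate * (f_grad + f_edge_ + f_bal)
    else:
        f_ext = gate * (b_grad * f_grad + b_edge * f_edge_ + f_bal)
    zero = np.zeros(3)
    return VertexForces(
        f_internal=zero,
        f_external=f_ext,
        f_tangent=zero,
        f_normal=zero,
        f_gradient=f_grad,
        f_edge=f_edge_,
        f_balloon=f_bal,
        alpha_tangent=0.0,
        alpha_normal=1.0,
        beta_grad=b_grad,
        beta_edge=b_edge,
        gate=gate,
    )


# ---------------------------------------------------------------------------
# vectorized mesh-wide evaluation (used by evolve.step)
# ---------------------------------------------------------------------------


def internal_force_bulk(bulk: dict, grad_at_p: np.ndarray,
                        theta_ref: np.ndarray | float = 0.0) -> np.ndarray:
    """Internal forces for all vertices from a geometry-bulk dict.

    Degenerate vertices (bulk["valid"] False) get zero force.  ``theta_ref``
    may be a scalar or per-vertex array.
    """
    g = np.asarray(grad_at_p, np.float64)
    a_n = 1.0 / (1.0 + g * g)
    a_t = 1.0 - a_n
    f_tan = bulk["C"] - bulk["p_star"]
    # the circumcenter diverges for near-collinear neighbor triples; clamp
    # the tangential pull to the local edge scale so relaxation stays stable
    tan_norm = np.linalg.norm(f_tan, axis=-1)
    over = tan_norm > bulk["scale"]
    if np.any(over):
        f_tan[over] *= (bulk["scale"][over] / tan_norm[over])[:, None]
    r, d, h = bulk["r"], bulk["d"], bulk["h"]
    ref = np.broadcast_to(np.asarray(theta_ref, np.float64), r.shape)
    ok = bulk["valid"] & (d < r) & (np.abs(ref) < np.pi)
    L_ref = np.zeros_like(r)
    if np.any(ok):
        L_ref[ok] = elevation_L(r[ok], d[ok], ref[ok])
    f_norm = (L_ref - h)[:, None] * bulk["n"]
    f = a_t[:, None] * f_tan + a_n[:, None] * f_norm
    f[~bulk["valid"]] = 0.0
    n_bad = int(np.sum(~bulk["valid"]))
    if n_bad:
        log.warning("%d vertices with degenerate neighbor geometry: internal force zeroed",
                    n_bad)
    return f


def external_force_bulk(positions: np.ndarray, normals: np.ndarray,
                        images: DerivedImages, params: ForceParams,
                        r: np.ndarray, use_gradient: bool = True,
                        use_binary: bool = True, use_balloon: bool = True) -> dict:
    """External force terms for all vertices at once.

    Returns dict with f_gradient, f_edge, f_balloon, f_external (V,3) and
    beta_grad, beta_edge, gate (V,).  The use_* switches implement the
    ablation variants: ``use_gradient`` adds the gradient force;
    ``use_binary`` adds everything derived from the binarized image — the
    edge force, the beta weighting of the gradient/edge pair, and the B(I)
    gate; ``use_balloon`` the inflation term.
    """
    P = np.asarray(positions, np.float64)
    n = np.asarray(normals, np.float64)
    V = len(P)
    K = resolve_K(params, images.edge_map)
    f_at_p = _sample(images.edge_map.data, P)
    beta_grad = 1.0 - np.exp(-f_at_p / K)
    beta_edge = 1.0 - beta_grad

    if params.search_len is not None:
        sl = min(float(params.search_len), params.search_cap)
        per_vertex_len = sl
    else:
        # per-vertex circumcircle extent, bounded below for degenerate-flat
        # triangles and above so one pathological facet cannot leap across
        # structures (or blow up the sample array)
        per_vertex_len = np.clip(np.maximum(r, 2.0), None, params.search_cap)
        sl = max(float(np.max(per_vertex_len)) if V else 2.0, 2.0)
    ts = _line_offsets(sl, params.step)
    pts = P[:, None, :] + ts[None, :, None] * n[:, None, :]  # (V, T, 3)
    reach = np.abs(ts)[None, :] <= np.asarray(per_vertex_len)[..., None] + 1e-12

    inside = _inside(images.smoothed.shape, P)

    grad_samples = _sample(images.grad_mag.data, pts)
    grad_samples = np.where(reach, grad_samples, -np.inf)
    t_grad = ts[np.argmax(grad_samples, axis=1)]
    f_gradient = (t_grad * inside)[:, None] * n

    edge_samples = _sample(images.edge_map.data, pts)
    edge_samples = np.where(reach, edge_samples, -np.inf)
    t_edge = ts[np.argmax(edge_samples, axis=1)]
    f_edge = (t_edge * inside)[:, None] * n

    f_balloon = params.q * n

    intensity = _sample(images.smoothed.data, P)
    if use_binary and params.gate_enabled:
        gate = ((intensity >= params.i_min) & (intensity <= params.i_max)).astype(np.float64)
    else:
        gate = np.ones(V)

    terms = np.zeros_like(P)
    if use_gradient and use_binary:
        if params.external_unweighted:
            terms = f_gradient + f_edge
        else:
            terms = beta_grad[:, None] * f_gradient + beta_edge[:, None] * f_edge
    elif use_gradient:
        terms = f_gradient.copy()
    elif use_binary:
        terms = f_edge.copy()
    if use_balloon:
        terms += f_balloon
    f_external = gate[:, None] * terms
    return {
        "f_gradient": f_gradient,
        "f_edge": f_edge,
        "f_balloon": f_balloon,
        "f_external": f_external,
        "beta_grad": beta_grad,
        "beta_edge": beta_edge,
        "gate": gate,
    }
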