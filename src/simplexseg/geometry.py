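"""Per-vertex simplex geometry: weights, normal, circumsphere, simplex angle.

For a simplex vertex P with neighbor triangle (P1, P2, P3) the local shape is
encoded by

* barycentric weights w of the in-plane projection P* of P,
* the circumcircle (C, r) of the neighbor triangle and d = |C - P*|,
* the circumsphere (O, R) of the tetrahedron (P, P1, P2, P3),
* the simplex angle theta in [-pi, pi], defined through
  sin(theta) = (r/R) * sign((P - P1) . n) and
  cos(theta) = (|OC|/R) * sign((C - O) . n),

together with the elevation function L(r, d, theta) giving the height of P
above the neighbor plane that realizes a prescribed simplex angle:

    P = w1 P1 + w2 P2 + w3 P3 + L(r, d, theta) n.

theta is a scaled mean-curvature descriptor: theta = 0 means P lies in its
neighbor plane; the sign follows the outward normal n.

All functions broadcast over leading axes (inputs of shape (..., 3)), which
is how the force stage evaluates whole meshes at once.  Scalar entry points
raise :class:`GeometryDegenerateError` on collinear/coplanar input; the bulk
helper returns validity masks instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "GeometryDegenerateError",
    "VertexGeometry",
    "face_normal",
    "project_to_neighbor_plane",
    "barycentric_weights",
    "circumcircle",
    "circumsphere",
    "simplex_angle",
    "elevation_L",
    "vertex_geometry",
]

_DEGENERATE_AREA = 1e-9  # voxel^2; below this a neighbor triangle is degenerate
_COPLANAR_TOL = 1e-12


class GeometryDegenerateError(ValueError):
    """Collinear neighbors / coplanar tetrahedron: the construction is undefined."""


@dataclass
class VertexGeometry:
    """All per-vertex quantities feeding the internal force."""

    w: np.ndarray  # (3,) barycentric weights of P*
    w_star: np.ndarray  # (3,) target weights (barycentric coords of C)
    n: np.ndarray  # unit outward normal of the neighbor triangle
    p_star: np.ndarray  # projection of P onto the neighbor plane
    r: float  # circumcircle radius of the neighbor triangle
    d: float  # |C - P*|
    circle_center: np.ndarray  # C
    sphere_center: np.ndarray | None  # O (None when P is coplanar)
    sphere_radius: float  # R (inf when coplanar)
    theta: float  # simplex angle in [-pi, pi]
    omega_sign: float  # sign(pi/2 - |theta|)


# -- elementary constructions ------------------------------------------------


def _cross_sum_normal(p1, p2, p3):
    """Unnormalized cyclic cross-product sum; translation invariant."""
    return np.cross(p1, p2) + np.cross(p2, p3) + np.cross(p3, p1)


def face_normal(p1, p2, p3):
    """Unit normal of the triangle, n = (P1xP2 + P2xP3 + P3xP1)/|...|.

    Equals the normalized (P2-P1)x(P3-P1); points toward the viewer for whom
    the vertices appear counterclockwise.
    """
    p1, p2, p3 = (np.asarray(p, np.float64) for p in (p1, p2, p3))
    n = _cross_sum_normal(p1, p2, p3)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    if np.any(norm < 2 * _DEGENERATE_AREA):
        raise GeometryDegenerateError("collinear or coincident triangle vertices")
    return n / norm


def project_to_neighbor_plane(p, p1, p2, p3):
    """Orthogonal projection of p onto the plane of (p1, p2, p3)."""
    p = np.asarray(p, np.float64)
    n = face_normal(p1, p2, p3)
    h = np.sum((p - np.asarray(p1, np.float64)) * n, axis=-1, keepdims=True)
    return p - h * n


def barycentric_weights(p_star, p1, p2, p3):
    """Weights (w1, w2, w3) with sum 1 and w1 P1 + w2 P2 + w3 P3 = P*.

    ``p_star`` must already lie in the triangle plane (project first).
    """
    p_star, p1, p2, p3 = (np.asarray(x, np.float64) for x in (p_star, p1, p2, p3))
    u = p1 - p3
    v = p2 - p3
    b = p_star - p3
    uu = np.sum(u * u, axis=-1)
    vv = np.sum(v * v, axis=-1)
    uv = np.sum(u * v, axis=-1)
    det = uu * vv - uv * uv
    if np.any(np.abs(det) < _COPLANAR_TOL):
        raise GeometryDegenerateError("degenerate neighbor triangle")
    bu = np.sum(b * u, axis=-1)
    bv = np.sum(b * v, axis=-1)
    w1 = (vv * bu - uv * bv) / det
    w2 = (uu * bv - uv * bu) / det
    return np.stack([w1, w2, 1.0 - w1 - w2], axis=-1)


def circumcircle(p1, p2, p3):
    """Center and radius of the circle through three points (in 3-D)."""
    p1, p2, p3 = (np.asarray(x, np.float64) for x in (p1, p2, p3))
    u = p2 - p1
    v = p3 - p1
    w = np.cross(u, v)
    w2 = np.sum(w * w, axis=-1, keepdims=True)
    if np.any(w2 < (2 * _DEGENERATE_AREA) ** 2):
        raise GeometryDegenerateError("collinear points have no circumcircle")
    uu = np.sum(u * u, axis=-1, keepdims=True)
    vv = np.sum(v * v, axis=-1, keepdims=True)
    center = p1 + (uu * np.cross(v, w) + vv * np.cross(w, u)) / (2.0 * w2)
    r = np.linalg.norm(center - p1, axis=-1)
    return center, r


def circumsphere(p, p1, p2, p3):
    """Center and radius of the sphere through four non-coplanar points."""
    pts = [np.asarray(x, np.float64) for x in (p, p1, p2, p3)]
    base = pts[0]
    rows = np.stack([q - base for q in pts[1:]], axis=-2)  # (..., 3, 3)
    rhs = 0.5 * np.sum(rows * rows, axis=-1)  # (..., 3)
    det = np.linalg.det(rows)
    scale = np.max(np.abs(rows), axis=(-2, -1))
    scale = np.where(scale == 0, 1.0, scale)
    if np.any(np.abs(det) < 1e-12 * scale**3):
        raise GeometryDegenerateError("coplanar points have no circumsphere")
    center = base + np.linalg.solve(rows, rhs[..., None])[..., 0]
    R = np.linalg.norm(center - base, axis=-1)
    return center, R


# -- simplex angle and elevation ---------------------------------------------


def _sin_cos_theta(p, p1, p2, p3):
    """(sin, cos) of the simplex angle; requires a defined circumsphere.

    sin carries the side of P: sign((P - P1) . n).  The cos sign factor
    sign((C - O) . n) is additionally referenced to the side of P (multiplied
    by sign((P - P1) . n)); without that reference cos would be odd under
    mirror reflection of P through the neighbor plane, breaking the required
    antisymmetry theta -> -theta and the triangle identity
    tan(theta) = 2 r L / ((r^2 - d^2) - L^2).
    """
    n = face_normal(p1, p2, p3)
    C, r = circumcircle(p1, p2, p3)
    O, R = circumsphere(p, p1, p2, p3)
    side = np.sign(np.sum((np.asarray(p, np.float64) - np.asarray(p1, np.float64)) * n, axis=-1))
    s = (r / R) * side
    oc = C - O
    c = (np.linalg.norm(oc, axis=-1) / R) * np.sign(np.sum(oc * n, axis=-1)) * side
    return s, c


def simplex_angle(p, p1, p2, p3) -> float:
    """Simplex angle theta in [-pi, pi] recovered by two-argument arctangent.

    A vertex in its neighbor plane has theta = 0 (handled as the coplanar
    limit); mirroring the vertex through the plane negates theta.
    """
    p = np.asarray(p, np.float64)
    n = face_normal(p1, p2, p3)
    h = np.sum((p - np.asarray(p1, np.float64)) * n, axis=-1)
    scale = max(float(np.max(np.abs(p - np.asarray(p1, np.float64)))), 1.0)
    if np.all(np.abs(h) < 1e-12 * scale):
        return 0.0 if np.ndim(h) == 0 else np.zeros(np.shape(h))
    s, c = _sin_cos_theta(p, p1, p2, p3)
    return float(np.arctan2(s, c)) if np.ndim(s) == 0 else np.arctan2(s, c)


def elevation_L(r, d, theta):
    """Height above the neighbor plane realizing simplex angle ``theta``.

    L = (r^2 - d^2) tan(theta) / (omega * sqrt(r^2 + (r^2 - d^2) tan^2 theta) + r)
    with omega = sign(pi/2 - |theta|).  Across theta = +-pi/2 the tan form is
    replaced by its finite circular-arc limit +-sqrt(r^2 - d^2); for
    |theta| > pi/2 the algebraically equivalent form -(r + sqrt(...))/tan(theta)
    avoids the catastrophic cancellation of the printed denominator.
    Odd in theta; diverges as theta -> +-pi (the circumsphere degenerates).
    """
    r = np.asarray(r, np.float64)
    d = np.asarray(d, np.float64)
    theta = np.asarray(theta, np.float64)
    if np.any(r <= d) or np.any(d < 0):
        raise ValueError("need r > d >= 0 (P* inside the circumcircle)")
    if np.any(np.abs(theta) >= np.pi):
        raise ValueError("theta must lie in the open interval (-pi, pi)")
    A = r * r - d * d
    s, c = np.sin(theta), np.cos(theta)
    near_half_pi = np.abs(c) < 1e-12
    t = np.where(near_half_pi, 1.0, np.tan(theta))
    S = np.sqrt(r * r + A * t * t)
    with np.errstate(divide="ignore", invalid="ignore"):
        inner = A * t / (S + r)  # omega = +1 branch, no cancellation
        outer = -(S + r) / t  # omega = -1 branch, conjugate form
    L = np.where(np.abs(theta) <= np.pi / 2, inner, outer)
    L = np.where(near_half_pi, np.sign(s) * np.sqrt(A), L)
    return float(L) if np.ndim(L) == 0 else L


def vertex_geometry(p, p1, p2, p3) -> VertexGeometry:
    """Bundle every per-vertex quantity used by the internal force."""
    p = np.asarray(p, np.float64)
    n = face_normal(p1, p2, p3)
    p_star = project_to_neighbor_plane(p, p1, p2, p3)
    w = barycentric_weights(p_star, p1, p2, p3)
    C, r = circumcircle(p1, p2, p3)
    w_star = barycentric_weights(C, p1, p2, p3)
    d = float(np.linalg.norm(C - p_star))
    h = float(np.sum((p - p_star) * n))
    scale = max(float(r), 1.0)
    if abs(h) < 1e-12 * scale:
        theta = 0.0
        O, R = None, float("inf")
    else:
        O, R = circumsphere(p, p1, p2, p3)
        s, c = _sin_cos_theta(p, p1, p2, p3)
        theta = float(np.arctan2(s, c))
        R = float(R)
    return VertexGeometry(
        w=w,
        w_star=w_star,
        n=n,
        p_star=p_star,
        r=float(r),
        d=d,
        circle_center=C,
        sphere_center=O,
        sphere_radius=R,
        theta=theta,
        omega_sign=float(np.sign(np.pi / 2 - abs(theta))),
    )


# -- vectorized mesh-wide evaluation (used by the force stage) ----------------


def vertex_geometry_bulk(positions: np.ndarray, neighbors: np.ndarray):
    """Vectorized geometry for all mesh vertices at once.

    Returns a dict of arrays: n (V,3), p_star (V,3), C (V,3), r (V,), d (V,),
    w (V,3), w_star (V,3), theta (V,), valid (V,) — ``valid`` is False where
    the neighbor triangle is degenerate; those rows hold zeros/NaN-free
    placeholders and the force stage must skip them.
    """
    P = np.asarray(positions, np.float64)
    nb = P[np.asarray(neighbors, np.int64)]  # (V, 3, 3)
    p1, p2, p3 = nb[:, 0], nb[:, 1], nb[:, 2]
    raw_n = _cross_sum_normal(p1, p2, p3)
    nn = np.linalg.norm(raw_n, axis=-1)
    valid = nn > 2 * _DEGENERATE_AREA
    safe = np.where(valid, nn, 1.0)[:, None]
    n = raw_n / safe
    h = np.sum((P - p1) * n, axis=-1)
    p_star = P - h[:, None] * n

    u = p2 - p1
    v = p3 - p1
    w_ = np.cross(u, v)
    w2 = np.sum(w_ * w_, axis=-1)
    w2s = np.where(valid, w2, 1.0)[:, None]
    uu = np.sum(u * u, axis=-1, keepdims=True)
    vv = np.sum(v * v, axis=-1, keepdims=True)
    C = p1 + (uu * np.cross(v, w_) + vv * np.cross(w_, u)) / (2.0 * w2s)
    r = np.linalg.norm(C - p1, axis=-1)
    d = np.linalg.norm(C - p_star, axis=-1)

    w_bary = _bary_bulk(p_star, p1, p2, p3, valid)
    w_star = _bary_bulk(C, p1, p2, p3, valid)

    # local length scale: mean neighbor edge length (bounded even when the
    # circumradius diverges for near-collinear triples)
    scale = (np.linalg.norm(p1 - p2, axis=-1) + np.linalg.norm(p2 - p3, axis=-1)
             + np.linalg.norm(p3 - p1, axis=-1)) / 3.0

    theta = _theta_bulk(P, p1, p2, p3, n, h, C, r, valid)
    return {
        "scale": scale,
        "n": n,
        "p_star": p_star,
        "C": C,
        "r": r,
        "d": d,
        "w": w_bary,
        "w_star": w_star,
        "theta": theta,
        "h": h,
        "valid": valid,
    }


def _bary_bulk(q, p1, p2, p3, valid):
    u = p1 - p3
    v = p2 - p3
    b = q - p3
    uu = np.sum(u * u, axis=-1)
    vv = np.sum(v * v, axis=-1)
    uv = np.sum(u * v, axis=-1)
    det = uu * vv - uv * uv
    det = np.where(np.abs(det) < _COPLANAR_TOL, 1.0, det)
    bu = np.sum(b * u, axis=-1)
    bv = np.sum(b * v, axis=-1)
    w1 = (vv * bu - uv * bv) / det
    w2 = (uu * bv - uv * bu) / det
    out = np.stack([w1, w2, 1.0 - w1 - w2], axis=-1)
    out[~valid] = 1.0 / 3.0
    return out


def _theta_bulk(P, p1, p2, p3, n, h, C, r, valid):
    """Simplex angle per vertex; coplanar vertices get theta = 0."""
    theta = np.zeros(len(P))
    scale = np.maximum(r, 1.0)
    elevated = valid & (np.abs(h) > 1e-12 * scale)
    if not np.any(elevated):
        return theta
    idx = np.where(elevated)[0]
    base = P[idx]
    rows = np.stack([p1[idx] - base, p2[idx] - base, p3[idx] - base], axis=-2)
    rhs = 0.5 * np.sum(rows * rows, axis=-1)
    det = np.linalg.det(rows)
    ok = np.abs(det) > 1e-300
    O = np.full((len(idx), 3), np.nan)
    if np.any(ok):
        O[ok] = base[ok] + np.linalg.solve(rows[ok], rhs[ok][..., None])[..., 0]
    R = np.linalg.norm(O - base, axis=-1)
    side = np.sign(h[idx])
    s = (r[idx] / R) * side
    oc = C[idx] - O
    c = (np.linalg.norm(oc, axis=-1) / R) * np.sign(np.sum(oc * n[idx], axis=-1)) * side
    th = np.arctan2(s, c)
    th[~ok] = 0.0
    theta[idx] = th
    return theta
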