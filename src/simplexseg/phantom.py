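"""Synthetic CT-like phantoms with exact analytic ground truth.

The phantoms emulate the imaging situation the segmenter is built for: a
bright organ-like body whose intensity falls inside the soft-tissue window
(default 100 HU, window [-250, 500]) embedded in darker background (default
-1000 HU, i.e. air-like, inside the [-1000, -250] background range), with a
~1-voxel partial-volume blur at the boundary and additive Gaussian noise.
Shapes: a sphere, an ellipsoid, and a "lobed" sphere with a narrow
cylinder-capped protrusion that a coarse fixed mesh cannot enter (exercises
adaptive refinement).  A distractor variant adds an adjacent structure of
out-of-window intensity (default 700 HU, bone-like) touching the body, to
exercise the intensity gate.

All randomness flows from ``rng_seed``; the ground-truth mask is the exact
analytic region, unaffected by blur or noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume_io import BinaryMask, Volume

__all__ = ["PhantomSpec", "make_phantom", "make_distractor_phantom", "distractor_region"]


@dataclass
class PhantomSpec:
    """Geometry and intensity description of a phantom.

    ``size`` is the cubic grid edge in voxels (>= 32).  ``radius`` is the
    body sphere radius / largest ellipsoid semi-axis.  For the lobed shape
    the protrusion extends ``lobe_length`` voxels beyond the sphere surface
    (hemispherical cap included) with radius ``lobe_radius`` along
    ``lobe_dir``.  The distractor phantom places a sphere of
    ``distractor_radius`` and ``distractor_intensity`` touching the body
    along ``lobe_dir``.
    """

    shape: str = "sphere"  # sphere | ellipsoid | lobed
    size: int = 64
    radius: float = 20.0
    semi_axes: tuple[float, float, float] = (20.0, 16.0, 13.0)
    body_intensity: float = 100.0
    background_intensity: float = -1000.0
    noise_sigma: float = 10.0
    lobe_dir: tuple[float, float, float] = (1.0, 0.0, 0.0)
    lobe_length: float = 14.0
    lobe_radius: float = 4.0
    distractor_intensity: float = 700.0
    distractor_radius: float = 10.0
    rng_seed: int = 0
    boundary_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "ellipsoid", "lobed"):
            raise ValueError(f"unknown phantom shape {self.shape!r}")
        if self.size < 32:
            raise ValueError("size must be >= 32")
        if self.radius <= 0 or self.lobe_radius <= 0:
            raise ValueError("radii must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    @property
    def center(self) -> np.ndarray:
        return np.full(3, (self.size - 1) / 2.0)


def _grid(size: int) -> np.ndarray:
    ax = np.arange(size, dtype=np.float64)
    return np.stack(np.meshgrid(ax, ax, ax, indexing="ij"), axis=-1)


def _body_mask(spec: PhantomSpec) -> np.ndarray:
    g = _grid(spec.size) - spec.center
    if spec.shape == "sphere":
        return np.sum(g * g, axis=-1) <= spec.radius**2
    if spec.shape == "ellipsoid":
        a = np.asarray(spec.semi_axes, np.float64)
        return np.sum((g / a) ** 2, axis=-1) <= 1.0
    # lobed: sphere plus a capsule whose tip (cap included) protrudes
    # lobe_length beyond the sphere surface
    d = np.asarray(spec.lobe_dir, np.float64)
    d = d / np.linalg.norm(d)
    seg_end = spec.radius + spec.lobe_length - spec.lobe_radius
    tip = spec.center + d * (seg_end + spec.lobe_radius)
    if np.any(tip + 2 > spec.size - 1) or np.any(tip - 2 < 0):
        raise ValueError("lobe exits the grid; enlarge size or shorten the lobe")
    t = np.clip(np.sum(g * d, axis=-1), 0.0, seg_end)
    closest = t[..., None] * d
    in_capsule = np.sum((g - closest) ** 2, axis=-1) <= spec.lobe_radius**2
    in_sphere = np.sum(g * g, axis=-1) <= spec.radius**2
    return in_sphere | in_capsule


def _render(intensity: np.ndarray, spec: PhantomSpec) -> Volume:
    smoothed = ndimage.gaussian_filter(intensity, spec.boundary_sigma, mode="nearest")
    rng = np.random.default_rng(spec.rng_seed)
    noisy = smoothed + rng.normal(0.0, spec.noise_sigma, smoothed.shape)
    return Volume(data=noisy)


def make_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask]:
    """Render the phantom volume and its exact ground-truth mask."""
    body = _body_mask(spec)
    intensity = np.where(body, spec.body_intensity, spec.background_intensity)
    return _render(intensity.astype(np.float64), spec), BinaryMask(data=body)


def make_distractor_phantom(spec: PhantomSpec) -> tuple[Volume, BinaryMask]:
    """Phantom plus an out-of-window structure touching the body.

    The distractor sphere is placed along ``lobe_dir`` with a one-voxel
    overlap so the smoothed interface has no background gap; the ground
    truth excludes it (distractor voxels override body voxels in the
    rendered intensity only where the body does not reach).
    """
    body = _body_mask(spec)
    d = np.asarray(spec.lobe_dir, np.float64)
    d = d / np.linalg.norm(d)
    offset = spec.radius + spec.distractor_radius - 1.0
    dc = spec.center + d * offset
    if np.any(dc + spec.distractor_radius + 2 > spec.size - 1) or np.any(
            dc - spec.distractor_radius - 2 < 0):
        raise ValueError("distractor exits the grid; enlarge size")
    g = _grid(spec.size)
    distractor = np.sum((g - dc) ** 2, axis=-1) <= spec.distractor_radius**2
    distractor &= ~body
    intensity = np.where(body, spec.body_intensity, spec.background_intensity)
    intensity = np.where(distractor, spec.distractor_intensity, intensity)
    vol = _render(intensity.astype(np.float64), spec)
    return vol, BinaryMask(data=body)


def distractor_region(spec: PhantomSpec) -> BinaryMask:
    """The distractor voxels of :func:`make_distractor_phantom` (for leakage
    measurements)."""
    body = _body_mask(spec)
    d = np.asarray(spec.lobe_dir, np.float64)
    d = d / np.linalg.norm(d)
    dc = spec.center + d * (spec.radius + spec.distractor_radius - 1.0)
    g = _grid(spec.size)
    distractor = np.sum((g - dc) ** 2, axis=-1) <= spec.distractor_radius**2
    return BinaryMask(data=distractor & ~body)
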