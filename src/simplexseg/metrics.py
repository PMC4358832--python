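"""Volumetric and surface evaluation criteria between two segmentations.

With A the predicted mask and B the ground truth:

* VOE  = 100 (1 - |A ∩ B| / |A ∪ B|)          volumetric overlap error, %
* RVD  = 100 (|A| - |B|) / |B|                relative volume difference, %
  (signed; over-segmentation positive)
* ASSD / RMSSSD / MSSD: mean / root-mean-square / maximum of the pooled
  symmetric nearest-surface distances (A-surface to B-surface and vice
  versa), in mm.  Surfaces are the border voxels of each mask (6-connected
  erosion difference); distances are measured between border-voxel centers
  with anisotropic spacing honored.
* SADE: mean distance (mm) from deformable-model vertices to the nearest
  ground-truth surface voxel center, evaluated by trilinear lookup in the
  surface distance transform; tracked per iteration during evolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .simplex_mesh import SimplexMesh
from .volume_io import BinaryMask

__all__ = [
    "MetricsReport",
    "overlap_metrics",
    "surface_distance_metrics",
    "sade",
    "evaluate_masks",
    "mask_surface",
]

_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass
class MetricsReport:
    voe: float  # %
    rvd: float  # %, signed
    assd: float  # mm
    rmsssd: float  # mm
    mssd: float  # mm
    sade: float | None = None  # mm, mesh-based

    def as_dict(self) -> dict:
        out = {"voe": self.voe, "rvd": self.rvd, "assd": self.assd,
               "rmsssd": self.rmsssd, "mssd": self.mssd}
        if self.sade is not None:
            out["sade"] = self.sade
        return out


def _check_geometry(pred: BinaryMask, truth: BinaryMask) -> None:
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    if not np.allclose(pred.spacing, truth.spacing):
        raise ValueError(f"spacing mismatch: {pred.spacing} vs {truth.spacing}")


def overlap_metrics(pred: BinaryMask, truth: BinaryMask) -> tuple[float, float]:
    """(VOE %, signed RVD %)."""
    _check_geometry(pred, truth)
    a = pred.data.astype(bool)
    b = truth.data.astype(bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both masks empty: VOE undefined")
    nb = np.count_nonzero(b)
    if nb == 0:
        raise ValueError("empty ground truth: RVD undefined")
    inter = np.count_nonzero(a & b)
    voe = 100.0 * (1.0 - inter / union)
    rvd = 100.0 * (np.count_nonzero(a) - nb) / nb
    return float(voe), float(rvd)


def mask_surface(mask: BinaryMask) -> np.ndarray:
    """Boolean array of border voxels (mask minus its 6-connected erosion)."""
    m = mask.data.astype(bool)
    er = ndimage.binary_erosion(m, structure=_STRUCT6, border_value=0)
    return m & ~er


def _surface_distance_field(mask: BinaryMask) -> np.ndarray:
    """Distance (mm) from every voxel center to the nearest surface voxel center."""
    surf = mask_surface(mask)
    if not surf.any():
        raise ValueError("mask has no surface voxels (empty mask)")
    return ndimage.distance_transform_edt(~surf, sampling=mask.spacing)


def surface_distance_metrics(pred: BinaryMask, truth: BinaryMask) -> tuple[float, float, float]:
    """(ASSD, RMSSSD, MSSD) in mm from the pooled symmetric distance set."""
    _check_geometry(pred, truth)
    surf_a = mask_surface(pred)
    surf_b = mask_surface(truth)
    if not surf_a.any() or not surf_b.any():
        raise ValueError("empty mask: surface distances undefined")
    dist_to_b = ndimage.distance_transform_edt(~surf_b, sampling=pred.spacing)
    dist_to_a = ndimage.distance_transform_edt(~surf_a, sampling=pred.spacing)
    pooled = np.concatenate([dist_to_b[surf_a], dist_to_a[surf_b]])
    return (float(pooled.mean()),
            float(np.sqrt(np.mean(pooled**2))),
            float(pooled.max()))


def _sade_from_field(mesh: SimplexMesh, field: np.ndarray, spacing) -> float:
    pts = mesh.positions.T
    vals = ndimage.map_coordinates(field, pts, order=1, mode="nearest")
    return float(vals.mean())


def sade(mesh: SimplexMesh, truth: BinaryMask) -> float:
    """Mean vertex-to-truth-surface distance (mm), trilinear DT lookup."""
    field = _surface_distance_field(truth)
    return _sade_from_field(mesh, field, truth.spacing)


def evaluate_masks(pred: BinaryMask, truth: BinaryMask,
                   mesh: SimplexMesh | None = None) -> MetricsReport:
    """All criteria in one report; SADE included when a mesh is given."""
    voe, rvd = overlap_metrics(pred, truth)
    assd, rmsssd, mssd = surface_distance_metrics(pred, truth)
    s = sade(mesh, truth) if mesh is not None else None
    return MetricsReport(voe=voe, rvd=rvd, assd=assd, rmsssd=rmsssd, mssd=mssd, sade=s)
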