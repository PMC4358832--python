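"""Volume and mesh I/O plus the coordinate contract shared by all modules.

Coordinate convention
---------------------
Internally every module works in continuous 0-based voxel-index coordinates
with ``data`` indexed ``data[x, y, z]`` and voxel centers at integer indices.
World coordinates (mm) enter only at mesh export and in the metrics:
``world = origin + index * spacing``.  Axis order is (x, y, z) in both the
array and the ``spacing``/``origin`` vectors, matching the on-disk order of
NIfTI and MetaImage headers.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import SimpleITK as sitk
import trimesh

__all__ = [
    "Volume",
    "BinaryMask",
    "VolumeFormatError",
    "read_volume",
    "read_mask",
    "write_volume",
    "write_mesh",
]

_VOLUME_SUFFIXES = (".nii", ".nii.gz", ".mhd", ".mha")


class VolumeFormatError(ValueError):
    """Unreadable or unsupported volume file."""


def _check_grid(data: np.ndarray, spacing, name: str) -> None:
    if data.ndim != 3:
        raise ValueError(f"{name}.data must be 3-D, got ndim={data.ndim}")
    if min(data.shape) < 2:
        raise ValueError(f"{name}.data needs every dimension >= 2, got {data.shape}")
    spacing = np.asarray(spacing, dtype=float)
    if spacing.shape != (3,) or not np.all(spacing > 0):
        raise ValueError(f"{name}.spacing must be 3 positive components, got {spacing}")


@dataclass
class Volume:
    """A 3-D scalar grid (intensity in arbitrary units / HU) with geometry."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        _check_grid(self.data, self.spacing, "Volume")
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


@dataclass
class BinaryMask:
    """A {0,1} grid with the same geometry contract as :class:`Volume`."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        _check_grid(data, self.spacing, "BinaryMask")
        vals = np.unique(data)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError(f"BinaryMask values must be in {{0,1}}, got {vals[:10]}")
        self.data = data.astype(np.uint8)
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def _check_suffix(path: str) -> None:
    p = str(path).lower()
    if not p.endswith(_VOLUME_SUFFIXES):
        raise VolumeFormatError(
            f"unsupported volume format for {path!r}; expected one of {_VOLUME_SUFFIXES}"
        )


def read_volume(path) -> Volume:
    """Read a NIfTI (.nii/.nii.gz) or MetaImage (.mhd/.mha) volume.

    Intensities are returned unchanged; spacing and origin come from the
    header.  The SimpleITK (z, y, x) array order is transposed to the
    package's (x, y, z) convention.
    """
    _check_suffix(path)
    if not os.path.exists(path):
        raise VolumeFormatError(f"no such file: {path}")
    try:
        img = sitk.ReadImage(str(path))
    except RuntimeError as exc:  # pragma: no cover - corrupt files
        raise VolumeFormatError(f"could not read {path}: {exc}") from exc
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    return Volume(data=data, spacing=tuple(img.GetSpacing()), origin=tuple(img.GetOrigin()))


def read_mask(path) -> BinaryMask:
    """Read a binary mask; nonzero voxels become 1."""
    vol = read_volume(path)
    return BinaryMask(data=(vol.data != 0), spacing=vol.spacing, origin=vol.origin)


def write_volume(vol: Volume | BinaryMask, path) -> None:
    """Write a volume or mask; round-trip exact for integer data."""
    _check_suffix(path)
    parent = os.path.dirname(os.path.abspath(str(path)))
    if not os.path.isdir(parent):
        raise FileNotFoundError(f"parent directory does not exist: {parent}")
    img = sitk.GetImageFromArray(np.ascontiguousarray(vol.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in vol.spacing))
    img.SetOrigin(tuple(float(o) for o in vol.origin))
    try:
        sitk.WriteImage(img, str(path))
    except RuntimeError as exc:  # pragma: no cover
        raise OSError(f"could not write {path}: {exc}") from exc


def write_mesh(mesh, path, spacing=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0)) -> None:
    """Export a mesh surface as PLY with vertices in world mm coordinates.

    Accepts either a ``SimplexMesh`` (its dual triangulation is exported) or a
    ``DualTriangulation``.  Vertex coordinates are converted from voxel-index
    space via ``world = origin + index * spacing``.
    """
    # local import: simplex_mesh depends on nothing here, avoid cycles at import time
    from .simplex_mesh import DualTriangulation, SimplexMesh, dual_triangulation, validate

    if isinstance(mesh, SimplexMesh):
        report = validate(mesh)
        if not report.ok:
            raise ValueError(f"invalid mesh: {report.violations[:3]}")
        tri = dual_triangulation(mesh)
    elif isinstance(mesh, DualTriangulation):
        tri = mesh
    else:
        raise TypeError(f"cannot export object of type {type(mesh).__name__}")
    if len(tri.tri_vertices) == 0 or len(tri.triangles) == 0:
        raise ValueError("cannot export an empty mesh")
    verts = np.asarray(origin, float) + np.asarray(tri.tri_vertices, float) * np.asarray(
        spacing, float
    )
    tm = trimesh.Trimesh(vertices=verts, faces=np.asarray(tri.triangles), process=False)
    tm.export(str(path))
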