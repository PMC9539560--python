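"""Mesh and point-cloud I/O for root CT scans.

CT systems export segmented roots as triangulated surface meshes (STL).
This module reads those meshes, converts them to point clouds by keeping
vertices where the discrete surface curvature changes, and applies the
scale factor (SF) — the single user parameter of the pipeline.  SF
multiplies the input coordinates; every downstream geometric parameter
(patch size, minimum cylinder length) is a fixed constant in scaled
units, so a larger SF yields relatively finer cylinders.  Physical
traits are recovered by dividing reported lengths by SF (areas by SF²,
volumes by SF³).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import trimesh

log = logging.getLogger(__name__)

#: minimum point count below which curvature selection falls back to all vertices
MIN_POINTS_FALLBACK = 1000


class STLFormatError(ValueError):
    """Raised when an STL file cannot be parsed."""


@dataclass
class TriMesh:
    """Triangulated surface mesh in input units ("ud")."""

    vertices: np.ndarray  # (n, 3) float
    faces: np.ndarray     # (m, 3) int

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise ValueError("vertices must be (n, 3)")
        if len(self.faces) and self.faces.max() >= len(self.vertices):
            raise ValueError("face index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


@dataclass
class PointCloud:
    """3D points in scaled units (input coordinates × SF)."""

    points: np.ndarray
    scale_factor: float = 1.0
    source_unit: str = "ud"

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        if self.points.shape[0] < 1 or self.points.shape[1] != 3:
            raise ValueError("point cloud needs >= 1 point with 3 coordinates")
        if not np.all(np.isfinite(self.points)):
            raise ValueError("point coordinates must be finite")
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be positive")

    def __len__(self) -> int:
        return len(self.points)


def read_stl(path) -> TriMesh:
    """Read a binary or ASCII STL file into a cleaned :class:`TriMesh`.

    Duplicate vertices are merged (tolerance 1e-9 × bounding-box
    diagonal) and degenerate faces dropped.  Raises
    :class:`STLFormatError` for malformed files and ``ValueError`` for
    empty meshes.
    """
    import os

    if not os.path.exists(path):
        raise FileNotFoundError(f"STL file not found: {path}")
    try:
        mesh = trimesh.load_mesh(str(path), file_type="stl", process=False)
    except FileNotFoundError:
        raise
    except Exception as exc:  # trimesh raises assorted types for bad bytes
        raise STLFormatError(f"cannot parse STL file {path!s}: {exc}") from exc
    if mesh.is_empty or len(mesh.faces) == 0:
        raise ValueError(f"STL file {path!s} contains no facets")
    diag = float(np.linalg.norm(mesh.vertices.max(0) - mesh.vertices.min(0)))
    tol = 1e-9 * diag if diag > 0 else 1e-12
    mesh.merge_vertices(digits_vertex=max(1, int(-np.log10(tol))) if tol > 0 else 10)
    mesh.update_faces(mesh.nondegenerate_faces())
    mesh.remove_unreferenced_vertices()
    out = TriMesh(np.asarray(mesh.vertices), np.asarray(mesh.faces))
    log.info("read %s: %d vertices, %d faces", path, out.n_vertices, out.n_faces)
    return out


def _vertex_curvature(mesh: TriMesh) -> np.ndarray:
    """Discrete mean-curvature proxy per vertex.

    Angle deficit (2π − Σ incident angles) divided by one third of the
    incident triangle area — the standard Gaussian-curvature estimate on
    a triangle fan, adequate as a change detector.
    """
    v, f = mesh.vertices, mesh.faces
    angle_sum = np.zeros(len(v))
    area_acc = np.zeros(len(v))
    tri = v[f]  # (m, 3, 3)
    # angles at each corner of each face
    for corner in range(3):
        a = tri[:, corner]
        b = tri[:, (corner + 1) % 3]
        c = tri[:, (corner + 2) % 3]
        u1, u2 = b - a, c - a
        n1 = np.linalg.norm(u1, axis=1)
        n2 = np.linalg.norm(u2, axis=1)
        denom = np.where(n1 * n2 > 0, n1 * n2, 1.0)
        cosang = np.clip((u1 * u2).sum(1) / denom, -1.0, 1.0)
        np.add.at(angle_sum, f[:, corner], np.arccos(cosang))
    areas = 0.5 * np.linalg.norm(
        np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
    )
    for corner in range(3):
        np.add.at(area_acc, f[:, corner], areas / 3.0)
    deficit = 2.0 * np.pi - angle_sum
    with np.errstate(divide="ignore", invalid="ignore"):
        curv = np.where(area_acc > 0, deficit / area_acc, 0.0)
    return curv


def mesh_to_pointcloud(
    mesh: TriMesh,
    sf: float,
    curvature_threshold: float = 0.0,
    min_points: int = MIN_POINTS_FALLBACK,
) -> PointCloud:
    """Convert a mesh to a scaled point cloud by curvature-change sampling.

    Vertices whose curvature measure deviates from the global median by
    more than ``curvature_threshold`` are kept; selection happens before
    scaling, so it is independent of SF.  If fewer than ``min_points``
    survive, all vertices are used (with a warning) to keep the pipeline
    total.
    """
    if sf <= 0:
        raise ValueError("scale factor must be positive")
    if mesh.n_vertices == 0:
        raise ValueError("empty mesh")
    if curvature_threshold > 0:
        curv = _vertex_curvature(mesh)
        dev = np.abs(curv - np.median(curv))
        keep = dev > curvature_threshold
        if keep.sum() < min_points:
            warnings.warn(
                f"curvature selection kept {int(keep.sum())} < {min_points} "
                "points; falling back to all vertices",
                stacklevel=2,
            )
            keep = np.ones(mesh.n_vertices, dtype=bool)
    else:
        keep = np.ones(mesh.n_vertices, dtype=bool)
    return PointCloud(mesh.vertices[keep] * sf, scale_factor=sf)


def write_pointcloud(cloud: PointCloud, path, fmt: str = "xyz") -> None:
    """Write a point cloud as whitespace XYZ or ASCII PLY."""
    if fmt == "xyz":
        np.savetxt(path, cloud.points, fmt="%.10g")
    elif fmt == "ply":
        with open(path, "w") as fh:
            fh.write(
                "ply\nformat ascii 1.0\n"
                f"element vertex {len(cloud)}\n"
                "property float x\nproperty float y\nproperty float z\n"
                "end_header\n"
            )
            for p in cloud.points:
                fh.write(f"{p[0]:.10g} {p[1]:.10g} {p[2]:.10g}\n")
    else:
        raise ValueError(f"unknown point cloud format: {fmt!r}")


def read_pointcloud(path, fmt: str = "xyz", scale_factor: float = 1.0) -> PointCloud:
    """Read a point cloud written by :func:`write_pointcloud`."""
    if fmt == "xyz":
        pts = np.loadtxt(path, ndmin=2)
    elif fmt == "ply":
        with open(path) as fh:
            lines = fh.read().splitlines()
        start = lines.index("end_header") + 1
        pts = np.array([[float(x) for x in ln.split()[:3]] for ln in lines[start:] if ln.strip()])
    else:
        raise ValueError(f"unknown point cloud format: {fmt!r}")
    return PointCloud(pts, scale_factor=scale_factor)


def depth_colored_view(cloud: PointCloud) -> np.ndarray:
    """Per-point normalized depth in [0, 1] (0 = shallowest, 1 = deepest).

    Depth increases downward along −z from the topmost point.  A flat
    cloud maps to 0.5 everywhere with a warning.
    """
    z = cloud.points[:, 2]
    depth = z.max() - z
    rng = depth.max() - depth.min()
    if rng == 0:
        warnings.warn("all points at the same depth; returning 0.5", stacklevel=2)
        return np.full(len(cloud), 0.5)
    return (depth - depth.min()) / rng
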