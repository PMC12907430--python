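"""Readers, writers and validated containers for surfaces and centerlines.

The estimator consumes two geometric inputs that must share one Cartesian
frame in millimetres:

* a triangulated surface of the aortic root / ascending aorta (STL or PLY),
* an ordered coronary centerline sampled proximal-to-distal (CSV with
  columns ``x,y,z``).

No unit or orientation metadata is read from the files: coordinates are
taken as millimetres in whatever frame the upstream segmentation used, and
the only contract is that mesh and centerline share that frame.
"""

from __future__ import annotations

import json
import math
import os
import warnings
from dataclasses import dataclass, field

import numpy as np
import trimesh

from imlen.errors import (
    CenterlineError,
    DuplicatePointWarning,
    EmptyMeshError,
    MeshReadError,
    MeshValidationError,
    NonFiniteCoordinateError,
    ResultWriteError,
)

_AREA_EPS = 1e-12


@dataclass
class TriangleMesh:
    """A validated triangulated surface.

    Attributes
    ----------
    vertices : (V, 3) float array, mm
    faces : (F, 3) int array of vertex indices
    is_watertight : bool
        True when every undirected edge is shared by exactly two faces.
    """

    vertices: np.ndarray
    faces: np.ndarray
    is_watertight: bool
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    @classmethod
    def from_arrays(cls, vertices, faces) -> "TriangleMesh":
        """Validate raw arrays and build a mesh.

        Zero-area faces are dropped; the watertightness flag is computed
        with the edge-manifold test. Raises the distinct error types for
        non-finite coordinates, empty geometry and index violations.
        """
        vertices = np.ascontiguousarray(vertices, dtype=np.float64)
        faces = np.ascontiguousarray(faces, dtype=np.int64)
        if vertices.size == 0 or faces.size == 0:
            raise EmptyMeshError("mesh has no vertices or no faces")
        if vertices.ndim != 2 or vertices.shape[1] != 3:
            raise MeshValidationError(f"vertices must be (V, 3), got {vertices.shape}")
        if faces.ndim != 2 or faces.shape[1] != 3:
            raise MeshValidationError(f"faces must be (F, 3), got {faces.shape}")
        if not np.isfinite(vertices).all():
            raise NonFiniteCoordinateError("mesh vertices contain NaN or inf")
        if faces.min() < 0 or faces.max() >= len(vertices):
            raise MeshValidationError("face indices out of range")

        # drop degenerate (zero-area) triangles
        tri = vertices[faces]
        areas = 0.5 * np.linalg.norm(
            np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1
        )
        faces = faces[areas > _AREA_EPS]

        if len(vertices) < 4 or len(faces) < 4:
            raise MeshValidationError(
                f"a usable surface needs >=4 vertices and >=4 faces, "
                f"got {len(vertices)} vertices / {len(faces)} non-degenerate faces"
            )
        return cls(vertices=vertices, faces=faces,
                   is_watertight=_edge_manifold(faces))

    def __len__(self) -> int:
        return len(self.vertices)

    @property
    def kdtree(self):
        """k-d tree over the vertices (built once, cached)."""
        if "kdtree" not in self._cache:
            from scipy.spatial import cKDTree

            self._cache["kdtree"] = cKDTree(self.vertices)
        return self._cache["kdtree"]

    @property
    def vertex_pseudo_normals(self) -> np.ndarray:
        """Angle-weighted pseudo-normals at every vertex (unit where defined).

        Each incident face contributes its normal weighted by the corner
        angle at the vertex; the sum is normalised. Vertices with a
        degenerate accumulated normal keep a zero vector.
        """
        if "pnormals" not in self._cache:
            self._cache["pnormals"] = _angle_weighted_normals(self.vertices, self.faces)
        return self._cache["pnormals"]

    def edge_lengths(self) -> np.ndarray:
        """Lengths of all unique undirected edges, mm."""
        e = np.sort(
            np.concatenate([self.faces[:, [0, 1]], self.faces[:, [1, 2]],
                            self.faces[:, [2, 0]]]),
            axis=1,
        )
        e = np.unique(e, axis=0)
        return np.linalg.norm(self.vertices[e[:, 0]] - self.vertices[e[:, 1]], axis=1)

    def as_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)


def _edge_manifold(faces: np.ndarray) -> bool:
    """True iff every undirected edge is shared by exactly two faces."""
    e = np.sort(
        np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]]),
        axis=1,
    )
    _, counts = np.unique(e, axis=0, return_counts=True)
    return bool((counts == 2).all())


def _angle_weighted_normals(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    tri = vertices[faces]
    fn = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    norms = np.linalg.norm(fn, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    fn = fn / norms

    out = np.zeros_like(vertices)
    for corner in range(3):
        a = tri[:, (corner + 1) % 3] - tri[:, corner]
        b = tri[:, (corner + 2) % 3] - tri[:, corner]
        na = np.linalg.norm(a, axis=1)
        nb = np.linalg.norm(b, axis=1)
        cosang = np.einsum("ij,ij->i", a, b) / np.maximum(na * nb, 1e-300)
        ang = np.arccos(np.clip(cosang, -1.0, 1.0))
        np.add.at(out, faces[:, corner], fn * ang[:, None])

    n = np.linalg.norm(out, axis=1, keepdims=True)
    good = n[:, 0] > 1e-12
    out[good] /= n[good]
    out[~good] = 0.0
    return out


def read_mesh(path: str | os.PathLike, format: str = "auto") -> TriangleMesh:
    """Read an STL (binary or ASCII) or PLY surface.

    ``format`` may be ``stl``, ``ply`` or ``auto`` (extension-based).
    Duplicate vertices (STL stores a triangle soup) are merged so that the
    vertex-based distance queries and the watertightness test are meaningful.
    """
    path = os.fspath(path)
    if not os.path.isfile(path):
        raise MeshReadError(f"mesh file not found: {path}")
    if format not in ("auto", "stl", "ply"):
        raise MeshReadError(f"unsupported mesh format: {format!r}")
    try:
        loaded = trimesh.load_mesh(
            path, file_type=None if format == "auto" else format, process=False
        )
    except Exception as exc:  # trimesh raises a mix of types on bad input
        raise MeshReadError(f"could not parse mesh file {path}: {exc}") from exc
    if isinstance(loaded, trimesh.Scene):
        geoms = list(loaded.geometry.values())
        if not geoms:
            raise EmptyMeshError(f"no geometry in {path}")
        loaded = trimesh.util.concatenate(geoms)
    vertices = np.asarray(loaded.vertices, dtype=np.float64)
    faces = np.asarray(loaded.faces, dtype=np.int64)
    if vertices.size == 0 or faces.size == 0:
        raise EmptyMeshError(f"no geometry in {path}")
    if not np.isfinite(vertices).all():
        raise NonFiniteCoordinateError(f"non-finite coordinates in {path}")
    merged = trimesh.Trimesh(vertices, faces, process=True)  # merge soup vertices
    return TriangleMesh.from_arrays(np.asarray(merged.vertices),
                                    np.asarray(merged.faces))


def write_mesh(mesh: TriangleMesh, path: str | os.PathLike) -> None:
    """Write a mesh to STL or PLY (chosen by extension)."""
    mesh.as_trimesh().export(os.fspath(path))


@dataclass
class Centerline:
    """Ordered 3D polyline with cumulative chord-length arc length.

    ``points`` run proximal to distal; ``cum_arc[i]`` is the summed
    Euclidean chord length from the first point, so ``cum_arc[0] == 0``.
    """

    points: np.ndarray
    cum_arc: np.ndarray

    @classmethod
    def from_points(cls, points) -> "Centerline":
        points = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if points.ndim != 2 or points.shape[1] != 3:
            raise CenterlineError(f"centerline points must be (N, 3), got {points.shape}")
        if not np.isfinite(points).all():
            raise NonFiniteCoordinateError("centerline contains non-finite coordinates")
        if len(points) >= 2:
            steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
            keep = np.concatenate([[True], steps > 0.0])
            if not keep.all():
                warnings.warn(
                    f"dropped {int((~keep).sum())} duplicate consecutive "
                    "centerline point(s)",
                    DuplicatePointWarning,
                    stacklevel=2,
                )
                points = points[keep]
        if len(points) < 2:
            raise CenterlineError("centerline needs at least 2 distinct points")
        steps = np.linalg.norm(np.diff(points, axis=0), axis=1)
        cum_arc = np.concatenate([[0.0], np.cumsum(steps)])
        return cls(points=points, cum_arc=cum_arc)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length_mm(self) -> float:
        return float(self.cum_arc[-1])

    @property
    def median_spacing_mm(self) -> float:
        return float(np.median(np.diff(self.cum_arc)))


def read_centerline(path: str | os.PathLike) -> Centerline:
    """Read a centerline from a CSV with header columns ``x,y,z`` (mm)."""
    import pandas as pd

    path = os.fspath(path)
    if not os.path.isfile(path):
        raise CenterlineError(f"centerline file not found: {path}")
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise CenterlineError(f"could not parse centerline CSV {path}: {exc}") from exc
    missing = [c for c in ("x", "y", "z") if c not in df.columns]
    if missing:
        raise CenterlineError(f"centerline CSV {path} missing columns: {missing}")
    try:
        pts = df[["x", "y", "z"]].apply(lambda col: col.astype(np.float64)).to_numpy()
    except (TypeError, ValueError) as exc:
        raise CenterlineError(f"non-numeric cell in centerline CSV {path}: {exc}") from exc
    return Centerline.from_points(pts)


def write_centerline(centerline: Centerline, path: str | os.PathLike) -> None:
    import pandas as pd

    pd.DataFrame(centerline.points, columns=["x", "y", "z"]).to_csv(path, index=False)


@dataclass
class EstimateResult:
    """Output of the end-to-end IM length estimator.

    ``im_length_mm`` equals the fitted transition point ``k``; ``c`` is
    ``nan`` when the transition lies beyond the fitted window so the second
    slope has no supporting data.
    """

    im_length_mm: float
    a: float
    b: float
    c: float
    k: float
    window_mm: float
    spacing_mm: float
    sse: float
    ostium_offset_mm: float
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        def _f(v):
            v = float(v)
            return None if math.isnan(v) else v

        return {
            "im_length_mm": _f(self.im_length_mm),
            "a": _f(self.a),
            "b": _f(self.b),
            "c": _f(self.c),
            "k": _f(self.k),
            "window_mm": _f(self.window_mm),
            "spacing_mm": _f(self.spacing_mm),
            "sse": _f(self.sse),
            "ostium_offset_mm": _f(self.ostium_offset_mm),
            "warnings": list(self.warnings),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EstimateResult":
        def _f(v):
            return math.nan if v is None else float(v)

        return cls(
            im_length_mm=_f(d["im_length_mm"]),
            a=_f(d["a"]), b=_f(d["b"]), c=_f(d["c"]), k=_f(d["k"]),
            window_mm=_f(d["window_mm"]), spacing_mm=_f(d["spacing_mm"]),
            sse=_f(d["sse"]), ostium_offset_mm=_f(d["ostium_offset_mm"]),
            warnings=list(d.get("warnings", [])),
        )


def write_result(result: EstimateResult, path: str | os.PathLike) -> None:
    """Serialize a result to JSON at full float precision.

    Undefined values (an unsupported second slope) are stored as JSON null.
    """
    try:
        with open(os.fspath(path), "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise ResultWriteError(f"cannot write result to {path}: {exc}") from exc


def read_result(path: str | os.PathLike) -> EstimateResult:
    with open(os.fspath(path)) as fh:
        return EstimateResult.from_dict(json.load(fh))
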