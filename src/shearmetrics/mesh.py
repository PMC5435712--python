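"""Triangulated vessel-wall surfaces with lumped node areas and named regions.

The surface of a vessel model is represented as an indexed triangle mesh.
Area statistics (regional means, thresholded area ratios) are computed over
*node-lumped* areas: every triangle contributes one third of its area to each
of its three vertices.  Barycentric lumping keeps all node areas positive and
makes area ratios reproducible bit-for-bit, independent of triangle ordering.

Coordinates are in millimetres; areas in mm².
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh


class MeshFormatError(ValueError):
    """Raised when a mesh file cannot be read or contains no triangles."""


@dataclass
class SurfaceMesh:
    """Indexed triangle surface with per-node lumped areas.

    Parameters
    ----------
    vertices : (n, 3) float array, mm
    triangles : (m, 3) int array of vertex indices (0-based)
    wall_labels : optional (n,) bool array; True marks vessel-wall nodes.
        Inlet/outlet cap nodes, when labelled, are excluded from area
        statistics. When absent every node counts as wall.
    """

    vertices: np.ndarray
    triangles: np.ndarray
    wall_labels: np.ndarray | None = None
    node_areas: np.ndarray = field(init=False)
    wall_mask: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float).reshape(-1, 3)
        self.triangles = np.asarray(self.triangles, dtype=np.int64).reshape(-1, 3)
        n = len(self.vertices)
        if len(self.triangles) == 0:
            raise MeshFormatError("mesh has no triangles")
        if self.triangles.min() < 0 or self.triangles.max() >= n:
            raise MeshFormatError("triangle references an out-of-range vertex")
        tri_areas = self.triangle_areas()
        if np.any(tri_areas <= 0.0):
            raise MeshFormatError("mesh contains degenerate (zero-area) triangles")
        # barycentric (one-third) lumping
        areas = np.zeros(n)
        np.add.at(areas, self.triangles.ravel(),
                  np.repeat(tri_areas / 3.0, 3))
        self.node_areas = areas
        if self.wall_labels is not None:
            wl = np.asarray(self.wall_labels, dtype=bool).reshape(-1)
            if wl.shape != (n,):
                raise ValueError("wall_labels length must match vertex count")
            self.wall_mask = np.flatnonzero(wl)
        else:
            self.wall_mask = np.arange(n)

    @property
    def n_nodes(self) -> int:
        return len(self.vertices)

    def triangle_areas(self) -> np.ndarray:
        p = self.vertices
        a, b, c = (p[self.triangles[:, k]] for k in range(3))
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def total_area(self) -> float:
        """Total surface area (all triangles), mm²."""
        return float(self.triangle_areas().sum())

    def wall_area(self) -> float:
        """Lumped area of wall nodes, mm²."""
        return float(self.node_areas[self.wall_mask].sum())

    def whole_wall_mask(self) -> "RegionMask":
        return RegionMask("whole_wall", self.wall_mask)


@dataclass
class RegionMask:
    """Named subset of mesh nodes (e.g. ``inner_arch``, ``whole_wall``)."""

    name: str
    node_ids: np.ndarray

    def __post_init__(self) -> None:
        ids = np.unique(np.asarray(self.node_ids, dtype=np.int64).reshape(-1))
        if ids.size == 0:
            raise ValueError(f"region mask {self.name!r} is empty")
        self.node_ids = ids

    def validate(self, mesh: SurfaceMesh) -> None:
        if not np.isin(self.node_ids, mesh.wall_mask).all():
            raise ValueError(
                f"region mask {self.name!r} contains non-wall node ids")


def region_area(mesh: SurfaceMesh, mask: RegionMask) -> float:
    """Lumped area (mm²) of the nodes in ``mask``."""
    mask.validate(mesh)
    return float(mesh.node_areas[mask.node_ids].sum())


# ---------------------------------------------------------------------------
# file I/O

def load_mesh(path: str | Path, fmt: str | None = None) -> SurfaceMesh:
    """Read a surface mesh from STL (binary or ASCII) or legacy VTK.

    STL stores a triangle soup; duplicate vertices are welded on load, so the
    node count equals the number of geometrically distinct vertices. Welding
    is deterministic (first occurrence order).
    """
    path = Path(path)
    if not path.exists():
        raise MeshFormatError(f"mesh file not found: {path}")
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower()
    if fmt == "stl":
        try:
            raw = trimesh.load(path, file_type="stl", process=False)
        except Exception as exc:  # noqa: BLE001 - normalise loader errors
            raise MeshFormatError(f"cannot parse STL file {path}: {exc}") from exc
        verts, tris = _weld(np.asarray(raw.vertices, float),
                            np.asarray(raw.faces, np.int64))
    elif fmt == "vtk":
        verts, tris = _read_legacy_vtk(path)
    else:
        raise MeshFormatError(f"unsupported mesh format: {fmt!r}")
    if len(tris) == 0:
        raise MeshFormatError(f"mesh file {path} contains no triangles")
    return SurfaceMesh(verts, tris)


def _weld(vertices: np.ndarray, faces: np.ndarray):
    """Merge exactly-coincident vertices, keeping first-occurrence order."""
    keys = {}
    remap = np.empty(len(vertices), dtype=np.int64)
    order = []
    for i, v in enumerate(map(tuple, vertices)):
        j = keys.get(v)
        if j is None:
            j = len(order)
            keys[v] = j
            order.append(i)
        remap[i] = j
    return vertices[order], remap[faces]


def save_stl(mesh: SurfaceMesh, path: str | Path) -> None:
    """Write the surface as binary STL (vertex indexing is not preserved)."""
    tm = trimesh.Trimesh(vertices=mesh.vertices, faces=mesh.triangles,
                         process=False)
    tm.export(Path(path), file_type="stl")


def _read_legacy_vtk(path: Path):
    tokens = []
    with open(path) as fh:
        lines = fh.readlines()
    if len(lines) < 4 or "vtk" not in lines[0].lower():
        raise MeshFormatError(f"{path} is not a legacy VTK file")
    for line in lines[2:]:
        tokens.extend(line.split())
    try:
        i = [t.upper() for t in tokens].index("POINTS")
        npts = int(tokens[i + 1])
        coords = np.array(tokens[i + 3:i + 3 + 3 * npts], dtype=float)
        verts = coords.reshape(npts, 3)
        up = [t.upper() for t in tokens]
        j = up.index("POLYGONS")
        ncells = int(tokens[j + 1])
        tris = []
        k = j + 3
        for _ in range(ncells):
            cnt = int(tokens[k])
            if cnt != 3:
                raise MeshFormatError("only triangle polygons are supported")
            tris.append([int(tokens[k + 1]), int(tokens[k + 2]),
                         int(tokens[k + 3])])
            k += cnt + 1
        return verts, np.array(tris, dtype=np.int64)
    except (ValueError, IndexError) as exc:
        raise MeshFormatError(f"cannot parse legacy VTK file {path}") from exc


def save_legacy_vtk(mesh: SurfaceMesh, path: str | Path,
                    point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write legacy-VTK ASCII POLYDATA with optional point scalars."""
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("shearmetrics surface\nASCII\nDATASET POLYDATA\n")
        fh.write(f"POINTS {mesh.n_nodes} double\n")
        for v in mesh.vertices:
            fh.write(f"{v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        m = len(mesh.triangles)
        fh.write(f"POLYGONS {m} {4 * m}\n")
        for t in mesh.triangles:
            fh.write(f"3 {t[0]} {t[1]} {t[2]}\n")
        if point_data:
            fh.write(f"POINT_DATA {mesh.n_nodes}\n")
            for name, values in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                for x in np.asarray(values, float):
                    fh.write(f"{x:.9g}\n")


def save_vtp(mesh: SurfaceMesh, path: str | Path,
             point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write an XML VTP PolyData file (ASCII) with optional point scalars."""

    def arr(values, fmt="{:.9g}"):
        return " ".join(fmt.format(x) for x in np.asarray(values).ravel())

    n, m = mesh.n_nodes, len(mesh.triangles)
    with open(path, "w") as fh:
        fh.write('<?xml version="1.0"?>\n')
        fh.write('<VTKFile type="PolyData" version="0.1" '
                 'byte_order="LittleEndian">\n<PolyData>\n')
        fh.write(f'<Piece NumberOfPoints="{n}" NumberOfPolys="{m}">\n')
        if point_data:
            fh.write("<PointData>\n")
            for name, values in point_data.items():
                fh.write(f'<DataArray type="Float64" Name="{name}" '
                         'format="ascii">\n')
                fh.write(arr(values) + "\n</DataArray>\n")
            fh.write("</PointData>\n")
        fh.write('<Points>\n<DataArray type="Float64" '
                 'NumberOfComponents="3" format="ascii">\n')
        fh.write(arr(mesh.vertices) + "\n</DataArray>\n</Points>\n")
        fh.write("<Polys>\n")
        fh.write('<DataArray type="Int64" Name="connectivity" format="ascii">\n')
        fh.write(arr(mesh.triangles, "{:d}") + "\n</DataArray>\n")
        fh.write('<DataArray type="Int64" Name="offsets" format="ascii">\n')
        fh.write(arr(3 * (np.arange(m) + 1), "{:d}") + "\n</DataArray>\n")
        fh.write("</Polys>\n</Piece>\n</PolyData>\n</VTKFile>\n")


def save_masks_json(masks: dict[str, RegionMask] | list[RegionMask],
                    path: str | Path) -> None:
    if isinstance(masks, dict):
        masks = list(masks.values())
    payload = {m.name: m.node_ids.tolist() for m in masks}
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_masks_json(path: str | Path) -> dict[str, RegionMask]:
    with open(path) as fh:
        payload = json.load(fh)
    return {name: RegionMask(name, ids) for name, ids in payload.items()}
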