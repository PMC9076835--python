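"""Conforming triangular meshing of the planar section.

Strategy: sample every region boundary (and the cavity boundary) at roughly
the target edge length, scatter a hexagonal lattice of interior points kept
clear of the boundaries, take the global Delaunay triangulation of the
combined point set, and keep/label triangles by the region polygon that
contains their centroid.  Because every internal interface is straight and
shared with identical endpoints between neighbouring regions, the boundary
samples coincide and the triangulation conforms to the region layout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon, box

from .geometry import PlanarDomain
from .params import REGIONS


class MeshingError(RuntimeError):
    pass


@dataclass
class TriMesh:
    """Triangle mesh with per-element region labels and node marker sets.

    ``nodes`` is (N, 2) in μm; ``triangles`` is (M, 3) CCW node indices;
    ``region_id[m]`` indexes into ``region_names``.  ``markers`` maps
    boundary-set names (``vascular_base``, ``symmetry_axis``) to node-index
    arrays.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    region_id: np.ndarray
    region_names: tuple[str, ...]
    markers: dict[str, np.ndarray] = field(default_factory=dict)
    half_model: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.triangles)

    def element_areas(self, nodes: np.ndarray | None = None) -> np.ndarray:
        """Signed areas of all triangles (on ``nodes`` if given, else wet)."""
        p = self.nodes if nodes is None else nodes
        a, b, c = (p[self.triangles[:, i]] for i in range(3))
        return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                      - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))

    def region_area(self, region: str, nodes: np.ndarray | None = None) -> float:
        rid = self.region_names.index(region)
        return float(self.element_areas(nodes)[self.region_id == rid].sum())

    @property
    def total_area(self) -> float:
        return float(self.element_areas().sum())

    def region_elements(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region_id == self.region_names.index(region))

    def save(self, path: str | Path) -> None:
        """Write the mesh as a minimal ASCII Gmsh v2.2 interchange file."""
        out = io.StringIO()
        out.write("$MeshFormat\n2.2 0 8\n$EndMeshFormat\n")
        out.write(f"$Nodes\n{self.n_nodes}\n")
        for i, (x, y) in enumerate(self.nodes, 1):
            out.write(f"{i} {x:.9g} {y:.9g} 0\n")
        out.write(f"$EndNodes\n$Elements\n{self.n_elements}\n")
        for i, (tri, rid) in enumerate(zip(self.triangles, self.region_id), 1):
            a, b, c = tri + 1
            out.write(f"{i} 2 2 {rid + 1} {rid + 1} {a} {b} {c}\n")
        out.write("$EndElements\n")
        Path(path).write_text(out.getvalue())


def _densify_ring(coords: np.ndarray, target: float) -> np.ndarray:
    """Subdivide each ring segment longer than ~1.5x the target edge."""
    pts = []
    n = len(coords) - 1  # closed ring: last == first
    for i in range(n):
        a, b = coords[i], coords[i + 1]
        seg = np.hypot(*(b - a))
        k = max(1, int(np.ceil(seg / target - 0.49)))
        for j in range(k):
            pts.append(a + (b - a) * (j / k))
    return np.asarray(pts)


def _interior_points(poly: Polygon, target: float, clearance: float) -> np.ndarray:
    minx, miny, maxx, maxy = poly.bounds
    dy = target * np.sqrt(3) / 2
    rows = int(np.floor((maxy - miny) / dy)) + 1
    pts = []
    for r in range(rows):
        y = miny + (r + 0.5) * dy
        if y >= maxy:
            break
        off = 0.0 if r % 2 == 0 else target / 2
        xs = np.arange(minx + off + target / 2, maxx, target)
        pts.append(np.column_stack([xs, np.full_like(xs, y)]))
    if not pts:
        return np.empty((0, 2))
    cand = np.vstack(pts)
    inside = shapely.contains_xy(poly, cand[:, 0], cand[:, 1])
    cand = cand[inside]
    if len(cand) == 0:
        return cand
    near = shapely.dwithin(poly.boundary, shapely.points(cand), clearance)
    return cand[~near]


def mesh_domain(domain: PlanarDomain, target_edge: float = 3.0,
                half_model: bool = True, tol: float = 1e-6) -> TriMesh:
    """Mesh the section into labelled triangles.

    Parameters
    ----------
    domain : PlanarDomain
        Section to discretize.
    target_edge : float
        Requested typical edge length in μm.
    half_model : bool
        If True, clip at the symmetry axis and mark the axis nodes; the
        domain must be mirror-symmetric about ``domain.symmetry_x``.
    """
    if target_edge <= 0:
        raise MeshingError("target_edge must be positive")

    region_polys = {n: list(ps) for n, ps in domain.region_polys.items()}
    cavity = domain.cavity
    if half_model:
        minx, miny, maxx, maxy = domain.bounds
        halfplane = box(domain.symmetry_x, miny - 1, maxx + 1, maxy + 1)
        clipped: dict[str, list[Polygon]] = {}
        for name, ps in region_polys.items():
            out = []
            for p in ps:
                q = p.intersection(halfplane)
                for g in getattr(q, "geoms", [q]):
                    if g.geom_type == "Polygon" and g.area > tol:
                        out.append(g)
            clipped[name] = out
        region_polys = clipped
        if not cavity.is_empty:
            cavity = cavity.intersection(halfplane)

    polys: list[tuple[str, Polygon]] = [
        (name, p) for name in REGIONS for p in region_polys.get(name, [])
    ]
    if not polys:
        raise MeshingError("domain has no material regions")

    pts = [_densify_ring(np.asarray(p.exterior.coords), target_edge)
           for _, p in polys]
    if not cavity.is_empty:
        pts.append(_densify_ring(np.asarray(cavity.exterior.coords), target_edge))
    for _, p in polys:
        ip = _interior_points(p, target_edge, 0.45 * target_edge)
        if len(ip):
            pts.append(ip)
    allpts = np.vstack(pts)
    # merge coincident samples from shared boundaries
    allpts = np.unique(np.round(allpts / tol).astype(np.int64), axis=0) * tol

    tri = Delaunay(allpts)
    simplices = tri.simplices
    a, b, c = (allpts[simplices[:, i]] for i in range(3))
    areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    flip = areas < 0
    simplices[flip] = simplices[flip][:, ::-1]
    keep_area = np.abs(areas) > 1e-6 * target_edge ** 2
    cent = (a + b + c) / 3.0

    region_id = np.full(len(simplices), -1, dtype=np.int64)
    names = tuple(REGIONS)
    for rid, (name, _) in enumerate([(n, None) for n in names]):
        for p in region_polys.get(name, []):
            hit = shapely.contains_xy(p, cent[:, 0], cent[:, 1])
            region_id[hit & (region_id < 0)] = rid

    keep = keep_area & (region_id >= 0)
    simplices = simplices[keep]
    region_id = region_id[keep]

    used = np.unique(simplices)
    remap = np.full(len(allpts), -1, dtype=np.int64)
    remap[used] = np.arange(len(used))
    mesh = TriMesh(
        nodes=allpts[used],
        triangles=remap[simplices],
        region_id=region_id,
        region_names=names,
        half_model=half_model,
    )
    _check_areas(mesh, region_polys, tol=0.05)
    mesh.markers = _markers(mesh, domain, half_model, tol=1e-6)
    return mesh


def _check_areas(mesh: TriMesh, region_polys: dict[str, list[Polygon]],
                 tol: float) -> None:
    for name, ps in region_polys.items():
        poly_area = sum(p.area for p in ps)
        if poly_area == 0:
            continue
        mesh_area = mesh.region_area(name)
        if abs(mesh_area - poly_area) > tol * poly_area:
            raise MeshingError(
                f"meshed area of {name} ({mesh_area:.3f}) deviates from the "
                f"polygon area ({poly_area:.3f}) by more than {tol:.0%}"
            )


def _markers(mesh: TriMesh, domain: PlanarDomain, half_model: bool,
             tol: float) -> dict[str, np.ndarray]:
    x, y = mesh.nodes[:, 0], mesh.nodes[:, 1]
    on_base = np.abs(y) < 1e-6
    vasc = np.zeros(mesh.n_nodes, dtype=bool)
    for x0, x1 in domain.vasc_base_intervals:
        lo, hi = sorted((x0, x1))
        vasc |= on_base & (x >= lo - 1e-6) & (x <= hi + 1e-6)
    markers = {"vascular_base": np.flatnonzero(vasc)}
    if half_model:
        markers["symmetry_axis"] = np.flatnonzero(
            np.abs(x - domain.symmetry_x) < 1e-6)
    boundary_nodes = _boundary_nodes(mesh)
    free = np.setdiff1d(boundary_nodes,
                        np.concatenate(list(markers.values())) if markers else [])
    markers["free_surface"] = free
    return markers


def _boundary_nodes(mesh: TriMesh) -> np.ndarray:
    t = mesh.triangles
    edges = np.vstack([t[:, [0, 1]], t[:, [1, 2]], t[:, [2, 0]]])
    edges_sorted = np.sort(edges, axis=1)
    uniq, counts = np.unique(edges_sorted, axis=0, return_counts=True)
    return np.unique(uniq[counts == 1])
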