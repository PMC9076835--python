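"""Landmark-based strain mapping between dry and wet tissue images.

Paired landmarks annotated on dry and wet images of the same sample are
turned into local deformation maps: a Delaunay triangulation built on the
dry positions, per-triangle wet/dry area ratios (with exclusion of
triangles leaving the sample outline or overlapping in the wet state),
neighbourhood smoothing, principal stretches from the per-triangle affine
map, tissue-region assignment by polygon overlap, and per-region mean
expansions that feed the swelling-factor calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon
from shapely.strtree import STRtree

#: Region priority used to break exact ties in overlap assignment.
REGION_PRIORITY = ("podium", "vasculature", "side")

OVERLAP_THRESHOLD = 0.40


@dataclass
class LandmarkSet:
    """Paired dry/wet landmarks with outline and region annotations.

    Coordinates are y-up μm.  ``from_pixels`` converts y-down pixel
    coordinates using a pixel size in μm.
    """

    ids: np.ndarray
    dry: np.ndarray   # (N, 2)
    wet: np.ndarray   # (N, 2)
    reference_id: object
    outline_dry: Polygon
    regions: dict[str, Polygon] = field(default_factory=dict)
    outline_wet: Polygon | None = None

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.dry = np.asarray(self.dry, dtype=float)
        self.wet = np.asarray(self.wet, dtype=float)
        if len(self.ids) != len(self.dry) or len(self.dry) != len(self.wet):
            raise ValueError("ids, dry and wet must pair one-to-one")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("landmark ids must be unique")
        if self.reference_id not in set(self.ids.tolist()):
            raise ValueError(f"reference id {self.reference_id!r} not present")

    @property
    def reference_index(self) -> int:
        return int(np.flatnonzero(self.ids == self.reference_id)[0])

    @classmethod
    def from_csv(cls, landmarks_csv: str | Path, outline: Polygon,
                 regions: dict[str, Polygon] | None = None,
                 reference_id=None) -> "LandmarkSet":
        df = pd.read_csv(landmarks_csv)
        need = {"id", "x_dry", "y_dry", "x_wet", "y_wet"}
        if not need <= set(df.columns):
            raise ValueError(f"landmark CSV must have columns {sorted(need)}")
        ref = reference_id if reference_id is not None else df["id"].iloc[0]
        return cls(ids=df["id"].to_numpy(),
                   dry=df[["x_dry", "y_dry"]].to_numpy(),
                   wet=df[["x_wet", "y_wet"]].to_numpy(),
                   reference_id=ref, outline_dry=outline,
                   regions=regions or {})

    @classmethod
    def from_pixels(cls, ids, dry_px, wet_px, reference_id, outline_px,
                    pixel_size: float, image_height_px: float,
                    regions_px: dict[str, np.ndarray] | None = None) -> "LandmarkSet":
        """Convert y-down pixel annotations to y-up μm coordinates."""
        def conv(a):
            a = np.asarray(a, dtype=float)
            out = a.copy()
            out[:, 1] = image_height_px - a[:, 1]
            return out * pixel_size
        regions = {k: Polygon(conv(v)) for k, v in (regions_px or {}).items()}
        return cls(ids=np.asarray(ids), dry=conv(dry_px), wet=conv(wet_px),
                   reference_id=reference_id,
                   outline_dry=Polygon(conv(outline_px)), regions=regions)


def relative_displacement(lm: LandmarkSet) -> np.ndarray:
    """Wet-minus-dry displacement of each landmark, relative to the reference.

    The reference landmark's own displacement is subtracted from all
    landmarks, so its row is exactly the zero vector.
    """
    disp = lm.wet - lm.dry
    return disp - disp[lm.reference_index]


@dataclass
class TriangulationMap:
    """Delaunay triangles on the dry landmarks with derived per-triangle data."""

    triangles: np.ndarray          # (M, 3) landmark indices
    valid: np.ndarray              # bool per triangle
    reason: np.ndarray             # '', 'outside-outline', 'wet-overlap', 'degenerate'
    ratio: np.ndarray | None = None
    smoothed: np.ndarray | None = None
    stretches: np.ndarray | None = None   # (M, 2) descending
    directions: np.ndarray | None = None  # (M, 2, 2) rows = principal axes (dry frame)
    region: np.ndarray | None = None

    def to_frame(self, lm: LandmarkSet) -> pd.DataFrame:
        df = pd.DataFrame({
            "v0": lm.ids[self.triangles[:, 0]],
            "v1": lm.ids[self.triangles[:, 1]],
            "v2": lm.ids[self.triangles[:, 2]],
            "valid": self.valid,
            "reason": self.reason,
        })
        if self.ratio is not None:
            df["area_ratio"] = self.ratio
        if self.smoothed is not None:
            df["smoothed_ratio"] = self.smoothed
        if self.stretches is not None:
            df["stretch_major"] = self.stretches[:, 0]
            df["stretch_minor"] = self.stretches[:, 1]
            df["angle_deg"] = np.degrees(
                np.arctan2(self.directions[:, 0, 1], self.directions[:, 0, 0]))
        if self.region is not None:
            df["region"] = self.region
        return df


def _signed_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    a, b, c = (points[tris[:, i]] for i in range(3))
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


def triangulate_dry(lm: LandmarkSet) -> TriangulationMap:
    """Delaunay triangulation of the dry landmarks, clipped to the outline.

    Triangles not fully enclosed by the dry outline are excluded (marked
    invalid with reason ``outside-outline``).
    """
    if len(lm.dry) < 3:
        raise ValueError("at least 3 landmarks required")
    try:
        tri = Delaunay(lm.dry)
    except Exception as exc:
        raise ValueError(f"degenerate landmark configuration: {exc}") from exc
    tris = tri.simplices.copy()
    areas = _signed_areas(lm.dry, tris)
    flip = areas < 0
    tris[flip] = tris[flip][:, ::-1]
    outline = shapely.prepared.prep(lm.outline_dry.buffer(1e-9))
    valid = np.ones(len(tris), dtype=bool)
    reason = np.array([""] * len(tris), dtype=object)
    for i, t in enumerate(tris):
        if not outline.covers(Polygon(lm.dry[t])):
            valid[i] = False
            reason[i] = "outside-outline"
    return TriangulationMap(triangles=tris, valid=valid, reason=reason)


def area_change(tmap: TriangulationMap, lm: LandmarkSet,
                overlap_tol: float = 1e-6) -> TriangulationMap:
    """Per-triangle wet/dry area ratio with wet-overlap exclusion.

    A triangle is invalidated if its dry area is (near) zero, its wet
    image inverts (non-positive signed area), or its wet image overlaps
    the interior of another retained triangle's wet image by more than
    ``overlap_tol`` of its own area.
    """
    tris = tmap.triangles
    dry_a = _signed_areas(lm.dry, tris)
    wet_a = _signed_areas(lm.wet, tris)
    ratio = np.full(len(tris), np.nan)
    scale = np.median(np.abs(dry_a[dry_a != 0])) if np.any(dry_a != 0) else 1.0
    for i in range(len(tris)):
        if not tmap.valid[i]:
            continue
        if abs(dry_a[i]) < 1e-12 * scale:
            tmap.valid[i] = False
            tmap.reason[i] = "degenerate"
        elif wet_a[i] <= 0:
            tmap.valid[i] = False
            tmap.reason[i] = "wet-overlap"
        else:
            ratio[i] = wet_a[i] / dry_a[i]
    # pairwise wet-image overlap among remaining triangles
    cand = np.flatnonzero(tmap.valid)
    polys = [Polygon(lm.wet[tris[i]]) for i in cand]
    tree = STRtree(polys)
    bad: set[int] = set()
    for local_i, poly in enumerate(polys):
        for local_j in tree.query(poly):
            if local_j <= local_i:
                continue
            other = polys[local_j]
            inter = poly.intersection(other).area
            if inter > overlap_tol * min(poly.area, other.area):
                bad.add(int(cand[local_i]))
                bad.add(int(cand[local_j]))
    for i in bad:
        tmap.valid[i] = False
        tmap.reason[i] = "wet-overlap"
        ratio[i] = np.nan
    tmap.ratio = ratio
    return tmap


def smooth_area_change(tmap: TriangulationMap) -> TriangulationMap:
    """One pass of neighbourhood smoothing over edge-adjacent triangles.

    Each valid triangle's smoothed ratio is the arithmetic mean of its own
    raw ratio and the raw ratios of its edge-adjacent valid neighbours;
    invalid triangles neither receive nor contribute values.
    """
    if tmap.ratio is None:
        raise ValueError("compute area_change before smoothing")
    tris = tmap.triangles
    edge_owner: dict[tuple[int, int], list[int]] = {}
    for i, t in enumerate(tris):
        for k in range(3):
            e = tuple(sorted((int(t[k]), int(t[(k + 1) % 3]))))
            edge_owner.setdefault(e, []).append(i)
    neighbours: dict[int, set[int]] = {i: set() for i in range(len(tris))}
    for owners in edge_owner.values():
        for i in owners:
            for j in owners:
                if i != j:
                    neighbours[i].add(j)
    smoothed = np.full(len(tris), np.nan)
    for i in range(len(tris)):
        if not tmap.valid[i]:
            continue
        vals = [tmap.ratio[i]] + [tmap.ratio[j] for j in neighbours[i]
                                  if tmap.valid[j]]
        smoothed[i] = float(np.mean(vals))
    tmap.smoothed = smoothed
    return tmap


def principal_strain(tmap: TriangulationMap, lm: LandmarkSet) -> TriangulationMap:
    """Principal stretches and directions of the dry→wet affine map.

    For each valid triangle the deformation gradient ``F`` maps dry edge
    vectors to wet edge vectors; principal stretches are the singular
    values of ``F`` and the principal directions are the corresponding
    right singular vectors (material directions in the dry frame).  The
    ×3 display magnification used for strain crosses is applied only at
    render time, never here.
    """
    tris = tmap.triangles
    n = len(tris)
    stretches = np.full((n, 2), np.nan)
    directions = np.full((n, 2, 2), np.nan)
    for i, t in enumerate(tris):
        if not tmap.valid[i]:
            continue
        Dm = np.column_stack([lm.dry[t[1]] - lm.dry[t[0]],
                              lm.dry[t[2]] - lm.dry[t[0]]])
        Wm = np.column_stack([lm.wet[t[1]] - lm.wet[t[0]],
                              lm.wet[t[2]] - lm.wet[t[0]]])
        try:
            F = Wm @ np.linalg.inv(Dm)
        except np.linalg.LinAlgError:
            tmap.valid[i] = False
            tmap.reason[i] = "degenerate"
            continue
        _, s, vt = np.linalg.svd(F)
        stretches[i] = s
        directions[i] = vt  # rows are right singular vectors
    tmap.stretches = stretches
    tmap.directions = directions
    return tmap


def assign_regions(tmap: TriangulationMap, lm: LandmarkSet,
                   overlap_threshold: float = OVERLAP_THRESHOLD) -> TriangulationMap:
    """Label triangles by dry-state region-polygon overlap.

    A triangle is assigned to the named region whose polygon covers at
    least ``overlap_threshold`` of the triangle's area; with several
    qualifying regions the largest overlap wins, exact ties broken by a
    fixed priority (podium > vasculature > side).  Everything else is
    cortex.
    """
    tris = tmap.triangles
    labels = np.array(["cortex"] * len(tris), dtype=object)
    prio = {name: k for k, name in enumerate(REGION_PRIORITY)}
    for i, t in enumerate(tris):
        poly = Polygon(lm.dry[t])
        if poly.area <= 0:
            continue
        best_name, best_frac = None, 0.0
        for name, region in lm.regions.items():
            if name == "cortex" or name == "cavity":
                continue
            frac = poly.intersection(region).area / poly.area
            if frac >= overlap_threshold - 1e-12:
                better = (frac > best_frac + 1e-12
                          or (abs(frac - best_frac) <= 1e-12 and best_name is not None
                              and prio.get(name, 99) < prio.get(best_name, 99)))
                if best_name is None or better:
                    best_name, best_frac = name, frac
        if best_name is not None:
            labels[i] = best_name
    tmap.region = labels
    return tmap


def regional_mean_area_change(tmap: TriangulationMap) -> dict[str, float]:
    """Arithmetic mean of smoothed ratios over valid triangles per region.

    Regions with no valid triangle map to NaN (a missing value, not zero).
    """
    if tmap.smoothed is None or tmap.region is None:
        raise ValueError("smoothing and region assignment must run first")
    out: dict[str, float] = {}
    for name in sorted(set(tmap.region.tolist())):
        sel = (tmap.region == name) & tmap.valid & ~np.isnan(tmap.smoothed)
        out[name] = float(np.mean(tmap.smoothed[sel])) if np.any(sel) else float("nan")
    return out


def circularity(polygon: Polygon | np.ndarray) -> float:
    """Shape circularity 4π·Area/Perimeter² (1 for a circle, →0 elongated)."""
    poly = polygon if isinstance(polygon, Polygon) else Polygon(np.asarray(polygon))
    if len(poly.exterior.coords) < 4:
        raise ValueError("polygon needs at least 3 vertices")
    if not poly.is_valid:
        raise ValueError("polygon is self-intersecting or otherwise invalid")
    return float(4 * np.pi * poly.area / poly.length ** 2)


def run_pipeline(lm: LandmarkSet,
                 overlap_threshold: float = OVERLAP_THRESHOLD) -> tuple[TriangulationMap, dict[str, float]]:
    """Full strain-mapping pipeline; returns the map and per-region means."""
    tmap = triangulate_dry(lm)
    tmap = area_change(tmap, lm)
    tmap = smooth_area_change(tmap)
    tmap = principal_strain(tmap, lm)
    tmap = assign_regions(tmap, lm, overlap_threshold)
    return tmap, regional_mean_area_change(tmap)
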