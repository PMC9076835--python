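"""Parametric 2D longitudinal-section geometry of the apical plate.

The hydrated section is built from the nine measured lengths alone, with
origin at the intersection of the symmetry axis with the base, x radial,
y up, lengths in μm.  Four tissue regions surround a central cavity (a
hole, not a region):

* **central cavity** — an isosceles trapezoid flaring upward from basal
  width ``D_cavity`` to the underside of the floral podium.  The measured
  lengths interlock here: the podium chord half-width
  ``w_pod = sqrt(H_pod (2R − H_pod))`` nearly equals
  ``D/2 − W_side − W_vasc``, so the cavity roof, the vascular band tops
  and the side regions tile the top of the section.
* **vasculature** — two straight bands of horizontal width ``W_vasc``
  running along the cavity flanks from the base to the podium underside,
  where each band top straddles a chord end of the podium.
* **floral podium** — the circular segment of radius ``R`` and sagitta
  ``H_pod`` capping the section, its chord at height ``H − H_pod``.
* **side regions** — ``W_side × H_side`` rectangles at the upper outer
  flanks, their lateral edge at ``x = ±D/2`` (the holding-angle edge).
* **cortex** — a thin rind of width ``W_vasc`` outside each vascular band
  (the vasculature–cortex bilayer that drives actuation) plus the shelf
  joining the bilayer walls to the side regions in the upper block.

The holding-angle landmarks are the upper corner of the apical plate
``(D/2, H − H_pod)`` and the lowest point of the side region's lateral
edge ``(D/2, H − H_pod − H_side)``; in the hydrated state the line through
them is vertical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .params import GeometryParams, InvalidGeometryError

#: Chord length (μm) used to discretize the podium arc into a polyline.
ARC_CHORD = 2.0

PERTURBATION_KINDS = (
    "fill_cavity_horizontal",
    "fill_cavity_vertical",
    "trim_corner_vertical",
    "move_corner_horizontal",
)


class PerturbationRangeError(ValueError):
    """Perturbation magnitude outside the geometrically admissible range."""

    def __init__(self, kind: str, magnitude: float, lo: float, hi: float):
        self.admissible = (lo, hi)
        super().__init__(
            f"{kind} magnitude {magnitude:g} outside admissible interval [{lo:g}, {hi:g}] μm"
        )


@dataclass(frozen=True)
class GeometryPerturbation:
    """A named geometric modification of the reference section (μm)."""

    kind: str
    magnitude: float

    def __post_init__(self) -> None:
        if self.kind not in PERTURBATION_KINDS:
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass
class PlanarDomain:
    """The planar section: region polygons, cavity hole and landmarks.

    ``region_polys`` maps each region name to a list of simple polygons
    (two mirrored pieces for vasculature and sides).  ``cavity`` may be an
    empty polygon when the cavity is fully filled.
    """

    region_polys: dict[str, list[Polygon]]
    cavity: Polygon
    vasc_base_intervals: list[tuple[float, float]]
    theta_top: tuple[float, float]
    theta_bottom: tuple[float, float]
    symmetry_x: float = 0.0

    @property
    def material_union(self) -> Polygon:
        return unary_union([p for ps in self.region_polys.values() for p in ps])

    @property
    def envelope(self) -> Polygon:
        u = self.material_union
        if not self.cavity.is_empty:
            u = unary_union([u, self.cavity])
        return u

    def region_area(self, region: str) -> float:
        return sum(p.area for p in self.region_polys[region])

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return self.envelope.bounds

    def validate(self) -> None:
        for name, polys in self.region_polys.items():
            for p in polys:
                if not p.is_valid or p.area <= 0:
                    raise InvalidGeometryError(f"region {name} has an invalid polygon piece")
        names = list(self.region_polys)
        flat = [(n, p) for n in names for p in self.region_polys[n]]
        for i, (ni, pi) in enumerate(flat):
            for nj, pj in flat[i + 1:]:
                inter = pi.intersection(pj).area
                if inter > 1e-6 * min(pi.area, pj.area):
                    raise InvalidGeometryError(f"regions {ni} and {nj} overlap (area {inter:g})")
        if not self.material_union.geom_type == "Polygon":
            raise InvalidGeometryError("union of regions is not connected")


def _podium_arc(params: GeometryParams, n: int) -> np.ndarray:
    """Polyline along the podium arc from +chord to -chord (excl. endpoints)."""
    R, H, H_pod = params.R, params.H, params.H_pod
    w = math.sqrt(H_pod * (2 * R - H_pod))  # half chord
    cy = H - R  # arc centre on the symmetry axis
    a0 = math.atan2(H - H_pod - cy, w)
    a1 = math.pi - a0
    ang = np.linspace(a0, a1, n + 1)[1:-1]
    return np.column_stack([R * np.cos(ang), cy + R * np.sin(ang)])


class _Frame:
    """Derived construction lengths shared by builder and perturbations."""

    def __init__(self, p: GeometryParams):
        self.H_cav = p.H - p.H_pod                      # podium chord level
        self.hc = p.D_cavity / 2                        # cavity half-width at base
        self.w_pod = math.sqrt(p.H_pod * (2 * p.R - p.H_pod))
        self.x_si = p.D / 2 - p.W_side                  # side inner edge
        self.x_ct = self.x_si - 1.5 * p.W_vasc          # cavity half-width at top
        self.xvt = self.x_ct + p.W_vasc                 # band outer edge at top
        self.x_base = self.hc + p.W_vasc                # band outer edge at base
        self.y0 = self.H_cav - p.H_side                 # block / side bottom
        self.wall = p.W_vasc                            # cortex-rind thickness
        if not self.x_ct < self.w_pod:
            raise InvalidGeometryError(
                "podium chord does not reach the cavity roof "
                "(requires D/2 - W_side - 1.5 W_vasc < sqrt(H_pod (2R - H_pod)))")
        if not self.hc < self.x_ct:
            raise InvalidGeometryError("cavity must flare upward (D_cavity/2 < top half-width)")
        if not self.y0 > 0:
            raise InvalidGeometryError("side regions reach below the base (H_side too large)")
        if not self.x_base + self.wall < self.x_si:
            raise InvalidGeometryError("base wall wider than the side inner edge")

    def wall_outer(self, y: float, p: GeometryParams) -> float:
        """x of the outer surface of the lower bilayer wall at height y."""
        t = y / self.H_cav
        return self.x_base + (self.xvt - self.x_base) * t + self.wall


def _vasc_polys(p: GeometryParams, f: _Frame) -> list[Polygon]:
    def band(s: float) -> Polygon:
        return Polygon([
            (s * f.hc, 0), (s * f.x_base, 0),
            (s * f.xvt, f.H_cav), (s * f.x_ct, f.H_cav),
        ])
    return [band(+1), band(-1)]


def _side_polys(p: GeometryParams, f: _Frame, half_width: float) -> list[Polygon]:
    def rect(s: float) -> Polygon:
        x0, x1 = sorted([s * f.x_si, s * half_width])
        return box(x0, f.y0, x1, f.H_cav)
    return [rect(+1), rect(-1)]


def _reference_cavity(f: _Frame) -> Polygon:
    return Polygon([(-f.hc, 0), (f.hc, 0), (f.x_ct, f.H_cav), (-f.x_ct, f.H_cav)])


def _envelope(p: GeometryParams, f: _Frame, arc: np.ndarray,
              rind_shift: float = 0.0, half_width: float | None = None) -> Polygon:
    hw = p.D / 2 if half_width is None else half_width
    xw0 = f.x_base + f.wall + rind_shift
    xwy0 = f.wall_outer(f.y0, p) + rind_shift
    return Polygon(np.vstack([
        [[xw0, 0], [xwy0, f.y0], [hw, f.y0], [hw, f.H_cav], [f.w_pod, f.H_cav]],
        arc,
        [[-f.w_pod, f.H_cav], [-hw, f.H_cav], [-hw, f.y0], [-xwy0, f.y0], [-xw0, 0]],
    ]))


def _assemble(p: GeometryParams, f: _Frame, envelope: Polygon, podium: Polygon,
              cavity: Polygon, vascs: list[Polygon], sides: list[Polygon],
              theta_x: float | None = None) -> PlanarDomain:
    cortex = envelope.difference(podium)
    if not cavity.is_empty and cavity.area > 0:
        cortex = cortex.difference(cavity)
    for poly in vascs + sides:
        cortex = cortex.difference(poly)
    pieces = [g for g in getattr(cortex, "geoms", [cortex]) if g.area > 1e-9]
    hw = p.D / 2 if theta_x is None else theta_x
    domain = PlanarDomain(
        region_polys={
            "podium": [podium],
            "vasculature": vascs,
            "side": sides,
            "cortex": pieces,
        },
        cavity=cavity if cavity.area > 0 else Polygon(),
        vasc_base_intervals=[(f.hc, f.x_base), (-f.x_base, -f.hc)],
        theta_top=(hw, f.H_cav),
        theta_bottom=(hw, f.y0),
    )
    domain.validate()
    return domain


def build_reference_geometry(params: GeometryParams) -> PlanarDomain:
    """Construct the hydrated (stress-free) section from the nine lengths."""
    f = _Frame(params)
    arc_len = params.R * 2 * math.asin(f.w_pod / params.R)
    arc = _podium_arc(params, max(8, math.ceil(arc_len / ARC_CHORD)))
    podium = Polygon(np.vstack([[[f.w_pod, f.H_cav]], arc, [[-f.w_pod, f.H_cav]]]))
    return _assemble(params, f, _envelope(params, f, arc), podium,
                     _reference_cavity(f), _vasc_polys(params, f),
                     _side_polys(params, f, params.D / 2))


def apply_geometry_perturbation(params: GeometryParams,
                                p: GeometryPerturbation) -> PlanarDomain:
    """Apply one of the geometric modifications and rebuild the section.

    ``fill_cavity_horizontal`` narrows the cavity from the flanks (the
    freed space becomes cortex); ``fill_cavity_vertical`` lowers its roof;
    ``trim_corner_vertical`` removes the cortex shelf above the block
    bottom (between the bilayer wall and the side regions);
    ``move_corner_horizontal`` moves the outer surface of the lower
    cortex rind in or out (signed: positive adds material).
    """
    f = _Frame(params)
    arc_len = params.R * 2 * math.asin(f.w_pod / params.R)
    arc = _podium_arc(params, max(8, math.ceil(arc_len / ARC_CHORD)))
    podium = Polygon(np.vstack([[[f.w_pod, f.H_cav]], arc, [[-f.w_pod, f.H_cav]]]))
    m = p.magnitude

    if p.kind == "fill_cavity_horizontal":
        if not 0 <= m <= f.hc:
            raise PerturbationRangeError(p.kind, m, 0.0, f.hc)
        b = f.hc - m
        if b <= 1e-12:
            cavity = Polygon()
        else:
            xt = f.x_ct * b / f.hc  # flanks shift inward by similarity
            cavity = Polygon([(-b, 0), (b, 0), (xt, f.H_cav), (-xt, f.H_cav)])
        return _assemble(params, f, _envelope(params, f, arc), podium, cavity,
                         _vasc_polys(params, f), _side_polys(params, f, params.D / 2))

    if p.kind == "fill_cavity_vertical":
        if not 0 <= m <= f.H_cav:
            raise PerturbationRangeError(p.kind, m, 0.0, f.H_cav)
        htop = f.H_cav - m
        if htop <= 1e-12:
            cavity = Polygon()
        else:
            xt = f.hc + (f.x_ct - f.hc) * htop / f.H_cav
            cavity = Polygon([(-f.hc, 0), (f.hc, 0), (xt, htop), (-xt, htop)])
        return _assemble(params, f, _envelope(params, f, arc), podium, cavity,
                         _vasc_polys(params, f), _side_polys(params, f, params.D / 2))

    if p.kind == "trim_corner_vertical":
        hi = params.H_side - 1.0  # keep a sliver of side support at the rim
        if not 0 <= m <= hi:
            raise PerturbationRangeError(p.kind, m, 0.0, hi)
        env = _envelope(params, f, arc)
        if m > 0:
            xwy0 = f.wall_outer(f.y0, params)
            cut = box(xwy0, f.y0 - 1, f.x_si, f.y0 + m)
            cut = unary_union([cut, box(-f.x_si, f.y0 - 1, -xwy0, f.y0 + m)])
            env = env.difference(cut)
        return _assemble(params, f, env, podium, _reference_cavity(f),
                         _vasc_polys(params, f), _side_polys(params, f, params.D / 2))

    if p.kind == "move_corner_horizontal":
        lo = -(f.wall - 2.0)  # keep at least 2 μm of cortex rind
        hi = params.D / 2 - f.wall_outer(f.y0, params) - 1.0  # stay inside the block edge
        if not lo <= m <= hi:
            raise PerturbationRangeError(p.kind, m, lo, hi)
        env = _envelope(params, f, arc, rind_shift=m)
        return _assemble(params, f, env, podium, _reference_cavity(f),
                         _vasc_polys(params, f), _side_polys(params, f, params.D / 2))

    raise ValueError(f"unknown perturbation kind {p.kind!r}")


def shoelace_area(coords: np.ndarray) -> float:
    """Signed polygon area by the shoelace formula (positive if CCW)."""
    xy = np.asarray(coords, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
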