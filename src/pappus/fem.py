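"""Plane-strain finite-element model of apical-plate dehydration.

The hydrated section is stress-free.  Dehydration is modelled as linear,
isotropic, plane-strain elasticity with a region-wise isotropic shrinkage
eigenstrain ``eps* = (sqrt(1 - s) - 1) I`` (``s`` = intrinsic fractional
area loss), so a detached region with a free boundary shrinks to exactly
``1 - s`` of its wet area.  Region Young's moduli are proportional to the
measured relative cell-wall densities; all regions share one Poisson ratio.
Boundary conditions: the vascular-base nodes are displaced horizontally
toward the symmetry axis by ``d_vasc`` (vertical motion free); on a half
model the symmetry axis blocks horizontal motion, and the remaining
rigid-body modes are pinned at a single reference node.  Linear (CST)
triangles, small-strain kinematics, one sparse direct solve.

The model's main output is the holding angle ``theta``: the angle between
the vertical and the line from the upper corner of the apical plate to the
lowest point of the side region's lateral edge, measured in the dry state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import PlanarDomain, build_reference_geometry
from .mesh import TriMesh, mesh_domain
from .params import GeometryParams, MaterialParams, REGIONS

__all__ = [
    "SwellingProblem", "DisplacementField", "StressField", "ActuatorState",
    "solve_dehydration", "compute_stress", "compute_holding_angle",
    "regional_area_change", "substitute_materials", "solve_reference_state",
    "NonPhysicalDeformationWarning",
]


class RigidBodyModeError(RuntimeError):
    """The stiffness system is singular: unconstrained rigid-body motion."""


class NonPhysicalDeformationWarning(UserWarning):
    """Some triangles invert in the dry configuration."""


@dataclass
class DisplacementField:
    """Per-node wet->dry displacement vectors (μm)."""

    u: np.ndarray  # (N, 2)

    def dry_nodes(self, mesh: TriMesh) -> np.ndarray:
        return mesh.nodes + self.u


@dataclass
class StressField:
    """Per-element in-plane stress with the out-of-plane component.

    Components are in the units of the modulus scale ``E_vasc``.  Principal
    values are ordered ``sigma_1 >= sigma_2``; ``angle`` is the direction of
    the first principal axis (radians from the x axis).
    """

    sxx: np.ndarray
    syy: np.ndarray
    sxy: np.ndarray
    szz: np.ndarray
    principal: np.ndarray  # (M, 2) ordered
    angle: np.ndarray


def eigenstrain_scalar(s: float) -> float:
    """In-plane linear eigenstrain for fractional area loss ``s``."""
    return float(np.sqrt(1.0 - s) - 1.0)


class SwellingProblem:
    """Assembled dehydration problem on a mesh.

    The stiffness matrix depends only on the mesh, the relative densities
    and the Poisson ratio, so its factorization is cached and reused across
    solves with different swelling factors (as in the swelling-factor fit).
    """

    def __init__(self, mesh: TriMesh, materials: MaterialParams,
                 d_vasc: float, domain: PlanarDomain | None = None):
        self.mesh = mesh
        self.materials = materials
        self.d_vasc = float(d_vasc)
        self.domain = domain
        for name in mesh.region_names:
            if np.any(mesh.region_id == mesh.region_names.index(name)):
                materials.modulus(name)  # raises for unknown regions
        self._geom_cache = _element_geometry(mesh)
        self._K = _assemble_stiffness(mesh, materials, self._geom_cache)
        self._bc_dofs, self._bc_vals = self._dirichlet()
        if len(self._bc_dofs) == 0:
            raise RigidBodyModeError("no constrained nodes: rigid-body modes remain")
        self._factorized = None

    def _dirichlet(self) -> tuple[np.ndarray, np.ndarray]:
        mesh = self.mesh
        dofs, vals = [], []
        base = mesh.markers.get("vascular_base", np.empty(0, dtype=int))
        x = mesh.nodes[base, 0]
        dofs.append(2 * base)          # horizontal: pulled toward the axis
        vals.append(-np.sign(x) * self.d_vasc)
        axis = mesh.markers.get("symmetry_axis", np.empty(0, dtype=int))
        dofs.append(2 * axis)
        vals.append(np.zeros(len(axis)))
        # vertical motion of the vascular base is left free; pin the
        # remaining rigid modes at a single reference node (theta and all
        # relative outputs are invariant to the choice)
        if len(axis):
            pin = axis[int(np.argmin(mesh.nodes[axis, 1]))]
            dofs.append(np.array([2 * pin + 1]))
            vals.append(np.zeros(1))
        else:
            pin = int(np.argmax(mesh.nodes[:, 1]))  # apex, on the axis
            dofs.append(np.array([2 * pin, 2 * pin + 1]))
            vals.append(np.zeros(2))
        d = np.concatenate(dofs)
        v = np.concatenate(vals)
        order = np.argsort(d)
        d, v = d[order], v[order]
        d, idx = np.unique(d, return_index=True)
        return d, v[idx]

    def set_boundary_displacement(self, dofs: np.ndarray, vals: np.ndarray) -> None:
        """Override the Dirichlet set entirely (for patch-type tests)."""
        order = np.argsort(dofs)
        self._bc_dofs = np.asarray(dofs)[order]
        self._bc_vals = np.asarray(vals)[order]
        self._factorized = None

    # -- solving -----------------------------------------------------------

    def _factorize(self):
        if self._factorized is None:
            n = 2 * self.mesh.n_nodes
            free = np.setdiff1d(np.arange(n), self._bc_dofs)
            K = self._K.tocsc()
            Kff = K[free][:, free]
            Kfc = K[free][:, self._bc_dofs]
            try:
                lu = splu(Kff.tocsc())
            except RuntimeError as exc:  # pragma: no cover - singular systems
                raise RigidBodyModeError(str(exc)) from exc
            self._factorized = (free, lu, Kfc)
        return self._factorized

    def eigenstrain_load(self, swelling: dict[str, float]) -> np.ndarray:
        """Global load vector equivalent to the region-wise eigenstrain."""
        mesh = self.mesh
        f = np.zeros(2 * mesh.n_nodes)
        B, areas, dof_idx = self._geom_cache
        Dmats = _region_D(self.materials)
        for rid, name in enumerate(mesh.region_names):
            els = np.flatnonzero(mesh.region_id == rid)
            if len(els) == 0:
                continue
            e0 = eigenstrain_scalar(swelling[name])
            eps = np.array([e0, e0, 0.0])
            s_el = Dmats[name] @ eps  # constant stress-like source per element
            fe = np.einsum("eji,j,e->ei", B[els], s_el, areas[els])
            np.add.at(f, dof_idx[els].ravel(), fe.ravel())
        return f

    def solve(self, swelling: dict[str, float] | None = None) -> DisplacementField:
        if swelling is None:
            swelling = self.materials.swelling_factors
        f = self.eigenstrain_load(swelling)
        free, lu, Kfc = self._factorize()
        rhs = f[free] - Kfc @ self._bc_vals
        u = np.zeros(2 * self.mesh.n_nodes)
        u[free] = lu.solve(rhs)
        u[self._bc_dofs] = self._bc_vals
        field = DisplacementField(u=u.reshape(-1, 2))
        dry_areas = self.mesh.element_areas(field.dry_nodes(self.mesh))
        bad = np.flatnonzero(dry_areas <= 0)
        if len(bad):
            warnings.warn(
                f"{len(bad)} triangles invert in the dry state "
                f"(ids {bad[:5].tolist()}...)", NonPhysicalDeformationWarning,
                stacklevel=2)
        return field

    def elastic_energy(self, field: DisplacementField,
                       swelling: dict[str, float] | None = None) -> float:
        """Discrete elastic energy 0.5 (eps-eps*):D:(eps-eps*) integrated."""
        if swelling is None:
            swelling = self.materials.swelling_factors
        mesh = self.mesh
        B, areas, dof_idx = self._geom_cache
        u_el = field.u.reshape(-1)[dof_idx.reshape(len(mesh.triangles), 6)]
        strain = np.einsum("eij,ej->ei", B, u_el)
        Dmats = _region_D(self.materials)
        total = 0.0
        for rid, name in enumerate(mesh.region_names):
            els = np.flatnonzero(mesh.region_id == rid)
            if len(els) == 0:
                continue
            e0 = eigenstrain_scalar(swelling[name])
            e = strain[els] - np.array([e0, e0, 0.0])
            total += 0.5 * np.einsum("ei,ij,ej,e->", e, Dmats[name], e, areas[els])
        return float(total)


def _element_geometry(mesh: TriMesh):
    """Per-element strain-displacement matrices B (M,3,6), areas, dof maps."""
    t = mesh.triangles
    p = mesh.nodes
    a, b, c = p[t[:, 0]], p[t[:, 1]], p[t[:, 2]]
    areas = 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                   - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    if np.any(areas <= 0):
        raise ValueError("mesh contains non-positively-oriented triangles")
    M = len(t)
    B = np.zeros((M, 3, 6))
    ys = np.stack([b[:, 1] - c[:, 1], c[:, 1] - a[:, 1], a[:, 1] - b[:, 1]], axis=1)
    xs = np.stack([c[:, 0] - b[:, 0], a[:, 0] - c[:, 0], b[:, 0] - a[:, 0]], axis=1)
    inv2A = 1.0 / (2.0 * areas)
    for i in range(3):
        B[:, 0, 2 * i] = ys[:, i] * inv2A
        B[:, 1, 2 * i + 1] = xs[:, i] * inv2A
        B[:, 2, 2 * i] = xs[:, i] * inv2A
        B[:, 2, 2 * i + 1] = ys[:, i] * inv2A
    dof_idx = np.empty((M, 6), dtype=np.int64)
    dof_idx[:, 0::2] = 2 * t
    dof_idx[:, 1::2] = 2 * t + 1
    return B, areas, dof_idx


def plane_strain_stiffness(E: float, nu: float) -> np.ndarray:
    """Plane-strain constitutive matrix for [eps_xx, eps_yy, gamma_xy]."""
    f = E / ((1 + nu) * (1 - 2 * nu))
    return f * np.array([
        [1 - nu, nu, 0],
        [nu, 1 - nu, 0],
        [0, 0, (1 - 2 * nu) / 2],
    ])


def _region_D(materials: MaterialParams) -> dict[str, np.ndarray]:
    return {r: plane_strain_stiffness(materials.modulus(r), materials.nu)
            for r in REGIONS}


def _assemble_stiffness(mesh: TriMesh, materials: MaterialParams,
                        geom) -> sp.csr_matrix:
    B, areas, dof_idx = geom
    Dmats = _region_D(materials)
    M = len(mesh.triangles)
    Ke = np.zeros((M, 6, 6))
    for rid, name in enumerate(mesh.region_names):
        els = np.flatnonzero(mesh.region_id == rid)
        if len(els) == 0:
            continue
        Ke[els] = np.einsum("eji,jk,ekl,e->eil", B[els], Dmats[name],
                            B[els], areas[els])
    rows = np.repeat(dof_idx, 6, axis=1).ravel()
    cols = np.tile(dof_idx, (1, 6)).ravel()
    n = 2 * mesh.n_nodes
    return sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(n, n)).tocsr()


# ---------------------------------------------------------------------------
# Derived quantities


def solve_dehydration(problem: SwellingProblem) -> DisplacementField:
    """Solve the plane-strain eigenstrain problem (wet -> dry)."""
    return problem.solve()


def compute_stress(problem: SwellingProblem,
                   field: DisplacementField) -> StressField:
    """Element stresses from Hooke's law on (strain - eigenstrain)."""
    mesh = problem.mesh
    B, areas, dof_idx = problem._geom_cache
    u_el = field.u.reshape(-1)[dof_idx]
    strain = np.einsum("eij,ej->ei", B, u_el)
    Dmats = _region_D(problem.materials)
    nu = problem.materials.nu
    sig = np.zeros_like(strain)
    for rid, name in enumerate(mesh.region_names):
        els = np.flatnonzero(mesh.region_id == rid)
        if len(els) == 0:
            continue
        e0 = eigenstrain_scalar(problem.materials.swelling(name))
        sig[els] = (strain[els] - np.array([e0, e0, 0.0])) @ Dmats[name].T
    sxx, syy, sxy = sig[:, 0], sig[:, 1], sig[:, 2]
    szz = nu * (sxx + syy)  # zero out-of-plane eigenstrain under plane strain
    avg = 0.5 * (sxx + syy)
    rad = np.sqrt((0.5 * (sxx - syy)) ** 2 + sxy ** 2)
    principal = np.stack([avg + rad, avg - rad], axis=1)
    angle = 0.5 * np.arctan2(2 * sxy, sxx - syy)
    return StressField(sxx=sxx, syy=syy, sxy=sxy, szz=szz,
                       principal=principal, angle=angle)


def compute_holding_angle(mesh: TriMesh, field: DisplacementField,
                          domain: PlanarDomain) -> float:
    """Holding angle theta (degrees) in the dry configuration.

    Measured between the vertical and the line joining two advected
    material points: the upper corner of the apical plate and the lowest
    point of the side region's lateral edge.  Positive theta tilts the line
    outward (away from the symmetry axis) at the top.
    """
    top = np.asarray(domain.theta_top, dtype=float)
    bot = np.asarray(domain.theta_bottom, dtype=float)
    i_top = int(np.argmin(np.sum((mesh.nodes - top) ** 2, axis=1)))
    i_bot = int(np.argmin(np.sum((mesh.nodes - bot) ** 2, axis=1)))
    if i_top == i_bot:
        raise ValueError("holding-angle landmarks coincide on this mesh")
    dry = field.dry_nodes(mesh)
    v = dry[i_top] - dry[i_bot]
    if np.hypot(*v) < 1e-12:
        raise ValueError("holding-angle landmarks coincide in the dry state")
    outward = np.sign(top[0]) if top[0] != 0 else 1.0
    return float(np.degrees(np.arctan2(outward * v[0], v[1])))


def regional_area_change(mesh: TriMesh,
                         field: DisplacementField) -> dict[str, dict[str, float]]:
    """Per-region dry/wet area ratio and the wet/dry expansion convention."""
    dry_nodes = field.dry_nodes(mesh)
    out: dict[str, dict[str, float]] = {}
    wet_areas = mesh.element_areas()
    dry_areas = mesh.element_areas(dry_nodes)
    for rid, name in enumerate(mesh.region_names):
        els = mesh.region_id == rid
        if not np.any(els):
            continue
        wet = float(wet_areas[els].sum())
        dry = float(dry_areas[els].sum())
        out[name] = {"dry_over_wet": dry / wet, "wet_over_dry": wet / dry}
    return out


def substitute_materials(materials: MaterialParams,
                         mapping: dict[str, str]) -> MaterialParams:
    """Give recipient regions a donor region's density and swelling factor."""
    return materials.substitute(mapping)


@dataclass
class ActuatorState:
    """Solved dehydration state with its headline outputs."""

    domain: PlanarDomain
    mesh: TriMesh
    field: DisplacementField
    theta: float
    area_change: dict[str, dict[str, float]]
    podium_centre_node: int

    @property
    def dry_nodes(self) -> np.ndarray:
        return self.field.dry_nodes(self.mesh)

    def displacement_relative_to_podium(self) -> np.ndarray:
        return self.field.u - self.field.u[self.podium_centre_node]


def solve_reference_state(geometry: GeometryParams | None = None,
                          materials: MaterialParams | None = None,
                          domain: PlanarDomain | None = None,
                          target_edge: float = 3.0,
                          half_model: bool = True) -> ActuatorState:
    """Build (or take) a domain, mesh it, solve dehydration, extract outputs."""
    geometry = geometry or GeometryParams()
    materials = materials or MaterialParams()
    if domain is None:
        domain = build_reference_geometry(geometry)
    mesh = mesh_domain(domain, target_edge=target_edge, half_model=half_model)
    problem = SwellingProblem(mesh, materials, geometry.d_vasc, domain=domain)
    fld = problem.solve()
    theta = compute_holding_angle(mesh, fld, domain)
    centre = np.array(domain.region_polys["podium"][0].centroid.coords[0])
    i_c = int(np.argmin(np.sum((mesh.nodes - centre) ** 2, axis=1)))
    return ActuatorState(domain=domain, mesh=mesh, field=fld, theta=theta,
                         area_change=regional_area_change(mesh, fld),
                         podium_centre_node=i_c)
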