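import numpy as np
import pytest

from pappus.fem import (DisplacementField, SwellingProblem,
                        compute_holding_angle, compute_stress,
                        plane_strain_stiffness, regional_area_change,
                        solve_reference_state, substitute_materials)
from pappus.mesh import mesh_domain
from pappus.params import REGIONS, GeometryParams, MaterialParams


def _uniform_swelling_solution(mesh, materials, s):
    """Solve uniform swelling with the compatible boundary prescription."""
    lam = np.sqrt(1 - s)
    problem = SwellingProblem(mesh, materials.with_swelling(
        {r: s for r in REGIONS}), 0.0)
    base = mesh.markers["vascular_base"]
    axis = mesh.markers.get("symmetry_axis", np.empty(0, dtype=int))
    dofs = np.concatenate([2 * base, 2 * base + 1, 2 * axis])
    vals = np.concatenate([(lam - 1) * mesh.nodes[base, 0],
                           (lam - 1) * mesh.nodes[base, 1],
                           np.zeros(len(axis))])
    problem.set_boundary_displacement(dofs, vals)
    return problem, problem.solve()


class TestSolver:
    def test_uniform_swelling_is_stress_free_pure_scaling(self, coarse_mesh,
                                                          ref_materials):
        s = 0.3
        problem, field = _uniform_swelling_solution(coarse_mesh, ref_materials, s)
        expected = (np.sqrt(1 - s) - 1) * coarse_mesh.nodes
        assert np.abs(field.u - expected).max() < 1e-8
        stress = compute_stress(problem, field)
        scale = ref_materials.E_vasc
        assert max(np.abs(stress.sxx).max(), np.abs(stress.syy).max(),
                   np.abs(stress.sxy).max()) < 1e-6 * scale

    def test_patch_linear_boundary_displacement(self, rect_mesh, ref_materials):
        """Linear displacement on the whole boundary reproduces exactly."""
        A = np.array([[1e-3, 4e-4], [-2e-4, 5e-4]])
        problem = SwellingProblem(rect_mesh, ref_materials, 0.0)
        from pappus.mesh import _boundary_nodes
        bnd = _boundary_nodes(rect_mesh)
        ub = rect_mesh.nodes[bnd] @ A.T
        dofs = np.concatenate([2 * bnd, 2 * bnd + 1])
        vals = np.concatenate([ub[:, 0], ub[:, 1]])
        problem.set_boundary_displacement(dofs, vals)
        field = problem.solve(
            {r: 1e-12 for r in REGIONS})  # effectively zero swelling
        expected = rect_mesh.nodes @ A.T
        assert np.abs(field.u - expected).max() < 1e-9
        stress = compute_stress(problem, field)
        assert np.ptp(stress.sxx) < 1e-9 and np.ptp(stress.sxy) < 1e-9

    def test_single_element_fully_fixed_matches_closed_form(self, ref_materials):
        """Clamped eigenstrain element: stress = -C : eps*."""
        from pappus.mesh import TriMesh
        nodes = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        mesh = TriMesh(nodes=nodes, triangles=np.array([[0, 1, 2]]),
                       region_id=np.array([3]), region_names=tuple(REGIONS),
                       markers={})
        problem = SwellingProblem.__new__(SwellingProblem)
        problem.mesh = mesh
        problem.materials = ref_materials
        problem.d_vasc = 0.0
        problem.domain = None
        from pappus.fem import _element_geometry, _assemble_stiffness
        problem._geom_cache = _element_geometry(mesh)
        problem._K = _assemble_stiffness(mesh, ref_materials, problem._geom_cache)
        problem._factorized = None
        dofs = np.arange(6)
        problem.set_boundary_displacement(dofs, np.zeros(6))
        s = ref_materials.s_cort
        field = problem.solve()
        stress = compute_stress(problem, field)
        e0 = np.sqrt(1 - s) - 1
        C = plane_strain_stiffness(ref_materials.modulus("cortex"),
                                   ref_materials.nu)
        expected = -C @ np.array([e0, e0, 0.0])
        np.testing.assert_allclose(
            [stress.sxx[0], stress.syy[0], stress.sxy[0]], expected, atol=1e-12)

    def test_modulus_scale_invariance(self, ref_mesh, ref_materials,
                                      ref_geometry, ref_solution):
        scaled = SwellingProblem(ref_mesh, ref_materials.replace(E_vasc=13.7),
                                 ref_geometry.d_vasc)
        assert np.abs(scaled.solve().u - ref_solution.u).max() < 1e-8

    def test_discrete_energy_minimality(self, ref_problem, ref_solution):
        rng = np.random.default_rng(0)
        e0 = ref_problem.elastic_energy(ref_solution)
        mask = np.ones(ref_solution.u.size, bool)
        mask[ref_problem._bc_dofs] = False
        for _ in range(3):
            du = rng.normal(0, 0.3, ref_solution.u.size) * mask
            other = DisplacementField((ref_solution.u.reshape(-1) + du).reshape(-1, 2))
            assert ref_problem.elastic_energy(other) > e0

    def test_prescribed_boundary_values_hold_exactly(self, ref_problem,
                                                     ref_solution, ref_geometry):
        mesh = ref_problem.mesh
        base = mesh.markers["vascular_base"]
        np.testing.assert_allclose(
            ref_solution.u[base, 0],
            -np.sign(mesh.nodes[base, 0]) * ref_geometry.d_vasc)


class TestHoldingAngle:
    def test_identity_deformation_reproduces_wet_angle(self, ref_mesh, ref_domain):
        zero = DisplacementField(np.zeros_like(ref_mesh.nodes))
        theta = compute_holding_angle(ref_mesh, zero, ref_domain)
        assert theta == pytest.approx(0.0, abs=1e-9)

    def test_rigid_rotation_shifts_theta_by_the_rotation_angle(
            self, ref_mesh, ref_domain, ref_solution):
        theta0 = compute_holding_angle(ref_mesh, ref_solution, ref_domain)
        ang = np.radians(10.0)
        R = np.array([[np.cos(ang), np.sin(ang)], [-np.sin(ang), np.cos(ang)]])
        centre = np.array([0.0, 220.0])
        dry = ref_solution.dry_nodes(ref_mesh)
        rotated = (dry - centre) @ R.T + centre
        field = DisplacementField(rotated - ref_mesh.nodes)
        theta1 = compute_holding_angle(ref_mesh, field, ref_domain)
        assert theta1 - theta0 == pytest.approx(10.0, abs=1e-9)

    def test_reference_model_theta_near_twenty_degrees(self, ref_mesh, ref_domain,
                                                       ref_solution):
        theta = compute_holding_angle(ref_mesh, ref_solution, ref_domain)
        assert 15.0 < theta < 25.0

    def test_half_and_full_domain_agree(self, ref_domain):
        half = solve_reference_state(domain=ref_domain, target_edge=3.0,
                                     half_model=True)
        full = solve_reference_state(domain=ref_domain, target_edge=3.0,
                                     half_model=False)
        assert abs(half.theta - full.theta) < 0.3

    def test_full_domain_displacement_mirror_structure(self, ref_domain):
        from scipy.spatial import cKDTree
        state = solve_reference_state(domain=ref_domain, target_edge=4.0,
                                      half_model=False)
        mesh, u = state.mesh, state.field.u
        tree = cKDTree(mesh.nodes)
        dist, idx = tree.query(mesh.nodes * [-1, 1])
        paired = dist < 1e-6
        scale = np.abs(u).max()
        anti = np.abs(u[paired, 0] + u[idx[paired], 0]).max()
        sym = np.abs(u[paired, 1] - u[idx[paired], 1]).max()
        assert anti < 0.1 * scale and sym < 0.1 * scale


class TestStressAndAreas:
    def test_reference_stress_sign_structure(self, ref_problem, ref_solution):
        """Vasculature compressive; cortex under tension."""
        stress = compute_stress(ref_problem, ref_solution)
        mesh = ref_problem.mesh
        vasc = mesh.region_id == mesh.region_names.index("vasculature")
        cort = mesh.region_id == mesh.region_names.index("cortex")
        assert np.median(stress.principal[vasc, 1]) < 0
        assert abs(np.median(stress.principal[vasc, 1])) > \
            abs(np.median(stress.principal[vasc, 0]))
        assert np.median(stress.principal[cort, 0]) > 0

    def test_uniform_swelling_area_ratio(self, coarse_mesh, ref_materials):
        s = 0.3
        _, field = _uniform_swelling_solution(coarse_mesh, ref_materials, s)
        change = regional_area_change(coarse_mesh, field)
        for rec in change.values():
            assert rec["dry_over_wet"] == pytest.approx(1 - s, abs=1e-6)

    def test_isolated_free_region_shrinks_to_one_minus_s(self, rect_mesh,
                                                         ref_materials):
        """Definition of the intrinsic swelling factor on a detached region."""
        s = 0.46
        problem = SwellingProblem(rect_mesh, ref_materials.with_swelling(
            {r: s for r in REGIONS}), 0.0)
        # pin only rigid-body modes
        i0 = int(np.argmin(np.sum(rect_mesh.nodes ** 2, axis=1)))
        i1 = int(np.argmax(rect_mesh.nodes[:, 0]))
        problem.set_boundary_displacement(
            np.array([2 * i0, 2 * i0 + 1, 2 * i1 + 1]),
            np.array([(np.sqrt(1 - s) - 1) * rect_mesh.nodes[i0, 0], 0.0, 0.0]))
        change = regional_area_change(rect_mesh, problem.solve())
        assert change["cortex"]["dry_over_wet"] == pytest.approx(1 - s, abs=1e-6)

    def test_vasculature_expands_least(self, ref_mesh, ref_solution):
        change = regional_area_change(ref_mesh, ref_solution)
        vasc = change["vasculature"]["wet_over_dry"]
        for name in ("cortex", "side", "podium"):
            assert vasc < change[name]["wet_over_dry"]

    def test_lower_cortex_displaces_more_than_vasculature(self, ref_mesh,
                                                          ref_solution):
        """Radial motion relative to the podium centre, dry vs wet."""
        mesh = ref_mesh
        centre = mesh.nodes[int(np.argmax(mesh.nodes[:, 1]))]
        u_rel = ref_solution.u - ref_solution.u[
            int(np.argmax(mesh.nodes[:, 1]))]
        cort = mesh.region_id == mesh.region_names.index("cortex")
        vasc = mesh.region_id == mesh.region_names.index("vasculature")
        lower = mesh.nodes[:, 1] < 100.0
        nodes_cort = np.unique(mesh.triangles[cort])
        nodes_vasc = np.unique(mesh.triangles[vasc])
        nodes_cort = nodes_cort[mesh.nodes[nodes_cort, 1] < 100.0]
        nodes_vasc = nodes_vasc[mesh.nodes[nodes_vasc, 1] < 100.0]
        rad_cort = np.abs(u_rel[nodes_cort, 0]).mean()
        rad_vasc = np.abs(u_rel[nodes_vasc, 0]).mean()
        assert rad_cort > rad_vasc


class TestSubstitutions:
    def test_identity_mapping_changes_nothing(self, ref_materials):
        assert substitute_materials(
            ref_materials, {r: r for r in REGIONS}) == ref_materials

    def test_unknown_region_rejected(self, ref_materials):
        with pytest.raises(ValueError):
            substitute_materials(ref_materials, {"pith": "cortex"})

    def test_vasculature_and_podium_to_side_inverts_the_actuator(
            self, ref_domain, ref_materials):
        mat = substitute_materials(ref_materials,
                                   {"vasculature": "side", "podium": "side"})
        state = solve_reference_state(materials=mat, domain=ref_domain,
                                      target_edge=4.0)
        assert state.theta < 0

    def test_podium_to_vasculature_exceeds_reference(self, ref_domain,
                                                     ref_materials):
        ref = solve_reference_state(domain=ref_domain, target_edge=4.0)
        mat = substitute_materials(ref_materials, {"podium": "vasculature"})
        state = solve_reference_state(materials=mat, domain=ref_domain,
                                      target_edge=4.0)
        assert state.theta > ref.theta

    def test_swelling_sensitivity_sign_structure(self, ref_domain, ref_geometry):
        """More swelling in cortex/side opens; in vasculature/podium closes."""
        base = MaterialParams()
        ref = solve_reference_state(domain=ref_domain, target_edge=4.0).theta
        for attr, sign in [("s_cort", +1), ("s_side", +1),
                           ("s_vasc", -1), ("s_pod", -1)]:
            bumped = base.replace(**{attr: getattr(base, attr) * 1.05})
            theta = solve_reference_state(materials=bumped, domain=ref_domain,
                                          target_edge=4.0).theta
            assert np.sign(theta - ref) == sign
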