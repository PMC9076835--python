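import numpy as np
import pytest

from pappus.fem import SwellingProblem
from pappus.geometry import build_reference_geometry
from pappus.mesh import mesh_domain
from pappus.params import GeometryParams, MaterialParams


@pytest.fixture(scope="session")
def ref_geometry():
    return GeometryParams()


@pytest.fixture(scope="session")
def ref_materials():
    return MaterialParams()


@pytest.fixture(scope="session")
def ref_domain(ref_geometry):
    return build_reference_geometry(ref_geometry)


@pytest.fixture(scope="session")
def coarse_mesh(ref_domain):
    """Half-model mesh at 6 μm: fast, adequate for invariant checks."""
    return mesh_domain(ref_domain, target_edge=6.0, half_model=True)


@pytest.fixture(scope="session")
def ref_mesh(ref_domain):
    """Half-model mesh at the default 3 μm resolution."""
    return mesh_domain(ref_domain, target_edge=3.0, half_model=True)


@pytest.fixture(scope="session")
def ref_problem(ref_mesh, ref_materials, ref_geometry, ref_domain):
    return SwellingProblem(ref_mesh, ref_materials, ref_geometry.d_vasc,
                           domain=ref_domain)


@pytest.fixture(scope="session")
def ref_solution(ref_problem):
    return ref_problem.solve()


def rectangle_domain(width=100.0, height=60.0, region="cortex"):
    """A free-standing single-region rectangle as a PlanarDomain."""
    from shapely.geometry import Polygon, box

    from pappus.geometry import PlanarDomain

    poly = box(0.0, 0.0, width, height)
    return PlanarDomain(
        region_polys={region: [poly]},
        cavity=Polygon(),
        vasc_base_intervals=[],
        theta_top=(width, height),
        theta_bottom=(width, 0.0),
    )


@pytest.fixture(scope="session")
def rect_mesh():
    return mesh_domain(rectangle_domain(), target_edge=5.0, half_model=False)
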