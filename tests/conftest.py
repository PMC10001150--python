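"""Shared fixtures: the default eye geometry and coarse meshes/flows.

Session-scoped so the expensive objects (meshes, Darcy factorizations) are
built once per run.
"""

import numpy as np
import pytest

import eyevit as ev
from eyevit.darcy_flow import calibrate_inflow


@pytest.fixture(scope="session")
def eye_params():
    return ev.LimaconParams(11.0, 1.5, 0.5, 1.0)


@pytest.fixture(scope="session")
def eye_domain(eye_params):
    return ev.build_domain(eye_params)


@pytest.fixture(scope="session")
def sphere_domain():
    return ev.build_domain(ev.LimaconParams(10.0, 0.0, 0.0, 0.0))


@pytest.fixture(scope="session")
def axi_mesh(eye_domain):
    """Axisymmetric profile mesh of the default eye, h = 0.8 mm."""
    return ev.build_mesh(eye_domain, 0.8, "axisymmetric-2d")


@pytest.fixture(scope="session")
def axi_flow(eye_domain, axi_mesh):
    """Calibrated aqueous flow on the axisymmetric mesh."""
    fp = calibrate_inflow(eye_domain, ev.FlowParams())
    return ev.solve_darcy(ev.assemble_darcy(axi_mesh, fp))


@pytest.fixture(scope="session")
def axi_rest_flow(axi_mesh):
    """Zero-inflow (rest) flow on the axisymmetric mesh."""
    return ev.solve_darcy(ev.assemble_darcy(axi_mesh, ev.FlowParams()))


@pytest.fixture(scope="session")
def coarse3d_mesh(eye_domain):
    """Coarse full-3d mesh for structural/consistency checks."""
    return ev.build_mesh(eye_domain, 2.2, "full-3d")


@pytest.fixture(scope="session")
def coarse3d_flow(eye_domain, coarse3d_mesh):
    fp = calibrate_inflow(eye_domain, ev.FlowParams())
    return ev.solve_darcy(ev.assemble_darcy(coarse3d_mesh, fp))


@pytest.fixture(scope="session")
def mid3d_mesh(eye_domain):
    """Medium full-3d mesh (h = 1.25 mm) for quantitative 3d checks."""
    return ev.build_mesh(eye_domain, 1.25, "full-3d")


@pytest.fixture(scope="session")
def mid3d_flow(eye_domain, mid3d_mesh):
    fp = calibrate_inflow(eye_domain, ev.FlowParams())
    return ev.solve_darcy(ev.assemble_darcy(mid3d_mesh, fp))
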