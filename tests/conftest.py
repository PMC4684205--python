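import numpy as np
import pytest

from plesioswim import body_dynamics as bd
from plesioswim import geometry as ge
from plesioswim import stroke as st


@pytest.fixture(scope="session")
def presets():
    return st.load_presets()


@pytest.fixture(scope="session")
def swimmer():
    return ge.build_swimmer()


@pytest.fixture(scope="session")
def sphere_mesh():
    return ge.icosphere(radius=0.45, subdivisions=4)


def make_single_link_body(mesh):
    """Free rigid body (no joints) wrapped as an articulated body."""
    m, com, inertia = mesh.mass_properties()
    link = bd.RigidLink("torso", mesh, m, com, inertia)
    return bd.ArticulatedBody(spec=None, links={"torso": link}, joints={})


@pytest.fixture(scope="session")
def sphere_body(sphere_mesh):
    return make_single_link_body(sphere_mesh)


@pytest.fixture(scope="session")
def box_body():
    return make_single_link_body(ge.box_mesh((0.4, 0.3, 0.2)))
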