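import numpy as np
import pytest
import trimesh

from elbow4d import (
    PhantomSpec,
    TriMesh,
    humeral_osteophyte_for_contact,
    make_phantom,
)


def tri_from(m: trimesh.Trimesh) -> TriMesh:
    return TriMesh(np.asarray(m.vertices), np.asarray(m.faces))


@pytest.fixture(scope="session")
def unit_cube() -> TriMesh:
    """Unit cube occupying [0, 1]^3."""
    box = trimesh.creation.box(extents=(1, 1, 1))
    box.apply_translation([0.5, 0.5, 0.5])
    return tri_from(box)


@pytest.fixture(scope="session")
def sphere10() -> TriMesh:
    """Radius-10 icosphere, 4 subdivisions."""
    return tri_from(trimesh.creation.icosphere(subdivisions=4, radius=10.0))


@pytest.fixture(scope="session")
def clean_phantom():
    """Default phantom: no osteophytes, designed clearance everywhere."""
    return make_phantom()


@pytest.fixture(scope="session")
def osteophyte_spec() -> PhantomSpec:
    """Phantom spec with a flexion-side humeral osteophyte contacting at 120 deg."""
    spec = PhantomSpec()
    spec.osteophytes.append(humeral_osteophyte_for_contact(spec, 120.0))
    return spec


@pytest.fixture(scope="session")
def osteophyte_phantom(osteophyte_spec):
    return make_phantom(osteophyte_spec)
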