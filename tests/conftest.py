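import numpy as np
import pytest
import trimesh

from ventriflow import lv, mitral, overset


@pytest.fixture(scope="session")
def shape_coarse():
    return lv.LVShapeParams(n_circumferential=24, n_longitudinal=16)


@pytest.fixture(scope="session")
def volume_curve():
    return lv.VolumeCurve()


@pytest.fixture(scope="session")
def mesh4d(shape_coarse, volume_curve):
    return lv.build_lv_mesh4d(shape_coarse, volume_curve, 12)


@pytest.fixture(scope="session")
def valve():
    return mitral.build_valve()


@pytest.fixture(scope="session")
def unit_sphere():
    m = trimesh.creation.icosphere(subdivisions=4, radius=1.0)
    return np.asarray(m.vertices, dtype=float), np.asarray(m.faces, dtype=np.int64)


@pytest.fixture(scope="session")
def unit_cube():
    m = trimesh.creation.box(extents=(1.0, 1.0, 1.0))
    v = np.asarray(m.vertices, dtype=float) + 0.5  # corner at origin
    return v, np.asarray(m.faces, dtype=np.int64)


@pytest.fixture
def small_grid():
    return overset.CartesianGrid((-10.0, -10.0, -10.0), 0.5, (40, 40, 40))
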