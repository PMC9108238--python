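import numpy as np
import pytest

from aortamorph.phantom import PhantomSpec, make_tube, make_dissected_phantom


@pytest.fixture(scope="session")
def cylinder():
    """Standard straight-tube phantom: r = 10 mm, L = 100 mm, 64-gon rings."""
    spec = PhantomSpec("straight_tube", radius_mm=10.0, length_mm=100.0)
    mesh, cl = make_tube(spec)
    return spec, mesh, cl


@pytest.fixture(scope="session")
def small_cylinder():
    """Coarser, shorter tube for the more expensive correspondence tests."""
    spec = PhantomSpec("straight_tube", radius_mm=10.0, length_mm=60.0,
                       mesh_density=48)
    mesh, cl = make_tube(spec)
    return spec, mesh, cl


@pytest.fixture(scope="session")
def semicircle_torus():
    spec = PhantomSpec("torus_segment", radius_mm=10.0, bend_radius_mm=50.0,
                       arc_angle_deg=180.0)
    mesh, cl = make_tube(spec)
    return spec, mesh, cl


@pytest.fixture(scope="session")
def arch():
    """Asymmetric straight-arc-straight tube (identifiable under rotation)."""
    spec = PhantomSpec("composite_arch", radius_mm=10.0, length_mm=60.0,
                       bend_radius_mm=50.0, arc_angle_deg=120.0)
    mesh, cl = make_tube(spec)
    return spec, mesh, cl


@pytest.fixture(scope="session")
def dissected():
    spec = PhantomSpec("dissected_segment", radius_mm=10.0, length_mm=100.0,
                       septum_fraction=0.3, tear_arclengths_mm=[80.0, 20.0])
    tl, fl, cl, tears = make_dissected_phantom(spec)
    return spec, tl, fl, cl, tears


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
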