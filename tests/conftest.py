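import numpy as np
import pytest

import simplexseg as S


@pytest.fixture(scope="session")
def sphere_study():
    """Reference sphere phantom (64 cubed, radius 20, noise 10, seed 42) with
    its preprocessing products."""
    spec = S.PhantomSpec(shape="sphere", size=64, radius=20.0, noise_sigma=10.0, rng_seed=42)
    vol, truth = S.make_phantom(spec)
    images = S.compute_derived_images(vol)
    return spec, vol, truth, images


@pytest.fixture(scope="session")
def lobed_study():
    """Reference lobed phantom (72 cubed grid so the protrusion fits) with
    preprocessing products, keyed by phantom noise seed."""
    out = {}
    for seed in (0, 1, 2):
        spec = S.PhantomSpec(shape="lobed", size=72, radius=18.0, noise_sigma=10.0,
                             rng_seed=seed)
        vol, truth = S.make_phantom(spec)
        images = S.compute_derived_images(vol)
        out[seed] = (spec, vol, truth, images)
    return out


@pytest.fixture()
def unit_sphere_mesh():
    return S.init_simplex_sphere((0.0, 0.0, 0.0), 10.0, level=2)


def random_neighbor_triangle(rng, scale=5.0):
    """A non-degenerate triangle plus interior projection point and weights."""
    while True:
        tri = rng.normal(size=(3, 3)) * rng.uniform(0.5, scale)
        area = 0.5 * np.linalg.norm(np.cross(tri[1] - tri[0], tri[2] - tri[0]))
        if area > 1e-3:
            return tri
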