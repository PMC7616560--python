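import numpy as np
import pytest

from fbsem.priors import _shift, _valid_mask, neighbourhood_8

from fbsem import (
    build_system,
    default_geometry,
    make_base_phantom,
    add_lesions,
    sample_poisson,
    scale_to_counts,
)


def random_symmetric_weights(shape, seed):
    """Random positive neighbourhood weights with w_jb == w_bj."""
    offsets = neighbourhood_8()
    rng = np.random.default_rng(seed)
    w = np.stack(
        [rng.uniform(0.2, 1.5, shape) * _valid_mask(shape, di, dj) for di, dj in offsets]
    )
    rev = {o: k for k, o in enumerate(offsets)}
    return np.stack(
        [
            0.5 * (w[k] + _shift(w[rev[(-di, -dj)]], di, dj)) * _valid_mask(shape, di, dj)
            for k, (di, dj) in enumerate(offsets)
        ]
    )


@pytest.fixture(scope="session")
def phantom32():
    sample = make_base_phantom(32, 2.08, seed=5)
    return add_lesions(sample, n_lesions=4, radius_range_mm=(3, 8), seed=6)


@pytest.fixture(scope="session")
def model32(phantom32):
    geom = default_geometry(32, 2.08, n_subsets=4)
    return build_system(geom, phantom32.mumap, n_subsets=4)


@pytest.fixture(scope="session")
def problem32(phantom32, model32):
    """A scaled phantom with its noisy low-dose sinogram (fixed seed)."""
    x, bbar = scale_to_counts(model32, phantom32.activity, 6e4, randoms_fraction=0.2)
    sino = sample_poisson(model32, x, bbar, seed=7)
    return x, bbar, sino


@pytest.fixture(scope="session")
def toy16():
    """A tiny single-subset problem: smooth blob on a 16x16 grid."""
    size = 16
    c = (np.arange(size) + 0.5) - size / 2
    yy, xx = np.meshgrid(c, c, indexing="ij")
    activity = 2.0 * np.exp(-(yy**2 + xx**2) / 18.0) + 0.2 * ((yy**2 + xx**2) < 40)
    geom = default_geometry(size, 2.08, n_subsets=1)
    model = build_system(geom, None, n_subsets=1)
    x, bbar = scale_to_counts(model, __import__("fbsem").EmissionImage(activity, 2.08), 2e4, 0.2)
    sino = sample_poisson(model, x, bbar, seed=11)
    return model, x, bbar, sino
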