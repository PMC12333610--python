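import numpy as np
import pytest

from progplan.phantom import GridSpec, Phantom, PhantomConfig, build_phantom


@pytest.fixture(scope="session")
def small_phantom() -> Phantom:
    """Coarse (8 mm) version of the synthetic thorax for fast unit tests."""
    cfg = PhantomConfig(grid_shape=(36, 28, 24), grid_spacing_mm=(8.0, 8.0, 8.0))
    return build_phantom(cfg, seed=7)


@pytest.fixture()
def flat_phantom() -> Phantom:
    """Tiny single-slab phantom with hand-placed ROIs for objective tests."""
    grid = GridSpec((10, 10, 5), (4.0, 4.0, 4.0))
    ph = Phantom(grid=grid, density=np.ones(grid.shape))
    body = np.ones(grid.shape, dtype=bool)
    roi = np.zeros(grid.shape, dtype=bool)
    roi[3:7, 3:7, 1:4] = True
    ptv = np.zeros(grid.shape, dtype=bool)
    ptv[4:6, 4:6, 2] = True
    ph.add_structure("body", body)
    ph.add_structure("roi", roi)
    ph.add_structure("ptv", ptv)
    return ph


def random_doses(rng: np.random.Generator, n: int, lo=0.0, hi=7000.0) -> np.ndarray:
    return rng.uniform(lo, hi, size=n)
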