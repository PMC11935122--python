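import numpy as np
import pytest

from stedqc.phantom import PhantomParams, generate_phantom


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_phantom():
    """A 128 px phantom with tubes and one sheet, shared across read-only tests."""
    return generate_phantom(PhantomParams(
        height_px=128, width_px=128, n_seed_nodes=15, n_sheets=1,
        sheet_area_px_range=(150, 400), rng_seed=7))


def draw_stroke(shape, p0, p1, half_width):
    """Binary constant-width stroke between two points (test helper)."""
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    (r0, c0), (r1, c1) = p0, p1
    dr, dc = r1 - r0, c1 - c0
    L2 = dr * dr + dc * dc
    if L2 == 0:
        dist = np.hypot(rr - r0, cc - c0)
    else:
        t = np.clip(((rr - r0) * dr + (cc - c0) * dc) / L2, 0, 1)
        dist = np.hypot(rr - (r0 + t * dr), cc - (c0 + t * dc))
    return dist <= half_width
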