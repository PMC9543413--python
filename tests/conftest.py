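import numpy as np
import pytest

from fearcf.constants import MASS_H, MASS_O, TIP3P


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)


def make_random_dimer(rng, n=1):
    """Physically plausible random water-dimer geometries (n, 6, 3):
    equilibrium internal geometry, random orientations, O-O 2.5-5.5 Å."""
    th = np.deg2rad(TIP3P["theta0_deg"])
    r0 = TIP3P["r0"]
    base = np.array([[0.0, 0.0, 0.0],
                     [r0, 0.0, 0.0],
                     [r0 * np.cos(th), r0 * np.sin(th), 0.0]])

    def rot(rng):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        return np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])

    out = np.empty((n, 6, 3))
    for i in range(n):
        w1 = base @ rot(rng).T
        sep = 2.5 + 3.0 * rng.random()
        w2 = base @ rot(rng).T + np.array([sep, 0.0, 0.0])
        out[i, :3] = w1
        out[i, 3:] = w2
    return out


@pytest.fixture
def random_dimers(rng):
    return make_random_dimer(rng, 64)


WATER_MASSES = np.array([MASS_O, MASS_H, MASS_H])
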