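import numpy as np
import pytest

from flexor.fixtures import ideal_helix, two_helix_dimer
from flexor.structure_io import add_polar_hydrogens


@pytest.fixture(scope="session")
def helix20():
    return ideal_helix(20)


@pytest.fixture(scope="session")
def helix20_h():
    return add_polar_hydrogens(ideal_helix(20))


@pytest.fixture(scope="session")
def dimer():
    return two_helix_dimer(0)


@pytest.fixture(scope="session")
def dimer_h():
    return add_polar_hydrogens(two_helix_dimer(0))


def generic_bar_matrix(g, rng: np.random.Generator) -> np.ndarray:
    """Numeric oracle: bar matrix of a random generic realization of a
    body-bar graph.  Each bar is a line segment between random points fixed
    in its two bodies; the row constrains the relative velocity of the
    endpoints along the bar direction.  Independent of the pebble-game
    implementation."""
    centers = rng.normal(0.0, 10.0, (g.n_bodies, 3))
    rows = []
    for (u, v), mult in g.edges.items():
        for _ in range(mult):
            pu = centers[u] + rng.normal(0.0, 2.0, 3)
            pv = centers[v] + rng.normal(0.0, 2.0, 3)
            direction = pv - pu
            uvec = direction / np.linalg.norm(direction)
            ru, rv = pu - centers[u], pv - centers[v]
            row = np.zeros(6 * g.n_bodies)
            row[6 * u:6 * u + 3] = -uvec
            row[6 * u + 3:6 * u + 6] = -np.cross(ru, uvec)
            row[6 * v:6 * v + 3] = uvec
            row[6 * v + 3:6 * v + 6] = np.cross(rv, uvec)
            rows.append(row)
    if not rows:
        return np.zeros((0, 6 * g.n_bodies))
    return np.array(rows)


def generic_rank(g, rng: np.random.Generator) -> int:
    m = generic_bar_matrix(g, rng)
    return int(np.linalg.matrix_rank(m, tol=1e-8)) if m.size else 0
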