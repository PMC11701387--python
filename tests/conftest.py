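import numpy as np
import pytest

from depcorr.feasibility import rho2y_bounds


def random_feasible_triplets(rng, size, margin=0.05, n_range=(10, 500)):
    """Random (r1y, r2y, r12, n) strictly inside the feasibility region.

    r12 and r1y are uniform on (-0.95, 0.95); r2y is uniform on the
    admissible open interval shrunk by ``margin`` of its width, keeping the
    correlation matrix comfortably positive definite.
    """
    out = []
    while len(out) < size:
        r12 = rng.uniform(-0.95, 0.95)
        r1y = rng.uniform(-0.95, 0.95)
        lo, hi = rho2y_bounds(r12, r1y)
        width = hi - lo
        r2y = rng.uniform(lo + margin * width, hi - margin * width)
        if abs(r2y) >= 0.999:
            continue
        n = int(rng.integers(*n_range))
        out.append((r1y, r2y, r12, n))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20240612)


@pytest.fixture(scope="session")
def feasible_triplets():
    return random_feasible_triplets(np.random.default_rng(11), 1000)
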