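import numpy as np
import pytest

from dtplan.synth import Cylinder, Ellipsoid, SyntheticPhantomSpec, make_phantom


@pytest.fixture(scope="session")
def concentric_phantom():
    """Target sphere r=20 with a concentric OAR sphere r=10, 2 mm grid."""
    spec = SyntheticPhantomSpec(
        grid_shape=(50, 50, 50),
        spacing_mm=(2.0, 2.0, 2.0),
        target=("target", Ellipsoid((0, 0, 0), (20, 20, 20))),
        oars=[("oar", Ellipsoid((0, 0, 0), (10, 10, 10)), "parallel")],
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def displaced_phantom():
    """Equal 10 mm spheres separated by 50 mm along x."""
    spec = SyntheticPhantomSpec(
        grid_shape=(80, 40, 40),
        spacing_mm=(2.0, 2.0, 2.0),
        target=("target", Ellipsoid((0, 0, 0), (10, 10, 10))),
        oars=[("oar", Ellipsoid((50, 0, 0), (10, 10, 10)), "parallel")],
    )
    return make_phantom(spec)


@pytest.fixture(scope="session")
def hn_phantom():
    from dtplan.synth import default_hn_spec

    return make_phantom(default_hn_spec())


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)


def brute_force_min_path_cost(cost, excluded, max_step):
    """Independent column-DP oracle for the minimum path cost (inf when
    infeasible).  Plain-python, no shared code with the A* implementation."""
    n_col, n_row = cost.shape
    INF = float("inf")
    prev = [float(cost[0, r]) if not excluded[0, r] else INF for r in range(n_row)]
    for c in range(1, n_col):
        cur = [INF] * n_row
        for r in range(n_row):
            if excluded[c, r]:
                continue
            lo, hi = max(0, r - max_step), min(n_row, r + max_step + 1)
            best = min(prev[lo:hi])
            if best < INF:
                cur[r] = best + float(cost[c, r])
        prev = cur
    return min(prev)
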