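import numpy as np
import pytest

import stoichswitch as sw


@pytest.fixture(scope="session")
def params3():
    """Two-stable-equilibria bistability configuration (K in (K4, K2))."""
    return sw.SECTION3


@pytest.fixture(scope="session")
def params4():
    """Cycle/equilibrium bistability configuration (K in (K2, K3))."""
    return sw.SECTION4


@pytest.fixture(scope="session")
def interior3(params3):
    return sw.interior_equilibria(params3)


@pytest.fixture(scope="session")
def saddle3(interior3):
    return next(eq for eq in interior3 if eq.stability == "saddle")


@pytest.fixture(scope="session")
def stable3(interior3):
    """(E2, E4): the two stable coexistence equilibria, sorted by x."""
    return tuple(sorted((eq for eq in interior3 if eq.stability == "stable"),
                        key=lambda e: e.x))


@pytest.fixture(scope="session")
def separatrix3(saddle3, params3):
    return sw.stable_manifold(saddle3, params3)


@pytest.fixture(scope="session")
def attractors3(stable3):
    E2, E4 = stable3
    return {"basin_A": E2.location, "basin_B": E4.location}


@pytest.fixture(scope="session")
def focus4(params4):
    """The unstable interior focus on l1 that the limit cycle surrounds."""
    return next(eq for eq in sw.interior_equilibria(params4)
                if eq.branch == "l1" and eq.stability == "unstable")


@pytest.fixture(scope="session")
def cycle4(params4, focus4):
    return sw.find_limit_cycle(params4, focus4)


@pytest.fixture(scope="session")
def cssf4(cycle4, params4):
    return sw.cycle_ssf(cycle4, params4)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


def random_omega_points(params, n, rng):
    """Uniform draws from the invariant trapezoid Omega (rejection)."""
    pts = []
    while len(pts) < n:
        cand = np.column_stack([
            rng.uniform(1e-3, params.K - 1e-3, 2 * n),
            rng.uniform(1e-3, params.p - 1e-3, 2 * n),
        ])
        ok = params.q * cand[:, 0] + params.theta * cand[:, 1] < params.P_total
        pts.extend(cand[ok])
    return np.array(pts[:n])
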