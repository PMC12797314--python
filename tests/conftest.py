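import numpy as np
import pytest

import cactipm as c

#: dominant eigenvalue of [[0.8, 0.45], [0.2, 0.5]] = (trace + sqrt(trace^2 - 4 det)) / 2
LAMBDA_2X2 = (1.3 + np.sqrt(0.45)) / 2.0


@pytest.fixture(scope="session")
def default_params():
    return c.SimulationParams()


@pytest.fixture(scope="session")
def grid200():
    return c.make_grid(0.0, 70.0, 200)


@pytest.fixture(scope="session")
def true_vrs(default_params, grid200):
    return c.true_vital_rate_set(default_params, grid200)


def constant_rate_set(
    grid,
    s=0.9,
    p_b=1.0,
    b=1.0,
    r=0.2,
    u=0.5,
    p_r=0.1,
    G_u=None,
    G_r=None,
    c_mass=None,
):
    """Size-independent vital rates on an arbitrary grid (identity growth)."""
    n = grid.n
    eye = np.eye(n)
    cm = np.zeros(n)
    cm[0] = 1.0
    return c.VitalRateSet(
        grid=grid,
        s=np.full(n, s),
        p_b=np.full(n, p_b),
        b=np.full(n, b),
        r=np.full(n, r),
        u=np.full(n, u),
        G_u=eye.copy() if G_u is None else G_u,
        G_r=eye.copy() if G_r is None else G_r,
        c=cm if c_mass is None else c_mass,
        p_r=p_r,
    )


@pytest.fixture()
def two_state_2x2():
    """N = 1 grid whose megamatrix collapses to [[0.8, 0.45], [0.2, 0.5]]."""
    grid = c.make_grid(0.0, 70.0, 1)
    vrs = constant_rate_set(grid, s=0.9, p_b=1.0, b=1.0, r=0.2, u=0.5, p_r=0.1)
    return c.build_megamatrix(vrs, grid)


@pytest.fixture(scope="session")
def small_census(default_params):
    """Moderate synthetic census reused across fitting/IO tests."""
    import dataclasses

    params = dataclasses.replace(default_params, n_individuals=150, n_years=20)
    table = c.generate_population(params, seed=7)
    return c.apply_censoring_rule(table)
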