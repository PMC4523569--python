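import numpy as np
import pytest

from shellmodes import find_zeros


@pytest.fixture(scope="session")
def cyl_modes10():
    """First 10 annulus Neumann zeros for the reference case nu=2, gamma=5."""
    return find_zeros("cyl", 2, 5.0, 10)


@pytest.fixture(scope="session")
def sph_modes10():
    """First 10 spherical-shell Neumann zeros for nu=2, gamma=5."""
    return find_zeros("sph", 2, 5.0, 10)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230815)


@pytest.fixture(scope="session")
def mc_comparison():
    """Eigenmode-series K(tau) against 1e5 reflected Brownian walkers,
    gamma=5, both dimensions (shared because the walk is the slow part)."""
    from shellmodes import DiffusionSpec, ShellGeometry
    from shellmodes.diffusion import correlation_function, expansion_coefficients
    from shellmodes.random_walk import correlation_random_walk

    taus = [0.05, 0.2, 1.0]
    out = {}
    for dim, seed in (("cyl", 42), ("sph", 7)):
        expansion = expansion_coefficients(dim, 5.0, 300)
        spec = DiffusionSpec(dim, ShellGeometry(R=1.0, gamma=5.0), D=1.0)
        K = np.asarray(correlation_function(spec, expansion, taus))
        mc = correlation_random_walk(dim, 5.0, taus, n_walkers=100_000, seed=seed)
        out[dim] = (K, mc)
    return out
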