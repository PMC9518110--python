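import numpy as np
import pytest

from stcar import (
    MCMCConfig,
    ModelSpec,
    PanelData,
    PosteriorSamples,
    RegionGraph,
    SpatioTemporalPoissonModel,
    lattice_graph,
)
from stcar.simulate import lattice_scenario, simulate_panel


@pytest.fixture(scope="session")
def path3_graph():
    """Path graph A - B - C."""
    return RegionGraph.from_neighbour_ids({"A": ["B"], "B": ["A", "C"], "C": ["B"]})


@pytest.fixture(scope="session")
def small_panel():
    """3-region path x 4 periods with one covariate, fixed by seed."""
    rng = np.random.default_rng(11)
    g = RegionGraph.from_neighbour_ids({"A": ["B"], "B": ["A", "C"], "C": ["B"]})
    n, Z = 3, 4
    N = np.full((n, Z), 500.0)
    X = rng.normal(size=(n, Z, 1))
    Y = rng.poisson(50.0, size=(n, Z))
    E = N * (Y.sum() / N.sum())
    return PanelData(g, Y, N, E, X, ("x1",))


@pytest.fixture(scope="session")
def type2_fit():
    """One moderately long type II fit on a 3x3 lattice, reused across tests."""
    data, truth = simulate_panel(lattice_scenario(rows=3, cols=3, Z=6, seed=5))
    model = SpatioTemporalPoissonModel(data, ModelSpec(interaction_type="II"))
    res = model.fit(seed=55, n_iter=3000, n_burnin=1000, thin=2, n_chains=2)
    return data, truth, res


def make_samples(alpha, beta, u, v, gamma, psi, **kw):
    """Hand-assemble a PosteriorSamples from (chain, draw, ...) arrays."""
    C, S = np.asarray(alpha).shape[:2]
    ones = np.ones((C, S))
    return PosteriorSamples(
        alpha=np.asarray(alpha, float), beta=np.asarray(beta, float),
        u=np.asarray(u, float), v=np.asarray(v, float),
        gamma=np.asarray(gamma, float), psi=np.asarray(psi, float),
        tau_u=ones.copy(), tau_v=ones.copy(), tau_gamma=ones.copy(),
        tau_psi=ones.copy(), log_post=np.zeros((C, S)), **kw,
    )


@pytest.fixture()
def quick_config():
    return MCMCConfig(n_iter=400, n_burnin=200, thin=2, seed=3, n_chains=1)
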