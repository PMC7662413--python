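import numpy as np
import pytest

import mortsurv as ms
from mortsurv import pipeline as pl
from mortsurv.model import PRECISION_NAMES, PosteriorSamples
from mortsurv.synthetic import _age_grid


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("fixtures")
    pl.make_fixtures(out)
    return out


@pytest.fixture(scope="session")
def small_sim():
    """A 4x4-lattice synthetic dataset with one strong injected anomaly."""
    spec = ms.SimulationSpec(
        rows=4, cols=4, n_age_groups=5, n_years=6, n_deciles=4,
        first_year=2013, anomalies=[(3, 4, 0.5)], seed=7,
    )
    data, truth = ms.simulate_dataset(spec)
    graph = ms.make_lattice_graph(4, 4)
    return spec, data, truth, graph


@pytest.fixture(scope="session")
def small_fit(small_sim):
    """A short but usable MCMC fit of the small synthetic dataset."""
    _, data, _, graph = small_sim
    config = ms.ModelConfig(n_chains=2, burn_in=300, n_iter=250, seed=5)
    return ms.fit(data, graph, config)


def make_posterior(a0, omega=None, I=2, T=2, J=2, D=2, n_chains=1):
    """Hand-built PosteriorSamples for tests that need controlled draws."""
    a0 = np.asarray(a0, dtype=float)
    S = a0.shape[0]
    omega = np.zeros((S, I, T)) if omega is None else np.asarray(omega, float)
    I, T = omega.shape[1:]
    chain = np.repeat(np.arange(n_chains), S // n_chains)
    decile_index = np.arange(I) % D
    return PosteriorSamples(
        a0=a0,
        alpha=np.zeros((S, J)), gamma=np.zeros((S, I)), zeta=np.zeros((S, T)),
        phi=np.zeros((S, D)), omega=omega, delta=np.zeros((S, I, J)),
        kappa=np.zeros((S, J, T)), nu=np.zeros((S, D, T)),
        precisions={p: np.ones(S) for p in PRECISION_NAMES},
        chain=chain, acceptance={},
        area_ids=[f"A{i}" for i in range(I)],
        age_groups=_age_grid(J),
        years=list(range(2012, 2012 + T)),
        decile_index=decile_index, sex="female",
    )
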