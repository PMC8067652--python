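import numpy as np
import pytest

from microlvm import synthetic
from microlvm.data_io import CommunityTable
from microlvm.gllvm import GllvmFit, SamplerConfig, fit_gllvm


@pytest.fixture
def rng():
    return np.random.default_rng(7)


def make_taxa(n, frac_fungi=0.4):
    return synthetic._make_taxa(n, frac_fungi)


def make_fake_fit(beta_draws=None, loading_draws=None, z_draws=None, X=None,
                  covariate_names=None, phi_draws=None, d=None):
    """Assemble a GllvmFit directly from draw arrays (shape (n, ...)) for
    oracle tests of downstream operations that consume posterior draws."""
    if beta_draws is not None:
        n, t, k = beta_draws.shape
    else:
        n, t, _ = loading_draws.shape
        k = 1 if X is None else X.shape[1]
        beta_draws = np.zeros((n, t, k))
    if loading_draws is None:
        dd = d if d is not None else 2
        loading_draws = np.zeros((n, t, dd))
        loading_draws[:, :, 0] = 1e-6
    dd = loading_draws.shape[2]
    if X is None:
        X = np.zeros((4, k))
    s = X.shape[0]
    if z_draws is None:
        z_draws = np.zeros((n, s, dd))
    if phi_draws is None:
        phi_draws = np.ones((n, t))
    if covariate_names is None:
        covariate_names = [f"x{i}" for i in range(k)]
    draws = {
        "alpha": np.zeros((1, n, s)),
        "beta0": np.zeros((1, n, t)),
        "beta": beta_draws[None],
        "loadings": loading_draws[None],
        "z": z_draws[None],
        "phi": phi_draws[None],
    }
    return GllvmFit(draws=draws, n_chains=1, n_draws=n, diagnostics={},
                    model_spec={"family": "negative-binomial", "d": dd},
                    taxa=make_taxa(t), covariate_names=list(covariate_names),
                    site_ids=list(range(s)), X=np.asarray(X, float))


@pytest.fixture(scope="session")
def small_sim():
    """A 43-site x 20-taxon simulated dataset with known ground truth."""
    env, raw = synthetic.simulate_environment(
        43, seed=11, covariates=["elevation", "pH", "TC"])
    truth = synthetic.make_ground_truth(43, 20, 3, d=2, seed=12,
                                        beta_sparsity=0.7, loading_scale=0.6)
    counts = synthetic.simulate_community(env, truth, seed=13)
    return counts, env, truth


@pytest.fixture(scope="session")
def small_fit(small_sim):
    counts, env, _ = small_sim
    return fit_gllvm(counts, env, d=2, seed=14,
                     sampler=SamplerConfig(n_chains=2, n_draws=500, n_warmup=500))


@pytest.fixture
def toy_counts():
    taxa = make_taxa(4)
    counts = np.array([
        [5, 0, 2, 1],
        [3, 1, 0, 4],
        [0, 2, 1, 9],
        [7, 0, 0, 2],
        [1, 0, 3, 0],
        [2, 0, 1, 5],
    ])
    return CommunityTable(counts=counts, site_ids=[f"s{i}" for i in range(6)], taxa=taxa)
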