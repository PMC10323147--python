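import numpy as np
import pytest

from dynblup import GeneticParams, toy_genetic_params


@pytest.fixture
def toy_gp() -> GeneticParams:
    return toy_genetic_params()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def no_plasticity_params(p: int = 2) -> GeneticParams:
    """q = 0 system: plain additive traits with nonadditive noise."""
    Gaa = np.full((p, p), 0.1) + 0.1 * np.eye(p)
    return GeneticParams(
        p=p,
        q=0,
        Gaa=Gaa,
        Gab=np.zeros((p, 0)),
        Gbb=np.zeros((0, 0)),
        sigma_v2=np.full(p, 0.2),
        sigma_eta2=np.zeros((p, 0)),
    )


def random_instance(seed: int, n=None, p=None, q=None):
    """Random small mixed-model instance: dimensions, PSD G, positive
    nonadditive variances, cues, phenotypes and integer fitness."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 21)) if n is None else n
    p = int(rng.integers(1, 3)) if p is None else p
    q = int(rng.integers(0, 3)) if q is None else q
    k = p * (1 + q)
    M = rng.standard_normal((k, k + 2)) * 0.3
    G = M @ M.T + 0.05 * np.eye(k)
    gp = GeneticParams(
        p=p,
        q=q,
        Gaa=G[:p, :p],
        Gab=G[:p, p:],
        Gbb=G[p:, p:],
        sigma_v2=rng.uniform(0.1, 0.5, p),
        sigma_eta2=rng.uniform(0.05, 0.3, (p, q)),
    )
    u = rng.uniform(-2.0, 2.0, q)
    y = rng.standard_normal((n, p))
    W = rng.integers(0, 5, n)
    if W.sum() == 0:
        W[0] = 1
    w = W / W.mean()
    return gp, u, y, w
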