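import numpy as np
import pytest

from chromperc import degree_model as dm

# Excess-mean matrix of the three-community network with a small bridging
# atom (alpha = 0.1), as used across the criticality tests.  Strongly
# diagonally dominant, primitive, with a single valid phase transition.
BRIDGED_M = np.array([
    [2.4, 0.1, 0.02],
    [0.04, 1.4, 0.02],
    [0.04, 0.1, 4.71],
])

# Diagonal excess-mean matrix of the fully disjoint (alpha = 0) variant:
# three transitions at p = 1/5, 2/5, 2/3.
DISJOINT_M = np.diag([2.5, 1.5, 5.0])


@pytest.fixture(scope="session")
def coupled():
    """Three-colour network u(k) ∝ Poiss(3k1+2k2+4k3, 3), k != 0 — the
    near-critical worked example."""
    return dm.tabulate("coupled_poisson", truncation_tol=1e-12)


@pytest.fixture(scope="session")
def coupled_moments(coupled):
    return dm.moments(coupled)


@pytest.fixture(scope="session")
def modular0():
    """Three disjoint Poisson communities (rates 1.5, 2.5, 5)."""
    return dm.tabulate("modular_poisson", alpha=0.0)


@pytest.fixture(scope="session")
def modular01():
    """Same communities bridged by an atom of weight 0.1 at (1,1,1)."""
    return dm.tabulate("modular_poisson", alpha=0.1)


@pytest.fixture(scope="session")
def two_colour_mixture():
    """Small subcritical two-colour table with mixed colours."""
    counts = np.array([[0, 0], [1, 0], [0, 1], [1, 1], [2, 1],
                       [0, 2], [2, 0], [1, 2]])
    probs = np.array([0.25, 0.2, 0.2, 0.1, 0.08, 0.07, 0.06, 0.04])
    return dm.DegreeDistribution(counts, probs / probs.sum())


def poisson_dist(lam, tol=1e-14):
    return dm.tabulate("poisson", rates=[lam], truncation_tol=tol)


def random_summary(rng, n=3, rho=None):
    """Random valid moment summary: nonnegative M (optionally rescaled to
    spectral radius rho) with random PSD T_i and positive mu0."""
    M = rng.random((n, n)) + 0.2 * np.eye(n)
    if rho is not None:
        M *= rho / np.abs(np.linalg.eigvals(M)).max()
    T = np.empty((n, n, n))
    for i in range(n):
        A = rng.standard_normal((n, n))
        T[i] = A @ A.T + 0.3 * np.eye(n)
    mu0 = rng.random(n) + 0.3
    return dm.MomentSummary(mu0, M, T)
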